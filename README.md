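# morphpair

Matched-pair voxel-based morphometry at desk scale: seeded synthetic
multi-site cohorts of Jacobian-determinant volumes, reading-disability
profile classification, coarsened + propensity-score case-control matching,
TFCE permutation inference with familywise-error correction, matching-quality
bootstraps, and residualization-bias simulations.

## What's inside

| module | role |
| --- | --- |
| `morphpair.synthio` | synthetic phenotype tables and 3-D Jacobian volumes: site offsets, brain-size coupling, smooth noise, focal case expansion in ellipsoidal effect regions; NIfTI/CSV/YAML I/O |
| `morphpair.profiles` | deterministic expert rule classifier (percentile thresholds), leave-one-out cross-validated vote ensemble (500 trees, 2 features/split), permutation variable importance, Cronbach's alpha, classical MDS of class probabilities, per-dimension ANOVA + Tukey |
| `morphpair.matching` | site × brain-size median-split strata, logistic propensity scores (penalized fallback on separation), greedy/optimal unique nearest-neighbor pairing, random pairing, balance diagnostics (paired t, Yates chi-square, propensity tests) |
| `morphpair.vbm` | residualization, pair differences, one/two-sample t maps, TFCE (numba union-find + scipy engine), sign-flip / label-permutation max-TFCE FWE, Cohen's d maps, cluster tables, ROI means, Freedman–Lane covariate control, Pearson r |
| `morphpair.bootstrap` | B well-matched vs B randomly matched re-pairings of the same subjects; pooled cluster t distributions and balance checks |
| `morphpair.bias_sim` | scalar and voxelwise simulations of bias from residualizing a nuisance collinear with case status, vs matching first |
| `morphpair.pipeline` | end-to-end orchestration with manifest, report, and stage-tagged errors |

## CLI

```bash
morphpair simulate --out data/ --seed 1 --amplitude 0.05
morphpair classify --phenotypes data/phenotypes.csv --out cls/
morphpair match    --phenotypes data/phenotypes.csv --out match/
morphpair vbm      --phenotypes data/phenotypes.csv --pairs match/pairs.csv \
                   --volumes data/volumes --out vbm/ --perms 1000 --seed 1 \
                   --tfce-h 2 --tfce-e 0.5 --alpha 0.05
morphpair bootstrap --phenotypes data/phenotypes.csv --volumes data/volumes \
                    --out boot/ -b 100
morphpair bias-sim --out bias.json
morphpair run-all  --out run/ --perms 500 -b 50 --seed 1
```

`run-all` with no inputs generates a synthetic cohort, then runs
classification → matching → paired + unpaired voxel inference → bootstrap →
covariate control, writing CSV/JSON tables, NIfTI maps, a markdown report,
and a `manifest.json` with seeds and a parameter hash.

## Python API sketch

```python
from morphpair import synthio, matching, vbm

cfg = synthio.CohortConfig(seed=1)
subjects = synthio.generate_cohort(cfg)
volumes = synthio.generate_volumes(subjects, synthio.default_regions(cfg, 0.05), cfg)

strata = matching.stratify(subjects)
model = matching.fit_propensity(subjects)
pairs = matching.pair_nearest(strata, model, subjects)

adj = vbm.residualize(volumes.data, model.scores.loc[volumes.ids].to_numpy())
diffs = vbm.pair_differences(adj, pairs.pairs, volumes.ids)
result = vbm.permutation_fwe(diffs, design="sign_flip", mask=volumes.mask,
                             n_perm=1000, seed=1)
clusters = vbm.extract_clusters(result.p_corrected, result.t_map.data,
                                mask=volumes.mask, affine=volumes.affine)
```

## Notes

- Everything stochastic is driven by explicit seeds; identical seeds give
  byte-identical cohorts, volumes, pairings, and permutation results.
- The smoothed noise field is rescaled so its voxel SD equals `noise_sd`
  exactly, making effect sizes calibratable: an injected amplitude `a` yields
  paired Cohen's d ≈ `a / (noise_sd * sqrt(2))`.
- TFCE enhances the positive tail only; test the opposite tail by negating
  the input. With ≤12 difference volumes the sign-flip null is enumerated
  exhaustively.
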