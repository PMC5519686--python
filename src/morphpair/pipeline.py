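"""End-to-end orchestration: classification -> matching -> voxel inference ->
bootstrap -> covariate control, with a manifest and a readable report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstrap as bootstrap_mod
from . import matching, profiles, synthio, vbm
from .vbm.tfce import TfceParams

__all__ = ["RunConfig", "StageError", "run_all", "make_report"]

log = logging.getLogger("morphpair")

STAGES = ("profiles", "matching", "vbm_paired", "vbm_unpaired",
          "bootstrap", "covariate_control")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, output directory, and per-stage parameters of one run."""

    out_dir: str = "morphpair_out"
    phenotype_csv: str | None = None     # if None, generate synthetically
    volume_dir: str | None = None
    cohort: synthio.CohortConfig = field(default_factory=synthio.CohortConfig)
    effect_amplitude: float = 0.05
    n_perm: int = 1000
    bootstrap_B: int = 100
    bootstrap_t_threshold: float = 2.87
    tfce: TfceParams = field(default_factory=TfceParams)
    alpha: float = 0.05
    ensemble_trees: int = 500
    ensemble_mtry: int = 2
    seed: int = 0

    def params_hash(self) -> str:
        """Hash of the analysis parameters; file-system paths are excluded."""
        params = dataclasses.asdict(self)
        for key in ("out_dir", "phenotype_csv", "volume_dir"):
            params.pop(key, None)
        payload = json.dumps(_serializable(params), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _serializable(obj):
    if isinstance(obj, dict):
        return {str(k): _serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _stage(manifest, name, fn):
    t0 = time.time()
    log.info("stage %s: start", name)
    try:
        out = fn()
    except Exception as exc:
        manifest["stages"][name] = {"status": "failed", "error": str(exc),
                                    "seconds": round(time.time() - t0, 2)}
        raise StageError(name, exc) from exc
    manifest["stages"][name] = {"status": "complete",
                                "seconds": round(time.time() - t0, 2)}
    log.info("stage %s: done in %.1fs", name, time.time() - t0)
    return out


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the in-memory bundle and writes outputs.

    Stage order mirrors the analysis design: profile classification, pair
    matching, paired + unpaired voxel inference, matching-quality bootstrap,
    and covariate control for the behavioral-space dimensions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = {
        "version": __import__("morphpair").__version__,
        "seed": config.seed,
        "params_hash": config.params_hash(),
        "stages": {},
    }
    bundle = {"manifest": manifest}

    # ---- inputs -----------------------------------------------------------
    if config.phenotype_csv is None:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        subjects = synthio.generate_cohort(cohort_cfg)
        regions = synthio.default_regions(cohort_cfg, amplitude=config.effect_amplitude)
        volumes = synthio.generate_volumes(subjects, regions, cohort_cfg)
        synthio.write_phenotypes(subjects, out / "phenotypes.csv")
    else:
        subjects = synthio.read_phenotypes(config.phenotype_csv)
        if config.volume_dir is None:
            raise ValueError("volume_dir is required with phenotype_csv")
        volumes = synthio.VolumeSet.from_dir(config.volume_dir,
                                             list(subjects["subject_id"]))
    bundle["subjects"] = subjects
    bundle["volumes"] = volumes
    frame = subjects.set_index("subject_id", drop=False)

    # ---- stage 1: profiles ------------------------------------------------
    def stage_profiles():
        labels = profiles.classify_cohort(frame)
        pred, acc, prob = profiles.classify_ensemble_loocv(
            frame, labels, n_trees=config.ensemble_trees,
            mtry=config.ensemble_mtry,
            seed=int(rng.integers(2 ** 31)))
        dims = profiles.classical_mds(prob, k=2)
        codes = {lab: i for i, lab in enumerate(profiles.CLASS_ORDER)}
        reliability = profiles.cronbach_alpha(np.column_stack([
            [codes[l] for l in labels], [codes[p] for p in pred]]))
        labels.to_frame().assign(predicted=pred).to_csv(out / "labels.csv")
        prob.to_csv(out / "probabilities.csv")
        dims.coords.to_csv(out / "dimensions.csv")
        return {"labels": labels, "predicted": pred, "accuracy": acc,
                "probabilities": prob, "dimensions": dims,
                "reliability": reliability}
    bundle["profiles"] = _stage(manifest, "profiles", stage_profiles)

    # ---- stage 2: matching ------------------------------------------------
    def stage_matching():
        strata = matching.stratify(subjects)
        model = matching.fit_propensity(subjects)
        pairs = matching.pair_nearest(strata, model, subjects)
        case_profiles = bundle["profiles"]["labels"].reindex(
            frame.index).loc[pairs.pairs["case_id"]]
        balance = matching.balance_diagnostics(pairs, subjects, model,
                                               case_profiles)
        pairs.to_csv(out / "pairs.csv")
        (out / "balance.json").write_text(json.dumps(
            _serializable(balance.entries), indent=2, default=str))
        return {"strata": strata, "model": model, "pairs": pairs,
                "balance": balance}
    bundle["matching"] = _stage(manifest, "matching", stage_matching)

    # ---- stage 3: paired voxel inference ---------------------------------
    def stage_vbm_paired():
        model = bundle["matching"]["model"]
        pairs = bundle["matching"]["pairs"]
        adj = vbm.residualize(volumes.data, model.scores.loc[volumes.ids].to_numpy())
        diffs = vbm.pair_differences(adj, pairs.pairs, volumes.ids)
        res = vbm.permutation_fwe(
            diffs, design="sign_flip", mask=volumes.mask,
            tfce_params=config.tfce, n_perm=config.n_perm,
            seed=int(rng.integers(2 ** 31)))
        clusters = vbm.extract_clusters(
            res.p_corrected, res.t_map.data, mask=volumes.mask,
            alpha=config.alpha, connectivity=config.tfce.connectivity,
            affine=volumes.affine)
        d_paired, d_unpaired, d_summary = vbm.cohens_d_maps(
            adj, pairs.pairs, volumes.ids,
            frame.loc[volumes.ids, "is_case"], mask=volumes.mask)
        clusters.to_csv(out / "clusters_paired.csv", index=False)
        _save_map(res.t_map.data, volumes, out / "t_paired.nii")
        _save_map(res.p_corrected, volumes, out / "p_paired.nii")

        subgroup = {}
        labels = bundle["profiles"]["labels"].reindex(frame.index)
        for _, row in clusters.iterrows():
            roi = _cluster_mask(res.p_corrected, volumes.mask, config.alpha,
                                config.tfce.connectivity, int(row["label"]))
            roi_diffs = vbm.roi_mean(diffs, roi)
            per_profile = {"all": _one_sample_summary(roi_diffs)}
            case_profile = labels.loc[pairs.pairs["case_id"]].to_numpy()
            for prof in pd.unique(case_profile):
                sel = case_profile == prof
                if sel.sum() >= 2:
                    per_profile[prof] = _one_sample_summary(roi_diffs[sel])
            subgroup[int(row["label"])] = per_profile
        return {"adjusted": adj, "diffs": diffs, "result": res,
                "clusters": clusters, "d_paired": d_paired,
                "d_unpaired": d_unpaired, "d_summary": d_summary,
                "subgroup_t": subgroup}
    bundle["vbm_paired"] = _stage(manifest, "vbm_paired", stage_vbm_paired)

    # ---- stage 4: unpaired comparison ------------------------------------
    def stage_vbm_unpaired():
        adj = bundle["vbm_paired"]["adjusted"]
        flags = frame.loc[volumes.ids, "is_case"].to_numpy()
        res = vbm.permutation_fwe(
            adj, design="label_perm", labels=flags, mask=volumes.mask,
            tfce_params=config.tfce, n_perm=config.n_perm,
            seed=int(rng.integers(2 ** 31)))
        clusters = vbm.extract_clusters(
            res.p_corrected, res.t_map.data, mask=volumes.mask,
            alpha=config.alpha, connectivity=config.tfce.connectivity,
            affine=volumes.affine)
        clusters.to_csv(out / "clusters_unpaired.csv", index=False)
        return {"result": res, "clusters": clusters}
    bundle["vbm_unpaired"] = _stage(manifest, "vbm_unpaired", stage_vbm_unpaired)

    # ---- stage 5: bootstrap ----------------------------------------------
    def stage_bootstrap():
        adj = bundle["vbm_paired"]["adjusted"]
        clusters = bundle["vbm_paired"]["clusters"]
        res = bundle["vbm_paired"]["result"]
        rois = {}
        for _, row in clusters.iterrows():
            rois[f"cluster_{int(row['label'])}"] = _cluster_mask(
                res.p_corrected, volumes.mask, config.alpha,
                config.tfce.connectivity, int(row["label"]))
        summary = bootstrap_mod.run_bootstrap(
            subjects, adj, volumes.ids, B=config.bootstrap_B,
            seed=int(rng.integers(2 ** 31)), rois=rois,
            t_threshold=config.bootstrap_t_threshold, mask=volumes.mask,
            strata=bundle["matching"]["strata"])
        balance = bootstrap_mod.balance_check_bootstrap(summary)
        (out / "bootstrap_balance.json").write_text(
            json.dumps(_serializable(balance), indent=2))
        pooled_rows = {
            f"{cond}_{name}": vals
            for cond, d in summary.pooled_t.items() for name, vals in d.items()}
        if pooled_rows:
            pd.DataFrame(pooled_rows).to_csv(out / "bootstrap_pooled_t.csv",
                                             index=False)
        _save_map(summary.mean_t["well"], volumes, out / "bootstrap_mean_t_well.nii")
        _save_map(summary.mean_t["random"], volumes,
                  out / "bootstrap_mean_t_random.nii")
        return {"summary": summary, "balance": balance}
    bundle["bootstrap"] = _stage(manifest, "bootstrap", stage_bootstrap)

    # ---- stage 6: covariate control --------------------------------------
    def stage_covariate():
        pairs = bundle["matching"]["pairs"]
        diffs = bundle["vbm_paired"]["diffs"]
        dims = bundle["profiles"]["dimensions"].coords
        results = {}
        for col in dims.columns:
            cov = (dims.loc[pairs.pairs["case_id"], col].to_numpy()
                   - dims.loc[pairs.pairs["control_id"], col].to_numpy())
            res = vbm.covariate_control(
                diffs, cov, mode="intercept", mask=volumes.mask,
                tfce_params=config.tfce, n_perm=config.n_perm,
                seed=int(rng.integers(2 ** 31)))
            results[col] = res
        return results
    bundle["covariate_control"] = _stage(manifest, "covariate_control",
                                         stage_covariate)

    report = make_report(bundle)
    (out / "report.md").write_text(report)
    (out / "manifest.json").write_text(json.dumps(_serializable(manifest),
                                                  indent=2))
    bundle["report"] = report
    return bundle


def _save_map(grid, volumes, path):
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float32),
                             volumes.affine), str(path))


def _cluster_mask(p_map, mask, alpha, connectivity, label):
    from scipy import ndimage

    from .vbm.tfce import _structure
    sig = (p_map < alpha) & mask
    labeled, _ = ndimage.label(sig, structure=_structure(connectivity))
    return labeled == label


def _one_sample_summary(values):
    from scipy import stats as sps
    values = np.asarray(values, dtype=float)
    if values.var(ddof=1) == 0:
        return {"n": int(values.size), "t": 0.0, "p": 1.0}
    t, p = sps.ttest_1samp(values, 0.0)
    return {"n": int(values.size), "t": float(t), "p": float(p)}


def make_report(bundle) -> str:
    """Deterministic human-readable summary of a completed (or partial) run."""
    lines = ["# Matched-pair morphometry report", ""]
    man = bundle.get("manifest", {})
    lines.append(f"seed: {man.get('seed')}  params: {man.get('params_hash')}")
    lines.append("")

    prof = bundle.get("profiles")
    if prof is None:
        lines.append("## Profiles: absent")
    else:
        lines.append("## Profiles")
        counts = pd.Series(prof["labels"]).value_counts().sort_index()
        lines.append("counts: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
        lines.append(f"LOOCV accuracy: {prof['accuracy']:.3f}; "
                     f"label agreement alpha: "
                     f"{prof['reliability'].cronbach_alpha:.3f}")
    lines.append("")

    mat = bundle.get("matching")
    if mat is None:
        lines.append("## Matching: absent")
    else:
        lines.append("## Matching")
        lines.append(f"pairs: {mat['pairs'].n_pairs}; "
                     f"unmatched: {len(mat['pairs'].unmatched)}")
        bal = mat["balance"].to_frame()
        lines.append(bal.to_string())
    lines.append("")

    vp = bundle.get("vbm_paired")
    if vp is None:
        lines.append("## Paired inference: absent")
    else:
        lines.append("## Paired inference (cluster table)")
        if len(vp["clusters"]) == 0:
            lines.append("no significant clusters")
        else:
            lines.append(vp["clusters"].to_string(index=False))
            lines.append("")
            lines.append("### Per-profile subgroup t on cluster ROI means")
            for lab, per in vp["subgroup_t"].items():
                parts = [f"{k}: t={v['t']:.2f} (n={v['n']}, p={v['p']:.3g})"
                         for k, v in per.items()]
                lines.append(f"cluster {lab}: " + "; ".join(parts))
    lines.append("")

    vu = bundle.get("vbm_unpaired")
    if vu is not None:
        lines.append("## Unpaired inference")
        n_sig = len(vu["clusters"])
        lines.append(f"significant clusters: {n_sig}")
    else:
        lines.append("## Unpaired inference: absent")
    lines.append("")

    bs = bundle.get("bootstrap")
    if bs is not None:
        lines.append("## Bootstrap")
        summary = bs["summary"]
        lines.append(f"B={summary.B}, threshold t>={summary.t_threshold}")
        for cond in ("well", "random"):
            pooled = summary.pooled_t[cond]
            if pooled:
                means = {k: float(np.mean(v)) for k, v in pooled.items()}
                lines.append(f"{cond}: mean pooled t " + ", ".join(
                    f"{k}={v:.2f}" for k, v in means.items()))
    else:
        lines.append("## Bootstrap: absent")
    lines.append("")
    return "\n".join(lines) + "\n"
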