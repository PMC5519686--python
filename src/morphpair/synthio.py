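"""Seeded synthetic multi-site cohorts: phenotypes and Jacobian-determinant volumes.

The generator emulates the structure the downstream analysis assumes: several
research sites with site-specific intensity offsets, case-control status
confounded with total brain size, behavioral scores drawn inside the
percentile windows implied by the expert profile rules (so every generated
subject is recovered by the rule classifier), and smooth subject-level noise
fields with focal case expansion in parameterized ellipsoidal regions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, stats

from . import profiles
from .profiles import (
    CONTROL,
    GENERALLY_POOR_READER,
    POOR_COMPREHENDER,
    POOR_DECODER,
    DEFAULT_RULES,
    RuleSet,
    percentile_to_standard,
)

__all__ = [
    "SubjectRecord",
    "VolumeImage",
    "VolumeSet",
    "EffectRegion",
    "CohortConfig",
    "generate_cohort",
    "generate_volumes",
    "default_regions",
    "percentile_to_standard",
    "write_phenotypes",
    "read_phenotypes",
]

PHENOTYPE_COLUMNS = (
    "subject_id", "site", "sex", "age",
    "word_attack", "word_id", "passage_comp", "verbal_comp",
    "perceptual_reasoning", "ran",
    "gm_volume", "wm_volume", "brain_size", "is_case", "true_profile",
)


@dataclass
class SubjectRecord:
    """One participant's demographics, standardized scores, and tissue volumes."""

    subject_id: str
    site: int
    sex: str
    age: float
    word_attack: float
    word_id: float
    passage_comp: float
    verbal_comp: float
    perceptual_reasoning: float
    ran: float
    gm_volume: float
    wm_volume: float
    is_case: bool
    true_profile: str | None = None

    @property
    def brain_size(self) -> float:
        return self.gm_volume + self.wm_volume


@dataclass
class VolumeImage:
    """A 3-D Jacobian-determinant grid with affine metadata and analysis mask."""

    data: np.ndarray
    voxel_size: tuple
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.data.shape != self.mask.shape:
            raise ValueError("data and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask is empty")


@dataclass
class VolumeSet:
    """A stack of per-subject volumes on one shared grid.

    ``data`` has shape (n_subjects, nx, ny, nz) in the order of ``ids``.
    """

    ids: list
    data: np.ndarray
    affine: np.ndarray
    voxel_size: tuple
    mask: np.ndarray

    def __post_init__(self):
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def get(self, subject_id) -> VolumeImage:
        return VolumeImage(
            data=self.data[self._index[subject_id]],
            voxel_size=self.voxel_size, affine=self.affine, mask=self.mask)

    def stack(self, subject_ids) -> np.ndarray:
        """Rows of ``data`` for ``subject_ids``, in that order."""
        rows = [self._index[s] for s in subject_ids]
        return self.data[rows]

    def to_dir(self, path):
        """Write one uncompressed NIfTI-1 per subject plus the mask."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for sid in self.ids:
            img = nib.Nifti1Image(
                np.asarray(self.data[self._index[sid]], dtype=np.float32), self.affine)
            img.header.set_zooms(self.voxel_size)
            nib.save(img, path / f"{sid}.nii")
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine),
                 path / "mask.nii")

    @classmethod
    def from_dir(cls, path, subject_ids) -> "VolumeSet":
        path = Path(path)
        mask_img = nib.load(path / "mask.nii")
        mask = np.asarray(mask_img.dataobj).astype(bool)
        vols, affine = [], None
        for sid in subject_ids:
            img = nib.load(path / f"{sid}.nii")
            affine = img.affine
            vols.append(np.asarray(img.dataobj, dtype=np.float64))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(ids=list(subject_ids), data=np.stack(vols), affine=affine,
                   voxel_size=zooms, mask=mask)


@dataclass(frozen=True)
class EffectRegion:
    """Ellipsoidal locus of additive case expansion, in world mm."""

    center: tuple
    radii: tuple
    amplitude: float
    name: str = "region"

    def __post_init__(self):
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")

    def mask_on(self, shape, affine) -> np.ndarray:
        """Boolean indicator of the ellipsoid on the given voxel grid."""
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        ijk1 = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
        world = ijk1 @ affine.T
        c = np.asarray(self.center, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        q = ((world[..., :3] - c) / r) ** 2
        return q.sum(axis=-1) <= 1.0


_DEFAULT_SITES = (24, 22, 20, 18, 16, 14, 12, 8)  # sums to 134
_DEFAULT_MIX = {
    CONTROL: 0.5,
    POOR_DECODER: 33 / 134,
    POOR_COMPREHENDER: 22 / 134,
    GENERALLY_POOR_READER: 12 / 134,
}
_DEFAULT_SITE_OFFSETS = (0.00, 0.06, -0.05, 0.09, -0.08, 0.04, -0.03, 0.07)
_DEFAULT_SITE_SIZE_OFFSETS = (0.0, 15.0, -20.0, 25.0, -10.0, 5.0, -15.0, 20.0)


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort and volume generator."""

    n_per_site: tuple = _DEFAULT_SITES
    profile_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    site_offsets: tuple = _DEFAULT_SITE_OFFSETS
    site_size_offsets: tuple = _DEFAULT_SITE_SIZE_OFFSETS
    brain_size_case_shift: float = 15.0  # cases smaller on average, cm^3
    noise_sd: float = 0.04               # voxel sd of the smoothed noise field
    smoothing_fwhm_mm: float = 8.0
    brain_size_coupling: float = 0.03    # Jacobian offset per brain-size SD
    female_fraction: float = 0.43
    age_mean: float = 9.6
    age_sd: float = 1.5
    gm_mean: float = 740.0
    gm_sd: float = 55.0
    wm_mean: float = 460.0
    wm_sd: float = 40.0
    grid_shape: tuple = (24, 24, 24)
    voxel_size_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.profile_mix.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"profile_mix proportions sum to {total}, not 1")
        if any(p < 0 for p in self.profile_mix.values()):
            raise ValueError("profile_mix proportions must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.site_offsets) < len(self.n_per_site):
            raise ValueError("site_offsets shorter than n_per_site")

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        d["n_per_site"] = list(d["n_per_site"])
        d["site_offsets"] = list(d["site_offsets"])
        d["site_size_offsets"] = list(d["site_size_offsets"])
        d["grid_shape"] = list(d["grid_shape"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("n_per_site", "site_offsets", "site_size_offsets", "grid_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# Percentile windows used to sample scores per profile.  Bounds were chosen
# strictly inside the rule thresholds so the rule classifier recovers every
# generated label; "typically" clauses are enforced strictly here.
def _score_windows(rules: RuleSet):
    lo = 2.0
    return {
        CONTROL: {
            "word_attack": (rules.control_min + 5, 98),
            "word_id": (rules.control_min + 5, 98),
            "passage_comp": (rules.control_min + 5, 98),
            "verbal_comp": (30, 98),
            "ran": (30, 98),
        },
        POOR_DECODER: {
            "word_attack": (lo, rules.word_attack_max - 5),
            "verbal_comp": (rules.verbal_min + 5, 95),
            "ran": (lo, rules.ran_pd_max - 5),
        },
        POOR_COMPREHENDER: {
            "word_attack": (rules.above_wa + 5, 90),
            "word_id": (lo + 1, rules.pc_wid_max - 3),
            "passage_comp": (lo + 1, rules.pc_wid_max - 3),
            "verbal_comp": (rules.verbal_min + 5, 95),
            "ran": (rules.ran_pc_min + 9, 90),
        },
        GENERALLY_POOR_READER: {
            "word_attack": (lo, rules.poorreader_max - 3),
            "word_id": (lo, rules.poorreader_max - 3),
            "passage_comp": (lo, rules.poorreader_max - 3),
            "verbal_comp": (lo, rules.poorreader_max - 3),
            "ran": (lo, 50),
        },
    }


def _truncated_standard(rng, pct_window, size=None):
    """Sample standard scores whose percentile lies in ``pct_window``.

    Truncated normal on the standard-score scale with bounds at the window's
    percentile-converted endpoints.
    """
    lo, hi = percentile_to_standard(pct_window[0]), percentile_to_standard(pct_window[1])
    a, b = (lo - 100.0) / 15.0, (hi - 100.0) / 15.0
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    return 100.0 + 15.0 * stats.norm.ppf(u)


def _profile_counts(n, mix, rng):
    """Largest-remainder allocation of n subjects to profiles."""
    names = list(mix)
    quotas = np.array([mix[k] for k in names]) * n
    counts = np.floor(quotas).astype(int)
    rem = n - counts.sum()
    if rem > 0:
        frac_order = np.argsort(-(quotas - counts))
        for j in frac_order[:rem]:
            counts[j] += 1
    return dict(zip(names, counts))


def generate_cohort(config: CohortConfig, rules: RuleSet = DEFAULT_RULES) -> pd.DataFrame:
    """Generate a phenotype table; every row satisfies its true_profile rules.

    Reproducible given ``config.seed``.  Case brain sizes are shifted down by
    ``brain_size_case_shift`` on average; sites carry their configured
    brain-size offsets.
    """
    windows = _score_windows(rules)
    infeasible = [
        (p, v, w) for p, cols in windows.items() for v, w in cols.items()
        if w[0] >= w[1]
    ]
    if infeasible:
        raise ValueError(f"infeasible profile score windows: {infeasible}")

    rng = np.random.default_rng(config.seed)
    rows = []
    sid = 0
    for site_idx, n_site in enumerate(config.n_per_site):
        counts = _profile_counts(n_site, config.profile_mix, rng)
        labels = [p for p, c in counts.items() for _ in range(c)]
        rng.shuffle(labels)
        for lab in labels:
            sid += 1
            subject_id = f"sub-{sid:04d}"
            is_case = lab != CONTROL
            age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 6.5, 13.5))
            if lab == POOR_COMPREHENDER:
                age = float(np.clip(age, rules.pc_min_age + 0.5, 13.5))
            win = windows[lab]
            scores = {}
            for var in ("word_attack", "word_id", "passage_comp", "verbal_comp", "ran"):
                if var in win:
                    scores[var] = float(_truncated_standard(rng, win[var]))
            if lab == POOR_DECODER:
                # WID and PC consistent with Word Attack: within a few points
                wa = scores["word_attack"]
                scores["word_id"] = float(wa + rng.uniform(-6, 6))
                scores["passage_comp"] = float(wa + rng.uniform(-6, 6))
            pr = float(_truncated_standard(rng, (5, 98)))
            gm = rng.normal(config.gm_mean, config.gm_sd)
            wm = rng.normal(config.wm_mean, config.wm_sd)
            gm += config.site_size_offsets[site_idx] * 0.6
            wm += config.site_size_offsets[site_idx] * 0.4
            if is_case:
                gm -= config.brain_size_case_shift * 0.6
                wm -= config.brain_size_case_shift * 0.4
            sex = "F" if rng.random() < config.female_fraction else "M"
            rows.append({
                "subject_id": subject_id,
                "site": site_idx + 1,
                "sex": sex,
                "age": age,
                "word_attack": scores["word_attack"],
                "word_id": scores["word_id"],
                "passage_comp": scores["passage_comp"],
                "verbal_comp": scores["verbal_comp"],
                "perceptual_reasoning": pr,
                "ran": scores["ran"],
                "gm_volume": float(gm),
                "wm_volume": float(wm),
                "brain_size": float(gm + wm),
                "is_case": bool(is_case),
                "true_profile": lab,
            })
    frame = pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS))
    recovered = profiles.classify_cohort(frame, rules)
    mismatch = frame.loc[recovered.to_numpy() != frame["true_profile"].to_numpy()]
    if len(mismatch):  # pragma: no cover - generator contract
        raise RuntimeError(
            f"generator produced {len(mismatch)} rule-inconsistent subjects")
    return frame


def make_grid(config: CohortConfig):
    """RAS affine (grid centered on the world origin) and ellipsoidal mask."""
    shape = tuple(config.grid_shape)
    vs = float(config.voxel_size_mm)
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -vs * (np.asarray(shape) - 1) / 2.0
    center = (np.asarray(shape) - 1) / 2.0
    semiaxes = np.asarray(shape) * 0.45
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    q = (((ii - center[0]) / semiaxes[0]) ** 2
         + ((jj - center[1]) / semiaxes[1]) ** 2
         + ((kk - center[2]) / semiaxes[2]) ** 2)
    mask = q <= 1.0
    return affine, mask


def default_regions(config: CohortConfig, amplitude: float = 0.05):
    """Two stand-in effect loci (one lateral-superior, one deep central)."""
    vs = config.voxel_size_mm
    extent = np.asarray(config.grid_shape) * vs
    return [
        EffectRegion(center=(-0.22 * extent[0], -0.10 * extent[1], 0.18 * extent[2]),
                     radii=(0.14 * extent[0],) * 3, amplitude=amplitude,
                     name="lateral_superior"),
        EffectRegion(center=(0.10 * extent[0], 0.08 * extent[1], -0.05 * extent[2]),
                     radii=(0.11 * extent[0],) * 3, amplitude=amplitude,
                     name="deep_central"),
    ]


def _fwhm_to_sigma_vox(fwhm_mm, voxel_mm):
    return fwhm_mm / (voxel_mm * 2.0 * np.sqrt(2.0 * np.log(2.0)))


def generate_volumes(
    subjects: pd.DataFrame,
    regions,
    config: CohortConfig,
) -> VolumeSet:
    """Per-subject Jacobian volumes: baseline 1 + site offset + brain-size
    component + smoothed noise + case amplitude inside the effect regions.

    The smoothed noise field is rescaled so its voxel standard deviation
    equals ``config.noise_sd`` exactly, which makes effect-size calibration
    explicit (paired d of an injected amplitude a is about a/(noise_sd*sqrt 2)).
    Raises if any generated determinant is <= 0.
    """
    affine, mask = make_grid(config)
    shape = tuple(config.grid_shape)
    for reg in regions:
        if not (reg.mask_on(shape, affine) & mask).any():
            raise ValueError(f"effect region {reg.name!r} does not intersect the mask")
    region_field = np.zeros(shape)
    for reg in regions:
        region_field += reg.amplitude * reg.mask_on(shape, affine)

    rng = np.random.default_rng(config.seed + 1)
    bs = subjects["brain_size"].to_numpy(dtype=float)
    bs_sd = bs.std(ddof=1) if len(bs) > 1 and bs.std(ddof=1) > 0 else 1.0
    z_bs = (bs - bs.mean()) / bs_sd

    sigma = _fwhm_to_sigma_vox(config.smoothing_fwhm_mm, config.voxel_size_mm)
    n = len(subjects)
    data = np.empty((n,) + shape)
    for i, (_, row) in enumerate(subjects.iterrows()):
        vol = np.full(shape, 1.0)
        vol += config.site_offsets[int(row["site"]) - 1]
        vol += config.brain_size_coupling * z_bs[i]
        if config.noise_sd > 0:
            noise = rng.standard_normal(shape)
            if sigma > 0:
                noise = ndimage.gaussian_filter(noise, sigma)
            sd = noise.std()
            if sd > 0:
                noise *= config.noise_sd / sd
            vol += noise
        if bool(row["is_case"]):
            vol += region_field
        data[i] = vol
    if data.min() <= 0:
        raise ValueError(
            "generated Jacobian determinants are not strictly positive; "
            "reduce |amplitude|, |site offsets|, or noise_sd")
    return VolumeSet(ids=list(subjects["subject_id"]), data=data, affine=affine,
                     voxel_size=(config.voxel_size_mm,) * 3, mask=mask)


def write_phenotypes(subjects: pd.DataFrame, path):
    subjects.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - {"true_profile"} - set(frame.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    frame["is_case"] = frame["is_case"].astype(bool)
    return frame
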