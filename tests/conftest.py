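import numpy as np
import pytest

from morphpair import matching, synthio


def small_config(**overrides):
    """16^3 grid, 6 mm voxels, 8 sites -- the desk-scale default for tests."""
    kwargs = dict(n_per_site=(6,) * 8, grid_shape=(16, 16, 16),
                  voxel_size_mm=6.0, seed=0)
    kwargs.update(overrides)
    return synthio.CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size (134-subject) cohort shared across read-only tests."""
    return synthio.generate_cohort(synthio.CohortConfig(seed=42))


@pytest.fixture(scope="session")
def matched_setup():
    """Cohort + volumes + matching artifacts on a small grid, shared."""
    cfg = small_config(seed=5)
    cohort = synthio.generate_cohort(cfg)
    regions = synthio.default_regions(cfg, amplitude=0.05)
    volumes = synthio.generate_volumes(cohort, regions, cfg)
    strata = matching.stratify(cohort)
    model = matching.fit_propensity(cohort)
    pairs = matching.pair_nearest(strata, model, cohort)
    region_mask = np.zeros(volumes.mask.shape, dtype=bool)
    for reg in regions:
        region_mask |= reg.mask_on(volumes.mask.shape, volumes.affine)
    region_mask &= volumes.mask
    return {
        "config": cfg, "cohort": cohort, "regions": regions,
        "volumes": volumes, "strata": strata, "model": model,
        "pairs": pairs, "region_mask": region_mask,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
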