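import numpy as np
import pytest

import vbmdecode as vd

# A small-grid effect layout mirroring the default bilateral blobs, used by
# tests that want a 16-cubed cohort for speed.
SMALL_GRID = (16, 16, 16)
SMALL_REGIONS = (
    vd.EffectRegion(center=(5, 8, 8), radius=3.0),
    vd.EffectRegion(center=(11, 8, 8), radius=3.0),
)


def small_config(**kwargs) -> vd.CohortConfig:
    defaults = dict(grid_shape=SMALL_GRID, effect_regions=SMALL_REGIONS)
    defaults.update(kwargs)
    return vd.CohortConfig(**defaults)


def cohort_features(cohort: vd.SyntheticCohort, fwhm_mm: float = 8.0) -> vd.FeatureMatrix:
    smoothed = [vd.gaussian_smooth(v, fwhm_mm) for v in cohort.volumes]
    return vd.vectorize(smoothed, vd.build_mask(smoothed))


@pytest.fixture(scope="session")
def strong_cohort() -> vd.SyntheticCohort:
    """17+17 cohort at default (strong-effect) conditions, fixed seed."""
    return vd.generate_cohort(vd.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def strong_features(strong_cohort) -> vd.FeatureMatrix:
    return cohort_features(strong_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
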