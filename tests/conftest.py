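import numpy as np
import pytest

from dvhstack.dvh import DVHPrincipalComponents, default_dose_grid, postprocess_curves
from dvhstack.synthetic import CohortConfig, generate_cohort, make_dvh_family


@pytest.fixture(scope="session")
def family():
    return make_dvh_family()


@pytest.fixture(scope="session")
def grid():
    return default_dose_grid()


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-case clean cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_cases=30, seed=42))


@pytest.fixture(scope="session")
def rank3_curves(family):
    """Curves exactly in the span of the family (valid without projection)."""
    rng = np.random.default_rng(7)
    scores = rng.normal(0.0, [0.15, 0.08, 0.04], size=(25, 3))
    raw = family.decode(scores, raw=True)
    assert np.allclose(postprocess_curves(raw), raw, atol=1e-12)
    return raw


@pytest.fixture(scope="session")
def fitted_basis(rank3_curves, grid):
    return DVHPrincipalComponents(n_components=3).fit(rank3_curves, dose_grid=grid)
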