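import numpy as np
import pytest

from impactcurves import (
    Bathymetry,
    LakeScenario,
    ProductionSeries,
    TrajectoryParams,
    generate_trajectory,
)


@pytest.fixture(scope="session")
def hudson_like_series() -> ProductionSeries:
    """A 130-yr variable production series, long enough to outlast the
    slow-dissolution burn-in (100 yr at k=0.05)."""
    return generate_trajectory(TrajectoryParams(n_years=130, mean_level=1.0, seed=42))


@pytest.fixture(scope="session")
def shallow_unproductive() -> LakeScenario:
    return LakeScenario(Bathymetry.conical(5.0), chl_pre=3.0, label="shallow unproductive")


@pytest.fixture(scope="session")
def deep_productive() -> LakeScenario:
    return LakeScenario(Bathymetry.conical(50.0), chl_pre=30.0, label="deep productive")


@pytest.fixture(scope="session")
def shelf_productive() -> LakeScenario:
    return LakeScenario(Bathymetry.shelf(), chl_pre=30.0, label="shelf productive")


@pytest.fixture(scope="session")
def dfr_grid() -> np.ndarray:
    return np.arange(0.0, 101.0, 1.0)
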