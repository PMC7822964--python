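import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssci import (
    ScanConfig,
    SceneSpec,
    StratumSpec,
    compute_scan_metrics,
    make_scene,
    simulate_scan,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dome_config() -> ScanConfig:
    """Fast scan geometry: full azimuth, 60-degree-half-angle zenith dome."""
    return ScanConfig(vertical_fov=120.0)


@pytest.fixture(scope="session")
def overstory_scene():
    """One 25-30 m stratum on a 60 x 60 m extent, seed 7."""
    spec = SceneSpec(
        strata=[StratumSpec((25.0, 30.0), 250.0)],
        extent=(-30.0, -30.0, 30.0, 30.0),
    )
    return make_scene(spec, seed=7)


@pytest.fixture(scope="session")
def overstory_metrics(overstory_scene, dome_config):
    cloud = simulate_scan(overstory_scene, (0.0, 0.0), dome_config, seed=7)
    return compute_scan_metrics(cloud, dome_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
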