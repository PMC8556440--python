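import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from renalpet.phantom import Biokinetics, build_phantom, default_phantom_spec


@pytest.fixture(scope="session")
def coarse_phantom():
    """Default scene rasterized at 6 mm (fast; VOI totals are voxel-size
    independent because the mm geometry is fixed)."""
    spec = default_phantom_spec(split_fraction_left=0.483, voxel_size=6.0)
    return build_phantom(spec, Biokinetics(), dose_mbq_per_kg=4.0)


@pytest.fixture(scope="session")
def default_study_result():
    """One full default-condition study run, shared across tests."""
    from renalpet.study import StudyConfig, run_study

    return run_study(StudyConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
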