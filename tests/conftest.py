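import pytest
from hypothesis import settings

from trichoflux import SimulationConfig, SweepGrid

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def short_config():
    """A 48-hour run for tests that only need the recurrence, not the full horizon."""
    return SimulationConfig(c0=100.0, duration_hours=48, dt_hours=1.0)


@pytest.fixture(scope="session")
def coarse_tau_grids():
    """Coarser τ / r_p grids for fast sweep-structure tests."""
    return {
        "tau": SweepGrid("tau", 1.0, 5.0, 0.5),
        "r_p": SweepGrid("r_p_shared", 0.0, 1.0, 0.05),
    }
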