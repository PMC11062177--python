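import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from intergen.landscape import default_config
from intergen.simulate import estimate_learning_curve


@pytest.fixture(scope="session")
def default_land():
    """(calibrated default landscape, common fixed initial design)."""
    return default_config()


@pytest.fixture(scope="session")
def reference_curves(default_land):
    """Full-size (10,000-agent) learning curves for two master seeds.

    Session-scoped because each takes a couple of seconds; used by the
    simulation-optima checks.
    """
    land, init = default_land
    return {seed: estimate_learning_curve(10_000, land, init, seed) for seed in (1, 2)}
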