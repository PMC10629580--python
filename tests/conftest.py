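import pytest
from hypothesis import HealthCheck, settings

import chronodiv as cd

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def balanced_tree() -> cd.TimeTree:
    """Perfectly balanced 8-tip tree, all tip-adjacent structure symmetric."""
    nwk = (
        "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
    )
    return cd.parse_newick(nwk, f=1.0)


@pytest.fixture(scope="session")
def yule_tree_50() -> cd.TimeTree:
    """A ~50-tip pure-birth tree reused by several statistics tests."""
    cfg = cd.SimConfig(
        cd.RateSpec("constant", 0.12),
        None,
        crown_age=28.0,
        sampling_fraction=1.0,
        min_tips=45,
        max_tips=60,
    )
    tree, _ = cd.simulate_bd_tree(cfg, seed=42)
    return tree


@pytest.fixture(scope="session")
def cooling_climate() -> cd.PaleoSeries:
    """The frozen Cenozoic-like cooling proxy used by recovery studies."""
    scn = cd.ClimateScenario(
        start=5.0,
        end=0.0,
        oscillation_amplitude=1.0,
        oscillation_period=8.0,
        oscillation_recency=1.0,
        noise_sd=0.15,
        step=0.5,
        span=90.0,
        trend_curvature=3.5,
    )
    return cd.simulate_climate(scn, seed=7)
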