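import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def tiny_model():
    """One panmictic population, 10 generations, non-spatial."""
    import geodemes as gd

    pop = gd.population("p", time=1, N=100)
    return gd.compile_model([pop], generation_time=1, direction="forward",
                            end_time=10)


@pytest.fixture(scope="session")
def small_spatial_model():
    """Two spatial demes on a circular world, short run."""
    import geodemes as gd

    world = gd.toy_world(radius=20.0)
    sp = gd.SpatialParams(competition=0.0, mating=5.0, dispersal=1.0)
    a = gd.population("a", time=1, N=40, spatial=sp,
                      range=gd.circle_region("a0", gd.Point(-8, 0), 8))
    b = gd.population("b", time=5, N=30, parent=a, spatial=sp,
                      range=gd.circle_region("b0", gd.Point(8, 0), 8))
    return gd.compile_model([a, b], generation_time=1, direction="forward",
                            world=world, end_time=30)


def run_small(model, seed=1, L=100_000, rho=1e-6, **kwargs):
    import geodemes as gd

    params = gd.SimulationParams(sequence_length=L, recombination_rate=rho,
                                 seed=seed, quiet=True, **kwargs)
    return gd.run_simulation(model, params)
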