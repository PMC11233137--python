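"""Ready-made worlds and demographic models.

These generators build the models used throughout the documentation and
test suite: the six-population admixture model used to demonstrate the
f4-ratio estimator, the eight-lineage dispersal-dynamics model on a
featureless circular world, and an abstract-continent analogue of a
spatio-temporal range-dynamics model with scheduled ancient sampling.

Each generator's defaults define the study conditions; a ``scale``
argument divides all times (and, where noted, sizes) proportionally to
produce cheaper but statistically equivalent runs.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .demography import (
    CompiledModel,
    SpatialParams,
    compile_model,
    gene_flow,
    expand_range,
    move,
    population,
    resize,
    sampling_event,
)
from .landscape import Point, Region, World, circle_region, make_world

__all__ = [
    "toy_world",
    "example1_model",
    "example2_model",
    "example3_like_model",
    "f4_ratio_study",
]


def toy_world(radius: float = 50.0, vertices: int = 64) -> World:
    """A featureless circular world of the given radius, centred on (0, 0)."""
    circle = circle_region("world", Point(0.0, 0.0), radius, vertices)
    return make_world((-radius, -radius, radius, radius), [circle])


def example1_model(scale: float = 1.0, N: int = 100,
                   internal_N: Optional[int] = None,
                   gene_flow_rate: float = 0.1) -> CompiledModel:
    """Six-population admixture model with one gene-flow event b -> x1.

    An ancestral outgroup ``o`` gives rise to ``c``; ``a`` and (via ``a``)
    ``b`` branch off on one side while ``x1`` and ``x2`` split from ``c``;
    ``b`` then contributes ``gene_flow_rate`` total ancestry to ``x1`` over
    a late window, while ``x2`` receives none.  Under the f4-ratio
    estimator alpha = f4(a, o; x, c) / f4(a, o; b, c), population ``x1``
    should show ~10% ancestry from ``b`` and ``x2`` ~0%.

    Times are in generations (generation_time 1, forward); ``scale``
    divides all times, preserving the expected ancestry proportions.
    ``internal_N`` optionally reduces the size of ``a`` on the internal
    branch between its origin and the split of ``b`` (after which ``a``
    returns to ``N``): at reduced time scales this restores the strong
    shared drift on that branch that makes the f4-ratio denominator
    well conditioned, without inflating drift noise elsewhere.
    """
    def t(v: float) -> float:
        return max(1.0, round(v / scale))

    o = population("o", time=t(1), N=N)
    c = population("c", time=t(2500), N=N, parent=o)
    a = population("a", time=t(3000), N=internal_N or N, parent=c)
    b = population("b", time=t(4000), N=N, parent=a)
    x1 = population("x1", time=t(4800), N=N, parent=c)
    x2 = population("x2", time=t(4800), N=N, parent=c)
    events = []
    if internal_N is not None and internal_N != N:
        events.append(resize(a, time=t(4000), N=N))
    events.append(gene_flow(source=b, target=x1, rate=gene_flow_rate,
                            start=t(5500), end=t(6000)))
    return compile_model(
        populations=[o, c, a, b, x1, x2],
        events=events,
        generation_time=1,
        direction="forward",
        end_time=t(6000),
        name="example1",
    )


def f4_ratio_study(
    seed: int,
    scale: float = 10.0,
    N: int = 1000,
    internal_N: int = 50,
    sequence_length: int = 10_000_000,
    recombination_rate: float = 4e-7,
    mutation_rate: float = 4e-8,
    n_sample: int = 100,
) -> dict:
    """One full admixture-estimation run on the six-population model.

    Simulates the model, simplifies to ``n_sample`` individuals scheduled
    per population at the final generation, overlays mutations, and returns
    the f4-ratio ancestry-proportion estimates for the recipient ``x1`` and
    the unadmixed control ``x2`` (as fractions), plus the number of
    segregating sites.

    The defaults are the reduced-scale study conditions: times divided by
    10, terminal demes of 1000 diploids (which keeps the realized-ancestry
    noise of the gene-flow event low), the internal branch bottlenecked to
    50 diploids (which keeps the denominator's shared drift strong), and a
    scaled-up recombination rate (4 Morgans over 10 Mb) so that many
    quasi-independent genealogies average the drift noise.
    """
    import numpy as np

    from .demography import schedule_sampling
    from .engine import SimulationParams, run_simulation
    from .stats import f4_ratio, from_population
    from .tables import overlay_mutations, simplify

    model = example1_model(scale=scale, N=N, internal_N=internal_N)
    for pop in model.pop_names:
        schedule_sampling(model, [model.T1], pop, n_sample)
    params = SimulationParams(
        sequence_length=sequence_length,
        recombination_rate=recombination_rate,
        mutation_rate=mutation_rate,
        seed=seed,
        quiet=True,
    )
    tables, _state = run_simulation(model, params)
    simp = simplify(tables, tables.sample_nodes)
    del tables, _state  # raw history no longer needed; free before overlay
    mut_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    mutated = overlay_mutations(simp, mutation_rate, mut_rng)
    sets = {p: from_population(mutated, p) for p in model.pop_names}
    alpha_x1 = f4_ratio(mutated, sets["x1"], sets["a"], sets["b"],
                        sets["c"], sets["o"])
    alpha_x2 = f4_ratio(mutated, sets["x2"], sets["a"], sets["b"],
                        sets["c"], sets["o"])
    return {
        "alpha_x1": alpha_x1,
        "alpha_x2": alpha_x2,
        "num_sites": mutated.num_sites,
        "n_sample_per_pop": n_sample,
    }


def example2_model(
    N: int = 2000,
    generations: int = 5000,
    radius: float = 50.0,
    competition: Sequence[float] = (0.0, 1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0),
    mating: float = 2.0,
    dispersal: float = 1.0,
) -> CompiledModel:
    """Independent lineages on a circular world, competition varied per deme.

    Each population occupies the whole world and never interacts with the
    others genetically; only the competition radius differs.  With the
    radius far above the dispersal scale the demes self-organize into
    evenly spaced patches; far below, individuals remain diffusely spread.
    """
    world = toy_world(radius)
    pops = [
        population(
            f"pop{i}", time=1, N=N,
            spatial=SpatialParams(competition=c, mating=mating,
                                  dispersal=dispersal),
        )
        for i, c in enumerate(competition)
    ]
    return compile_model(
        populations=pops, generation_time=1, direction="forward",
        world=world, end_time=generations, name="example2",
    )


def example3_like_model(
    scale: float = 1.0,
    N: int = 500,
    sampling_interval: float = 1000.0,
) -> CompiledModel:
    """Range movements and expansions on an abstract continent, backward time.

    A toy analogue of a West-Eurasian-style model on an abstract landscape:
    an ancestral population ``anc`` in the south, a daughter ``west`` that
    migrates northwest over millennia, an ``east`` population that expands
    its range, and late gene flow east -> west.  Times are in years before
    present with a generation time of 30; individuals are sampled every
    ``sampling_interval`` years from each living population.
    """
    def t(v: float) -> float:
        return round(v / scale)

    continent = Region.from_vertices(
        "continent",
        [
            Point(0, 0), Point(70, 0), Point(90, 25), Point(80, 60),
            Point(55, 80), Point(20, 75), Point(0, 40),
        ],
    )
    world = make_world((0, 0, 90, 80), [continent])

    anc = population(
        "anc", time=t(50000), N=N,
        range=circle_region("anc_range", Point(40, 15), 12),
        spatial=SpatialParams(mating=10.0, dispersal=2.0),
    )
    west = population(
        "west", time=t(40000), N=N, parent=anc,
        range=circle_region("west_range", Point(35, 25), 10),
        spatial=SpatialParams(mating=10.0, dispersal=2.0),
    )
    east = population(
        "east", time=t(35000), N=N, parent=anc,
        range=circle_region("east_range", Point(65, 30), 10),
        spatial=SpatialParams(mating=10.0, dispersal=2.0),
    )
    events = [
        move(west, waypoints=[Point(25, 45), Point(30, 60)],
             start=t(30000), end=t(20000)),
        expand_range(east, by=15, start=t(25000), end=t(15000)),
        gene_flow(east, west, rate=0.2, start=t(8000), end=t(6000),
                  require_overlap=False),
    ]
    sampling = []
    time = t(20000)
    while time >= 0:
        for pop in ("anc", "west", "east"):
            sampling.append(sampling_event(time, pop, 5))
        time -= t(sampling_interval)
    return compile_model(
        populations=[anc, west, east], events=events, sampling=sampling,
        generation_time=30.0, direction="backward", world=world,
        end_time=0, name="example3_like",
    )
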