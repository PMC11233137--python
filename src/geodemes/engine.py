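"""Forward Wright-Fisher engine with genealogy recording.

Populations evolve in discrete non-overlapping generations at the exact
census sizes prescribed by the compiled model.  Reproduction per offspring:

1. the first parent is drawn proportionally to density-dependent fitness
   weights ``w = 1 / (1 + n)`` where ``n`` counts same-population
   neighbours within the competition radius (uniform when the radius is 0);
2. a mate is chosen uniformly among same-population individuals within the
   mating radius of the first parent (nearest individual as fallback,
   selfing disallowed); during an active gene-flow window the mate is
   drawn from the source population instead with the compiled probability;
3. each parent contributes one recombined gamete (crossover count
   Poisson(rho * L), breakpoints uniform), recorded as edges;
4. spatial offspring disperse from the first parent's location by the
   population's kernel, with rejection sampling against the current range
   snapshot and a uniform-teleport fallback after repeated failure.

Everything is driven by one seeded generator, single-threaded, so a fixed
seed yields bit-identical tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
import shapely

from .demography import CompiledModel, CompiledPopulation, ResolvedSpatial
from .landscape import Point, Region, sample_point_uniform
from .tables import GenealogyTables

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationParams",
    "EngineState",
    "Individual",
    "EngineError",
    "run_simulation",
    "wf_step",
    "fitness_weights",
    "choose_mate",
    "disperse",
    "apply_gene_flow",
]


class EngineError(RuntimeError):
    """Raised when the simulation cannot honour the model at run time."""


@dataclass(frozen=True)
class SimulationParams:
    """Run-time parameters of a simulation.

    Rates are per base pair per generation.  Mutations are not placed
    during the run: overlay them afterwards with
    :func:`geodemes.tables.overlay_mutations` (typically after
    simplification).
    """

    sequence_length: int
    recombination_rate: float = 0.0
    mutation_rate: float = 0.0
    seed: int = 1
    max_placement_attempts: int = 1000
    spatial: Optional[bool] = None  # None: spatial iff the model has a world
    quiet: bool = False

    def __post_init__(self) -> None:
        if int(self.sequence_length) <= 0:
            raise ValueError("sequence_length must be a positive integer")
        for rate in (self.recombination_rate, self.mutation_rate):
            if not (math.isfinite(rate) and rate >= 0):
                raise ValueError("rates must be finite and non-negative")


@dataclass(frozen=True)
class Individual:
    id: int
    population: str
    location: Optional[Point]
    node_ids: tuple[int, int]
    parent_ids: tuple[int, int]


@dataclass
class _PopState:
    ids: np.ndarray            # global individual ids, int64
    loc: Optional[np.ndarray]  # (N, 2) float64, or None in non-spatial mode


class _TableBuilder:
    """Accumulates individuals and edges chunk-wise during the run."""

    def __init__(self, model: CompiledModel, L: float) -> None:
        self.model = model
        self.L = float(L)
        self.n_ind = 0
        self._pop: list[np.ndarray] = []
        self._gen: list[np.ndarray] = []
        self._x: list[np.ndarray] = []
        self._y: list[np.ndarray] = []
        self._p1: list[np.ndarray] = []
        self._p2: list[np.ndarray] = []
        self._el: list[np.ndarray] = []
        self._er: list[np.ndarray] = []
        self._ep: list[np.ndarray] = []
        self._ec: list[np.ndarray] = []
        self.sampled: dict[int, str] = {}  # individual id -> permanent name
        self._name_counter: dict[int, int] = {}

    def add_individuals(self, pop_idx, gen, loc, parent1, parent2) -> np.ndarray:
        n = len(parent1)
        ids = np.arange(self.n_ind, self.n_ind + n, dtype=np.int64)
        self.n_ind += n
        self._pop.append(np.full(n, pop_idx, dtype=np.int32))
        self._gen.append(np.full(n, gen, dtype=np.int64))
        if loc is None:
            self._x.append(np.full(n, np.nan))
            self._y.append(np.full(n, np.nan))
        else:
            self._x.append(loc[:, 0].copy())
            self._y.append(loc[:, 1].copy())
        self._p1.append(np.asarray(parent1, dtype=np.int64))
        self._p2.append(np.asarray(parent2, dtype=np.int64))
        return ids

    def add_edges(self, left, right, parent, child) -> None:
        keep = left < right  # drop zero-span slivers from coincident breakpoints
        self._el.append(left[keep])
        self._er.append(right[keep])
        self._ep.append(parent[keep])
        self._ec.append(child[keep])

    def mark_sampled(self, pop_idx: int, ids: np.ndarray) -> None:
        name = self.model.populations[pop_idx].name
        for i in ids:
            i = int(i)
            if i not in self.sampled:
                k = self._name_counter.get(pop_idx, 0)
                self.sampled[i] = f"{name}_{k}"
                self._name_counter[pop_idx] = k + 1

    def finalize(self) -> GenealogyTables:
        pop = np.concatenate(self._pop) if self._pop else np.empty(0, np.int32)
        gen = np.concatenate(self._gen) if self._gen else np.empty(0, np.int64)
        x = np.concatenate(self._x) if self._x else np.empty(0)
        y = np.concatenate(self._y) if self._y else np.empty(0)
        n = self.n_ind
        node_ind = np.repeat(np.arange(n, dtype=np.int64), 2)
        is_sample = np.zeros(2 * n, dtype=bool)
        for i in self.sampled:
            is_sample[2 * i] = True
            is_sample[2 * i + 1] = True
        tables = GenealogyTables(
            sequence_length=self.L,
            node_birth_gen=np.repeat(gen, 2),
            node_population=np.repeat(pop, 2),
            node_individual=node_ind,
            node_is_sample=is_sample,
            indiv_population=pop,
            indiv_birth_gen=gen,
            indiv_x=x,
            indiv_y=y,
            indiv_names=dict(self.sampled),
            edges_left=np.concatenate(self._el) if self._el else np.empty(0),
            edges_right=np.concatenate(self._er) if self._er else np.empty(0),
            edges_parent=np.concatenate(self._ep) if self._ep else np.empty(0, np.int64),
            edges_child=np.concatenate(self._ec) if self._ec else np.empty(0, np.int64),
            population_names=[p.name for p in self.model.populations],
        )
        # release chunk storage (keeps peak memory to one copy of the edges);
        # pedigree chunks are kept for pedigree()
        self._el = self._er = self._ep = self._ec = []
        self._x = self._y = self._gen = []
        return tables

    def pedigree(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(parent1, parent2, population) per individual; -1 for founders."""
        return (
            np.concatenate(self._p1) if self._p1 else np.empty(0, np.int64),
            np.concatenate(self._p2) if self._p2 else np.empty(0, np.int64),
            np.concatenate(self._pop) if self._pop else np.empty(0, np.int32),
        )


@dataclass
class EngineState:
    """Living individuals at one generation, plus the RNG stream."""

    generation: int
    pops: dict[int, _PopState]
    rng: np.random.Generator
    builder: _TableBuilder
    spatial: bool
    dispersal_rejections: int = 0

    def census(self) -> dict[str, int]:
        return {
            self.builder.model.populations[i].name: len(ps.ids)
            for i, ps in sorted(self.pops.items())
        }

    def living_individuals(self) -> list[Individual]:
        model = self.builder.model
        p1, p2, _ = self.builder.pedigree()
        out = []
        for idx, ps in sorted(self.pops.items()):
            name = model.populations[idx].name
            for k, i in enumerate(ps.ids):
                i = int(i)
                loc = Point(*ps.loc[k]) if ps.loc is not None else None
                out.append(
                    Individual(i, name, loc, (2 * i, 2 * i + 1),
                               (int(p1[i]), int(p2[i])))
                )
        return out


# ---------------------------------------------------------------------------
# reproduction components
# ---------------------------------------------------------------------------

def fitness_weights(locations: Optional[np.ndarray], competition_radius: float) -> np.ndarray:
    """Density-dependent weights ``w = 1 / (1 + n_neighbours)``.

    ``n`` counts same-population individuals within the competition radius,
    excluding self.  A radius of 0 (or no locations) disables density
    dependence: all weights are 1.
    """
    if locations is None or competition_radius == 0:
        n = 0 if locations is None else len(locations)
        return np.ones(max(n, 0))
    tree = cKDTree(locations)
    counts = tree.query_ball_point(locations, competition_radius, return_length=True)
    return 1.0 / counts  # count includes self, so this is 1 / (1 + n)


def choose_mate(
    parent: int,
    locations: np.ndarray,
    mating_radius: float,
    rng: np.random.Generator,
) -> int:
    """Uniform mate among individuals within ``mating_radius`` of ``parent``.

    Falls back to the nearest individual when nobody is in range; selfing
    is never allowed.  ``parent`` indexes rows of ``locations``.
    """
    n = len(locations)
    if n < 2:
        raise EngineError("cannot mate in a population of size 1")
    d = np.hypot(*(locations - locations[parent]).T)
    d[parent] = np.inf
    cand = np.flatnonzero(d <= mating_radius)
    if len(cand) == 0:
        return int(np.argmin(d))
    return int(cand[rng.integers(len(cand))])


def _kernel_displacements(sp: ResolvedSpatial, m: int, rng: np.random.Generator) -> np.ndarray:
    s = sp.dispersal
    fun = sp.dispersal_fun
    if fun == "brownian":
        return rng.normal(0.0, s, size=(m, 2))
    if fun == "normal":
        r = np.abs(rng.normal(0.0, s, size=m))
    elif fun == "uniform":
        r = rng.uniform(0.0, s, size=m)
    elif fun == "cauchy":
        r = np.abs(s * rng.standard_cauchy(size=m))
    elif fun == "exponential":
        r = rng.exponential(s, size=m)
    else:  # pragma: no cover - validated at compile
        raise EngineError(f"unknown dispersal kernel {fun!r}")
    theta = rng.uniform(0.0, 2.0 * math.pi, size=m)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def disperse(
    parent_location: Point,
    spatial: ResolvedSpatial,
    range_region: Region,
    world,
    rng: np.random.Generator,
    max_placement_attempts: int = 1000,
) -> Point:
    """Offspring location: kernel displacement, rejected until inside the range."""
    loc = np.asarray(parent_location, dtype=float)[None, :]
    out, _, _ = _disperse_batch(
        loc, spatial, range_region.geometry, world, range_region, rng,
        max_placement_attempts,
    )
    return Point(float(out[0, 0]), float(out[0, 1]))


def _disperse_batch(
    parent_locs: np.ndarray,
    sp: ResolvedSpatial,
    geometry,
    world,
    range_region: Region,
    rng: np.random.Generator,
    max_attempts: int,
):
    """Vectorized rejection placement; returns (locations, rejections, teleports)."""
    m = len(parent_locs)
    out = np.empty((m, 2))
    pending = np.arange(m)
    rejections = 0
    for _ in range(max_attempts):
        if len(pending) == 0:
            break
        prop = parent_locs[pending] + _kernel_displacements(sp, len(pending), rng)
        ok = shapely.intersects_xy(geometry, prop[:, 0], prop[:, 1])
        out[pending[ok]] = prop[ok]
        rejections += int((~ok).sum())
        pending = pending[~ok]
    n_teleport = len(pending)
    if n_teleport:
        logger.debug(
            "placement fallback: %d offspring teleported uniformly into the range",
            n_teleport,
        )
        out[pending] = sample_point_uniform(world, range_region, rng, size=n_teleport)
    return out, rejections, n_teleport


def apply_gene_flow(
    n_offspring: int,
    p_mate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli mask of offspring whose mate is drawn from the source.

    The compiled per-generation mate-draw probability already accounts for
    the factor of two from the mate contributing half a genome.
    """
    if p_mate <= 0:
        return np.zeros(n_offspring, dtype=bool)
    if p_mate >= 1:
        return np.ones(n_offspring, dtype=bool)
    return rng.random(n_offspring) < p_mate


def _gamete_edges(rng, parent_ids, child_nodes, rho, L):
    """Edges of one recombined gamete per (parent individual, child node)."""
    m = len(parent_ids)
    if rho > 0:
        k = rng.poisson(rho * L, m)
    else:
        k = np.zeros(m, dtype=np.int64)
    start = rng.integers(0, 2, m)
    B = int(k.sum())
    if B == 0:
        return (
            np.zeros(m),
            np.full(m, L, dtype=float),
            2 * parent_ids + start,
            child_nodes.astype(np.int64),
        )
    gid = np.repeat(np.arange(m), k)
    bps = rng.uniform(0.0, L, B)
    order = np.lexsort((bps, gid))
    bps = bps[order]
    counts = k + 1
    E = m + B
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
    left = np.empty(E)
    first = np.zeros(E, dtype=bool)
    first[offsets] = True
    left[first] = 0.0
    left[~first] = bps
    right = np.empty(E)
    right[: E - 1] = left[1:]
    right[offsets + k] = L
    j = np.arange(E, dtype=np.int64) - np.repeat(offsets, counts)
    hap = (np.repeat(start, counts) + j) % 2
    parent_node = 2 * np.repeat(parent_ids, counts) + hap
    child = np.repeat(child_nodes, counts)
    return left, right, parent_node, child


# ---------------------------------------------------------------------------
# generation step
# ---------------------------------------------------------------------------

def _global_mates(parent1, pool_size, rng):
    """Uniform mates != first parent (vectorized redraw)."""
    if pool_size < 2:
        raise EngineError("cannot mate in a population of size 1")
    mates = rng.integers(0, pool_size, len(parent1))
    clash = mates == parent1
    while clash.any():
        mates[clash] = rng.integers(0, pool_size, int(clash.sum()))
        clash = mates == parent1
    return mates


def _local_mates(pool_locs, tree, parent1, r_m, rng):
    """Uniform mate within radius of each first parent, nearest fallback."""
    neighbour_lists = tree.query_ball_point(pool_locs[parent1], r_m)
    mates = np.empty(len(parent1), dtype=np.int64)
    for i, pi in enumerate(parent1):
        cand = [c for c in neighbour_lists[i] if c != pi]
        if cand:
            mates[i] = cand[rng.integers(len(cand))]
        else:
            _, nearest = tree.query(pool_locs[pi], k=2)
            mates[i] = int(nearest[1])
    return mates


def wf_step(state: EngineState, model: CompiledModel, params: SimulationParams,
            rng: Optional[np.random.Generator] = None) -> EngineState:
    """Advance one generation: produce the next census exactly.

    Handles resizes (via the model's N schedule), range/dispersal updates
    (via snapshot lookup), gene flow, population founding and removal.
    """
    if rng is None:
        rng = state.rng
    gen = state.generation
    gnext = gen + 1
    if gnext > model.G:
        raise EngineError("simulation already at the final generation")
    builder = state.builder
    spatial = state.spatial
    L = float(params.sequence_length)
    rho = params.recombination_rate

    # per-population KD-trees for this generation, built lazily
    trees: dict[int, cKDTree] = {}

    def tree_for(idx: int) -> cKDTree:
        if idx not in trees:
            trees[idx] = cKDTree(state.pops[idx].loc)
        return trees[idx]

    new_pops: dict[int, _PopState] = {}
    for pop in model.populations:
        if not pop.alive_at(gnext):
            continue
        n_next = pop.N_at(gnext)
        founding = pop.start_gen == gnext
        if founding and pop.parent_idx < 0:
            # root founders: no parents, fresh genomes
            if spatial:
                region = pop.range_at(gnext)
                loc = sample_point_uniform(model.world, region, rng, size=n_next)
            else:
                loc = None
            ids = builder.add_individuals(
                pop.idx, gnext, loc,
                np.full(n_next, -1, np.int64), np.full(n_next, -1, np.int64),
            )
            new_pops[pop.idx] = _PopState(ids, loc)
            continue

        src_idx = pop.parent_idx if founding else pop.idx
        if src_idx not in state.pops:
            raise EngineError(
                f"population {pop.name!r} needs parents from generation {gen} "
                f"but its source population is not alive"
            )
        pool = state.pops[src_idx]
        pool_n = len(pool.ids)
        sp = pop.spatial_at(gnext) if spatial else None

        # first parent: fitness-weighted draw
        src_sp = (model.populations[src_idx].spatial_at(gen) if spatial else None)
        if spatial and src_sp is not None and src_sp.competition > 0:
            w = fitness_weights(pool.loc, src_sp.competition)
            parent1 = rng.choice(pool_n, size=n_next, p=w / w.sum())
        else:
            parent1 = rng.integers(0, pool_n, n_next)

        # mate within the source population
        global_mating = (
            not spatial
            or src_sp is None
            or not math.isfinite(src_sp.mating)
            or src_sp.mating >= model.world.diagonal
        )
        if global_mating:
            mates = _global_mates(parent1, pool_n, rng)
        else:
            mates = _local_mates(pool.loc, tree_for(src_idx), parent1,
                                 src_sp.mating, rng)
        mate_ids = pool.ids[mates]

        # gene flow: replace the mate with a source-population individual
        if not founding:
            active = [
                f for f in model.gene_flows
                if f.target_idx == pop.idx and f.start_gen < gnext <= f.end_gen
            ]
            for flow in active:
                if flow.source_idx not in state.pops:
                    raise EngineError(
                        f"gene flow from {model.populations[flow.source_idx].name!r} "
                        f"into {pop.name!r}: source not alive at generation {gen}"
                    )
                mask = apply_gene_flow(n_next, flow.p_mate, rng)
                if not mask.any():
                    continue
                src_pool = state.pops[flow.source_idx]
                if spatial and flow.require_overlap:
                    src_tree = tree_for(flow.source_idx)
                    idxs = np.flatnonzero(mask)
                    r_m = sp.mating if sp is not None else np.inf
                    lists = src_tree.query_ball_point(
                        pool.loc[parent1[idxs]], r_m
                    )
                    failures = 0
                    for w_i, off in enumerate(idxs):
                        cand = lists[w_i]
                        if cand:
                            pick = cand[rng.integers(len(cand))]
                        else:
                            failures += 1
                            _, nearest = src_tree.query(pool.loc[parent1[off]], k=1)
                            pick = int(nearest)
                        mate_ids[off] = src_pool.ids[pick]
                    if failures and failures >= 0.99 * len(idxs):
                        raise EngineError(
                            f"gene flow from "
                            f"{model.populations[flow.source_idx].name!r} into "
                            f"{pop.name!r} at generation {gnext}: ranges do not "
                            f"overlap within the mating radius "
                            f"({failures}/{len(idxs)} draws failed)"
                        )
                else:
                    picks = rng.integers(0, len(src_pool.ids), int(mask.sum()))
                    mate_ids[mask] = src_pool.ids[picks]

        parent1_ids = pool.ids[parent1]

        # offspring locations
        if spatial:
            region = pop.range_at(gnext)
            loc, rej, _ = _disperse_batch(
                pool.loc[parent1], sp, region.geometry, model.world, region,
                rng, params.max_placement_attempts,
            )
            state.dispersal_rejections += rej
        else:
            loc = None

        ids = builder.add_individuals(pop.idx, gnext, loc, parent1_ids, mate_ids)

        # two gametes per offspring: node 2i from parent1, node 2i+1 from mate
        all_parents = np.concatenate([parent1_ids, mate_ids])
        child_nodes = np.concatenate([2 * ids, 2 * ids + 1])
        el, er, epar, echild = _gamete_edges(rng, all_parents, child_nodes, rho, L)
        builder.add_edges(el, er, epar, echild)

        new_pops[pop.idx] = _PopState(ids, loc)

    return EngineState(
        generation=gnext, pops=new_pops, rng=rng, builder=builder,
        spatial=spatial, dispersal_rejections=state.dispersal_rejections,
    )


def _apply_sampling(state: EngineState, model: CompiledModel,
                    rng: np.random.Generator) -> None:
    gen = state.generation
    for ev in model.sampling:
        if ev.gen != gen:
            continue
        if ev.pop_idx not in state.pops:
            raise EngineError(
                f"sampling event at generation {gen} targets "
                f"{model.populations[ev.pop_idx].name!r}, which is not alive"
            )
        pool = state.pops[ev.pop_idx]
        n_pool = len(pool.ids)
        if ev.n > n_pool:
            raise EngineError(
                f"sampling event for {model.populations[ev.pop_idx].name!r} at "
                f"time {ev.time_user} (generation {gen}) requests {ev.n} "
                f"individuals but only {n_pool} are alive"
            )
        if ev.location is not None:
            d = np.hypot(pool.loc[:, 0] - ev.location[0],
                         pool.loc[:, 1] - ev.location[1])
            order = np.lexsort((pool.ids, d))
            chosen = pool.ids[order[: ev.n]]
        else:
            chosen = pool.ids[rng.choice(n_pool, size=ev.n, replace=False)]
        state.builder.mark_sampled(ev.pop_idx, np.sort(chosen))


def run_simulation(
    model: CompiledModel, params: SimulationParams
) -> tuple[GenealogyTables, EngineState]:
    """Run the model forward for its full span and return raw tables.

    The returned tables are unsimplified: they contain every individual
    ever alive.  Sampled nodes are flagged; with no scheduled sampling all
    individuals alive at the final generation are samples.  Typical
    post-processing is ``simplify(tables, tables.sample_nodes)`` followed
    by ``overlay_mutations``.
    """
    spatial = params.spatial if params.spatial is not None else model.is_spatial
    if spatial and not model.is_spatial:
        raise EngineError("spatial run requested but the model has no world")
    rng = np.random.default_rng(params.seed)
    builder = _TableBuilder(model, params.sequence_length)
    state = EngineState(generation=1, pops={}, rng=rng, builder=builder,
                        spatial=spatial)

    # generation 1: root populations starting at the oldest time
    for pop in model.populations:
        if pop.start_gen != 1:
            continue
        n0 = pop.N_at(1)
        if spatial:
            region = pop.range_at(1)
            loc = sample_point_uniform(model.world, region, rng, size=n0)
        else:
            loc = None
        ids = builder.add_individuals(
            pop.idx, 1, loc, np.full(n0, -1, np.int64), np.full(n0, -1, np.int64)
        )
        state.pops[pop.idx] = _PopState(ids, loc)
    _apply_sampling(state, model, rng)

    for gen in range(2, model.G + 1):
        state = wf_step(state, model, params, rng)
        _apply_sampling(state, model, rng)
        if not params.quiet and gen % 100 == 0:
            census = ", ".join(f"{k}={v}" for k, v in state.census().items())
            logger.info(
                "generation %d/%d: %s; dispersal rejections so far: %d",
                gen, model.G, census, state.dispersal_rejections,
            )

    if not model.sampling:
        # default: everyone alive at the end is a sample
        for idx, pool in sorted(state.pops.items()):
            builder.mark_sampled(idx, pool.ids)

    tables = builder.finalize()
    return tables, state
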