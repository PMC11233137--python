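"""Declarative demographic models and their compilation.

A model is built from small components: :func:`population` configurations,
scheduled events (:func:`resize`, :func:`move`, :func:`expand_range`,
:func:`set_dispersal`, :func:`gene_flow`) and sampling events.  Times are
given in whatever units the user prefers, either forwards or backwards; the
direction is inferred from the event structure and everything is converted
to forward generation indices by :func:`compile_model` via the
``generation_time`` argument.

Conventions fixed here:

* the oldest time in the model is generation 1 and the simulation ends at
  generation ``G = round(|T1 - T0| / generation_time) + 1``;
* a gene-flow event with total rate ``r`` over ``T`` generations is
  converted to the per-generation ancestry rate ``m = 1 - (1 - r)**(1/T)``
  (so that ``1 - (1 - m)**T == r``); the engine draws the second parent
  (the mate) from the source population with probability ``2 m`` because a
  mate contributes only half an offspring's genome;
* simultaneous events at one generation apply in the order resizes,
  range updates, dispersal changes, gene-flow activation, sampling.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import shapely
import shapely.affinity

from .landscape import Point, Region, World, translate_region, buffer_region

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialParams",
    "PopulationConfig",
    "Resize",
    "Move",
    "Expand",
    "DispersalChange",
    "GeneFlow",
    "SamplingEvent",
    "CompiledModel",
    "population",
    "resize",
    "move",
    "expand_range",
    "set_dispersal",
    "gene_flow",
    "sampling_event",
    "schedule_sampling",
    "infer_direction",
    "compile_model",
    "ModelError",
]

KERNELS = ("normal", "uniform", "cauchy", "exponential", "brownian")

_NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")


class ModelError(ValueError):
    """Raised when a model fails a consistency check."""


# ---------------------------------------------------------------------------
# model components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialParams:
    """Within-population interaction and dispersal parameters (map units).

    ``None`` fields mean "inherit": the compile-time defaults for a
    population, or the previously active value for a scheduled change.

    * ``competition``: neighborhood radius of density-dependent fitness;
      0 disables density dependence entirely.
    * ``mating``: maximum distance at which a mate is searched for.
    * ``dispersal``: scale of the offspring dispersal kernel.
    * ``dispersal_fun``: one of normal, uniform, cauchy, exponential,
      brownian.
    """

    competition: Optional[float] = None
    mating: Optional[float] = None
    dispersal: Optional[float] = None
    dispersal_fun: Optional[str] = None

    def __post_init__(self) -> None:
        if self.competition is not None and self.competition < 0:
            raise ModelError("competition radius must be >= 0")
        if self.mating is not None and not self.mating > 0:
            raise ModelError("mating radius must be > 0 (may be math.inf)")
        if self.dispersal is not None and not self.dispersal > 0:
            raise ModelError("dispersal scale must be > 0")
        if self.dispersal_fun is not None and self.dispersal_fun not in KERNELS:
            raise ModelError(
                f"unknown dispersal kernel {self.dispersal_fun!r}; choose from {KERNELS}"
            )

    def merged_over(self, base: "SpatialParams") -> "SpatialParams":
        """Fill unset fields from ``base`` (used for partial updates)."""
        return SpatialParams(
            competition=self.competition if self.competition is not None else base.competition,
            mating=self.mating if self.mating is not None else base.mating,
            dispersal=self.dispersal if self.dispersal is not None else base.dispersal,
            dispersal_fun=self.dispersal_fun if self.dispersal_fun is not None else base.dispersal_fun,
        )


@dataclass(frozen=True)
class PopulationConfig:
    name: str
    start_time: float
    N: int
    parent: Optional[str] = None
    initial_range: Optional[Region] = None
    spatial: Optional[SpatialParams] = None
    removal_time: Optional[float] = None


PopRef = Union[str, PopulationConfig]


def _pop_name(pop: PopRef) -> str:
    return pop.name if isinstance(pop, PopulationConfig) else str(pop)


def population(
    name: str,
    time: float,
    N: int,
    parent: Optional[PopRef] = None,
    range: Optional[Region] = None,
    spatial: Optional[SpatialParams] = None,
    removal_time: Optional[float] = None,
) -> PopulationConfig:
    """Declare a population appearing at ``time`` with ``N`` diploids.

    A ``parent`` makes this a daughter population: at its first generation
    its founders are offspring of parents drawn from the parent population.
    """
    if not _NAME_RE.match(name):
        raise ModelError(f"population name {name!r} must match [A-Za-z0-9_]+")
    if int(N) <= 0:
        raise ModelError(f"population {name!r}: N must be positive, got {N}")
    return PopulationConfig(
        name=name,
        start_time=float(time),
        N=int(N),
        parent=_pop_name(parent) if parent is not None else None,
        initial_range=range,
        spatial=spatial,
        removal_time=float(removal_time) if removal_time is not None else None,
    )


@dataclass(frozen=True)
class Resize:
    pop: str
    time: float
    N_new: int
    how: str = "step"  # "step" or "exponential"
    end_time: Optional[float] = None


@dataclass(frozen=True)
class Move:
    pop: str
    start: float
    end: float
    waypoints: tuple[Point, ...]


@dataclass(frozen=True)
class Expand:
    pop: str
    start: float
    end: float
    by: float


@dataclass(frozen=True)
class DispersalChange:
    pop: str
    time: float
    params: SpatialParams


@dataclass(frozen=True)
class GeneFlow:
    source: str
    target: str
    rate: float
    start: float
    end: float
    require_overlap: bool = True


Event = Union[Resize, Move, Expand, DispersalChange, GeneFlow]


def resize(pop: PopRef, time: float, N: int, how: str = "step",
           end_time: Optional[float] = None) -> Resize:
    """Schedule a population-size change (stepwise or exponential)."""
    if how not in ("step", "exponential"):
        raise ModelError(f"resize how={how!r} must be 'step' or 'exponential'")
    if how == "exponential" and end_time is None:
        raise ModelError("exponential resize requires end_time")
    if int(N) <= 0:
        raise ModelError("resize target N must be positive")
    return Resize(_pop_name(pop), float(time), int(N), how,
                  float(end_time) if end_time is not None else None)


def move(pop: PopRef, waypoints: Sequence[Point], start: float, end: float) -> Move:
    """Displace a population range along a piecewise-linear trajectory.

    The range centroid travels from its current position through the
    waypoints at constant speed along the path's arc length; one range
    snapshot is produced per generation of the window.
    """
    wps = tuple(Point(float(x), float(y)) for x, y in waypoints)
    if len(wps) < 1:
        raise ModelError("move requires at least one waypoint")
    return Move(_pop_name(pop), float(start), float(end), wps)


def expand_range(pop: PopRef, by: float, start: float, end: float) -> Expand:
    """Grow (or with ``by < 0`` shrink) a population range gradually."""
    return Expand(_pop_name(pop), float(start), float(end), float(by))


def set_dispersal(
    pop: PopRef,
    time: float,
    competition: Optional[float] = None,
    mating: Optional[float] = None,
    dispersal: Optional[float] = None,
    dispersal_fun: Optional[str] = None,
) -> DispersalChange:
    """Schedule a (partial) change of spatial interaction parameters."""
    params = SpatialParams(competition, mating, dispersal, dispersal_fun)
    if all(v is None for v in (competition, mating, dispersal, dispersal_fun)):
        raise ModelError("set_dispersal: no parameter given")
    return DispersalChange(_pop_name(pop), float(time), params)


def gene_flow(
    source: PopRef,
    target: PopRef,
    rate: float,
    start: float,
    end: float,
    require_overlap: bool = True,
) -> GeneFlow:
    """Schedule gene flow contributing total ancestry ``rate`` over a window."""
    rate = float(rate)
    if not 0.0 <= rate <= 1.0:
        raise ModelError(f"gene-flow rate must be in [0, 1], got {rate}")
    if start == end:
        raise ModelError("gene-flow window is empty")
    return GeneFlow(_pop_name(source), _pop_name(target), rate,
                    float(start), float(end), bool(require_overlap))


@dataclass(frozen=True)
class SamplingEvent:
    time: float
    pop: str
    n: int
    location: Optional[Point] = None

    def __post_init__(self) -> None:
        if int(self.n) < 1:
            raise ModelError("sampling requires n >= 1")


def sampling_event(time: float, pop: PopRef, n: int,
                   location: Optional[Point] = None) -> SamplingEvent:
    loc = Point(float(location[0]), float(location[1])) if location is not None else None
    return SamplingEvent(float(time), _pop_name(pop), int(n), loc)


# ---------------------------------------------------------------------------
# time handling
# ---------------------------------------------------------------------------

def infer_direction(
    populations: Sequence[PopulationConfig], events: Sequence[Event]
) -> str:
    """Detect whether model times run forward or backward.

    Backward iff daughter start times and event windows decrease numerically
    along the causal order; forward iff they increase.  Mixed or absent
    signals are an error: pass ``direction`` explicitly in that case.
    """
    signs: list[int] = []
    by_name = {p.name: p for p in populations}
    for p in populations:
        if p.parent is not None and p.parent in by_name:
            d = p.start_time - by_name[p.parent].start_time
            if d != 0:
                signs.append(1 if d > 0 else -1)
    for ev in events:
        pairs = []
        if isinstance(ev, (Move, Expand, GeneFlow)):
            pairs.append((ev.start, ev.end))
        elif isinstance(ev, Resize) and ev.how == "exponential":
            pairs.append((ev.time, ev.end_time))
        for a, b in pairs:
            if b != a:
                signs.append(1 if b > a else -1)
    for p in populations:
        if p.removal_time is not None and p.removal_time != p.start_time:
            signs.append(1 if p.removal_time > p.start_time else -1)
    if not signs:
        raise ModelError(
            "cannot infer time direction (no splits or windowed events); "
            "pass direction='forward' or 'backward' explicitly"
        )
    if all(s > 0 for s in signs):
        return "forward"
    if all(s < 0 for s in signs):
        return "backward"
    raise ModelError(
        "conflicting time signals; pass direction explicitly"
    )


def _to_gen(t: float, T0: float, g: float, direction: str) -> int:
    span = (t - T0) if direction == "forward" else (T0 - t)
    return int(round(span / g)) + 1


def _from_gen(gen: int, T0: float, g: float, direction: str) -> float:
    off = (gen - 1) * g
    return T0 + off if direction == "forward" else T0 - off


# ---------------------------------------------------------------------------
# compiled model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResolvedSpatial:
    competition: float
    mating: float
    dispersal: float
    dispersal_fun: str


@dataclass
class CompiledPopulation:
    name: str
    idx: int
    parent_idx: int  # -1 for root populations
    start_gen: int
    end_gen: int  # inclusive
    N_of_gen: np.ndarray  # int64, length G + 1; 0 where the population is dead
    # generation-indexed stepwise schedules, sorted by generation
    ranges: list[tuple[int, Region]] = field(default_factory=list)
    spatial: list[tuple[int, ResolvedSpatial]] = field(default_factory=list)

    def alive_at(self, gen: int) -> bool:
        return self.start_gen <= gen <= self.end_gen

    def N_at(self, gen: int) -> int:
        return int(self.N_of_gen[gen])

    def range_at(self, gen: int) -> Optional[Region]:
        out = None
        for g, r in self.ranges:
            if g <= gen:
                out = r
            else:
                break
        return out

    def spatial_at(self, gen: int) -> Optional[ResolvedSpatial]:
        out = None
        for g, s in self.spatial:
            if g <= gen:
                out = s
            else:
                break
        return out


@dataclass(frozen=True)
class CompiledGeneFlow:
    source_idx: int
    target_idx: int
    rate: float
    m: float       # per-generation ancestry rate: 1 - (1 - m)**T == rate
    p_mate: float  # engine mate-draw probability (2 m, capped at 1)
    start_gen: int
    end_gen: int   # offspring cohorts start_gen+1 .. end_gen receive migrant mates
    require_overlap: bool


@dataclass(frozen=True)
class CompiledSampling:
    gen: int
    pop_idx: int
    n: int
    location: Optional[Point]
    time_user: float


@dataclass
class CompiledModel:
    world: Optional[World]
    direction: str
    generation_time: float
    T0: float  # oldest user time (generation 1)
    T1: float  # final user time (generation G)
    G: int
    populations: list[CompiledPopulation]
    gene_flows: list[CompiledGeneFlow]
    sampling: list[CompiledSampling]
    # original declarative inputs, kept for serialization round-trips
    config_populations: tuple[PopulationConfig, ...] = ()
    config_events: tuple[Event, ...] = ()
    config_sampling: tuple[SamplingEvent, ...] = ()
    name: str = "model"

    @property
    def is_spatial(self) -> bool:
        return self.world is not None

    @property
    def pop_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def pop(self, name: str) -> CompiledPopulation:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"no population named {name!r}")

    def to_generations(self, t: float) -> int:
        """Map a user-unit time onto a generation index in [1, G]."""
        gen = _to_gen(float(t), self.T0, self.generation_time, self.direction)
        if not 1 <= gen <= self.G:
            raise ModelError(
                f"time {t} maps to generation {gen}, outside the model span "
                f"[{self.T0}, {self.T1}] (generations 1..{self.G})"
            )
        return gen

    def from_generations(self, gen) -> float:
        """Inverse of :meth:`to_generations`; accepts scalars or arrays."""
        gen = np.asarray(gen, dtype=float)
        off = (gen - 1.0) * self.generation_time
        out = self.T0 + off if self.direction == "forward" else self.T0 - off
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def _stamp(t: float, gen: int) -> str:
    return f"time {t} (generation {gen})"


def compile_model(
    populations: Sequence[PopulationConfig],
    events: Sequence[Event] = (),
    sampling: Sequence[SamplingEvent] = (),
    generation_time: float = 1.0,
    direction: Optional[str] = None,
    world: Optional[World] = None,
    end_time: Optional[float] = None,
    name: str = "model",
) -> CompiledModel:
    """Validate a model and index every schedule by forward generation.

    ``end_time`` marks the final simulated time; if omitted it defaults to
    the latest time mentioned anywhere in the model (forward models) or to
    0, "the present" (backward models).  Compilation is pure: the same
    inputs always produce an identical compiled model.
    """
    populations = list(populations)
    events = list(events)
    sampling = list(sampling)
    g = float(generation_time)
    if not g > 0:
        raise ModelError("generation_time must be positive")

    # -- names ------------------------------------------------------------
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ModelError(f"duplicate population names: {dupes}")
    by_name = {p.name: p for p in populations}
    for p in populations:
        if p.parent is not None and p.parent not in by_name:
            raise ModelError(f"population {p.name!r}: unknown parent {p.parent!r}")
        if p.initial_range is not None and world is None:
            raise ModelError(
                f"population {p.name!r} has a spatial range but no world was given"
            )
    referenced = set()
    for ev in events:
        referenced.update(
            [ev.source, ev.target] if isinstance(ev, GeneFlow) else [ev.pop]
        )
    for s in sampling:
        referenced.add(s.pop)
    unknown = sorted(referenced - set(names))
    if unknown:
        raise ModelError(f"events or sampling refer to unknown populations: {unknown}")

    # -- direction and span ----------------------------------------------
    if direction is None:
        direction = infer_direction(populations, events)
    if direction not in ("forward", "backward"):
        raise ModelError(f"direction must be 'forward' or 'backward', got {direction!r}")

    times: list[float] = [p.start_time for p in populations]
    times += [p.removal_time for p in populations if p.removal_time is not None]
    for ev in events:
        if isinstance(ev, (Move, Expand, GeneFlow)):
            times += [ev.start, ev.end]
        elif isinstance(ev, Resize):
            times += [ev.time] + ([ev.end_time] if ev.end_time is not None else [])
        elif isinstance(ev, DispersalChange):
            times += [ev.time]
    times += [s.time for s in sampling]
    if end_time is not None:
        times.append(float(end_time))
    if direction == "forward":
        T0 = min(times)
        T1 = float(end_time) if end_time is not None else max(times)
        if T1 < max(times):
            raise ModelError(f"end_time {T1} precedes the latest model time {max(times)}")
    else:
        T0 = max(times)
        T1 = float(end_time) if end_time is not None else min(min(times), 0.0)
        if T1 > min(times):
            raise ModelError(f"end_time {T1} precedes the latest model time {min(times)}")
    G = int(round(abs(T1 - T0) / g)) + 1

    def to_gen(t: float) -> int:
        return _to_gen(t, T0, g, direction)

    # -- populations ------------------------------------------------------
    compiled: list[CompiledPopulation] = []
    for idx, p in enumerate(populations):
        start_gen = to_gen(p.start_time)
        end_gen = to_gen(p.removal_time) if p.removal_time is not None else G
        if not 1 <= start_gen <= G:
            raise ModelError(
                f"population {p.name!r} starts at {_stamp(p.start_time, start_gen)}, "
                f"outside the model span"
            )
        if end_gen < start_gen:
            raise ModelError(
                f"population {p.name!r} removed at {_stamp(p.removal_time, end_gen)} "
                f"before it exists"
            )
        N_of_gen = np.zeros(G + 1, dtype=np.int64)
        N_of_gen[start_gen : end_gen + 1] = p.N
        compiled.append(
            CompiledPopulation(
                name=p.name, idx=idx,
                parent_idx=names.index(p.parent) if p.parent is not None else -1,
                start_gen=start_gen, end_gen=end_gen, N_of_gen=N_of_gen,
            )
        )
    for cp, p in zip(compiled, populations):
        if cp.parent_idx >= 0:
            par = compiled[cp.parent_idx]
            if cp.start_gen <= par.start_gen:
                raise ModelError(
                    f"population {cp.name!r} starts at generation {cp.start_gen}, "
                    f"not strictly after its parent {par.name!r} (generation {par.start_gen})"
                )
            if par.end_gen < cp.start_gen - 1:
                raise ModelError(
                    f"population {cp.name!r} splits from {par.name!r} at generation "
                    f"{cp.start_gen} but the parent is removed at generation {par.end_gen}"
                )

    def require_alive(pop: CompiledPopulation, gen: int, t: float, what: str) -> None:
        if not pop.alive_at(gen):
            raise ModelError(
                f"{what} scheduled for population {pop.name!r} at {_stamp(t, gen)}, "
                f"when it does not exist (alive generations "
                f"{pop.start_gen}..{pop.end_gen})"
            )

    def window_gens(start: float, end: float, what: str) -> tuple[int, int]:
        gs, ge = to_gen(start), to_gen(end)
        if ge <= gs:
            raise ModelError(
                f"{what}: window {_stamp(start, gs)} .. {_stamp(end, ge)} is empty "
                f"or runs against the model's {direction} time direction"
            )
        if gs < 1 or ge > G:
            raise ModelError(f"{what}: window outside the model span")
        return gs, ge

    # -- N schedules (resizes first, per the fixed event ordering) ---------
    resizes = [ev for ev in events if isinstance(ev, Resize)]
    for ev in sorted(resizes, key=lambda e: to_gen(e.time)):
        pop = compiled[names.index(ev.pop)]
        t_gen = to_gen(ev.time)
        require_alive(pop, t_gen, ev.time, "resize")
        if ev.how == "step":
            pop.N_of_gen[t_gen : pop.end_gen + 1] = ev.N_new
        else:
            gs, ge = window_gens(ev.time, ev.end_time, f"resize of {ev.pop!r}")
            require_alive(pop, ge, ev.end_time, "resize")
            N0 = pop.N_at(gs)
            T = ge - gs
            ks = np.arange(gs, ge + 1)
            sched = np.rint(N0 * (ev.N_new / N0) ** ((ks - gs) / T)).astype(np.int64)
            pop.N_of_gen[gs : ge + 1] = sched
            pop.N_of_gen[ge : pop.end_gen + 1] = ev.N_new

    # -- range snapshots ---------------------------------------------------
    if world is not None:
        habitable = world.habitable_geometry

        def clipped_region(name: str, geom, gen: int, what: str) -> Region:
            inter = geom.intersection(habitable).intersection(world.extent_polygon)
            if inter.is_empty or inter.area <= 0:
                raise ModelError(
                    f"{what}: population {name!r} range has zero habitable area at "
                    f"generation {gen}"
                )
            return Region(name, inter)

        # working (unclipped) geometry per population, evolved through events
        base_geom = {}
        for cp, p in zip(compiled, populations):
            geom = (p.initial_range.geometry if p.initial_range is not None
                    else world.habitable_geometry)
            base_geom[cp.name] = geom
            cp.ranges.append(
                (cp.start_gen, clipped_region(cp.name, geom, cp.start_gen, "initial range"))
            )

        range_events = [ev for ev in events if isinstance(ev, (Move, Expand))]
        for ev in sorted(range_events, key=lambda e: (to_gen(e.start), to_gen(e.end))):
            pop = compiled[names.index(ev.pop)]
            what = ("move" if isinstance(ev, Move) else "range expansion") + f" of {ev.pop!r}"
            gs, ge = window_gens(ev.start, ev.end, what)
            require_alive(pop, gs, ev.start, what)
            require_alive(pop, ge, ev.end, what)
            T = ge - gs
            geom = base_geom[ev.pop]
            if isinstance(ev, Move):
                c = geom.centroid
                path = [Point(c.x, c.y)] + list(ev.waypoints)
                seg_len = [
                    math.hypot(b[0] - a[0], b[1] - a[1])
                    for a, b in zip(path[:-1], path[1:])
                ]
                total = sum(seg_len)
                cum = np.concatenate([[0.0], np.cumsum(seg_len)])
                for k in range(1, T + 1):
                    s = total * k / T
                    j = int(np.searchsorted(cum, s, side="right")) - 1
                    j = min(j, len(seg_len) - 1)
                    frac = 0.0 if seg_len[j] == 0 else (s - cum[j]) / seg_len[j]
                    x = path[j][0] + frac * (path[j + 1][0] - path[j][0])
                    y = path[j][1] + frac * (path[j + 1][1] - path[j][1])
                    moved = shapely.affinity.translate(geom, x - c.x, y - c.y)
                    pop.ranges.append(
                        (gs + k, clipped_region(ev.pop, moved, gs + k, what))
                    )
                    if k == T:
                        base_geom[ev.pop] = moved
            else:
                for k in range(1, T + 1):
                    d = ev.by * k / T
                    grown = geom.buffer(d) if d != 0 else geom
                    if grown.is_empty or grown.area <= 0:
                        raise ModelError(
                            f"{what}: contraction by {d:g} annihilates the range at "
                            f"generation {gs + k}"
                        )
                    pop.ranges.append(
                        (gs + k, clipped_region(ev.pop, grown, gs + k, what))
                    )
                    if k == T:
                        base_geom[ev.pop] = grown
        for cp in compiled:
            cp.ranges.sort(key=lambda t: t[0])

    # -- spatial parameter schedules ---------------------------------------
    if world is not None:
        diag = world.diagonal
        default = ResolvedSpatial(
            competition=0.0, mating=diag, dispersal=diag / 50.0, dispersal_fun="normal"
        )
        base_sp = SpatialParams(default.competition, default.mating,
                                default.dispersal, default.dispersal_fun)
        for cp, p in zip(compiled, populations):
            sp = (p.spatial.merged_over(base_sp) if p.spatial is not None else base_sp)
            cp.spatial.append((cp.start_gen, ResolvedSpatial(
                sp.competition, sp.mating, sp.dispersal, sp.dispersal_fun)))
        changes = [ev for ev in events if isinstance(ev, DispersalChange)]
        for decl_order, ev in sorted(
            enumerate(changes), key=lambda t: (to_gen(t[1].time), t[0])
        ):
            pop = compiled[names.index(ev.pop)]
            t_gen = to_gen(ev.time)
            require_alive(pop, t_gen, ev.time, "dispersal change")
            prev = pop.spatial_at(t_gen)
            cur = SpatialParams(prev.competition, prev.mating, prev.dispersal,
                                prev.dispersal_fun)
            sp = ev.params.merged_over(cur)
            new = ResolvedSpatial(sp.competition, sp.mating, sp.dispersal, sp.dispersal_fun)
            if any(g == t_gen for g, _ in pop.spatial):
                logger.warning(
                    "two dispersal changes for %r at generation %d; later declaration wins",
                    ev.pop, t_gen,
                )
                pop.spatial = [(g, s) for g, s in pop.spatial if g != t_gen]
            pop.spatial.append((t_gen, new))
            pop.spatial.sort(key=lambda t: t[0])
    else:
        for ev in events:
            if isinstance(ev, (Move, Expand, DispersalChange)):
                raise ModelError(
                    f"spatial event {type(ev).__name__} for {ev.pop!r} requires a world"
                )

    # -- gene flow ----------------------------------------------------------
    flows: list[CompiledGeneFlow] = []
    for ev in events:
        if not isinstance(ev, GeneFlow):
            continue
        src = compiled[names.index(ev.source)]
        dst = compiled[names.index(ev.target)]
        what = f"gene flow {ev.source!r} -> {ev.target!r}"
        gs, ge = window_gens(ev.start, ev.end, what)
        # offspring cohorts gs+1..ge draw mates from source generations gs..ge-1
        for gen, t in ((gs, ev.start), (ge, ev.end)):
            require_alive(dst, gen, t, what)
        for gen, t in ((gs, ev.start), (ge - 1, ev.end)):
            require_alive(src, gen, t, what)
        T = ge - gs
        m = 1.0 - (1.0 - ev.rate) ** (1.0 / T)
        flows.append(
            CompiledGeneFlow(
                source_idx=src.idx, target_idx=dst.idx, rate=ev.rate, m=m,
                p_mate=min(1.0, 2.0 * m), start_gen=gs, end_gen=ge,
                require_overlap=ev.require_overlap,
            )
        )

    # -- sampling ------------------------------------------------------------
    compiled_sampling: list[CompiledSampling] = []
    for decl_order, s in enumerate(sampling):
        pop = compiled[names.index(s.pop)]
        s_gen = to_gen(s.time)
        require_alive(pop, s_gen, s.time, "sampling")
        if s.location is not None:
            if world is None:
                raise ModelError("sampling location given for a non-spatial model")
            xmin, ymin, xmax, ymax = world.extent
            x, y = s.location
            if not (xmin <= x <= xmax and ymin <= y <= ymax):
                raise ModelError(
                    f"sampling location {tuple(s.location)} outside the world extent"
                )
        compiled_sampling.append(
            CompiledSampling(gen=s_gen, pop_idx=pop.idx, n=int(s.n),
                             location=s.location, time_user=s.time)
        )
    compiled_sampling.sort(key=lambda c: (c.gen, c.pop_idx))

    return CompiledModel(
        world=world, direction=direction, generation_time=g,
        T0=T0, T1=T1, G=G,
        populations=compiled, gene_flows=flows, sampling=compiled_sampling,
        config_populations=tuple(populations), config_events=tuple(events),
        config_sampling=tuple(sampling), name=name,
    )


def schedule_sampling(
    model: CompiledModel,
    times: Sequence[float],
    pop: PopRef,
    n: int,
    location: Optional[Point] = None,
) -> list[SamplingEvent]:
    """Append sampling events (validated against the model) and return them.

    With a ``location`` the engine samples the ``n`` living individuals
    nearest to it; otherwise individuals are drawn uniformly without
    replacement.
    """
    name = _pop_name(pop)
    evs = [sampling_event(t, name, n, location) for t in times]
    cpop = model.pop(name)
    for ev in evs:
        s_gen = model.to_generations(ev.time)
        if not cpop.alive_at(s_gen):
            raise ModelError(
                f"sampling from {name!r} at {_stamp(ev.time, s_gen)}, outside its "
                f"lifespan (generations {cpop.start_gen}..{cpop.end_gen})"
            )
        if ev.location is not None:
            if model.world is None:
                raise ModelError("sampling location given for a non-spatial model")
            xmin, ymin, xmax, ymax = model.world.extent
            if not (xmin <= ev.location[0] <= xmax and ymin <= ev.location[1] <= ymax):
                raise ModelError(
                    f"sampling location {tuple(ev.location)} outside the world extent"
                )
        model.sampling.append(
            CompiledSampling(gen=s_gen, pop_idx=cpop.idx, n=ev.n,
                             location=ev.location, time_user=ev.time)
        )
    model.sampling.sort(key=lambda c: (c.gen, c.pop_idx))
    model.config_sampling = model.config_sampling + tuple(evs)
    return evs
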