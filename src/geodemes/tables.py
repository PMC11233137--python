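"""Succinct genealogy tables: storage, simplification, mutations, trees.

The simulation's primary output is a set of flat tables over a genome
``[0, L)``: nodes (genome copies, two per diploid individual), individuals,
edges (inheritance intervals ``[left, right)`` from a parent node to a
child node), sites (integer positions with an ancestral state) and
mutations (one per site; infinite-sites model, ancestral "A", derived "T").

Node times are stored internally as forward birth generations; conversion
to the user's time units happens at export, via the compiled model.

:func:`simplify` reduces the tables to the ancestry of a chosen sample set,
keeping, per genomic interval, only nodes that are a most recent common
ancestor of at least two samples (no unary-node retention).  The algorithm
is a flat-array segment-propagation scheme jitted with numba; it is
validated in the test suite against both a brute-force pedigree-tracing
oracle and an independent tree-sequence library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from numba import njit

__all__ = [
    "GenealogyTables",
    "MarginalTree",
    "simplify",
    "overlay_mutations",
    "iterate_trees",
    "fully_coalesced",
]

ANCESTRAL_STATE = "A"
DERIVED_STATE = "T"


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class GenealogyTables:
    """Node/individual/edge/site/mutation tables over a [0, L) genome."""

    sequence_length: float
    # nodes
    node_birth_gen: np.ndarray    # int64, forward generation of birth
    node_population: np.ndarray   # int32 population index
    node_individual: np.ndarray   # int64 individual id (-1 if none)
    node_is_sample: np.ndarray    # bool
    # individuals
    indiv_population: np.ndarray  # int32
    indiv_birth_gen: np.ndarray   # int64
    indiv_x: np.ndarray           # float64 (NaN in non-spatial models)
    indiv_y: np.ndarray           # float64
    indiv_names: dict[int, str] = field(default_factory=dict)  # sampled only
    # edges
    edges_left: np.ndarray = field(default_factory=lambda: np.empty(0))
    edges_right: np.ndarray = field(default_factory=lambda: np.empty(0))
    edges_parent: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    edges_child: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    # sites & mutations (infinite sites: exactly one mutation per site)
    sites_position: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    mut_site: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    mut_node: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    population_names: list[str] = field(default_factory=list)

    @property
    def num_nodes(self) -> int:
        return len(self.node_birth_gen)

    @property
    def num_individuals(self) -> int:
        return len(self.indiv_birth_gen)

    @property
    def num_edges(self) -> int:
        return len(self.edges_left)

    @property
    def num_sites(self) -> int:
        return len(self.sites_position)

    @property
    def sample_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.node_is_sample)

    def nodes_of_individual(self, indiv: int) -> np.ndarray:
        return np.flatnonzero(self.node_individual == indiv)

    def individual_by_name(self, name: str) -> int:
        for i, nm in self.indiv_names.items():
            if nm == name:
                return i
        raise KeyError(f"no sampled individual named {name!r}")

    def validate(self) -> None:
        """Check the structural invariants; raises ValueError on violation."""
        L = self.sequence_length
        if np.any(self.edges_left >= self.edges_right):
            raise ValueError("edge with left >= right")
        if np.any(self.edges_left < 0) or np.any(self.edges_right > L):
            raise ValueError("edge outside [0, L)")
        pg = self.node_birth_gen[self.edges_parent]
        cg = self.node_birth_gen[self.edges_child]
        if np.any(pg >= cg):
            raise ValueError("edge with parent born at/after its child")
        if len(self.mut_site) != len(self.sites_position):
            raise ValueError("infinite-sites violation: sites and mutations differ")
        if len(self.sites_position) and len(np.unique(self.sites_position)) != len(
            self.sites_position
        ):
            raise ValueError("duplicate site positions")

    def copy(self) -> "GenealogyTables":
        return GenealogyTables(
            sequence_length=self.sequence_length,
            node_birth_gen=self.node_birth_gen.copy(),
            node_population=self.node_population.copy(),
            node_individual=self.node_individual.copy(),
            node_is_sample=self.node_is_sample.copy(),
            indiv_population=self.indiv_population.copy(),
            indiv_birth_gen=self.indiv_birth_gen.copy(),
            indiv_x=self.indiv_x.copy(),
            indiv_y=self.indiv_y.copy(),
            indiv_names=dict(self.indiv_names),
            edges_left=self.edges_left.copy(),
            edges_right=self.edges_right.copy(),
            edges_parent=self.edges_parent.copy(),
            edges_child=self.edges_child.copy(),
            sites_position=self.sites_position.copy(),
            mut_site=self.mut_site.copy(),
            mut_node=self.mut_node.copy(),
            population_names=list(self.population_names),
        )


# ---------------------------------------------------------------------------
# simplification kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _grow_f8(arr):
    out = np.empty(arr.shape[0] * 2, dtype=np.float64)
    out[: arr.shape[0]] = arr
    return out


@njit(cache=True)
def _grow_i8(arr):
    out = np.empty(arr.shape[0] * 2, dtype=np.int64)
    out[: arr.shape[0]] = arr
    return out


@njit(cache=True)
def _simplify_kernel(n_nodes, el, er, ep, ec, samples, L):
    """Propagate sample ancestry up the (parent-time-ordered) edge table.

    Edges must be sorted so that groups sharing a parent are contiguous and
    parents appear in order of decreasing birth generation (children before
    their parents).  Returns the output node list (as input ids), output
    edges, and the per-input-node ancestry segment lists used afterwards to
    remap mutations.
    """
    n_edges = el.shape[0]
    S = samples.shape[0]

    out_id = np.full(n_nodes, -1, dtype=np.int64)
    is_sample = np.zeros(n_nodes, dtype=np.uint8)
    out_in_id = np.empty(n_nodes, dtype=np.int64)
    for i in range(S):
        out_id[samples[i]] = i
        is_sample[samples[i]] = 1
        out_in_id[i] = samples[i]
    n_out = S

    seg_cap = n_edges // 2 + 2 * S + 1024
    seg_l = np.empty(seg_cap, dtype=np.float64)
    seg_r = np.empty(seg_cap, dtype=np.float64)
    seg_o = np.empty(seg_cap, dtype=np.int64)
    seg_next = np.empty(seg_cap, dtype=np.int64)
    head = np.full(n_nodes, -1, dtype=np.int64)
    tail = np.full(n_nodes, -1, dtype=np.int64)
    ns = 0
    for i in range(S):
        s = samples[i]
        seg_l[ns] = 0.0
        seg_r[ns] = L
        seg_o[ns] = i
        seg_next[ns] = -1
        head[s] = ns
        tail[s] = ns
        ns += 1

    ecap = n_edges // 4 + 1024
    oel = np.empty(ecap, dtype=np.float64)
    oer = np.empty(ecap, dtype=np.float64)
    oep = np.empty(ecap, dtype=np.int64)
    oec = np.empty(ecap, dtype=np.int64)
    ne = 0

    tcap = 256
    ts_l = np.empty(tcap, dtype=np.float64)
    ts_r = np.empty(tcap, dtype=np.float64)
    ts_o = np.empty(tcap, dtype=np.int64)
    pts = np.empty(2 * tcap, dtype=np.float64)

    i = 0
    while i < n_edges:
        P = ep[i]
        # collect child segments intersected with the edges of this group
        m = 0
        j = i
        while j < n_edges and ep[j] == P:
            c = ec[j]
            l = el[j]
            r = er[j]
            s = head[c]
            while s != -1:
                if seg_r[s] > l and seg_l[s] < r:
                    if m == tcap:
                        tcap *= 2
                        ts_l = _grow_f8(ts_l)
                        ts_r = _grow_f8(ts_r)
                        ts_o = _grow_i8(ts_o)
                        pts = _grow_f8(pts)
                    ts_l[m] = seg_l[s] if seg_l[s] > l else l
                    ts_r[m] = seg_r[s] if seg_r[s] < r else r
                    ts_o[m] = seg_o[s]
                    m += 1
                s = seg_next[s]
            j += 1
        i = j
        if m == 0:
            continue

        # elementary breakpoints (buffer reused across groups)
        for t in range(m):
            pts[t] = ts_l[t]
            pts[m + t] = ts_r[t]
        pts[: 2 * m].sort()
        npts = 0
        for t in range(2 * m):
            if npts == 0 or pts[t] != pts[npts - 1]:
                pts[npts] = pts[t]
                npts += 1

        # event-driven sweep over elementary intervals with an active list
        order_start = np.argsort(ts_l[:m], kind="mergesort")
        order_end = np.argsort(ts_r[:m], kind="mergesort")
        act_next = np.full(m, -1, dtype=np.int64)
        act_prev = np.full(m, -1, dtype=np.int64)
        act_head = -1
        act_cnt = 0
        si = 0
        ei = 0

        Pv = out_id[P]
        samp = is_sample[P] == 1
        for q in range(npts - 1):
            a = pts[q]
            b = pts[q + 1]
            while ei < m and ts_r[order_end[ei]] <= a:
                t = order_end[ei]
                if act_prev[t] == -1:
                    act_head = act_next[t]
                else:
                    act_next[act_prev[t]] = act_next[t]
                if act_next[t] != -1:
                    act_prev[act_next[t]] = act_prev[t]
                act_cnt -= 1
                ei += 1
            while si < m and ts_l[order_start[si]] <= a:
                t = order_start[si]
                if ts_r[t] > a:
                    act_next[t] = act_head
                    act_prev[t] = -1
                    if act_head != -1:
                        act_prev[act_head] = t
                    act_head = t
                    act_cnt += 1
                si += 1
            cnt = act_cnt
            if cnt == 0:
                continue
            if cnt == 1 and not samp:
                o = ts_o[act_head]
                tP = tail[P]
                if tP != -1 and seg_r[tP] == a and seg_o[tP] == o:
                    seg_r[tP] = b
                else:
                    if ns == seg_cap:
                        seg_cap *= 2
                        seg_l = _grow_f8(seg_l)
                        seg_r = _grow_f8(seg_r)
                        seg_o = _grow_i8(seg_o)
                        seg_next = _grow_i8(seg_next)
                    seg_l[ns] = a
                    seg_r[ns] = b
                    seg_o[ns] = o
                    seg_next[ns] = -1
                    if head[P] == -1:
                        head[P] = ns
                    else:
                        seg_next[tail[P]] = ns
                    tail[P] = ns
                    ns += 1
            else:
                if Pv == -1:
                    Pv = n_out
                    out_id[P] = Pv
                    out_in_id[n_out] = P
                    n_out += 1
                t = act_head
                while t != -1:
                    if ne == ecap:
                        ecap *= 2
                        oel = _grow_f8(oel)
                        oer = _grow_f8(oer)
                        oep = _grow_i8(oep)
                        oec = _grow_i8(oec)
                    oel[ne] = a
                    oer[ne] = b
                    oep[ne] = Pv
                    oec[ne] = ts_o[t]
                    ne += 1
                    t = act_next[t]
                if not samp:
                    tP = tail[P]
                    if tP != -1 and seg_r[tP] == a and seg_o[tP] == Pv:
                        seg_r[tP] = b
                    else:
                        if ns == seg_cap:
                            seg_cap *= 2
                            seg_l = _grow_f8(seg_l)
                            seg_r = _grow_f8(seg_r)
                            seg_o = _grow_i8(seg_o)
                            seg_next = _grow_i8(seg_next)
                        seg_l[ns] = a
                        seg_r[ns] = b
                        seg_o[ns] = Pv
                        seg_next[ns] = -1
                        if head[P] == -1:
                            head[P] = ns
                        else:
                            seg_next[tail[P]] = ns
                        tail[P] = ns
                        ns += 1

    return (
        out_in_id[:n_out].copy(),
        oel[:ne].copy(), oer[:ne].copy(), oep[:ne].copy(), oec[:ne].copy(),
        head, seg_l[:ns].copy(), seg_r[:ns].copy(), seg_o[:ns].copy(),
        seg_next[:ns].copy(),
    )


@njit(cache=True)
def _map_mutations_kernel(mut_node, mut_pos, head, seg_l, seg_r, seg_o, seg_next):
    out = np.full(mut_node.shape[0], -1, dtype=np.int64)
    for j in range(mut_node.shape[0]):
        s = head[mut_node[j]]
        x = mut_pos[j]
        while s != -1:
            if seg_l[s] <= x < seg_r[s]:
                out[j] = seg_o[s]
                break
            s = seg_next[s]
    return out


def _canonical_edge_order(tables: GenealogyTables) -> np.ndarray:
    """Sort edges by (parent birth gen desc, parent, child, left)."""
    return np.lexsort(
        (
            tables.edges_left,
            tables.edges_child,
            tables.edges_parent,
            -tables.node_birth_gen[tables.edges_parent],
        )
    )


def _squash_edges(left, right, parent, child):
    """Merge adjacent edges with identical parent/child into maximal intervals."""
    if len(left) == 0:
        return left, right, parent, child
    order = np.lexsort((left, child, parent))
    left, right, parent, child = (a[order] for a in (left, right, parent, child))
    # a row starts a run unless it continues the previous (same parent/child,
    # touching interval); runs are contiguous after the sort
    starts = np.ones(len(left), dtype=bool)
    starts[1:] = (
        (parent[1:] != parent[:-1])
        | (child[1:] != child[:-1])
        | (left[1:] != right[:-1])
    )
    run_id = np.cumsum(starts) - 1
    n_runs = run_id[-1] + 1
    out_l = left[starts]
    out_r = np.empty(n_runs, dtype=right.dtype)
    out_r[run_id] = right  # last assignment per run wins (sorted order)
    return out_l, out_r, parent[starts], child[starts]


def simplify(
    tables: GenealogyTables,
    sample_node_ids: Sequence[int],
    map_nodes: bool = False,
):
    """Reduce the tables to the genetic ancestry of ``sample_node_ids``.

    The stated samples come first in the output (order preserved), followed
    by ancestors in order of processing (younger first).  Per genomic
    interval only marginal-tree MRCAs of sample pairs are retained; the
    marginal trees restricted to the samples are unchanged.  Mutations are
    carried through: each is re-attached to the output node that inherited
    the mutated material at its site (dropped if unobserved in the sample
    set).

    With ``map_nodes=True``, also return an array mapping input node ids to
    output ids (-1 where not retained).
    """
    samples = np.asarray(sample_node_ids, dtype=np.int64)
    if samples.size == 0:
        raise ValueError("empty sample set")
    if len(np.unique(samples)) != samples.size:
        raise ValueError("duplicate sample node ids")
    if np.any(samples < 0) or np.any(samples >= tables.num_nodes):
        raise ValueError("unknown node id in sample set")

    order = np.lexsort(
        (
            tables.edges_left,
            tables.edges_child,
            tables.edges_parent,
            -tables.node_birth_gen[tables.edges_parent],
        )
    )
    el = np.ascontiguousarray(tables.edges_left[order], dtype=np.float64)
    er = np.ascontiguousarray(tables.edges_right[order], dtype=np.float64)
    ep = np.ascontiguousarray(tables.edges_parent[order])
    ec = np.ascontiguousarray(tables.edges_child[order])

    (out_in_id, oel, oer, oep, oec,
     head, seg_l, seg_r, seg_o, seg_next) = _simplify_kernel(
        tables.num_nodes, el, er, ep, ec, samples, float(tables.sequence_length)
    )
    del el, er, ep, ec, order  # sorted copies of the input edges

    n_out = len(out_in_id)
    S = samples.size

    # nodes
    node_birth_gen = tables.node_birth_gen[out_in_id]
    node_population = tables.node_population[out_in_id]
    node_individual_in = tables.node_individual[out_in_id]
    node_is_sample = np.zeros(n_out, dtype=bool)
    node_is_sample[:S] = True

    # individuals, renumbered by first appearance in the output node order
    new_indiv = np.full(n_out, -1, dtype=np.int64)
    indiv_map: dict[int, int] = {}
    for k, iv in enumerate(node_individual_in):
        iv = int(iv)
        if iv < 0:
            continue
        if iv not in indiv_map:
            indiv_map[iv] = len(indiv_map)
        new_indiv[k] = indiv_map[iv]
    old_ids = np.array(sorted(indiv_map, key=indiv_map.get), dtype=np.int64)
    names = {
        indiv_map[int(i)]: tables.indiv_names[int(i)]
        for i in old_ids
        if int(i) in tables.indiv_names
    }

    # edges, squashed and canonically ordered
    oel, oer, oep, oec = _squash_edges(oel, oer, oep, oec)

    # mutations carried through
    if len(tables.mut_node):
        mapped = _map_mutations_kernel(
            np.ascontiguousarray(tables.mut_node),
            tables.sites_position[tables.mut_site].astype(np.float64),
            head, seg_l, seg_r, seg_o, seg_next,
        )
        keep = mapped >= 0
        positions = tables.sites_position[tables.mut_site][keep]
        nodes = mapped[keep]
        site_order = np.argsort(positions, kind="stable")
        sites_position = positions[site_order]
        mut_node = nodes[site_order]
        mut_site = np.arange(len(mut_node), dtype=np.int64)
    else:
        sites_position = np.empty(0, dtype=np.int64)
        mut_site = np.empty(0, dtype=np.int64)
        mut_node = np.empty(0, dtype=np.int64)

    out = GenealogyTables(
        sequence_length=tables.sequence_length,
        node_birth_gen=node_birth_gen,
        node_population=node_population,
        node_individual=new_indiv,
        node_is_sample=node_is_sample,
        indiv_population=tables.indiv_population[old_ids] if len(old_ids)
        else np.empty(0, np.int32),
        indiv_birth_gen=tables.indiv_birth_gen[old_ids] if len(old_ids)
        else np.empty(0, np.int64),
        indiv_x=tables.indiv_x[old_ids] if len(old_ids) else np.empty(0),
        indiv_y=tables.indiv_y[old_ids] if len(old_ids) else np.empty(0),
        indiv_names=names,
        edges_left=oel, edges_right=oer, edges_parent=oep, edges_child=oec,
        sites_position=sites_position, mut_site=mut_site, mut_node=mut_node,
        population_names=list(tables.population_names),
    )
    order = _canonical_edge_order(out)
    out.edges_left = out.edges_left[order]
    out.edges_right = out.edges_right[order]
    out.edges_parent = out.edges_parent[order]
    out.edges_child = out.edges_child[order]

    if map_nodes:
        node_map = np.full(tables.num_nodes, -1, dtype=np.int64)
        node_map[out_in_id] = np.arange(n_out)
        return out, node_map
    return out


# ---------------------------------------------------------------------------
# neutral mutation overlay
# ---------------------------------------------------------------------------

def overlay_mutations(
    tables: GenealogyTables, mu: float, rng: np.random.Generator
) -> GenealogyTables:
    """Drop neutral mutations onto the genealogy (infinite-sites model).

    Each edge receives a Poisson(mu * span_bp * branch_generations) number
    of mutations at uniform integer positions on its interval; positions
    colliding with existing sites are redrawn.  Returns a new table set;
    the input is unchanged.
    """
    if mu < 0:
        raise ValueError("mutation rate must be >= 0")
    out = tables.copy()
    if mu == 0 or tables.num_edges == 0:
        return out

    span = tables.edges_right - tables.edges_left
    branch = (
        tables.node_birth_gen[tables.edges_child]
        - tables.node_birth_gen[tables.edges_parent]
    ).astype(np.float64)
    counts = rng.poisson(mu * span * branch)
    total = int(counts.sum())
    if total == 0:
        return out

    edge_idx = np.repeat(np.arange(tables.num_edges), counts)
    lo = np.ceil(tables.edges_left[edge_idx]).astype(np.int64)
    hi = np.ceil(tables.edges_right[edge_idx]).astype(np.int64)  # exclusive
    n_int = hi - lo
    ok = n_int > 0
    edge_idx, lo, n_int = edge_idx[ok], lo[ok], n_int[ok]
    pos = lo + rng.integers(0, n_int)

    taken = set(int(p) for p in tables.sites_position)
    final_pos: list[int] = []
    final_edge: list[int] = []
    for k in range(len(pos)):
        p = int(pos[k])
        attempts = 0
        while p in taken and attempts < 100:
            p = int(lo[k] + rng.integers(0, n_int[k]))
            attempts += 1
        if p in taken:
            continue  # tiny interval fully occupied; drop (documented)
        taken.add(p)
        final_pos.append(p)
        final_edge.append(int(edge_idx[k]))

    new_pos = np.concatenate([tables.sites_position,
                              np.array(final_pos, dtype=np.int64)])
    new_node = np.concatenate([
        tables.mut_node,
        tables.edges_child[np.array(final_edge, dtype=np.int64)]
        if final_edge else np.empty(0, np.int64),
    ])
    order = np.argsort(new_pos, kind="stable")
    out.sites_position = new_pos[order]
    out.mut_node = new_node[order]
    out.mut_site = np.arange(len(out.mut_node), dtype=np.int64)
    return out


# ---------------------------------------------------------------------------
# marginal trees
# ---------------------------------------------------------------------------

@dataclass
class MarginalTree:
    """The genealogy over one non-recombined interval ``[left, right)``.

    ``parent[u]`` is the parent node of ``u`` on this interval (-1 at
    roots and at nodes without ancestral material here).
    """

    index: int  # 1-based position in the tree sequence
    left: float
    right: float
    parent: np.ndarray  # int64 over all nodes

    def children_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(len(self.parent))]
        for u, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(u)
        return out

    def root_of(self, u: int) -> int:
        while self.parent[u] >= 0:
            u = self.parent[u]
        return u


def iterate_trees(tables: GenealogyTables) -> Iterator[MarginalTree]:
    """Yield marginal trees left to right; intervals partition [0, L)."""
    L = float(tables.sequence_length)
    n = tables.num_nodes
    E = tables.num_edges
    bps = np.unique(
        np.concatenate([[0.0, L], tables.edges_left, tables.edges_right])
    )
    bps = bps[(bps >= 0) & (bps <= L)]
    ins = np.lexsort((tables.edges_child, tables.edges_left))
    rem = np.lexsort((tables.edges_child, tables.edges_right))
    parent = np.full(n, -1, dtype=np.int64)
    i = j = 0
    for t, a in enumerate(bps[:-1]):
        while j < E and tables.edges_right[rem[j]] <= a:
            parent[tables.edges_child[rem[j]]] = -1
            j += 1
        while i < E and tables.edges_left[ins[i]] <= a:
            e = ins[i]
            if tables.edges_right[e] > a:
                parent[tables.edges_child[e]] = tables.edges_parent[e]
            i += 1
        yield MarginalTree(index=t + 1, left=float(a), right=float(bps[t + 1]),
                           parent=parent.copy())


def fully_coalesced(tables: GenealogyTables) -> bool:
    """True if every marginal tree joins all samples under a single root."""
    samples = tables.sample_nodes
    for tree in iterate_trees(tables):
        roots = {tree.root_of(int(s)) for s in samples}
        if len(roots) > 1:
            return False
    return True
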