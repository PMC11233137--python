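"""Population-genetic statistics on genealogy tables with mutations.

All statistics are computed in "site mode", from the mutations overlaid on
the genealogy: diversity and divergence as per-site mean pairwise
differences, Patterson's f4 as the mean over sites of
``(p_A - p_B)(p_C - p_D)`` with ``p`` the derived-allele sample frequency
(no bias correction), the f4-ratio admixture-proportion estimate as
``f4(A, O; X, C) / f4(A, O; B, C)``, and the allele frequency spectrum as
counts of sites by derived-allele count.

Derived-allele counts per sample set are obtained by a single left-to-right
sweep over the genome that maintains the current marginal tree and, for
each site, sums set membership over the subtree below the mutation's node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .tables import GenealogyTables

__all__ = [
    "SampleSet",
    "sample_set",
    "diversity",
    "divergence",
    "f4",
    "f4_ratio",
    "afs",
    "derived_counts",
    "genotype_matrix",
    "from_population",
]


@dataclass(frozen=True)
class SampleSet:
    """A labelled group of sampled individuals (two nodes each)."""

    label: str
    individuals: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.individuals:
            raise ValueError(f"sample set {self.label!r} is empty")

    def node_ids(self, tables: GenealogyTables) -> np.ndarray:
        name_to_id = {v: k for k, v in tables.indiv_names.items()}
        nodes = []
        for name in self.individuals:
            if name not in name_to_id:
                raise KeyError(f"no sampled individual named {name!r}")
            ind = name_to_id[name]
            ids = np.flatnonzero(
                (tables.node_individual == ind) & tables.node_is_sample
            )
            if len(ids) != 2:
                raise ValueError(
                    f"individual {name!r} has {len(ids)} sample nodes, expected 2"
                )
            nodes.extend(int(i) for i in ids)
        return np.array(nodes, dtype=np.int64)


def sample_set(label: str, individuals: Sequence[str]) -> SampleSet:
    return SampleSet(label, tuple(individuals))


def from_population(
    tables: GenealogyTables, pop_name: str, n: int | None = None,
    rng: np.random.Generator | None = None, label: str | None = None,
) -> SampleSet:
    """Sample set of (optionally ``n`` random) sampled individuals of a population."""
    pop_idx = tables.population_names.index(pop_name)
    names = [
        tables.indiv_names[int(i)]
        for i in sorted(tables.indiv_names)
        if tables.indiv_population[int(i)] == pop_idx
    ]
    if not names:
        raise ValueError(f"population {pop_name!r} has no sampled individuals")
    if n is not None:
        if n > len(names):
            raise ValueError(
                f"requested {n} individuals from {pop_name!r} but only "
                f"{len(names)} were sampled"
            )
        if rng is None:
            names = names[:n]
        else:
            idx = np.sort(rng.choice(len(names), size=n, replace=False))
            names = [names[i] for i in idx]
    return SampleSet(label or pop_name, tuple(names))


# ---------------------------------------------------------------------------
# derived-allele counting sweep
# ---------------------------------------------------------------------------

@njit(cache=True)
def _count_kernel(
    n_nodes, el, er, ep, ec, ins, rem, site_pos, site_node, member, out
):
    n_edges = el.shape[0]
    k = member.shape[1]
    parent = np.full(n_nodes, -1, dtype=np.int64)
    child_head = np.full(n_nodes, -1, dtype=np.int64)
    sib_next = np.full(n_nodes, -1, dtype=np.int64)
    sib_prev = np.full(n_nodes, -1, dtype=np.int64)
    active = np.zeros(n_edges, dtype=np.uint8)
    stack = np.empty(n_nodes, dtype=np.int64)

    i = 0
    j = 0
    for s in range(site_pos.shape[0]):
        x = site_pos[s]
        while j < n_edges and er[rem[j]] <= x:
            e = rem[j]
            if active[e] == 1:
                c = ec[e]
                if sib_prev[c] == -1:
                    child_head[ep[e]] = sib_next[c]
                else:
                    sib_next[sib_prev[c]] = sib_next[c]
                if sib_next[c] != -1:
                    sib_prev[sib_next[c]] = sib_prev[c]
                sib_next[c] = -1
                sib_prev[c] = -1
                parent[c] = -1
                active[e] = 0
            j += 1
        while i < n_edges and el[ins[i]] <= x:
            e = ins[i]
            if er[e] > x:
                p = ep[e]
                c = ec[e]
                parent[c] = p
                sib_prev[c] = -1
                sib_next[c] = child_head[p]
                if child_head[p] != -1:
                    sib_prev[child_head[p]] = c
                child_head[p] = c
                active[e] = 1
            i += 1
        # subtree sum below the mutation's node
        sp = 0
        stack[sp] = site_node[s]
        sp += 1
        while sp > 0:
            sp -= 1
            u = stack[sp]
            for t in range(k):
                out[s, t] += member[u, t]
            c = child_head[u]
            while c != -1:
                stack[sp] = c
                sp += 1
                c = sib_next[c]


def derived_counts(
    tables: GenealogyTables, node_sets: Sequence[np.ndarray]
) -> np.ndarray:
    """Per-site derived-allele counts within each set of sample nodes.

    Returns an ``(num_sites, len(node_sets))`` integer array.
    """
    k = len(node_sets)
    member = np.zeros((tables.num_nodes, k), dtype=np.int64)
    for t, nodes in enumerate(node_sets):
        member[np.asarray(nodes, dtype=np.int64), t] += 1
    out = np.zeros((tables.num_sites, k), dtype=np.int64)
    if tables.num_sites == 0 or tables.num_edges == 0:
        return out
    ins = np.lexsort((tables.edges_child, tables.edges_left))
    rem = np.lexsort((tables.edges_child, tables.edges_right))
    _count_kernel(
        tables.num_nodes,
        np.ascontiguousarray(tables.edges_left),
        np.ascontiguousarray(tables.edges_right),
        np.ascontiguousarray(tables.edges_parent),
        np.ascontiguousarray(tables.edges_child),
        ins.astype(np.int64),
        rem.astype(np.int64),
        tables.sites_position.astype(np.float64),
        np.ascontiguousarray(tables.mut_node),
        member,
        out,
    )
    return out


@njit(cache=True)
def _genotype_kernel(
    n_nodes, el, er, ep, ec, ins, rem, site_pos, site_node, col_of_node, out
):
    n_edges = el.shape[0]
    parent = np.full(n_nodes, -1, dtype=np.int64)
    child_head = np.full(n_nodes, -1, dtype=np.int64)
    sib_next = np.full(n_nodes, -1, dtype=np.int64)
    sib_prev = np.full(n_nodes, -1, dtype=np.int64)
    active = np.zeros(n_edges, dtype=np.uint8)
    stack = np.empty(n_nodes, dtype=np.int64)
    i = 0
    j = 0
    for s in range(site_pos.shape[0]):
        x = site_pos[s]
        while j < n_edges and er[rem[j]] <= x:
            e = rem[j]
            if active[e] == 1:
                c = ec[e]
                if sib_prev[c] == -1:
                    child_head[ep[e]] = sib_next[c]
                else:
                    sib_next[sib_prev[c]] = sib_next[c]
                if sib_next[c] != -1:
                    sib_prev[sib_next[c]] = sib_prev[c]
                sib_next[c] = -1
                sib_prev[c] = -1
                parent[c] = -1
                active[e] = 0
            j += 1
        while i < n_edges and el[ins[i]] <= x:
            e = ins[i]
            if er[e] > x:
                p = ep[e]
                c = ec[e]
                parent[c] = p
                sib_prev[c] = -1
                sib_next[c] = child_head[p]
                if child_head[p] != -1:
                    sib_prev[child_head[p]] = c
                child_head[p] = c
                active[e] = 1
            i += 1
        sp = 0
        stack[sp] = site_node[s]
        sp += 1
        while sp > 0:
            sp -= 1
            u = stack[sp]
            if col_of_node[u] >= 0:
                out[s, col_of_node[u]] = 1
            c = child_head[u]
            while c != -1:
                stack[sp] = c
                sp += 1
                c = sib_next[c]


def genotype_matrix(
    tables: GenealogyTables, sample_nodes: Sequence[int]
) -> np.ndarray:
    """0/1 derived-allele matrix of shape (num_sites, len(sample_nodes))."""
    nodes = np.asarray(sample_nodes, dtype=np.int64)
    col_of_node = np.full(tables.num_nodes, -1, dtype=np.int64)
    col_of_node[nodes] = np.arange(len(nodes))
    out = np.zeros((tables.num_sites, len(nodes)), dtype=np.uint8)
    if tables.num_sites == 0 or tables.num_edges == 0:
        return out
    ins = np.lexsort((tables.edges_child, tables.edges_left))
    rem = np.lexsort((tables.edges_child, tables.edges_right))
    _genotype_kernel(
        tables.num_nodes,
        np.ascontiguousarray(tables.edges_left),
        np.ascontiguousarray(tables.edges_right),
        np.ascontiguousarray(tables.edges_parent),
        np.ascontiguousarray(tables.edges_child),
        ins.astype(np.int64),
        rem.astype(np.int64),
        tables.sites_position.astype(np.float64),
        np.ascontiguousarray(tables.mut_node),
        col_of_node,
        out,
    )
    return out


def _resolve(tables, s) -> np.ndarray:
    if isinstance(s, SampleSet):
        return s.node_ids(tables)
    return np.asarray(s, dtype=np.int64)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def diversity(tables: GenealogyTables, sset) -> float:
    """Mean per-site pairwise difference (nucleotide diversity) in a set."""
    nodes = _resolve(tables, sset)
    n = len(nodes)
    if n < 2:
        raise ValueError("diversity requires at least 2 sample nodes")
    c = derived_counts(tables, [nodes])[:, 0].astype(np.float64)
    num_pairs = n * (n - 1) / 2.0
    return float(np.sum(c * (n - c)) / num_pairs / tables.sequence_length)


def divergence(tables: GenealogyTables, set1, set2) -> float:
    """Mean per-site difference between cross pairs of two sets (d_xy)."""
    nodes1 = _resolve(tables, set1)
    nodes2 = _resolve(tables, set2)
    if len(nodes1) == 0 or len(nodes2) == 0:
        raise ValueError("divergence requires two nonempty sets")
    overlap = len(np.intersect1d(nodes1, nodes2))
    if overlap:
        warnings.warn(
            f"divergence: sample sets share {overlap} nodes; identical-node "
            f"pairs are excluded from the average",
            stacklevel=2,
        )
    counts = derived_counts(tables, [nodes1, nodes2]).astype(np.float64)
    cx, cy = counts[:, 0], counts[:, 1]
    nx, ny = len(nodes1), len(nodes2)
    diff = cx * (ny - cy) + (nx - cx) * cy
    n_pairs = nx * ny - overlap
    return float(diff.sum() / n_pairs / tables.sequence_length)


def f4(tables: GenealogyTables, A, B, C, D) -> float:
    """Patterson's f4: mean over sites of (p_A - p_B)(p_C - p_D)."""
    sets = [_resolve(tables, s) for s in (A, B, C, D)]
    for s in sets:
        if len(s) == 0:
            raise ValueError("f4 requires four nonempty sets")
    if tables.num_sites == 0:
        return 0.0
    counts = derived_counts(tables, sets).astype(np.float64)
    sizes = np.array([len(s) for s in sets], dtype=np.float64)
    p = counts / sizes
    vals = (p[:, 0] - p[:, 1]) * (p[:, 2] - p[:, 3])
    return float(vals.mean())


def f4_ratio(tables: GenealogyTables, X, A, B, C, O) -> float:
    """Admixture proportion alpha = f4(A, O; X, C) / f4(A, O; B, C).

    Estimates the ancestry fraction that ``X`` derives from the lineage of
    ``B`` (relative to ``C``), assuming the topology in which ``A`` is the
    unadmixed sister of ``B`` and ``O`` an outgroup.
    """
    denom = f4(tables, A, O, B, C)
    if abs(denom) < 1e-12:
        raise ValueError(
            "uninformative f4-ratio configuration: denominator f4 is ~0"
        )
    return f4(tables, A, O, X, C) / denom


def afs(tables: GenealogyTables, sset, polarised: bool = True) -> np.ndarray:
    """Allele frequency spectrum of a set of 2n sampled genomes.

    Returns counts ``xi[1..2n-1]`` (index 0 unused) of sites by derived
    count; with ``polarised=False`` the folded spectrum
    ``xi[i] + xi[2n-i]`` for ``i <= n`` is returned instead.
    """
    nodes = _resolve(tables, sset)
    nn = len(nodes)  # number of genomes (2 per individual)
    if nn == 0:
        raise ValueError("afs requires a nonempty set")
    c = derived_counts(tables, [nodes])[:, 0]
    counts = np.bincount(c, minlength=nn + 1)
    full = np.zeros(nn, dtype=np.int64)
    full[1:nn] = counts[1:nn]  # drop monomorphic classes 0 and 2n
    if polarised:
        return full
    folded = np.zeros(nn // 2 + 1, dtype=np.int64)
    for i in range(1, nn // 2 + 1):
        folded[i] = full[i] if i == nn - i else full[i] + full[nn - i]
    return folded
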