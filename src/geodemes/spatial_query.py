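"""Spatio-temporal extraction: annotated tables, ancestor tracing, Newick.

Node and edge tables are exposed as pandas data frames with times converted
back to the user's units and locations attached to every recorded node, so
downstream plotting and spatial analysis need no knowledge of the internal
array layout.  Ancestor tracing walks a sampled individual's two genomes up
the (simplified) genealogy across every genomic interval; only ancestors
that survived simplification — marginal-tree MRCAs — can appear, so the
trace shows where *coalescent* ancestors lived, not every pedigree ancestor
along the way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .demography import CompiledModel
from .landscape import Point
from .tables import GenealogyTables, MarginalTree

__all__ = [
    "AncestryRecord",
    "nodes_table",
    "edges_table",
    "ancestors_of",
    "to_newick",
]


def _node_times_user(tables: GenealogyTables, model: CompiledModel) -> np.ndarray:
    return model.from_generations(tables.node_birth_gen)


def nodes_table(tables: GenealogyTables, model: CompiledModel) -> pd.DataFrame:
    """One row per node: identity, population, user-unit time, location."""
    ind = tables.node_individual
    has_ind = ind >= 0
    x = np.full(tables.num_nodes, np.nan)
    y = np.full(tables.num_nodes, np.nan)
    x[has_ind] = tables.indiv_x[ind[has_ind]]
    y[has_ind] = tables.indiv_y[ind[has_ind]]
    names = [
        tables.indiv_names.get(int(i), "") if i >= 0 else ""
        for i in ind
    ]
    return pd.DataFrame(
        {
            "node_id": np.arange(tables.num_nodes, dtype=np.int64),
            "name": names,
            "population": [tables.population_names[p] for p in tables.node_population],
            "time": _node_times_user(tables, model),
            "x": x,
            "y": y,
            "sampled": tables.node_is_sample.copy(),
            "individual": ind.copy(),
        }
    )


def edges_table(tables: GenealogyTables, model: CompiledModel) -> pd.DataFrame:
    """One row per edge with both endpoint locations attached."""
    nt = nodes_table(tables, model)
    parent = tables.edges_parent
    child = tables.edges_child
    return pd.DataFrame(
        {
            "parent": parent.copy(),
            "child": child.copy(),
            "left": tables.edges_left.copy(),
            "right": tables.edges_right.copy(),
            "parent_time": nt["time"].to_numpy()[parent],
            "child_time": nt["time"].to_numpy()[child],
            "parent_x": nt["x"].to_numpy()[parent],
            "parent_y": nt["y"].to_numpy()[parent],
            "child_x": nt["x"].to_numpy()[child],
            "child_y": nt["y"].to_numpy()[child],
        }
    )


@dataclass(frozen=True)
class AncestryRecord:
    """One (ancestor, maximal genomic interval) pair of a focal genome."""

    focal_node: int
    ancestor_node: int
    left: float
    right: float
    ancestor_location: Optional[Point]
    ancestor_time: float
    segment: tuple[Optional[Point], Optional[Point]]  # focal-side -> ancestor


def _location_of_node(tables: GenealogyTables, node: int) -> Optional[Point]:
    ind = int(tables.node_individual[node])
    if ind < 0:
        return None
    x, y = float(tables.indiv_x[ind]), float(tables.indiv_y[ind])
    if np.isnan(x):
        return None
    return Point(x, y)


def ancestors_of(
    tables: GenealogyTables, individual_name: str, model: CompiledModel
) -> list[AncestryRecord]:
    """Trace the full spatio-temporal ancestry of one sampled individual.

    For each of the individual's two sample nodes, parent edges are walked
    transitively across all genomic intervals; one record is emitted per
    (ancestor, maximal interval), with adjacent intervals of the same
    ancestor merged.
    """
    ind = tables.individual_by_name(individual_name)
    focal_nodes = [
        int(n) for n in np.flatnonzero(
            (tables.node_individual == ind) & tables.node_is_sample
        )
    ]
    # index edges by child
    order = np.argsort(tables.edges_child, kind="stable")
    by_child: dict[int, list[int]] = {}
    for e in order:
        by_child.setdefault(int(tables.edges_child[e]), []).append(int(e))

    times = _node_times_user(tables, model)
    records: list[AncestryRecord] = []
    for f in focal_nodes:
        focal_loc = _location_of_node(tables, f)
        # (ancestor -> list of intervals) via interval-restricted DFS
        found: dict[int, list[tuple[float, float]]] = {}
        stack: list[tuple[int, float, float]] = [(f, 0.0, tables.sequence_length)]
        while stack:
            u, a, b = stack.pop()
            for e in by_child.get(u, ()):
                l = max(tables.edges_left[e], a)
                r = min(tables.edges_right[e], b)
                if l >= r:
                    continue
                p = int(tables.edges_parent[e])
                found.setdefault(p, []).append((l, r))
                stack.append((p, l, r))
        for anc in sorted(found):
            ivals = sorted(found[anc])
            merged: list[list[float]] = []
            for l, r in ivals:
                if merged and l <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], r)
                else:
                    merged.append([l, r])
            anc_loc = _location_of_node(tables, anc)
            for l, r in merged:
                records.append(
                    AncestryRecord(
                        focal_node=f, ancestor_node=anc, left=float(l),
                        right=float(r), ancestor_location=anc_loc,
                        ancestor_time=float(times[anc]),
                        segment=(focal_loc, anc_loc),
                    )
                )
    return records


def ancestors_table(
    tables: GenealogyTables, individual_name: str, model: CompiledModel
) -> pd.DataFrame:
    """:func:`ancestors_of` as a plotting-ready data frame."""
    recs = ancestors_of(tables, individual_name, model)
    return pd.DataFrame(
        {
            "focal_node": [r.focal_node for r in recs],
            "ancestor_node": [r.ancestor_node for r in recs],
            "left": [r.left for r in recs],
            "right": [r.right for r in recs],
            "ancestor_time": [r.ancestor_time for r in recs],
            "ancestor_x": [r.ancestor_location[0] if r.ancestor_location else np.nan
                           for r in recs],
            "ancestor_y": [r.ancestor_location[1] if r.ancestor_location else np.nan
                           for r in recs],
        }
    )


def _leaf_label(tables: GenealogyTables, node: int) -> str:
    ind = int(tables.node_individual[node])
    name = tables.indiv_names.get(ind)
    if name is None:
        return f"node{node}"
    copies = [
        int(n) for n in np.flatnonzero(
            (tables.node_individual == ind) & tables.node_is_sample
        )
    ]
    suffix = copies.index(node) + 1
    return f"{name}_{suffix}"


def to_newick(
    tree: MarginalTree, tables: GenealogyTables, model: CompiledModel
) -> str:
    """Render one marginal tree as Newick, branch lengths in user units.

    Sample leaves are labelled ``{individual_name}_1`` / ``_2`` for the two
    genome copies.  Intervals with several roots yield a forest: one Newick
    string per root, newline-separated.
    """
    samples = [int(s) for s in tables.sample_nodes]
    # restrict to nodes on paths from samples to their roots
    relevant: set[int] = set()
    for s in samples:
        u = s
        seen_steps = 0
        while u >= 0 and u not in relevant:
            relevant.add(u)
            u = int(tree.parent[u])
            seen_steps += 1
            if seen_steps > len(tree.parent):
                raise ValueError("cyclic parent array in marginal tree")
        if u >= 0:
            continue
    children: dict[int, list[int]] = {}
    roots: list[int] = []
    for u in sorted(relevant):
        p = int(tree.parent[u])
        if p >= 0 and p in relevant:
            children.setdefault(p, []).append(u)
        else:
            roots.append(u)
    gens = tables.node_birth_gen
    g = model.generation_time

    def branch_length(u: int, p: int) -> float:
        return abs(float(gens[u] - gens[p])) * g

    out_lines: list[str] = []
    for root in roots:
        # iterative post-order rendering
        rendered: dict[int, str] = {}
        stack = [(root, False)]
        while stack:
            u, expanded = stack.pop()
            kids = children.get(u, [])
            if kids and not expanded:
                stack.append((u, True))
                for c in kids:
                    stack.append((c, False))
                continue
            if not kids:
                rendered[u] = _leaf_label(tables, u)
            else:
                inner = ",".join(
                    f"{rendered[c]}:{branch_length(c, u):.10g}" for c in kids
                )
                label = _leaf_label(tables, u) if tables.node_is_sample[u] else ""
                rendered[u] = f"({inner}){label}"
        out_lines.append(rendered[root] + ";")
    return "\n".join(out_lines)
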