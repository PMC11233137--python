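"""Independent brute-force oracles used to validate the fast implementations."""

import numpy as np


def parent_node_at(tables, node, x):
    """Parent of ``node`` at position ``x`` by scanning all edges (-1 if root)."""
    for e in range(tables.num_edges):
        if (tables.edges_child[e] == node
                and tables.edges_left[e] <= x < tables.edges_right[e]):
            return int(tables.edges_parent[e])
    return -1


def oracle_simplified_tree(tables, samples, x):
    """Marginal tree at ``x`` restricted to MRCAs, by pedigree tracing.

    Walks every sample's lineage to its root, keeps samples plus nodes where
    at least two distinct child lineages meet, and collapses unary nodes.
    Returns the set of (child, parent) links between retained input nodes.
    """
    samples = [int(s) for s in samples]
    parent_of = {}
    for s in samples:
        u = s
        while True:
            if u in parent_of:
                break
            p = parent_node_at(tables, u, x)
            parent_of[u] = p
            if p == -1:
                break
            u = p
    children = {}
    for u, p in parent_of.items():
        if p != -1:
            children.setdefault(p, set()).add(u)
    sample_set = set(samples)
    retained = set(samples) | {u for u, cs in children.items() if len(cs) >= 2}

    def nearest_retained_ancestor(u):
        p = parent_of.get(u, -1)
        while p != -1 and p not in retained:
            p = parent_of.get(p, -1)
        return p

    links = set()
    for u in retained:
        p = nearest_retained_ancestor(u)
        if p != -1:
            links.add((u, p))
    return retained, links


def simplified_tree_links(simp, node_map, x):
    """(child, parent) links in input-node ids for a simplified table at ``x``."""
    inv = {}
    for i, o in enumerate(node_map):
        if o >= 0:
            inv[int(o)] = i
    links = set()
    for e in range(simp.num_edges):
        if simp.edges_left[e] <= x < simp.edges_right[e]:
            links.add((inv[int(simp.edges_child[e])], inv[int(simp.edges_parent[e])]))
    return links


def stab_parent_array(tables, x):
    """Full parent array at position ``x`` by scanning all edges."""
    parent = np.full(tables.num_nodes, -1, dtype=np.int64)
    for e in range(tables.num_edges):
        if tables.edges_left[e] <= x < tables.edges_right[e]:
            parent[tables.edges_child[e]] = tables.edges_parent[e]
    return parent


def pairwise_differences(genotypes):
    """Hamming distances between all columns of a site x node 0/1 matrix."""
    g = np.asarray(genotypes, dtype=np.int64)
    n = g.shape[1]
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sum(g[:, i] != g[:, j])
    return out


def to_tskit(tables):
    """Convert native tables to a tskit TableCollection (tests only)."""
    import tskit

    tc = tskit.TableCollection(sequence_length=float(tables.sequence_length))
    maxgen = int(tables.node_birth_gen.max()) if tables.num_nodes else 0
    tc.nodes.set_columns(
        flags=np.where(tables.node_is_sample, 1, 0).astype(np.uint32),
        time=(maxgen - tables.node_birth_gen).astype(np.float64),
    )
    if tables.num_edges:
        order = np.lexsort(
            (tables.edges_left, tables.edges_child,
             -tables.node_birth_gen[tables.edges_parent])
        )
        tc.edges.set_columns(
            left=tables.edges_left[order],
            right=tables.edges_right[order],
            parent=tables.edges_parent[order].astype(np.int32),
            child=tables.edges_child[order].astype(np.int32),
        )
    tc.sort()
    return tc


def random_history(seed, max_n=10, max_gens=6, L=100.0):
    """A small random Wright-Fisher history via the engine (raw tables)."""
    import geodemes as gd

    rng = np.random.default_rng(seed)
    N = int(rng.integers(2, max_n + 1))
    G = int(rng.integers(2, max_gens + 1))
    pop = gd.population("p", time=1, N=N)
    model = gd.compile_model([pop], generation_time=1, direction="forward",
                             end_time=G)
    params = gd.SimulationParams(
        sequence_length=int(L), recombination_rate=float(rng.uniform(0.005, 0.03)),
        seed=int(rng.integers(0, 2**31)), quiet=True,
    )
    tables, _ = gd.run_simulation(model, params)
    n_keep = int(rng.integers(1, 2 * N + 1))
    all_samples = tables.sample_nodes
    keep = rng.choice(all_samples, size=n_keep, replace=False)
    return tables, np.sort(keep)
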