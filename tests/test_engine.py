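"""Wright-Fisher engine: census, reproduction components, determinism."""

import math

import numpy as np
import pytest

import geodemes as gd
from geodemes.engine import (
    EngineError,
    _gamete_edges,
    apply_gene_flow,
    choose_mate,
    disperse,
    fitness_weights,
)

from conftest import run_small


class TestCensusAndSampling:
    def test_default_sampling_2n_nodes(self, tiny_model):
        tables, state = run_small(tiny_model, rho=0.0)
        assert tables.node_is_sample.sum() == 200
        sampled_gens = tables.node_birth_gen[tables.node_is_sample]
        assert (sampled_gens == tiny_model.G).all()

    def test_census_matches_schedule_exactly(self):
        p = gd.population("p", time=1, N=100)
        q = gd.population("q", time=5, N=37, parent=p)
        ev = gd.resize(p, time=8, N=50)
        model = gd.compile_model([p, q], [ev], generation_time=1,
                                 direction="forward", end_time=12)
        tables, state = run_small(model, rho=0.0)
        gens = tables.indiv_birth_gen
        pops = tables.indiv_population
        for gen in range(1, 13):
            for pop in model.populations:
                expected = pop.N_at(gen)
                got = int(np.sum((gens == gen) & (pops == pop.idx)))
                assert got == expected, (gen, pop.name)

    def test_exponential_resize_followed(self):
        p = gd.population("p", time=1, N=100)
        ev = gd.resize(p, time=2, N=200, how="exponential", end_time=12)
        model = gd.compile_model([p], [ev], generation_time=1,
                                 direction="forward", end_time=12)
        tables, _ = run_small(model, rho=0.0)
        for k in range(11):
            got = int(np.sum(tables.indiv_birth_gen == 2 + k))
            assert got == round(100 * 2 ** (k / 10))

    def test_sampling_n_exceeds_population_errors(self):
        model = gd.compile_model([gd.population("p", time=1, N=10)],
                                 generation_time=1, direction="forward",
                                 end_time=5)
        gd.schedule_sampling(model, [3], "p", 11)
        with pytest.raises(EngineError, match="requests 11"):
            run_small(model, rho=0.0)

    def test_scheduled_sampling_names_sequential(self):
        model = gd.compile_model([gd.population("p", time=1, N=20)],
                                 generation_time=1, direction="forward",
                                 end_time=6)
        gd.schedule_sampling(model, [3, 6], "p", 4)
        tables, _ = run_small(model, rho=0.0)
        names = sorted(tables.indiv_names.values())
        assert names == [f"p_{k}" for k in range(8)]
        assert tables.node_is_sample.sum() == 16

    def test_location_based_sampling_nearest(self, small_spatial_model):
        target = gd.Point(-8, 0)
        gd.schedule_sampling(small_spatial_model, [20], "a", 5, location=target)
        tables, _ = run_small(small_spatial_model, seed=3)
        named = [i for i in tables.indiv_names if tables.indiv_birth_gen[i] == 20]
        locs = np.column_stack([tables.indiv_x[named], tables.indiv_y[named]])
        chosen_d = np.hypot(locs[:, 0] - target[0], locs[:, 1] - target[1])
        # all other generation-20 individuals of pop a are at least as far
        pool = np.flatnonzero(
            (tables.indiv_birth_gen == 20) & (tables.indiv_population == 0)
        )
        others = np.setdiff1d(pool, named)
        other_d = np.hypot(tables.indiv_x[others] - target[0],
                           tables.indiv_y[others] - target[1])
        assert chosen_d.max() <= other_d.min() + 1e-9
        # cleanup shared fixture state
        small_spatial_model.sampling.clear()
        small_spatial_model.config_sampling = ()


class TestDeterminism:
    def test_same_seed_identical_tables(self, small_spatial_model):
        t1, _ = run_small(small_spatial_model, seed=11)
        t2, _ = run_small(small_spatial_model, seed=11)
        assert np.array_equal(t1.edges_left, t2.edges_left)
        assert np.array_equal(t1.edges_parent, t2.edges_parent)
        assert np.array_equal(t1.indiv_x, t2.indiv_x)
        assert t1.indiv_names == t2.indiv_names

    def test_different_seed_differs(self, small_spatial_model):
        t1, _ = run_small(small_spatial_model, seed=11)
        t2, _ = run_small(small_spatial_model, seed=12)
        assert not np.array_equal(t1.indiv_x, t2.indiv_x)


class TestFitnessWeights:
    def test_isolated_individual(self):
        w = fitness_weights(np.array([[0.0, 0.0], [10.0, 10.0]]), 1.0)
        assert np.allclose(w, 1.0)

    def test_three_mutual_neighbours(self):
        locs = np.array([[0, 0], [0.1, 0], [0, 0.1]], dtype=float)
        w = fitness_weights(locs, 1.0)
        assert np.allclose(w, 1 / 3)

    def test_zero_radius_disables(self):
        locs = np.zeros((5, 2))
        assert np.allclose(fitness_weights(locs, 0.0), 1.0)

    def test_matches_brute_force_counts(self, rng):
        locs = rng.uniform(0, 50, size=(500, 2))
        r = 80.0  # covers the whole square (diagonal ~70.7)
        w = fitness_weights(locs, r)
        assert np.allclose(w, 1 / 500)
        r = 5.0
        w = fitness_weights(locs, r)
        d = np.hypot(*(locs[:, None, :] - locs[None, :, :]).transpose(2, 0, 1))
        counts = (d <= r).sum(axis=1) - 1  # exclude self
        assert np.allclose(w, 1 / (1 + counts))


class TestChooseMate:
    def test_single_candidate_chosen(self, rng):
        locs = np.array([[0, 0], [1, 0], [50, 50]], dtype=float)
        assert choose_mate(0, locs, 2.0, rng) == 1

    def test_uniform_among_candidates(self, rng):
        locs = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1], [9, 9]],
                        dtype=float)
        draws = np.array([choose_mate(0, locs, 2.0, rng) for _ in range(10_000)])
        counts = np.bincount(draws, minlength=6)
        assert counts[0] == 0 and counts[5] == 0
        expected = 10_000 / 4
        sigma = math.sqrt(10_000 * 0.25 * 0.75)
        for k in (1, 2, 3, 4):
            assert abs(counts[k] - expected) <= 4 * sigma

    def test_nearest_fallback(self, rng):
        locs = np.array([[0, 0], [5, 0], [9, 0]], dtype=float)
        assert choose_mate(0, locs, 1.0, rng) == 1

    def test_population_of_one_errors(self, rng):
        with pytest.raises(EngineError, match="size 1"):
            choose_mate(0, np.zeros((1, 2)), 1.0, rng)


class TestDisperse:
    def setup_method(self):
        self.world = gd.make_world((-1000, -1000, 1000, 1000))
        self.region = gd.Region.from_vertices("r", [
            gd.Point(-1000, -1000), gd.Point(1000, -1000),
            gd.Point(1000, 1000), gd.Point(-1000, 1000)])

    def test_uniform_kernel_bounded(self, rng):
        sp = gd.demography.ResolvedSpatial(0.0, 1.0, 5.0, "uniform")
        from geodemes.engine import _disperse_batch
        locs = np.zeros((10_000, 2))
        out, _, _ = _disperse_batch(locs, sp, self.region.geometry, self.world,
                                    self.region, rng, 1000)
        assert (np.hypot(out[:, 0], out[:, 1]) <= 5.0 + 1e-9).all()

    def test_half_normal_mean_displacement(self, rng):
        sp = gd.demography.ResolvedSpatial(0.0, 1.0, 2.0, "normal")
        from geodemes.engine import _disperse_batch
        locs = np.zeros((100_000, 2))
        out, _, _ = _disperse_batch(locs, sp, self.region.geometry, self.world,
                                    self.region, rng, 1000)
        mean_d = np.hypot(out[:, 0], out[:, 1]).mean()
        assert mean_d == pytest.approx(2.0 * math.sqrt(2 / math.pi), rel=0.02)

    def test_parent_outside_range_still_lands_inside(self, rng):
        sp = gd.demography.ResolvedSpatial(0.0, 1.0, 1.0, "normal")
        small = gd.circle_region("s", gd.Point(500, 500), 10)
        p = disperse(gd.Point(-900, -900), sp, small, self.world, rng,
                     max_placement_attempts=50)
        assert gd.point_in_region(p, small)

    @pytest.mark.parametrize("kernel", ["normal", "uniform", "cauchy",
                                        "exponential", "brownian"])
    def test_all_kernels_produce_finite_points(self, rng, kernel):
        sp = gd.demography.ResolvedSpatial(0.0, 1.0, 1.0, kernel)
        p = disperse(gd.Point(0, 0), sp, self.region, self.world, rng)
        assert math.isfinite(p.x) and math.isfinite(p.y)


class TestGameteEdges:
    def test_no_recombination_single_edges(self, rng):
        parents = np.arange(5, dtype=np.int64)
        children = np.arange(10, 15, dtype=np.int64)
        l, r, pn, c = _gamete_edges(rng, parents, children, 0.0, 100.0)
        assert np.array_equal(l, np.zeros(5))
        assert np.array_equal(r, np.full(5, 100.0))
        assert set(pn // 2) == set(parents)
        assert np.array_equal(c, children)

    def test_breakpoints_alternate_haplotypes(self, rng):
        parents = np.zeros(2000, dtype=np.int64)
        children = np.arange(2000, dtype=np.int64)
        l, r, pn, c = _gamete_edges(rng, parents, children, 0.02, 100.0)
        # per child: intervals tile [0, 100) and alternate between node 0 and 1
        for child in range(50):
            mask = c == child
            order = np.argsort(l[mask])
            ll, rr, hh = l[mask][order], r[mask][order], pn[mask][order]
            assert ll[0] == 0 and rr[-1] == 100.0
            assert np.allclose(rr[:-1], ll[1:])
            assert np.all(np.abs(np.diff(hh)) == 1)

    def test_crossover_count_poisson(self, rng):
        parents = np.zeros(20_000, dtype=np.int64)
        children = np.arange(20_000, dtype=np.int64)
        l, r, pn, c = _gamete_edges(rng, parents, children, 3e-2, 100.0)
        # mean crossovers per gamete = rho * L = 3
        mean_edges = len(l) / 20_000
        assert mean_edges == pytest.approx(4.0, rel=0.02)


class TestGeneFlowMechanics:
    def test_mask_extremes(self, rng):
        assert not apply_gene_flow(100, 0.0, rng).any()
        assert apply_gene_flow(100, 1.0, rng).all()

    def test_forced_gene_flow_half_ancestry_one_generation(self):
        # with p_mate=1 for a single generation, every offspring has one
        # migrant parent: expected source ancestry is exactly 1/2
        a = gd.population("a", time=1, N=200)
        b = gd.population("b", time=2, N=200, parent=a)
        gf = gd.gene_flow(a, b, rate=1.0 - 1e-12, start=8, end=9)
        model = gd.compile_model([a, b], [gf], generation_time=1,
                                 direction="forward", end_time=9)
        tables, state = run_small(model, rho=0.0, seed=5)
        p1, p2, pop = state.builder.pedigree()
        frac = _pedigree_source_fraction(tables, p1, p2, pop, model,
                                         source="a", target="b", window=(8, 9))
        assert frac == pytest.approx(0.5, abs=1e-12)

    def test_pedigree_ancestry_matches_rate_bookkeeping(self):
        # r = 0.1 over 10 generations: the compiled mate-draw probability is
        # doubled so that expected total ancestry is r (not r/2)
        a = gd.population("a", time=1, N=1000)
        b = gd.population("b", time=2, N=1000, parent=a)
        gf = gd.gene_flow(a, b, rate=0.1, start=10, end=20)
        model = gd.compile_model([a, b], [gf], generation_time=1,
                                 direction="forward", end_time=20)
        fracs = []
        for seed in range(1, 6):
            tables, state = run_small(model, rho=0.0, seed=seed, L=100)
            p1, p2, pop = state.builder.pedigree()
            fracs.append(
                _pedigree_source_fraction(tables, p1, p2, pop, model,
                                          source="a", target="b",
                                          window=(10, 20))
            )
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / math.sqrt(len(fracs))
        assert abs(mean - 0.1) <= max(3 * se, 0.01)

    def test_no_flow_means_no_source_mates(self):
        a = gd.population("a", time=1, N=50)
        b = gd.population("b", time=2, N=50, parent=a)
        model = gd.compile_model([a, b], generation_time=1,
                                 direction="forward", end_time=10)
        tables, state = run_small(model, rho=0.0, seed=2)
        p1, p2, pop = state.builder.pedigree()
        b_idx = model.pop("b").idx
        later = tables.indiv_birth_gen > 2
        b_members = np.flatnonzero((pop == b_idx) & later)
        for i in b_members:
            assert pop[p1[i]] == b_idx
            assert pop[p2[i]] == b_idx

    def test_disjoint_ranges_with_overlap_required_errors(self):
        world = gd.make_world((-30, -30, 30, 30))
        sp = gd.SpatialParams(mating=2.0, dispersal=0.5)
        a = gd.population("a", time=1, N=30, spatial=sp,
                          range=gd.circle_region("ra", gd.Point(-20, 0), 5))
        b = gd.population("b", time=2, N=30, parent=a, spatial=sp,
                          range=gd.circle_region("rb", gd.Point(20, 0), 5))
        gf = gd.gene_flow(a, b, rate=0.9, start=5, end=15, require_overlap=True)
        model = gd.compile_model([a, b], [gf], generation_time=1,
                                 direction="forward", world=world, end_time=15)
        with pytest.raises(EngineError, match="do not overlap"):
            run_small(model, seed=4)


def _pedigree_source_fraction(tables, p1, p2, pop, model, source, target,
                              window):
    """Expected migrant (source-population) ancestry of the final target
    generation, by forward dynamic programming over the recorded pedigree.

    Only ancestry entering through cross-population matings counts; the
    daughter population's founding generation starts at zero ancestry.
    """
    src = model.pop(source).idx
    tgt = model.pop(target).idx
    start_gen = model.pop(target).start_gen
    frac = np.zeros(len(p1))
    gens = tables.indiv_birth_gen
    order = np.argsort(gens, kind="stable")

    def parent_frac(j):
        return 1.0 if pop[j] == src else frac[j]

    for i in order:
        if pop[i] != tgt or gens[i] <= start_gen:
            continue
        frac[i] = 0.5 * (parent_frac(p1[i]) + parent_frac(p2[i]))
    final = np.flatnonzero((pop == tgt) & (gens == gens.max()))
    return float(frac[final].mean())


class TestWfStepDirect:
    def test_wf_step_advances_generation(self, tiny_model):
        import geodemes.engine as eng

        params = gd.SimulationParams(sequence_length=1000, seed=9, quiet=True)
        rng = np.random.default_rng(9)
        builder = eng._TableBuilder(tiny_model, 1000)
        pop = tiny_model.populations[0]
        ids = builder.add_individuals(0, 1, None,
                                      np.full(100, -1, np.int64),
                                      np.full(100, -1, np.int64))
        state = eng.EngineState(generation=1, pops={0: eng._PopState(ids, None)},
                                rng=rng, builder=builder, spatial=False)
        state2 = gd.wf_step(state, tiny_model, params, rng)
        assert state2.generation == 2
        assert len(state2.pops[0].ids) == 100
        assert builder.n_ind == 200

    def test_spatial_offspring_inside_range(self, small_spatial_model):
        tables, state = run_small(small_spatial_model, seed=21)
        for pop in small_spatial_model.populations:
            for gen in range(pop.start_gen, pop.end_gen + 1):
                mask = ((tables.indiv_population == pop.idx)
                        & (tables.indiv_birth_gen == gen))
                region = pop.range_at(gen)
                xs = tables.indiv_x[mask]
                ys = tables.indiv_y[mask]
                from geodemes.landscape import points_in_geometry
                assert points_in_geometry(region.geometry, xs, ys).all()
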