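"""Model construction, validation, time handling and compilation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import geodemes as gd
from geodemes.demography import (
    GeneFlow,
    ModelError,
    _from_gen,
    _to_gen,
    infer_direction,
)


def simple_pair(t_child=50):
    a = gd.population("a", time=1, N=50)
    b = gd.population("b", time=t_child, N=50, parent=a)
    return a, b


class TestPopulationConfig:
    def test_root_and_child(self):
        a, b = simple_pair()
        assert a.parent is None and b.parent == "a"

    def test_bad_name_and_size(self):
        with pytest.raises(ModelError, match="match"):
            gd.population("bad name!", time=1, N=10)
        with pytest.raises(ModelError, match="positive"):
            gd.population("p", time=1, N=0)

    def test_child_before_parent_fails_at_compile(self):
        a = gd.population("a", time=100, N=10)
        b = gd.population("b", time=50, N=10, parent=a)
        with pytest.raises(ModelError, match="strictly after"):
            gd.compile_model([a, b], generation_time=1, direction="forward",
                             end_time=200)

    def test_duplicate_names(self):
        with pytest.raises(ModelError, match="duplicate"):
            gd.compile_model(
                [gd.population("a", 1, 10), gd.population("a", 5, 10)],
                generation_time=1, direction="forward", end_time=10,
            )

    def test_range_without_world(self):
        r = gd.circle_region("r", gd.Point(0, 0), 1)
        p = gd.population("p", time=1, N=10, range=r)
        with pytest.raises(ModelError, match="no world"):
            gd.compile_model([p], generation_time=1, direction="forward",
                             end_time=10)


class TestGeneFlow:
    def test_per_generation_conversion(self):
        a, b = simple_pair(2)
        gf = gd.gene_flow(a, b, rate=0.1, start=10, end=20)
        m = gd.compile_model([a, b], [gf], generation_time=1,
                             direction="forward", end_time=20)
        flow = m.gene_flows[0]
        T = flow.end_gen - flow.start_gen
        assert T == 10
        assert flow.m == pytest.approx(1 - 0.9 ** 0.1, abs=1e-12)
        assert flow.m == pytest.approx(0.010481, abs=1e-6)

    @given(r=st.floats(0.001, 0.999), T=st.integers(1, 200))
    def test_conversion_invariant(self, r, T):
        m = 1 - (1 - r) ** (1.0 / T)
        assert 1 - (1 - m) ** T == pytest.approx(r, abs=1e-12)

    def test_zero_rate_noop(self):
        a, b = simple_pair(2)
        gf = gd.gene_flow(a, b, rate=0.0, start=10, end=20)
        m = gd.compile_model([a, b], [gf], generation_time=1,
                             direction="forward", end_time=20)
        assert m.gene_flows[0].m == 0.0
        assert m.gene_flows[0].p_mate == 0.0

    def test_mate_probability_doubles_ancestry_rate(self):
        a, b = simple_pair(2)
        gf = gd.gene_flow(a, b, rate=0.4, start=10, end=20)
        m = gd.compile_model([a, b], [gf], generation_time=1,
                             direction="forward", end_time=20)
        flow = m.gene_flows[0]
        assert flow.p_mate == pytest.approx(2 * flow.m)
        # total ancestry via the mate side recovers the declared rate
        T = flow.end_gen - flow.start_gen
        assert 1 - (1 - flow.p_mate / 2) ** T == pytest.approx(0.4, abs=1e-12)

    def test_window_before_source_exists(self):
        a = gd.population("a", time=1, N=10)
        b = gd.population("b", time=100, N=10, parent=a)
        gf = gd.gene_flow(b, a, rate=0.1, start=10, end=20)
        with pytest.raises(ModelError, match="does not exist"):
            gd.compile_model([a, b], [gf], generation_time=1,
                             direction="forward", end_time=200)

    def test_bad_rate(self):
        with pytest.raises(ModelError, match="rate"):
            gd.gene_flow("a", "b", rate=1.5, start=1, end=2)


class TestMoveAndExpand:
    @pytest.fixture
    def spatial_setup(self):
        world = gd.make_world((0, 0, 100, 100))
        r = gd.circle_region("r", gd.Point(20, 50), 10)
        return world, gd.population("p", time=1, N=10, range=r)

    def test_move_stationary_waypoint(self, spatial_setup):
        world, p = spatial_setup
        mv = gd.move(p, [gd.Point(20, 50)], start=5, end=15)
        m = gd.compile_model([p], [mv], generation_time=1,
                             direction="forward", world=world, end_time=20)
        pop = m.pop("p")
        areas = {gen: r.area for gen, r in pop.ranges}
        assert len(set(round(a, 6) for a in areas.values())) == 1
        c0 = pop.range_at(1).geometry.centroid
        cT = pop.range_at(20).geometry.centroid
        assert (c0.x, c0.y) == pytest.approx((cT.x, cT.y), abs=1e-9)

    def test_move_constant_speed(self, spatial_setup):
        world, p = spatial_setup
        mv = gd.move(p, [gd.Point(30, 50)], start=5, end=15)  # distance 10, T=10
        m = gd.compile_model([p], [mv], generation_time=1,
                             direction="forward", world=world, end_time=20)
        pop = m.pop("p")
        for k in range(1, 11):
            c = pop.range_at(5 + k).geometry.centroid
            assert c.x == pytest.approx(20 + k, abs=1e-6)

    def test_move_arc_length_partition(self, spatial_setup):
        # legs of lengths 3 and 7 over 10 generations: 3 then 7 steps
        world, p = spatial_setup
        mv = gd.move(p, [gd.Point(23, 50), gd.Point(30, 50)], start=1, end=11)
        m = gd.compile_model([p], [mv], generation_time=1,
                             direction="forward", world=world, end_time=20)
        pop = m.pop("p")
        xs = [pop.range_at(1 + k).geometry.centroid.x for k in range(11)]
        steps = np.diff(xs)
        assert np.allclose(steps, 1.0, atol=1e-6)  # constant speed
        assert xs[3] == pytest.approx(23, abs=1e-6)  # first leg ends at gen 3

    def test_expand_disk_area(self):
        world = gd.make_world((-50, -50, 50, 50))
        p = gd.population("p", time=1, N=10,
                          range=gd.circle_region("r", gd.Point(0, 0), 5))
        ev = gd.expand_range(p, by=5, start=5, end=15)
        m = gd.compile_model([p], [ev], generation_time=1,
                             direction="forward", world=world, end_time=20)
        pop = m.pop("p")
        a0 = pop.range_at(1).area
        aT = pop.range_at(20).area
        assert aT == pytest.approx(4 * a0, rel=0.02)

    def test_expand_zero_identity(self):
        world = gd.make_world((-50, -50, 50, 50))
        p = gd.population("p", time=1, N=10,
                          range=gd.circle_region("r", gd.Point(0, 0), 5))
        ev = gd.expand_range(p, by=0, start=5, end=15)
        m = gd.compile_model([p], [ev], generation_time=1,
                             direction="forward", world=world, end_time=20)
        areas = {gen: r.area for gen, r in m.pop("p").ranges}
        assert len(set(round(a, 9) for a in areas.values())) == 1

    def test_expansion_clipped_by_habitable(self):
        # habitable area is a narrow band; expansion cannot exceed it
        band = gd.Region.from_vertices("band", [
            gd.Point(-20, -3), gd.Point(20, -3), gd.Point(20, 3), gd.Point(-20, 3)])
        world = gd.make_world((-20, -20, 20, 20), [band])
        p = gd.population("p", time=1, N=10,
                          range=gd.circle_region("r", gd.Point(0, 0), 2))
        ev = gd.expand_range(p, by=10, start=1, end=11)
        m = gd.compile_model([p], [ev], generation_time=1,
                             direction="forward", world=world, end_time=20)
        final = m.pop("p").range_at(20)
        unclipped_area = math.pi * 12 ** 2
        assert final.area < unclipped_area
        assert final.geometry.bounds[3] <= 3 + 1e-9

    def test_contraction_annihilation_errors(self):
        world = gd.make_world((-50, -50, 50, 50))
        p = gd.population("p", time=1, N=10,
                          range=gd.circle_region("r", gd.Point(0, 0), 2))
        ev = gd.expand_range(p, by=-5, start=5, end=15)
        with pytest.raises(ModelError, match="annihilates"):
            gd.compile_model([p], [ev], generation_time=1,
                             direction="forward", world=world, end_time=20)


class TestSetDispersal:
    def test_partial_update(self):
        world = gd.toy_world(10)
        p = gd.population("p", time=1, N=10,
                          spatial=gd.SpatialParams(competition=1.0, mating=2.0,
                                                   dispersal=0.5))
        ev = gd.set_dispersal(p, time=10, mating=4.0)
        m = gd.compile_model([p], [ev], generation_time=1,
                             direction="forward", world=world, end_time=20)
        before = m.pop("p").spatial_at(5)
        after = m.pop("p").spatial_at(15)
        assert after.mating == 4.0
        assert after.competition == before.competition == 1.0
        assert after.dispersal == before.dispersal == 0.5

    def test_same_generation_later_wins(self, caplog):
        world = gd.toy_world(10)
        p = gd.population("p", time=1, N=10)
        ev1 = gd.set_dispersal(p, time=10, mating=4.0)
        ev2 = gd.set_dispersal(p, time=10, mating=6.0)
        import logging
        with caplog.at_level(logging.WARNING, logger="geodemes.demography"):
            m = gd.compile_model([p], [ev1, ev2], generation_time=1,
                                 direction="forward", world=world, end_time=20)
        assert m.pop("p").spatial_at(15).mating == 6.0
        assert any("later declaration wins" in r.message for r in caplog.records)

    def test_change_after_extinction_errors(self):
        world = gd.toy_world(10)
        p = gd.population("p", time=1, N=10, removal_time=5)
        q = gd.population("q", time=1, N=10)
        ev = gd.set_dispersal(p, time=10, mating=4.0)
        with pytest.raises(ModelError, match="does not exist"):
            gd.compile_model([p, q], [ev], generation_time=1,
                             direction="forward", world=world, end_time=20)

    def test_unknown_kernel(self):
        with pytest.raises(ModelError, match="kernel"):
            gd.set_dispersal("p", time=1, dispersal_fun="levy")


class TestDirectionAndTime:
    def test_backward_from_splits(self):
        a = gd.population("a", time=50_000, N=10)
        b = gd.population("b", time=40_000, N=10, parent=a)
        c = gd.population("c", time=30_000, N=10, parent=b)
        assert infer_direction([a, b, c], []) == "backward"

    def test_forward_from_splits(self):
        a = gd.population("a", time=1, N=10)
        b = gd.population("b", time=100, N=10, parent=a)
        c = gd.population("c", time=200, N=10, parent=b)
        assert infer_direction([a, b, c], []) == "forward"

    def test_no_signal_errors(self):
        p = gd.population("p", time=1, N=10)
        with pytest.raises(ModelError, match="infer"):
            infer_direction([p], [])

    def test_mixed_signals_error(self):
        a = gd.population("a", time=100, N=10)
        b = gd.population("b", time=200, N=10, parent=a)  # forward split
        gf = GeneFlow("a", "b", 0.1, 300, 250)  # backward window
        with pytest.raises(ModelError, match="conflicting"):
            infer_direction([a, b], [gf])

    def test_backward_generation_mapping(self):
        assert _to_gen(50_000, 50_000, 30, "backward") == 1
        assert _to_gen(49_970, 50_000, 30, "backward") == 2

    @given(t=st.floats(0, 50_000))
    def test_roundtrip_within_half_generation(self, t):
        g = 30.0
        gen = _to_gen(t, 50_000, g, "backward")
        back = _from_gen(gen, 50_000, g, "backward")
        assert abs(t - back) <= g / 2

    def test_times_outside_span_error(self, tiny_model):
        with pytest.raises(ModelError, match="outside"):
            tiny_model.to_generations(50)


class TestResize:
    def test_step_resize(self):
        p = gd.population("p", time=1, N=100)
        ev = gd.resize(p, time=10, N=50)
        m = gd.compile_model([p], [ev], generation_time=1,
                             direction="forward", end_time=20)
        assert m.pop("p").N_at(9) == 100
        assert m.pop("p").N_at(10) == 50
        assert m.pop("p").N_at(20) == 50

    def test_exponential_schedule(self):
        p = gd.population("p", time=1, N=100)
        ev = gd.resize(p, time=5, N=200, how="exponential", end_time=15)
        m = gd.compile_model([p], [ev], generation_time=1,
                             direction="forward", end_time=20)
        pop = m.pop("p")
        expected = [round(100 * 2 ** (k / 10)) for k in range(11)]
        got = [pop.N_at(5 + k) for k in range(11)]
        assert got == expected
        assert all(np.diff(got) >= 0)


class TestSampling:
    def test_schedule_series(self, tiny_model):
        import copy

        m = gd.compile_model([gd.population("p", time=1, N=100)],
                             generation_time=1, direction="forward", end_time=10)
        events = gd.schedule_sampling(m, [2, 5, 8], "p", 3)
        assert len(events) == 3
        assert [s.gen for s in m.sampling] == [2, 5, 8]

    def test_location_outside_world_errors(self):
        world = gd.toy_world(10)
        m = gd.compile_model([gd.population("p", time=1, N=10)],
                             generation_time=1, direction="forward",
                             world=world, end_time=10)
        with pytest.raises(ModelError, match="outside the world extent"):
            gd.schedule_sampling(m, [5], "p", 2, location=gd.Point(100, 100))

    def test_sampling_outside_lifespan_errors(self):
        p = gd.population("p", time=1, N=10, removal_time=5)
        q = gd.population("q", time=1, N=10)
        m = gd.compile_model([p, q], generation_time=1, direction="forward",
                             end_time=10)
        with pytest.raises(ModelError, match="lifespan"):
            gd.schedule_sampling(m, [8], "p", 2)


class TestCompileModel:
    def test_example1_structure(self):
        m = gd.example1_model()
        assert m.G == 6000
        assert len(m.gene_flows) == 1
        flow = m.gene_flows[0]
        assert m.populations[flow.source_idx].name == "b"
        assert m.populations[flow.target_idx].name == "x1"
        # split relationships form the expected graph
        parents = {
            p.name: (m.populations[p.parent_idx].name if p.parent_idx >= 0 else None)
            for p in m.populations
        }
        assert parents == {
            "o": None, "c": "o", "a": "c", "b": "a", "x1": "c", "x2": "c",
        }

    def test_unknown_population_in_event(self):
        p = gd.population("p", time=1, N=10)
        ev = gd.resize("ghost", time=5, N=5)
        with pytest.raises(ModelError, match="ghost"):
            gd.compile_model([p], [ev], generation_time=1,
                             direction="forward", end_time=10)

    def test_every_generation_has_schedule(self, small_spatial_model):
        m = small_spatial_model
        for pop in m.populations:
            for gen in range(pop.start_gen, pop.end_gen + 1):
                assert pop.N_at(gen) > 0
                assert pop.range_at(gen) is not None
                assert pop.spatial_at(gen) is not None

    def test_compilation_pure(self, tmp_path):
        m1 = gd.example3_like_model(scale=20)
        m2 = gd.example3_like_model(scale=20)
        assert gd.model_digest(m1) == gd.model_digest(m2)


class TestBundleRoundTrip:
    @pytest.mark.parametrize("factory", [
        lambda: gd.example1_model(scale=20),
        lambda: gd.example3_like_model(scale=20),
    ])
    def test_serialize_load_equal(self, tmp_path, factory):
        m = factory()
        gd.write_bundle(m, tmp_path / "bundle")
        m2 = gd.load_bundle(tmp_path / "bundle")
        assert m2.G == m.G
        assert m2.direction == m.direction
        assert m2.pop_names == m.pop_names
        assert [f.m for f in m2.gene_flows] == [f.m for f in m.gene_flows]
        assert [(s.gen, s.pop_idx, s.n) for s in m2.sampling] == \
               [(s.gen, s.pop_idx, s.n) for s in m.sampling]
        for p1, p2 in zip(m.populations, m2.populations):
            assert np.array_equal(p1.N_of_gen, p2.N_of_gen)
            assert [g for g, _ in p1.ranges] == [g for g, _ in p2.ranges]
        # serialization is byte-stable across a load/save cycle
        assert gd.model_digest(m2) == gd.model_digest(m)
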