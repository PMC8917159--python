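"""Synthetic network geometries, wall discretization, event streams and
closed-form velocity fields."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

from hemonet.networks import (DIAMETER_RANGE_UM, NetworkError, NetworkGraph,
                              NetworkSpec, SyntheticEventSpec, build_fixture,
                              discretize_walls, generate_network,
                              synthesize_event_stream,
                              synthesize_velocity_field)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

class TestFixtures:
    def test_straight_channel_degenerate_network(self):
        g = build_fixture("straight_channel", diameter=12.0, length=100.0)
        assert len(g.segments) == 1 and len(g.junctions) == 0
        assert g.segments[1].arclength == pytest.approx(100.0)

    def test_side_branch_diameters(self):
        g = build_fixture("side_branch", feeder_diameter=17.5,
                          branch_diameter=6.0)
        j = g.junctions[1]
        assert g.segments[j.mother_ids[0]].diameter == pytest.approx(17.5)
        ds = sorted(g.segments[d].diameter for d in j.daughter_ids)
        assert ds == pytest.approx([6.0, 17.5])

    def test_y_bifurcation_mirror_symmetry(self):
        g = build_fixture("y_bifurcation", daughter_diameters=(9.0, 9.0),
                          angles_deg=(30.0, -30.0))
        d1, d2 = (g.segments[i] for i in g.junctions[1].daughter_ids)
        assert d1.diameter == d2.diameter
        # mirrored centerlines across the feeder axis
        assert np.allclose(d1.centerline[:, 0], d2.centerline[:, 0])
        assert np.allclose(d1.centerline[:, 1], -d2.centerline[:, 1])

    def test_curved_channel_constant_curvature(self):
        R = 60.0
        g = build_fixture("curved_channel", radius_of_curvature=R)
        cl = g.segments[1].centerline
        # every vertex equidistant from the arc center (0, R)
        d = np.hypot(cl[:, 0], cl[:, 1] - R)
        assert np.allclose(d, R, rtol=1e-9)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(NetworkError):
            build_fixture("moebius_vessel")

    def test_out_of_range_diameter_rejected(self):
        with pytest.raises(NetworkError):
            build_fixture("straight_channel", diameter=3.0)

    def test_all_fixtures_validate(self):
        for name in ("straight_channel", "curved_channel", "y_bifurcation",
                     "side_branch", "two_generation_net"):
            g = build_fixture(name)
            g.validate()  # raises on violation

    def test_json_roundtrip(self):
        g = build_fixture("two_generation_net")
        g2 = NetworkGraph.from_json(g.to_json())
        g2.validate()
        assert set(g2.segments) == set(g.segments)
        assert g2.segments[1].diameter == g.segments[1].diameter

    def test_graphml_export(self, tmp_path):
        g = build_fixture("y_bifurcation")
        path = tmp_path / "net.graphml"
        g.to_graphml(str(path))
        import networkx as nx
        gg = nx.read_graphml(str(path))
        assert gg.number_of_edges() == len(g.segments)


# --------------------------------------------------------------------------
# random generator
# --------------------------------------------------------------------------

class TestGenerator:
    def test_same_seed_identical(self):
        a = generate_network(NetworkSpec(generations=3, seed=1))
        b = generate_network(NetworkSpec(generations=3, seed=1))
        assert a.to_json() == b.to_json()

    def test_diameters_in_physiological_range_many_seeds(self):
        lo, hi = DIAMETER_RANGE_UM
        for seed in range(100):
            g = generate_network(NetworkSpec(generations=2, seed=seed))
            g.validate()
            for s in g.segments.values():
                assert lo - 1e-9 <= s.diameter <= hi + 1e-9
                assert s.tortuosity >= 1.0 - 1e-12

    def test_generation_mean_diameter_non_increasing(self):
        g = generate_network(NetworkSpec(generations=4, seed=7))
        by_gen = {}
        for s in g.segments.values():
            if s.generation >= 0:
                by_gen.setdefault(s.generation, []).append(s.diameter)
        means = [np.mean(by_gen[k]) for k in sorted(by_gen)]
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))

    def test_requires_at_least_one_generation(self):
        with pytest.raises(NetworkError):
            generate_network(NetworkSpec(generations=0))

    def test_structure_bifurcations_then_mergers(self):
        g = generate_network(NetworkSpec(generations=3, seed=2))
        kinds = [j.kind for j in g.junctions.values()]
        assert kinds.count("bifurcation") == 7   # 1 + 2 + 4
        assert kinds.count("merger") == 7
        assert len([n for n in g.nodes.values() if n.role == "outlet"]) == 1


# --------------------------------------------------------------------------
# walls
# --------------------------------------------------------------------------

class TestWalls:
    def test_straight_channel_parallel_walls(self):
        g = build_fixture("straight_channel", diameter=12.0, length=100.0)
        w = discretize_walls(g, 1.0)
        # closed rectangle-ish boundary of perimeter 2(L + d)
        assert w.polygon.is_valid
        assert w.total_length() == pytest.approx(2 * (100 + 12), rel=1e-3)
        ys = np.vstack(w.rings)[:, 1]
        on_walls = np.isclose(np.abs(ys), 6.0, atol=1e-6).mean()
        assert on_walls > 0.8  # most samples lie on the two straight walls

    def test_centerline_contained(self):
        for name in ("y_bifurcation", "side_branch", "two_generation_net"):
            g = build_fixture(name)
            w = discretize_walls(g, 1.0)
            for s in g.segments.values():
                mid = s.point_at(s.arclength / 2)
                assert w.contains(mid[0], mid[1])

    def test_y_perimeter_matches_idealized_union(self):
        g = build_fixture("y_bifurcation")
        w = discretize_walls(g, 1.0)
        parts = [LineString(s.centerline).buffer(s.radius, cap_style="flat",
                                                 quad_segs=64)
                 for s in g.segments.values()]
        r = max(s.radius for s in g.segments.values())
        parts.append(Point(g.junctions[1].apex).buffer(r, quad_segs=64))
        ideal = unary_union(parts)
        assert w.total_length() == pytest.approx(ideal.exterior.length,
                                                 rel=0.02)

    def test_resolution_bounds_enforced(self):
        g = build_fixture("straight_channel", diameter=12.0)
        with pytest.raises(NetworkError):
            discretize_walls(g, 4.0)   # > diameter/4
        with pytest.raises(NetworkError):
            discretize_walls(g, -1.0)

    def test_outward_normals(self):
        g = build_fixture("y_bifurcation")
        w = discretize_walls(g, 1.0)
        pts, nrm, _own = w.all_samples()
        probe = pts + 0.3 * nrm
        assert (~w.contains(probe[:, 0], probe[:, 1])).mean() > 0.99


# --------------------------------------------------------------------------
# synthetic event streams
# --------------------------------------------------------------------------

class TestEventStreams:
    def test_routing_fraction_within_binomial_3_sigma(self):
        spec = SyntheticEventSpec(p_route=0.75, n_cells=10000, seed=0)
        ev, _tr, truth = synthesize_event_stream(spec)
        n1 = (ev["gate_id"] == "J1:d1").sum()
        p_hat = n1 / spec.n_cells
        sigma = np.sqrt(0.75 * 0.25 / spec.n_cells)
        assert abs(p_hat - 0.75) < 3 * sigma
        assert truth["n_to_d1"] == n1

    def test_no_planted_lingering_gives_zero_gamma(self):
        _ev, _tr, truth = synthesize_event_stream(
            SyntheticEventSpec(n_cells=50, seed=1))
        assert truth["gamma_true"] == 0.0
        assert truth["episodes"] == []

    def test_deterministic_routing_p1(self):
        ev, _tr, _truth = synthesize_event_stream(
            SyntheticEventSpec(p_route=1.0, n_cells=200, seed=2))
        assert (ev["gate_id"] == "J1:d2").sum() == 0

    def test_planted_stall_appears_in_trajectory(self):
        spec = SyntheticEventSpec(n_cells=5, seed=3,
                                  linger_episodes=((2, 30.0),))
        _ev, tr, truth = synthesize_event_stream(spec)
        assert truth["gamma_true"] == pytest.approx(0.2)
        t2 = tr[tr["cell_id"] == 2]
        at_apex = t2[(np.hypot(t2["x"], t2["y"]) < 0.5)]
        span = at_apex["t_ms"].max() - at_apex["t_ms"].min()
        assert span == pytest.approx(30.0, abs=1.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(NetworkError):
            SyntheticEventSpec(p_route=1.5).validate()

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(NetworkError):
            SyntheticEventSpec(linger_episodes=((0, -5.0),)).validate()


# --------------------------------------------------------------------------
# closed-form fields
# --------------------------------------------------------------------------

class TestVelocityFields:
    def test_parabolic_centerline_speed(self):
        g = build_fixture("straight_channel", diameter=12.0, length=60.0)
        st = synthesize_velocity_field("parabolic", g, flow_rate=18.0,
                                       resolution=64)
        u_mid = st.interp_velocity(np.array([[30.0, 0.0]]))[0, 0]
        assert u_mid == pytest.approx(3 * 18.0 / (2 * 12.0), rel=2e-3)

    def test_parabolic_divergence_free(self):
        g = build_fixture("straight_channel", diameter=12.0, length=60.0)
        st = synthesize_velocity_field("parabolic", g, flow_rate=18.0)
        assert np.abs(st.divergence()).max() < 1e-12

    def test_constant_profile_zero_shear(self):
        g = build_fixture("straight_channel", diameter=12.0, length=60.0)
        st = synthesize_velocity_field("constant", g, flow_rate=18.0)
        assert np.ptp(st.u) < 1e-12

    def test_zero_skew_reduces_to_parabolic(self):
        g = build_fixture("straight_channel", diameter=12.0, length=60.0)
        a = synthesize_velocity_field("parabolic", g, flow_rate=18.0)
        b = synthesize_velocity_field("skewed", g, flow_rate=18.0, skew=0.0)
        assert np.allclose(a.u, b.u)
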