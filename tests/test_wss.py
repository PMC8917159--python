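"""Wall shear stress: analytic plane-Poiseuille oracle, averaging
rules, paired relative changes and unit conversions."""

import numpy as np
import pandas as pd
import pytest

from hemonet.membrane import MembraneParams
from hemonet.networks import build_fixture, discretize_walls
from hemonet.solver import SimulationRecord
from hemonet.units import dyn_cm2_to_pa, pa_to_dyn_cm2
from hemonet.vessel_stats import gate_flux
from hemonet.wss import (WSSField, delta_tau, time_average_field,
                         vessel_average_wss, wall_traction)

MU_SI = 0.0012  # plasma, Pa*s


def make_record(graph, states, times=None):
    times = times if times is not None else list(np.arange(len(states),
                                                           dtype=float))
    return SimulationRecord(config={}, seed=0, graph_json=graph.to_json(),
                            field_times=times, field_snapshots=states,
                            events=pd.DataFrame(columns=["cell_id", "gate_id",
                                                         "time_ms",
                                                         "direction"]))


class TestTimeAverage:
    def test_steady_field_unchanged(self, channel_graph):
        from hemonet.networks import synthesize_velocity_field
        st = synthesize_velocity_field("parabolic", channel_graph,
                                       flow_rate=18.0)
        rec = make_record(channel_graph, [st.copy(), st.copy(), st.copy()])
        avg = time_average_field(rec)
        assert np.allclose(avg.u, st.u)

    def test_field_plus_negation_zero(self, channel_graph):
        from hemonet.networks import synthesize_velocity_field
        st = synthesize_velocity_field("parabolic", channel_graph,
                                       flow_rate=18.0)
        neg = st.copy()
        neg.u = -neg.u
        avg = time_average_field(make_record(channel_graph, [st, neg]))
        assert np.abs(avg.u).max() < 1e-14

    def test_pulsed_poiseuille_over_whole_periods(self, channel_graph):
        """u(t) = (1 + 0.5 sin wt) * parabola averaged over whole periods
        equals the mean-amplitude parabola."""
        from hemonet.networks import synthesize_velocity_field
        base = synthesize_velocity_field("parabolic", channel_graph,
                                         flow_rate=18.0)
        n = 40
        states = []
        for k in range(n):  # two whole periods
            st = base.copy()
            st.u = base.u * (1.0 + 0.5 * np.sin(2 * np.pi * 2 * k / n))
            states.append(st)
        avg = time_average_field(make_record(channel_graph, states))
        assert np.abs(avg.u - base.u).max() < 1e-6 * np.abs(base.u).max()

    def test_warmup_needed(self, channel_graph):
        with pytest.raises(ValueError):
            time_average_field(make_record(channel_graph, []), 0.0)


class TestWallTraction:
    def test_poiseuille_wall_shear(self, poiseuille_solutions, channel_graph):
        """tau = 6 mu Q / w^2 at both walls within 1% (32-point run)."""
        dom, st = poiseuille_solutions[32]
        field = wall_traction(st, dom.walls, MU_SI)
        Q = gate_flux(st, channel_graph.gates()["seg1:mid"])
        tau_exact = pa_to_dyn_cm2(6 * MU_SI * 1e3 * Q / 12.0 ** 2)
        pts = field.points
        mid = (np.abs(pts[:, 0] - 50.0) < 20.0) & ~field.flagged
        tau = np.abs(field.tau_dyn_cm2[mid])
        assert np.median(tau) == pytest.approx(tau_exact, rel=0.01)

    def test_plug_flow_zero_interior_shear(self, channel_graph):
        from hemonet.networks import synthesize_velocity_field
        st = synthesize_velocity_field("constant", channel_graph,
                                       flow_rate=18.0, resolution=16)
        walls = discretize_walls(channel_graph, 0.5)
        field = wall_traction(st, walls, MU_SI)
        # a uniform field has no velocity gradient anywhere
        ok = ~field.flagged
        inner = ok & (np.abs(field.points[:, 0] - 50.0) < 30.0)
        assert np.abs(field.tau_dyn_cm2[inner]).max() < 1e-9

    def test_linearity_in_flux(self, poiseuille_solutions):
        dom, st = poiseuille_solutions[16]
        st2 = st.copy()
        st2.u = 2.0 * st.u
        st2.v = 2.0 * st.v
        f1 = wall_traction(st, dom.walls, MU_SI)
        f2 = wall_traction(st2, dom.walls, MU_SI)
        ok = ~f1.flagged & ~f2.flagged
        assert np.allclose(f2.tau_dyn_cm2[ok], 2 * f1.tau_dyn_cm2[ok],
                           rtol=1e-12)


class TestVesselAverage:
    def mk(self, taus, owners=None, weights=None):
        n = len(taus)
        return WSSField(points=np.zeros((n, 2)), normals=np.zeros((n, 2)),
                        owners=np.asarray(owners if owners is not None
                                          else [1] * n),
                        tau_dyn_cm2=np.asarray(taus, dtype=float),
                        weights_um=np.asarray(weights if weights is not None
                                              else [1.0] * n),
                        mu_plasma_pa_s=MU_SI,
                        flagged=np.zeros(n, dtype=bool))

    def test_constant_tau(self):
        assert vessel_average_wss(self.mk([4.0] * 7), 1) == pytest.approx(4.0)

    def test_linear_tau_midpoint(self):
        taus = np.linspace(2.0, 6.0, 21)
        assert vessel_average_wss(self.mk(list(taus)), 1) == \
            pytest.approx(4.0, rel=1e-9)

    def test_sampling_refinement_stable(self, poiseuille_solutions,
                                        channel_graph):
        """Refining the wall sampling changes the per-vessel average by
        less than 1% (same lumen geometry, denser samples)."""
        _dom, st = poiseuille_solutions[16]
        walls_a = discretize_walls(channel_graph, 0.5)
        walls_b = discretize_walls(channel_graph, 0.25)
        a = vessel_average_wss(wall_traction(st, walls_a, MU_SI), 1)
        b = vessel_average_wss(wall_traction(st, walls_b, MU_SI), 1)
        assert a == pytest.approx(b, rel=0.01)

    def test_unowned_segment_rejected(self):
        with pytest.raises(ValueError):
            vessel_average_wss(self.mk([1.0], owners=[2]), 1)


class TestDeltaTau:
    def pair(self, graph, tn, ts):
        walls = discretize_walls(graph, 1.0)
        pts, nrm, own = walls.all_samples()
        n = len(pts)
        mk = lambda tau: WSSField(points=pts, normals=nrm, owners=own,
                                  tau_dyn_cm2=np.full(n, float(tau)),
                                  weights_um=np.ones(n),
                                  mu_plasma_pa_s=MU_SI,
                                  flagged=np.zeros(n, dtype=bool))
        return mk(tn), mk(ts)

    def test_identical_runs_zero(self, channel_graph):
        a, b = self.pair(channel_graph, 40.0, 40.0)
        d = delta_tau(a, b, channel_graph)
        assert np.nanmax(np.abs(d.delta_tau)) == 0.0

    def test_relative_change_formula(self, channel_graph):
        a, b = self.pair(channel_graph, 40.0, 50.0)
        d = delta_tau(a, b, channel_graph)
        assert np.nanmedian(d.delta_tau) == pytest.approx(0.25)

    def test_scale_invariance(self, channel_graph):
        a, b = self.pair(channel_graph, 40.0, 50.0)
        a2, b2 = self.pair(channel_graph, 80.0, 100.0)
        d1 = delta_tau(a, b, channel_graph)
        d2 = delta_tau(a2, b2, channel_graph)
        assert np.nanmedian(d1.delta_tau) == \
            pytest.approx(np.nanmedian(d2.delta_tau), rel=1e-12)

    def test_apex_tagging(self):
        g = build_fixture("y_bifurcation")
        walls = discretize_walls(g, 1.0)
        pts, nrm, own = walls.all_samples()
        n = len(pts)
        mk = lambda tau: WSSField(pts, nrm, own, np.full(n, tau),
                                  np.ones(n), MU_SI,
                                  np.zeros(n, dtype=bool))
        d = delta_tau(mk(40.0), mk(50.0), g)
        apex = np.asarray(g.junctions[1].apex)
        r_feed = g.segments[1].radius
        dist = np.hypot(*(pts - apex).T)
        assert set(d.tags[dist < 2 * r_feed]) == {"apex"}
        assert (d.tags[dist > 3.5 * r_feed] != "apex").all()


class TestUnits:
    def test_pa_dyn_roundtrip_exact(self):
        assert pa_to_dyn_cm2(1.0) == 10.0
        assert dyn_cm2_to_pa(pa_to_dyn_cm2(3.7)) == 3.7
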