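"""Flow-core operators: delta spreading/interpolation, projection,
ghost-node walls, boundary conditions, viscosity indicator, seeding."""

import numpy as np
import pytest

from hemonet.grid import FluidState
from hemonet.membrane import MembraneParams
from hemonet.networks import BoundaryCondition, build_fixture
from hemonet.solver import (Cell, FlowDomain, SimConfig, SolverError,
                            enforce_walls, interpolate_velocity,
                            measure_inlet_hematocrit, project_velocity,
                            run_simulation, seed_cells_at_inlet,
                            solve_steady_plasma, spread_forces,
                            update_viscosity_indicator)
from hemonet.vessel_stats import gate_flux

MU = MembraneParams().mu_plasma_model


@pytest.fixture(scope="module")
def channel_domain():
    g = build_fixture("straight_channel", diameter=12.0, length=60.0,
                      dp_pa=10.0)
    return g, FlowDomain(g, 12.0 / 16, margin=1.0)


# --------------------------------------------------------------------------
# discrete delta
# --------------------------------------------------------------------------

class TestSpreadInterpolate:
    def test_constant_field_reproduced(self, channel_domain):
        _g, dom = channel_domain
        st = FluidState.zeros(dom.grid, MU)
        st.u[:] = 1.7
        st.v[:] = -0.4
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(10, 50, 40),
                               rng.uniform(-4, 4, 40)])
        U = interpolate_velocity(st, pts)
        assert np.allclose(U[:, 0], 1.7, atol=1e-12)
        assert np.allclose(U[:, 1], -0.4, atol=1e-12)

    def test_spreading_conserves_total_force(self, channel_domain):
        _g, dom = channel_domain
        st = FluidState.zeros(dom.grid, MU)
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(10, 50, 30),
                               rng.uniform(-4, 4, 30)])
        F = rng.standard_normal((30, 2))
        fx, fy = spread_forces(st, pts, F)
        h2 = dom.grid.h ** 2
        assert fx.sum() * h2 == pytest.approx(F[:, 0].sum(), rel=1e-12)
        assert fy.sum() * h2 == pytest.approx(F[:, 1].sum(), rel=1e-12)

    def test_spread_interp_adjointness(self, channel_domain):
        """<spread(F), u>_grid = <F, interp(u)> for random F and u."""
        _g, dom = channel_domain
        st = FluidState.zeros(dom.grid, MU)
        rng = np.random.default_rng(2)
        st.u = rng.standard_normal(st.u.shape)
        st.v = rng.standard_normal(st.v.shape)
        pts = np.column_stack([rng.uniform(10, 50, 25),
                               rng.uniform(-4, 4, 25)])
        F = rng.standard_normal((25, 2))
        fx, fy = spread_forces(st, pts, F)
        h2 = dom.grid.h ** 2
        lhs = (fx * st.u).sum() * h2 + (fy * st.v).sum() * h2
        U = interpolate_velocity(st, pts)
        rhs = (F * U).sum()
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_point_outside_support_rejected(self, channel_domain):
        _g, dom = channel_domain
        st = FluidState.zeros(dom.grid, MU)
        with pytest.raises(SolverError):
            spread_forces(st, np.array([[dom.grid.x0 - 5.0, 0.0]]),
                          np.array([[1.0, 0.0]]))


# --------------------------------------------------------------------------
# projection
# --------------------------------------------------------------------------

class TestProjection:
    def test_random_field_becomes_divergence_free(self, channel_domain):
        _g, dom = channel_domain
        st = FluidState.zeros(dom.grid, MU)
        rng = np.random.default_rng(3)
        st.u = rng.standard_normal(st.u.shape)
        st.v = rng.standard_normal(st.v.shape)
        dom.fill_ghosts(st)
        project_velocity(dom, st)
        div = dom.lumen_divergence(st)[dom.p_unk]
        assert np.abs(div).max() < 1e-8

    def test_divergence_free_field_unchanged(self, channel_domain):
        _g, dom = channel_domain
        st = solve_steady_plasma(dom)
        u0 = st.u.copy()
        project_velocity(dom, st)
        assert np.abs(st.u - u0).max() < 1e-8 * np.abs(u0).max()

    def test_idempotence(self, channel_domain):
        _g, dom = channel_domain
        st = FluidState.zeros(dom.grid, MU)
        rng = np.random.default_rng(4)
        st.u = rng.standard_normal(st.u.shape)
        st.v = rng.standard_normal(st.v.shape)
        dom.fill_ghosts(st)
        project_velocity(dom, st)
        u1 = st.u.copy()
        project_velocity(dom, st)
        assert np.abs(st.u - u1).max() < 1e-10


# --------------------------------------------------------------------------
# walls
# --------------------------------------------------------------------------

class TestWallEnforcement:
    def test_quiescent_fluid_unchanged(self, channel_domain):
        _g, dom = channel_domain
        st = FluidState.zeros(dom.grid, MU)
        enforce_walls(dom, st)
        assert np.abs(st.u).max() == 0.0

    def test_driven_flow_no_slip_at_wall(self, channel_domain):
        _g, dom = channel_domain
        st = solve_steady_plasma(dom)
        pts, nrm, _own = dom.walls.all_samples()
        # interpolate velocity exactly at the wall samples
        inner = (pts[:, 0] > 10) & (pts[:, 0] < 50)
        U = st.interp_velocity(pts[inner])
        speed = np.hypot(U[:, 0], U[:, 1])
        mean_lumen = np.abs(st.u[dom.u_unk]).mean()
        assert np.median(speed) < 0.02 * mean_lumen

    def test_poiseuille_profile_shape(self, channel_domain):
        """The mid-channel profile matches the parabola carrying the
        same discrete flux (isolates the wall treatment from the port
        regions)."""
        g, dom = channel_domain
        st = solve_steady_plasma(dom)
        Q = gate_flux(st, g.gates()["seg1:mid"])
        y = np.linspace(-5.8, 5.8, 101)
        U = st.interp_velocity(np.column_stack([np.full_like(y, 30.0), y]))[:, 0]
        Uex = 1.5 * (Q / 12.0) * (1 - (y / 6.0) ** 2)
        assert np.max(np.abs(U - Uex)) / Uex.max() < 0.01


# --------------------------------------------------------------------------
# boundary conditions
# --------------------------------------------------------------------------

class TestBoundaryConditions:
    def test_pressure_bc_flux_matches_poiseuille(self):
        """End-to-end: prescribed port pressures drive the analytic
        Poiseuille flux (32 points across the width; the effective
        driven length runs between the port pressure stations)."""
        g = build_fixture("straight_channel", diameter=12.0, length=60.0,
                          dp_pa=10.0)
        dom = FlowDomain(g, 12.0 / 32, margin=1.0)
        st = solve_steady_plasma(dom)
        L_eff = dom.grid.lx - dom.grid.h
        Qa = 10.0 * 12.0 ** 3 / (12 * MU * L_eff)
        Q = gate_flux(st, g.gates()["seg1:mid"])
        assert Q == pytest.approx(Qa, rel=0.02)

    def test_flow_rate_bc_realizes_prescribed_flux(self):
        g = build_fixture("straight_channel", diameter=12.0, length=60.0)
        Q0 = 15.0
        g.boundary_conditions = [
            BoundaryCondition(1, "flow_rate", Q0, "um2/ms"),
            BoundaryCondition(2, "pressure", 0.0, "Pa"),
        ]
        dom = FlowDomain(g, 12.0 / 16, margin=1.0)
        st = solve_steady_plasma(dom)
        Q = gate_flux(st, g.gates()["seg1:mid"])
        assert Q == pytest.approx(Q0, rel=0.005)

    def test_junction_flux_conservation(self):
        g = build_fixture("y_bifurcation", feeder_diameter=12.0,
                          daughter_diameters=(9.0, 9.0))
        dom = FlowDomain(g, 12.0 / 16, margin=1.0)
        st = solve_steady_plasma(dom)
        gates = g.gates()
        Qm = gate_flux(st, gates["seg1:mid"])
        Q1 = gate_flux(st, gates["seg2:mid"])
        Q2 = gate_flux(st, gates["seg3:mid"])
        assert (Q1 + Q2) == pytest.approx(Qm, rel=0.005)


# --------------------------------------------------------------------------
# viscosity indicator
# --------------------------------------------------------------------------

class TestViscosityIndicator:
    def test_no_cells_uniform_plasma(self, channel_domain):
        _g, dom = channel_domain
        p = MembraneParams()
        st = FluidState.zeros(dom.grid, p.mu_plasma_model)
        update_viscosity_indicator(dom, st, [], p)
        assert np.allclose(st.mu, 0.0012e3)  # 0.0012 Pa*s in Pa*ms

    def test_cell_interior_hemoglobin_viscosity(self, channel_domain):
        """Deep inside a circular cell the viscosity is the hemoglobin
        value 0.006 Pa*s (plasma 0.0012 Pa*s outside)."""
        from hemonet.membrane import MembraneMesh
        _g, dom = channel_domain
        p = MembraneParams()
        st = FluidState.zeros(dom.grid, p.mu_plasma_model)
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ring = np.column_stack([30.0 + 3.0 * np.cos(th), 3.0 * np.sin(th)])
        cell = Cell(0, MembraneMesh(ring, None, ring.copy()),
                    area_ref=np.pi * 9.0)
        update_viscosity_indicator(dom, st, [cell], p)
        gi = int((30.0 - dom.grid.x0) / dom.grid.h)
        gj = int((0.0 - dom.grid.y0) / dom.grid.h)
        assert st.mu[gi, gj] == pytest.approx(0.006e3)  # 0.006 Pa*s

    def test_indicator_integral_matches_cell_area(self, channel_domain):
        _g, dom = channel_domain
        p = MembraneParams()
        st = FluidState.zeros(dom.grid, p.mu_plasma_model)
        cell = Cell.create(0, (30.0, 0.0))
        update_viscosity_indicator(dom, st, [cell], p)
        ind = (st.mu - p.mu_plasma_model) / (p.mu_interior_model
                                             - p.mu_plasma_model)
        area = ind.sum() * dom.grid.h ** 2
        assert area == pytest.approx(cell.area(), rel=0.02)


# --------------------------------------------------------------------------
# inlet seeding
# --------------------------------------------------------------------------

class TestSeeding:
    def test_zero_target_inserts_nothing(self, channel_domain):
        g, _dom = channel_domain
        cfg = SimConfig(target_hematocrit=0.0)
        sched = seed_cells_at_inlet(cfg, g, np.random.default_rng(0))
        assert len(sched) == 0

    def test_same_seed_identical_schedule(self, channel_domain):
        g, _dom = channel_domain
        cfg = SimConfig(target_hematocrit=0.3, duration_ms=200.0)
        a = seed_cells_at_inlet(cfg, g, np.random.default_rng(5))
        b = seed_cells_at_inlet(cfg, g, np.random.default_rng(5))
        assert np.array_equal(a.times_ms, b.times_ms)
        assert np.array_equal(a.offsets_um, b.offsets_um)

    def test_target_hematocrit_achieved(self, channel_graph):
        """Default seeding in the 12-um channel sustains 30% +/- 3%
        time-averaged inlet tube hematocrit."""
        cfg = SimConfig(target_hematocrit=0.30, duration_ms=2000.0)
        sched = seed_cells_at_inlet(cfg, channel_graph,
                                    np.random.default_rng(11),
                                    mean_speed=1.5, duration_ms=2000.0)
        H = measure_inlet_hematocrit(sched, duration_ms=2000.0)
        assert H == pytest.approx(0.30, abs=0.03)

    def test_unreachable_target_reported(self):
        """A cell larger than the admissible lateral band cannot be
        inserted; the geometric impossibility is raised explicitly."""
        g = build_fixture("straight_channel", diameter=5.5, length=60.0)
        cfg = SimConfig(target_hematocrit=0.30, cell_diameter_um=12.0)
        with pytest.raises(SolverError):
            seed_cells_at_inlet(cfg, g, np.random.default_rng(0))


# --------------------------------------------------------------------------
# coupled stepping
# --------------------------------------------------------------------------

class TestRunSimulation:
    def test_quiescent_cell_stays_put(self):
        """A cell at its resting shape in a force-free closed box must
        not drift (equilibrium is preserved by the discrete coupling)."""
        g = build_fixture("straight_channel", diameter=12.0, length=40.0,
                          dp_pa=0.0)
        cfg = SimConfig(duration_ms=2.0, points_per_cell=8, seed=0)
        dom = FlowDomain(g, cfg.h, margin=1.0)
        cell = Cell.create(0, (20.0, 0.0))
        rec = run_simulation(g, [cell], cfg, domain=dom)
        tr = rec.trajectories()
        drift = np.hypot(tr.x.iloc[-1] - tr.x.iloc[0],
                         tr.y.iloc[-1] - tr.y.iloc[0])
        assert drift < 0.05 * dom.grid.h

    def test_same_seed_identical_records(self):
        g = build_fixture("straight_channel", diameter=12.0, length=40.0,
                          dp_pa=8.0)
        cfg = SimConfig(duration_ms=1.0, points_per_cell=8, seed=9)
        recs = []
        for _ in range(2):
            dom = FlowDomain(g, cfg.h, margin=1.0)
            cell = Cell.create(0, (12.0, 1.0))
            recs.append(run_simulation(g, [cell], cfg, domain=dom))
        a, b = recs
        assert a.cell_times == b.cell_times
        for sa, sb in zip(a.cell_snapshots, b.cell_snapshots):
            for cid in sa:
                assert np.array_equal(sa[cid], sb[cid])
        assert np.array_equal(a.field_snapshots[-1].u,
                              b.field_snapshots[-1].u)
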