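"""Shared fixtures: small geometries and the session-scoped solver runs
reused across test modules (steady channel solutions, the sparse
Y-bifurcation partitioning run, paired migration runs)."""

from __future__ import annotations

import numpy as np
import pytest

from hemonet.membrane import MembraneParams
from hemonet.networks import build_fixture
from hemonet.solver import (Cell, FlowDomain, SimConfig, run_simulation,
                            solve_steady_plasma)

CHANNEL_W = 12.0
CHANNEL_L = 100.0
CHANNEL_DP = 15.0


@pytest.fixture(scope="session")
def channel_graph():
    return build_fixture("straight_channel", diameter=CHANNEL_W,
                         length=CHANNEL_L, dp_pa=CHANNEL_DP)


@pytest.fixture(scope="session")
def poiseuille_solutions(channel_graph):
    """Steady plasma flow in the straight channel at 16 and 32 points
    across the width (used by the analytic-oracle and WSS tests)."""
    out = {}
    for res in (16, 32):
        h = CHANNEL_W / res
        dom = FlowDomain(channel_graph, h, margin=1.0)
        st = solve_steady_plasma(dom)
        out[res] = (dom, st)
    return out


@pytest.fixture(scope="session")
def ybif_graph():
    """Symmetric Y bifurcation (14-um feeder, 11-um daughters) with
    outlet flow-rate conditions pinning the split at Q* = 0.6 toward
    the upper daughter (the imposed-split study condition)."""
    from hemonet.networks import BoundaryCondition
    g = build_fixture("y_bifurcation", feeder_diameter=14.0,
                      daughter_diameters=(11.0, 11.0),
                      angles_deg=(26.0, -26.0), feeder_length=40.0,
                      daughter_length=40.0, straighten_outlets=True)
    Q = 16.0
    g.boundary_conditions = [
        BoundaryCondition(1, "pressure", 10.0, "Pa"),
        BoundaryCondition(3, "flow_rate", 0.6 * Q, "um2/ms"),
        BoundaryCondition(4, "flow_rate", 0.4 * Q, "um2/ms"),
    ]
    return g


@pytest.fixture(scope="session")
def sparse_ybif_run(ybif_graph):
    """Dilute single-file suspension through the Y bifurcation: cells
    enter near the feeder axis one at a time (the low-hematocrit
    regime, where the cell core rides the fast central streamlines), so
    the time-averaged partitioning reflects single-cell routing.
    Shared by the partitioning and conservation tests."""
    import numpy as np
    from hemonet.solver import InsertionSchedule
    cfg = SimConfig(duration_ms=230.0, points_per_cell=8, seed=7,
                    seed_inlet=True, target_hematocrit=0.05)
    dom = FlowDomain(ybif_graph, cfg.h, margin=1.0)
    rng = np.random.default_rng(cfg.seed)
    n = 11
    times = 16.0 * (np.arange(n) + 0.3) + rng.uniform(-4.0, 4.0, n)
    gate = ybif_graph.gates()["seg1:entry"]
    schedule = InsertionSchedule(
        times_ms=np.sort(np.clip(times, 0.0, None)),
        offsets_um=rng.uniform(-1.5, 1.5, n), segment_id=1,
        entry_point=gate.point, tangent=gate.tangent,
        normal=np.array([-gate.tangent[1], gate.tangent[0]]),
        width=14.0, cell_diameter=7.8, mean_speed=1.1,
        target_hematocrit=0.05)
    rec = run_simulation(ybif_graph, None, cfg, domain=dom,
                         schedule=schedule)
    return ybif_graph, cfg, dom, rec


@pytest.fixture(scope="session")
def migration_runs():
    """Single off-center cell in channel flow, normal vs 10x-stiffer
    membrane, matched geometry and duration."""
    g = build_fixture("straight_channel", diameter=12.0, length=60.0,
                      dp_pa=10.0)
    out = {}
    for label, params in (("normal", MembraneParams()),
                          ("stiffer", MembraneParams.stiffer(10.0))):
        cfg = SimConfig(duration_ms=12.0, points_per_cell=8, seed=1,
                        membrane=params)
        dom = FlowDomain(g, cfg.h, margin=1.0)
        cell = Cell.create(0, (15.0, 2.5), n_nodes=64)
        out[label] = run_simulation(g, [cell], cfg, domain=dom)
    return out


@pytest.fixture(scope="session")
def equal_flux_pair():
    """Plasma-only vs dilute-suspension flow at the same prescribed
    flux (flow-rate BC), for the WSS-increase mechanism test."""
    from hemonet.networks import BoundaryCondition, NetworkGraph
    g = build_fixture("straight_channel", diameter=12.0, length=60.0)
    Q = 15.0  # um^2/ms per unit depth
    g.boundary_conditions = [
        BoundaryCondition(1, "flow_rate", Q, "um2/ms"),
        BoundaryCondition(2, "pressure", 0.0, "Pa"),
    ]
    cfg = SimConfig(duration_ms=30.0, points_per_cell=8, seed=2)
    dom = FlowDomain(g, cfg.h, margin=1.0)
    cells = [Cell.create(k, (12.0 + 11.0 * k, off), n_nodes=64)
             for k, off in enumerate((0.8, -1.2, 0.4, -0.6))]
    rec_susp = run_simulation(g, cells, cfg, domain=dom)
    rec_plasma = run_simulation(g, [], cfg, domain=dom)
    return g, dom, cfg, rec_plasma, rec_susp
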