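"""Per-vessel hemodynamics statistics.

Computes, for every vessel segment of a run: the tube hematocrit time
series H(t) (instantaneous cell area fraction inside the segment
lumen), flow rate Q(t) through the mid-gate, pressure drop and flow
resistance, temporal coefficients of variation, mean cell length,
cross-sectional hematocrit profiles with skewness, cell-free layer
thickness, and the paired normal-vs-stiffer percentage changes
(Delta-H, Delta-Q, Delta-R).

Cells whose centroid lies within one blend radius of a junction apex
belong to the junction region and are excluded from vessel hematocrit
(the gate rule), so no cell is double-counted between segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from .networks import NetworkGraph, Segment
from .solver import SimulationRecord

__all__ = [
    "VesselRecord", "VesselDelta", "assign_cells_to_vessels",
    "hematocrit_series", "flow_series", "delta_metrics", "spatial_cv",
    "cross_section_profile", "build_vessel_record", "segment_lumen_polygon",
    "junction_blend_radius", "interp_pressure",
]


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def junction_blend_radius(graph: NetworkGraph, junction_id: int) -> float:
    j = graph.junctions[junction_id]
    return max(graph.segments[i].radius
               for i in list(j.mother_ids) + list(j.daughter_ids))


def segment_lumen_polygon(graph: NetworkGraph, segment_id: int) -> Polygon:
    """Segment lumen: swept strip minus the junction blend disks at its
    ends (the junction region belongs to no segment)."""
    s = graph.segments[segment_id]
    poly = LineString(s.centerline).buffer(s.radius, cap_style="flat",
                                           join_style="round", quad_segs=24)
    for j in graph.junctions.values():
        if segment_id in list(j.mother_ids) + list(j.daughter_ids):
            poly = poly.difference(
                Point(j.apex).buffer(junction_blend_radius(graph, j.id),
                                     quad_segs=24))
    return poly


def interp_pressure(state, point: np.ndarray) -> float:
    """Bilinear pressure sample at a point (cell-centered field)."""
    g = state.grid
    from .grid import _bilinear
    return float(_bilinear(state.p, np.atleast_2d(point),
                           g.x0 + 0.5 * g.h, g.y0 + 0.5 * g.h, g.h)[0])


def _gate_points(gate, n=64, inset=0.02):
    a, b = gate.endpoints()
    t = np.linspace(inset, 1.0 - inset, n)[:, None]
    return a[None, :] * (1 - t) + b[None, :] * t


def gate_flux(state, gate, n=100) -> float:
    """Velocity flux through a gate cross-section (per unit depth).

    Trapezoid rule over the interior plus quadratic no-slip wall
    panels: within one grid cell of each wall the profile is taken as
    the parabola through the wall zero and the samples at h and 2h
    (matching the solver's sharp-interface wall closure), whose panel
    integral is h*(8*u(h) - u(2h))/12.
    """
    h = state.grid.h
    w = gate.width
    a, b = gate.endpoints()
    if w <= 4.0 * h:
        t = np.linspace(0.0, 1.0, n)[1:-1][:, None]
        pts = a[None, :] * (1 - t) + b[None, :] * t
        un = state.interp_velocity(pts) @ gate.tangent
        s = np.concatenate([[0.0], t[:, 0], [1.0]]) * w
        return float(np.trapezoid(np.concatenate([[0.0], un, [0.0]]), s))
    d = (b - a) / w                      # unit vector a -> b
    # sample at ~grid spacing (pointwise-accurate values) and integrate
    # with Simpson, which reconstructs the profile curvature that a
    # finely-integrated bilinear interpolant would miss
    m = max(int(np.ceil((w - 2 * h) / h)) | 1, 5)  # odd count
    s_in = np.linspace(h, w - h, m)
    pts = a[None, :] + s_in[:, None] * d[None, :]
    un = state.interp_velocity(pts) @ gate.tangent
    from scipy.integrate import simpson
    core = float(simpson(un, x=s_in))
    panels = 0.0
    for (p0, sgn) in ((a, +1.0), (b, -1.0)):
        u1 = float(state.interp_velocity((p0 + sgn * h * d)[None, :])[0]
                   @ gate.tangent)
        u2 = float(state.interp_velocity((p0 + sgn * 2 * h * d)[None, :])[0]
                   @ gate.tangent)
        panels += h * (8.0 * u1 - u2) / 12.0
    return core + panels


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class VesselRecord:
    """Hemodynamic summary of one vessel segment over one run."""

    segment_id: int
    diameter_um: float
    times_ms: np.ndarray
    H_t: np.ndarray
    H_mean: float
    H_cv: float | None          # std/mean of H(t); None if H_mean == 0
    Q_t: np.ndarray | None = None
    Q_times_ms: np.ndarray | None = None
    Q_mean: float | None = None
    Q_cv: float | None = None
    dp_pa: float | None = None
    resistance: float | None = None   # Pa / (um^2/ms), per unit depth
    mean_cell_length_um: float | None = None
    cfl_um: float | None = None

    def to_row(self) -> dict:
        return {
            "segment_id": self.segment_id, "d_um": self.diameter_um,
            "H_mean": self.H_mean, "H_cv": self.H_cv,
            "Q_mean": self.Q_mean, "Q_cv": self.Q_cv,
            "dp_pa": self.dp_pa, "R": self.resistance,
            "cell_length_um": self.mean_cell_length_um, "CFL_um": self.cfl_um,
        }


@dataclass
class VesselDelta:
    """Paired stiffer-vs-normal percentage changes for one segment."""

    segment_id: int
    dH_pct: float | None
    dQ_pct: float | None
    dR_pct: float | None

    def to_row(self) -> dict:
        return {"segment_id": self.segment_id, "dH_pct": self.dH_pct,
                "dQ_pct": self.dQ_pct, "dR_pct": self.dR_pct}


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def assign_cells_to_vessels(record: SimulationRecord,
                            graph: NetworkGraph) -> pd.DataFrame:
    """Per-snapshot cell-to-element map.

    Returns a DataFrame (t_ms, cell_id, element) where ``element`` is a
    positive segment id, or ``-junction_id`` for cells whose centroid
    lies within the junction blend disk (gate rule).
    """
    apices = [(j.id, np.asarray(j.apex), junction_blend_radius(graph, j.id))
              for j in graph.junctions.values()]
    cls = {s.id: LineString(s.centerline) for s in graph.segments.values()}
    rows = []
    for t, snap in zip(record.cell_times, record.cell_snapshots):
        for cid, X in snap.items():
            c = X.mean(axis=0)
            elem = 0
            for (jid, apex, r) in apices:
                if np.hypot(*(c - apex)) <= r:
                    elem = -jid
                    break
            if elem == 0:
                P = Point(c)
                best, bd = 0, np.inf
                for sid, cl in cls.items():
                    d = P.distance(cl)
                    if d < bd:
                        best, bd = sid, d
                elem = best
            rows.append((t, cid, elem))
    return pd.DataFrame(rows, columns=["t_ms", "cell_id", "element"])


def hematocrit_series(record: SimulationRecord, graph: NetworkGraph,
                      segment_id: int, warmup_ms: float = 0.0):
    """Tube hematocrit H(t) of a segment: clipped cell area inside the
    segment lumen polygon divided by the lumen area.

    Returns (times, H(t), H_mean, H_cv); H_cv is None for an empty
    vessel (mean zero).
    """
    lumen = segment_lumen_polygon(graph, segment_id)
    A = lumen.area
    times, H = [], []
    for t, snap in zip(record.cell_times, record.cell_snapshots):
        if t < warmup_ms:
            continue
        a = 0.0
        for X in snap.values():
            poly = Polygon(X)
            if not poly.is_valid:
                poly = poly.buffer(0)
            if poly.intersects(lumen):
                a += poly.intersection(lumen).area
        times.append(t)
        H.append(a / A)
    times = np.asarray(times)
    H = np.asarray(H)
    mean = float(H.mean()) if len(H) else 0.0
    cv = float(H.std() / mean) if mean > 0 else None
    return times, H, mean, cv


def flow_series(record: SimulationRecord, graph: NetworkGraph,
                segment_id: int, warmup_ms: float = 0.0):
    """Q(t) through the mid-gate, pressure drop between entry and exit
    gates, and the resistance R = dp / Q_mean.

    Returns (times, Q(t), Q_mean, Q_cv, dp, R)."""
    gates = graph.gates()
    gm = gates[f"seg{segment_id}:mid"]
    ge = gates[f"seg{segment_id}:entry"]
    gx = gates[f"seg{segment_id}:exit"]
    times, Q, dps = [], [], []
    for t, st in zip(record.field_times, record.field_snapshots):
        if t < warmup_ms:
            continue
        times.append(t)
        Q.append(gate_flux(st, gm))
        dps.append(np.mean([interp_pressure(st, p) for p in _gate_points(ge, 24)])
                   - np.mean([interp_pressure(st, p) for p in _gate_points(gx, 24)]))
    times = np.asarray(times)
    Q = np.asarray(Q)
    qmean = float(Q.mean()) if len(Q) else None
    qcv = float(Q.std() / abs(qmean)) if qmean else None
    dp = float(np.mean(dps)) if dps else None
    R = (dp / qmean) if (dp is not None and qmean) else None
    return times, Q, qmean, qcv, dp, R


def delta_metrics(normal: VesselRecord, stiffer: VesselRecord) -> VesselDelta:
    """Percentage changes (stiffer - normal)/normal * 100 for H, Q, R."""
    if normal.segment_id != stiffer.segment_id:
        raise ValueError("paired records must refer to the same segment")

    def pct(a, b):
        if a is None or b is None or a == 0:
            return None
        return (b - a) / a * 100.0

    return VesselDelta(normal.segment_id,
                       pct(normal.H_mean, stiffer.H_mean),
                       pct(normal.Q_mean, stiffer.Q_mean),
                       pct(normal.resistance, stiffer.resistance))


def spatial_cv(records: list[VesselRecord]) -> float:
    """Coefficient of variation of time-averaged H across vessels
    (population standard deviation over the mean)."""
    H = np.asarray([r.H_mean for r in records if r.H_mean is not None])
    if len(H) < 2:
        raise ValueError("need at least two vessels with defined H")
    m = H.mean()
    if m == 0:
        raise ValueError("all-zero hematocrits")
    return float(H.std() / m)


def cross_section_profile(record: SimulationRecord, graph: NetworkGraph,
                          segment_id: int, station: float | str = "mid",
                          n_bins: int = 20, warmup_ms: float = 0.0):
    """Time-averaged lateral hematocrit profile at a station.

    ``station`` is an arclength in um or one of 'entry'/'mid'/'exit'.
    Returns (bin_centers_um, occupancy, skewness, cfl_um).  The lateral
    axis points along the gate's left normal (rotate the flow direction
    by +90 degrees); skewness is the third standardized moment of the
    occupancy distribution, positive when cells crowd the positive side.
    The cell-free layer (CFL) is the time-averaged distance from each
    wall to the nearest cell boundary, averaged over both walls.
    """
    s = graph.segments[segment_id]
    if isinstance(station, str):
        gate = graph.gates()[f"seg{segment_id}:{station}"]
        point, tangent = gate.point, gate.tangent
    else:
        point, tangent = s.point_at(float(station)), s.tangent_at(float(station))
    nrm = np.array([-tangent[1], tangent[0]])
    r = s.radius
    edges = np.linspace(-r, r, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    probes = point[None, :] + centers[:, None] * nrm[None, :]
    occ = np.zeros(n_bins)
    cfl_samples = []
    wall_pts = [Point(point + r * nrm), Point(point - r * nrm)]
    n_t = 0
    for t, snap in zip(record.cell_times, record.cell_snapshots):
        if t < warmup_ms:
            continue
        n_t += 1
        polys = []
        for X in snap.values():
            poly = Polygon(X)
            if not poly.is_valid:
                poly = poly.buffer(0)
            polys.append(poly)
        if polys:
            union = shapely.unary_union(polys)
            inside = shapely.contains_xy(union, probes[:, 0], probes[:, 1])
            occ += inside
            near = [p for p in polys
                    if p.distance(Point(point)) < 3.0 * s.diameter]
            if near:
                u2 = shapely.unary_union(near)
                cfl_samples.append(np.mean([wp.distance(u2) for wp in wall_pts]))
            else:
                cfl_samples.append(2.0 * r)
        else:
            cfl_samples.append(2.0 * r)
    occ = occ / max(n_t, 1)
    w = occ.sum()
    if w > 0:
        mu = float((centers * occ).sum() / w)
        var = float(((centers - mu) ** 2 * occ).sum() / w)
        skew = (float(((centers - mu) ** 3 * occ).sum() / w) / var ** 1.5
                if var > 0 else 0.0)
    else:
        skew = 0.0
    cfl = float(np.mean(cfl_samples)) if cfl_samples else None
    return centers, occ, skew, cfl


def build_vessel_record(record: SimulationRecord, graph: NetworkGraph,
                        segment_id: int, warmup_ms: float = 0.0,
                        with_profile: bool = False) -> VesselRecord:
    """Assemble the full per-vessel summary for one segment."""
    from .membrane import cell_length
    s = graph.segments[segment_id]
    times, H, hmean, hcv = hematocrit_series(record, graph, segment_id, warmup_ms)
    qt, Q, qmean, qcv, dp, R = flow_series(record, graph, segment_id, warmup_ms)
    # mean cell length over cells assigned to this segment
    lumen = segment_lumen_polygon(graph, segment_id)
    lengths = []
    for t, snap in zip(record.cell_times, record.cell_snapshots):
        if t < warmup_ms:
            continue
        for X in snap.values():
            if shapely.contains_xy(lumen, *X.mean(axis=0)):
                lengths.append(cell_length(X))
    mcl = float(np.mean(lengths)) if lengths else None
    cfl = None
    if with_profile:
        _, _, _, cfl = cross_section_profile(record, graph, segment_id,
                                             "mid", warmup_ms=warmup_ms)
    return VesselRecord(segment_id, s.diameter, times, H, hmean, hcv,
                        Q_t=Q, Q_times_ms=qt, Q_mean=qmean, Q_cv=qcv,
                        dp_pa=dp, resistance=R, mean_cell_length_um=mcl,
                        cfl_um=cfl)


def vessel_table(records: list[VesselRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


def delta_table(deltas: list[VesselDelta]) -> pd.DataFrame:
    return pd.DataFrame([d.to_row() for d in deltas])
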