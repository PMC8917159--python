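"""Wall shear stress from time-averaged velocity fields.

The WSS is the axial component of the wall traction,
tau = mu * du_s/dr evaluated at the wall with the *plasma* viscosity
(the cell-free layer separates RBCs from the wall, so plasma fills the
near-wall region).  The normal derivative uses a one-sided quadratic
fit through the no-slip zero and two interior probe points.  Values
are reported in dyn/cm^2 (1 Pa = 10 dyn/cm^2 exactly).

Per-vessel averages are wall-length-weighted line averages (the 2D
counterpart of the surface average over the vascular area), and the
paired relative change Delta-tau = (tau_stiffer - tau_normal)/tau_normal
is mapped point-by-point with a localization tag (apex-proximal,
curved-outer-side, other) so focal changes near bifurcations and along
curved vessels can be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .grid import FluidState
from .networks import NetworkGraph, WallGeometry
from .solver import SimulationRecord
from .units import pa_to_dyn_cm2

__all__ = [
    "WSSField", "WSSDelta", "time_average_field", "wall_traction",
    "vessel_average_wss", "delta_tau",
]


@dataclass
class WSSField:
    """Time-averaged axial wall shear stress at wall sample points."""

    points: np.ndarray          # (n, 2) um
    normals: np.ndarray         # outward unit normals
    owners: np.ndarray          # segment id (>0) or -junction_id
    tau_dyn_cm2: np.ndarray     # signed axial WSS
    weights_um: np.ndarray      # wall-length measure per sample
    mu_plasma_pa_s: float
    flagged: np.ndarray         # samples lacking interior support

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.points[:, 0], "y": self.points[:, 1],
            "segment_id": self.owners, "tau_dyn_cm2": self.tau_dyn_cm2,
            "weight_um": self.weights_um, "flagged": self.flagged,
        })


@dataclass
class WSSDelta:
    """Pointwise relative WSS change between paired runs."""

    points: np.ndarray
    owners: np.ndarray
    tags: np.ndarray            # 'apex' | 'curved_outer' | 'other'
    delta_tau: np.ndarray       # relative change; nan where floored
    abs_diff_dyn_cm2: np.ndarray
    floored: np.ndarray         # where |tau_normal| was below the floor

    def summary_by_tag(self) -> pd.DataFrame:
        rows = []
        for tag in ("apex", "curved_outer", "other"):
            m = (self.tags == tag) & ~self.floored
            if m.any():
                rows.append({"tag": tag, "n": int(m.sum()),
                             "delta_tau_mean": float(np.nanmean(self.delta_tau[m])),
                             "delta_tau_min": float(np.nanmin(self.delta_tau[m])),
                             "delta_tau_max": float(np.nanmax(self.delta_tau[m]))})
        return pd.DataFrame(rows)


def time_average_field(record: SimulationRecord,
                       warmup_ms: float = 0.0) -> FluidState:
    """Arithmetic mean of the post-warmup field snapshots.

    Averaging is linear, so it commutes with the derivative stencils
    used downstream."""
    snaps = [st for t, st in zip(record.field_times, record.field_snapshots)
             if t >= warmup_ms]
    if len(snaps) < 1:
        raise ValueError("no post-warmup field snapshots")
    avg = snaps[0].copy()
    for name in ("u", "v", "p", "mu"):
        setattr(avg, name, np.mean([getattr(s, name) for s in snaps], axis=0))
    avg.time_ms = float(np.mean([s.time_ms for s in snaps]))
    return avg


def wall_traction(avg: FluidState, walls: WallGeometry,
                  mu_plasma_pa_s: float = 0.0012) -> WSSField:
    """Axial WSS at every wall sample of the discretized boundary.

    tau = mu_plasma * du_s/dr with the wall-tangential velocity u_s
    sampled at h, 2h and 3h along the inward normal; the derivative at
    the wall comes from the quadratic through the three interior
    samples, du/dr|0 = (-5 u1 + 8 u2 - 3 u3)/(2h) — exact for a
    parabolic profile and zero for a uniform (plug) field.  Wall points
    with fewer than three interior samples along the normal are flagged
    and set to NaN.
    """
    from .units import VISCOSITY_PA_S_TO_MODEL
    mu_model = mu_plasma_pa_s * VISCOSITY_PA_S_TO_MODEL
    h = avg.grid.h
    pts, nrm, own = walls.all_samples()
    n = len(pts)
    tau = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)
    tang = np.column_stack([-nrm[:, 1], nrm[:, 0]])   # wall tangent
    us = []
    good = np.ones(n, dtype=bool)
    for k in (1, 2, 3):
        pk = pts - k * h * nrm   # inward probes (normals point outward)
        good &= walls.contains(pk[:, 0], pk[:, 1])
        us.append(np.einsum("ij,ij->i", avg.interp_velocity(pk), tang))
    u1, u2, u3 = us
    tau_model = mu_model * (-5.0 * u1 + 8.0 * u2 - 3.0 * u3) / (2.0 * h)
    tau[good] = pa_to_dyn_cm2(tau_model[good])
    flagged[~good] = True
    # wall-length weight per sample (ring spacing)
    weights = np.full(n, walls.resolution)
    return WSSField(points=pts, normals=nrm, owners=own,
                    tau_dyn_cm2=tau, weights_um=weights,
                    mu_plasma_pa_s=mu_plasma_pa_s, flagged=flagged)


def vessel_average_wss(field: WSSField, segment_id: int,
                       magnitude: bool = True) -> float:
    """Wall-length-weighted average WSS over one segment's wall samples
    (the 2D counterpart of the vascular surface average)."""
    m = (field.owners == segment_id) & ~field.flagged \
        & np.isfinite(field.tau_dyn_cm2)
    if not m.any():
        raise ValueError(f"no wall samples owned by segment {segment_id}")
    tau = np.abs(field.tau_dyn_cm2[m]) if magnitude else field.tau_dyn_cm2[m]
    w = field.weights_um[m]
    return float((tau * w).sum() / w.sum())


def delta_tau(normal: WSSField, stiffer: WSSField, graph: NetworkGraph,
              floor_frac: float = 0.01,
              apex_radii: float = 2.0) -> WSSDelta:
    """Pointwise relative WSS change with localization tags.

    Points where |tau_normal| is below ``floor_frac`` times the network
    median are excluded from the relative change (the division blows
    up); the absolute difference is reported there instead.  Tags:
    'apex' within ``apex_radii`` feeder radii of a junction apex,
    'curved_outer' on the outer side of a curved centerline, else
    'other'.
    """
    if normal.points.shape != stiffer.points.shape or \
            not np.allclose(normal.points, stiffer.points):
        raise ValueError("paired WSS fields must share the wall sampling")
    tn = np.abs(normal.tau_dyn_cm2)
    ts = np.abs(stiffer.tau_dyn_cm2)
    med = np.nanmedian(tn)
    floored = ~np.isfinite(tn) | ~np.isfinite(ts) | (tn < floor_frac * med)
    dt = np.full(len(tn), np.nan)
    dt[~floored] = (ts[~floored] - tn[~floored]) / tn[~floored]
    absd = ts - tn

    tags = np.full(len(tn), "other", dtype=object)
    # apex-proximal
    for j in graph.junctions.values():
        r_feed = graph.segments[j.mother_ids[0]].radius
        d = np.hypot(*(normal.points - np.asarray(j.apex)).T)
        tags[d <= apex_radii * r_feed] = "apex"
    # curved outer side: sample on the convex (outer) side of its segment
    for s in graph.segments.values():
        if s.tortuosity < 1.001 and _max_curvature(s.centerline) < 1e-4:
            continue
        m = (normal.owners == s.id) & (tags == "other")
        if not m.any():
            continue
        cl = LineString(s.centerline)
        for k in np.flatnonzero(m):
            pt = Point(normal.points[k])
            sarc = cl.project(pt)
            kappa, side = _curvature_and_side(s.centerline, sarc, normal.points[k])
            if kappa > 1e-4 and side > 0:
                tags[k] = "curved_outer"
    return WSSDelta(points=normal.points, owners=normal.owners,
                    tags=np.asarray(tags), delta_tau=dt,
                    abs_diff_dyn_cm2=absd, floored=floored)


def _max_curvature(cl: np.ndarray) -> float:
    if len(cl) < 3:
        return 0.0
    d1 = np.gradient(cl, axis=0)
    d2 = np.gradient(d1, axis=0)
    num = np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(den > 0, num / den, 0.0)
    return float(np.nanmax(k))


def _curvature_and_side(cl: np.ndarray, s_arc: float, pt: np.ndarray):
    """Local signed curvature and which side of the centerline the wall
    point lies on (+1 = convex/outer side)."""
    seg = np.diff(cl, axis=0)
    ls = np.hypot(seg[:, 0], seg[:, 1])
    cs = np.concatenate([[0.0], np.cumsum(ls)])
    k = int(np.clip(np.searchsorted(cs[1:], s_arc), 1, len(cl) - 2))
    a, b, c = cl[k - 1], cl[k], cl[k + 1]
    v1, v2 = b - a, c - b
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    ang = np.arctan2(cross, v1 @ v2)
    ds = 0.5 * (np.hypot(*v1) + np.hypot(*v2))
    kappa = abs(ang) / max(ds, 1e-12)
    # outer side: opposite the turn direction
    to_pt = pt - b
    t = v1 + v2
    side_sign = np.sign(t[0] * to_pt[1] - t[1] * to_pt[0])  # +1 left of tangent
    turn_sign = np.sign(cross)                               # +1 turning left
    side = 1.0 if side_sign != 0 and side_sign == -turn_sign else -1.0
    return kappa, side
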