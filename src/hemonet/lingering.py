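"""Detection and quantification of RBC lingering at bifurcation apices.

A cell *lingers* when it straddles the apex of a bifurcation — where
the flow resembles a stagnation point — and resides there longer than
a freely flowing cell would.  Operationally, an event is recorded when
a cell's centroid stays within a distance ``d_th`` of the apex while
its speed drops below ``alpha`` times its own upstream mean speed for
at least ``T_th``; events are maximal (non-overlapping per cell and
junction).

Per bifurcation the lingering fraction gamma is the number of distinct
lingering cells over the number of distinct cells passing the mother
gate; the paired change is Delta-gamma = gamma_stiffer - gamma_normal.
Linkage tables pair Delta-gamma with the partitioning change Delta_NQ
and with Delta-H^HF and tally the four sign quadrants (with a dead
zone for near-zero changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import NetworkGraph

__all__ = [
    "LingerEvent", "LingerSummary", "LingerThresholds",
    "detect_lingering", "lingering_fraction", "linkage_tables",
    "default_thresholds",
]


@dataclass
class LingerThresholds:
    """Detection thresholds for one junction.

    ``d_th``: apex radius within which a cell can linger (um; default
    one feeder radius).  ``alpha``: speed factor relative to the cell's
    own upstream mean speed.  ``T_th``: minimum duration (ms; default
    5x the apex transit time of a centerline tracer, 2*d_th/u_feed).
    """

    d_th_um: float
    alpha: float = 0.5
    T_th_ms: float = 0.0


def default_thresholds(graph: NetworkGraph, junction_id: int,
                       feeder_speed_um_ms: float,
                       alpha: float = 0.5,
                       transit_multiple: float = 5.0) -> LingerThresholds:
    """Thresholds from the junction geometry and feeder speed:
    d_th = feeder radius; T_th = ``transit_multiple`` times the apex
    transit time 2*d_th/u of a tracer advected at the feeder speed."""
    j = graph.junctions[junction_id]
    r = graph.segments[j.mother_ids[0]].radius
    if feeder_speed_um_ms <= 0:
        raise ValueError("feeder speed must be positive")
    transit = 2.0 * r / feeder_speed_um_ms
    return LingerThresholds(d_th_um=r, alpha=alpha,
                            T_th_ms=transit_multiple * transit)


@dataclass
class LingerEvent:
    cell_id: int
    junction_id: int
    t_start_ms: float
    duration_ms: float
    branch_segment_id: int | None
    min_speed_um_ms: float

    def to_row(self) -> dict:
        return {"cell_id": self.cell_id, "junction_id": self.junction_id,
                "t_start_ms": self.t_start_ms, "duration_ms": self.duration_ms,
                "branch_id": self.branch_segment_id,
                "min_speed_um_ms": self.min_speed_um_ms}


@dataclass
class LingerSummary:
    junction_id: int
    gamma: float
    n_linger_cells: int
    n_passing_cells: int
    events: list = field(default_factory=list)


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def detect_lingering(trajectories: pd.DataFrame, graph: NetworkGraph,
                     junction_id: int, thresholds: LingerThresholds,
                     events: pd.DataFrame | None = None):
    """Find lingering events of all cells at one junction.

    ``trajectories``: DataFrame (cell_id, t_ms, x, y) sampled at the
    shape-output cadence.  ``events`` (optional gate-event log) is used
    to attribute the branch each lingering cell eventually entered.
    Returns (events_list, gap_report): trajectory gaps longer than
    ``T_th`` inside the apex region are reported per cell, never
    silently bridged.
    """
    j = graph.junctions[junction_id]
    apex = np.asarray(j.apex)
    d_th = thresholds.d_th_um
    T_th = thresholds.T_th_ms
    out: list[LingerEvent] = []
    gaps: list[dict] = []
    for cid, tr in trajectories.groupby("cell_id"):
        tr = tr.sort_values("t_ms")
        t = tr["t_ms"].to_numpy()
        xy = tr[["x", "y"]].to_numpy()
        if len(t) < 3:
            continue
        dt = np.diff(t)
        speed = np.hypot(*(np.diff(xy, axis=0).T)) / np.maximum(dt, 1e-12)
        speed = np.concatenate([[speed[0]], speed])       # per-sample speed
        dist = np.hypot(*(xy - apex).T)
        near = dist <= d_th
        if not near.any():
            continue
        # upstream mean speed: samples in the 3-feeder-radii approach band
        r_feed = graph.segments[j.mother_ids[0]].radius
        first_near = int(np.argmax(near))
        approach = (dist > d_th) & (dist <= d_th + 3.0 * r_feed)
        approach[first_near:] = False
        u_up = speed[approach].mean() if approach.any() else speed[:first_near].mean() \
            if first_near > 0 else np.nan
        if not np.isfinite(u_up) or u_up <= 0:
            continue
        # trajectory gaps inside the apex region
        big = (dt > T_th) & near[:-1]
        for k in np.flatnonzero(big):
            gaps.append({"cell_id": int(cid), "t_ms": float(t[k]),
                         "gap_ms": float(dt[k])})
        slow = near & (speed < thresholds.alpha * u_up)
        # maximal runs of consecutive slow samples
        k = 0
        n = len(slow)
        while k < n:
            if not slow[k]:
                k += 1
                continue
            k1 = k
            while k1 + 1 < n and slow[k1 + 1]:
                k1 += 1
            dur = float(t[k1] - t[k]) + float(np.median(dt))
            if dur >= T_th:
                branch = _branch_entered(events, cid, j, float(t[k1]))
                out.append(LingerEvent(int(cid), junction_id, float(t[k]),
                                       dur, branch,
                                       float(speed[k:k1 + 1].min())))
            k = k1 + 1
    return out, gaps


def _branch_entered(events, cid, j, t_after):
    if events is None or not len(events):
        return None
    for d in j.daughter_ids:
        e = events[(events["cell_id"] == cid)
                   & (events["gate_id"] == f"seg{d}:entry")
                   & (events["time_ms"] >= t_after - 1e-9)]
        if len(e):
            return int(d)
    return None


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def lingering_fraction(events_list: list[LingerEvent],
                       gate_events: pd.DataFrame, graph: NetworkGraph,
                       junction_id: int) -> LingerSummary:
    """gamma = distinct lingering cells / distinct mother-gate-crossing
    cells at this junction."""
    j = graph.junctions[junction_id]
    mother_gate = f"seg{j.mother_ids[0]}:exit"
    passing = gate_events[(gate_events["gate_id"] == mother_gate)
                          & (gate_events["direction"] > 0)]["cell_id"].nunique()
    lingers = {e.cell_id for e in events_list if e.junction_id == junction_id}
    gamma = len(lingers) / passing if passing > 0 else 0.0
    return LingerSummary(junction_id, float(gamma), len(lingers), int(passing),
                         [e for e in events_list
                          if e.junction_id == junction_id])


def linkage_tables(deltas: pd.DataFrame, dead_zone: float = 0.02):
    """Quadrant tallies of (Delta-gamma, Delta_NQ) and (Delta-gamma,
    Delta-H^HF) sign combinations.

    ``deltas`` needs columns junction_id, delta_gamma, delta_NQ and
    (optionally) delta_H_HF.  Values within ``dead_zone`` of zero
    count as 'zero'.  Returns (pairs, tallies) where tallies maps e.g.
    'dgamma<0,dNQ>0' to a count.
    """
    def sign(x):
        if x is None or (isinstance(x, float) and not np.isfinite(x)):
            return "na"
        if x > dead_zone:
            return ">0"
        if x < -dead_zone:
            return "<0"
        return "0"

    pairs = deltas.copy()
    tallies: dict[str, int] = {}
    for _, row in deltas.iterrows():
        key = f"dgamma{sign(row['delta_gamma'])},dNQ{sign(row['delta_NQ'])}"
        tallies[key] = tallies.get(key, 0) + 1
        if "delta_H_HF" in row and row["delta_H_HF"] is not None:
            key2 = f"dgamma{sign(row['delta_gamma'])},dHHF{sign(row['delta_H_HF'])}"
            tallies[key2] = tallies.get(key2, 0) + 1
    return pairs, tallies
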