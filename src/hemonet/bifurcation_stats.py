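"""RBC partitioning statistics at bifurcations.

For each bifurcation the flow-rate ratio Q* and RBC number-flux ratio
N* of a designated daughter are computed in non-overlapping time
windows (default 0.1 s at model scale).  Their relation classifies the
partitioning: *regular* when the higher-flow daughter receives a
disproportionately higher cell fraction (N* > Q*, the Zweifach-Fung
effect), *reverse* when it receives less.  Derived quantities follow:

* f — fraction of valid windows with reverse partitioning (N* < Q*);
* sigma_NQ = sqrt( sum[(N*(t)-N*)^2 + (Q*(t)-Q*)^2] / M ) — scatter of
  the windowed partitioning around its time average;
* Delta_NQ = (N*-Q*)_stiffer - (N*-Q*)_normal — change in partitioning
  disproportionality between paired runs;
* Delta-H^HF = H^HF_stiffer - H^HF_normal — absolute hematocrit change
  in the higher-flow daughter (designated from the normal run).

Cell counting is by net gate crossings of the cell centroid (a cell
re-crossing a gate backwards decrements the count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import Junction, NetworkGraph

__all__ = [
    "BifurcationRecord", "BifurcationDelta", "WindowedPartitioning",
    "flux_ratios", "classify_partitioning", "delta_NQ", "reverse_fraction",
    "sigma_NQ", "higher_flow_hematocrit", "build_bifurcation_record",
    "DEFAULT_WINDOW_MS", "PROPORTIONALITY_TOL",
]

DEFAULT_WINDOW_MS = 100.0      # 0.1 s partitioning windows
PROPORTIONALITY_TOL = 0.02     # |N*-Q*| dead zone for 'proportionate'


@dataclass
class WindowedPartitioning:
    """Windowed Q*(t), N*(t) series for one daughter of one junction."""

    windows: pd.DataFrame        # t_start_ms, t_end_ms, Qstar, Nstar, valid
    Qstar_mean: float | None
    Nstar_mean: float | None

    @property
    def valid(self) -> pd.DataFrame:
        return self.windows[self.windows["valid"]]


@dataclass
class BifurcationRecord:
    """Partitioning summary of one junction over one run."""

    junction_id: int
    feeder_diameter_um: float
    daughter_segment_id: int     # the designated daughter for Q*, N*
    Qstar: float | None
    Nstar: float | None
    classification: str | None
    f_reverse: float | None
    sigma: float | None
    n_windows: int
    H_HF: float | None = None    # mean hematocrit of the higher-flow daughter

    def to_row(self) -> dict:
        return {"junction_id": self.junction_id,
                "D_feed_um": self.feeder_diameter_um,
                "daughter": self.daughter_segment_id,
                "Qstar": self.Qstar, "Nstar": self.Nstar,
                "class": self.classification, "f": self.f_reverse,
                "sigma_NQ": self.sigma, "M": self.n_windows,
                "H_HF": self.H_HF}


@dataclass
class BifurcationDelta:
    """Paired stiffer-vs-normal partitioning changes for one junction."""

    junction_id: int
    delta_NQ: float | None
    delta_f: float | None
    delta_H_HF: float | None

    def to_row(self) -> dict:
        return {"junction_id": self.junction_id, "delta_NQ": self.delta_NQ,
                "delta_f": self.delta_f, "delta_H_HF": self.delta_H_HF}


# --------------------------------------------------------------------------
# windowed ratios
# --------------------------------------------------------------------------

def _net_crossings(events: pd.DataFrame, gate_id: str, t0: float,
                   t1: float) -> int:
    e = events[(events["gate_id"] == gate_id) & (events["time_ms"] >= t0)
               & (events["time_ms"] < t1)]
    return int(e["direction"].sum())


def _window_flux(times: np.ndarray, values: np.ndarray, t0: float,
                 t1: float) -> float:
    """Mean of a sampled series over [t0, t1) (nan if unsampled)."""
    m = (times >= t0) & (times < t1)
    if not m.any():
        return np.nan
    return float(np.mean(values[m]))


def flux_ratios(events: pd.DataFrame, mother_gate: str, daughter_gate: str,
                q_mother: tuple[np.ndarray, np.ndarray],
                q_daughter: tuple[np.ndarray, np.ndarray],
                window_ms: float = DEFAULT_WINDOW_MS,
                t_start: float = 0.0,
                t_end: float | None = None) -> WindowedPartitioning:
    """Windowed flow-ratio Q*(t) and cell-flux ratio N*(t).

    ``q_mother`` / ``q_daughter`` are (times, Q) sampled series.  Per
    window: Q* = mean(Q_daughter)/mean(Q_mother); N* = (net daughter
    crossings)/(net mother crossings).  Windows with zero mother
    crossings are marked invalid (excluded from f and sigma) rather
    than propagating NaNs.  Time averages are over valid windows.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    tm, qm = q_mother
    td, qd = q_daughter
    if t_end is None:
        t_end = max(tm.max() if len(tm) else 0.0,
                    events["time_ms"].max() if len(events) else 0.0)
    rows = []
    t0 = t_start
    while t0 < t_end - 1e-9:
        t1 = min(t0 + window_ms, t_end)
        nm = _net_crossings(events, mother_gate, t0, t1)
        nd = _net_crossings(events, daughter_gate, t0, t1)
        Qm = _window_flux(tm, qm, t0, t1)
        Qd = _window_flux(td, qd, t0, t1)
        qstar = Qd / Qm if (np.isfinite(Qm) and Qm != 0) else np.nan
        valid = nm > 0 and np.isfinite(qstar)
        nstar = nd / nm if nm > 0 else np.nan
        rows.append((t0, t1, qstar, nstar, valid))
        t0 = t1
    df = pd.DataFrame(rows, columns=["t_start_ms", "t_end_ms", "Qstar",
                                     "Nstar", "valid"])
    ok = df[df["valid"]]
    return WindowedPartitioning(
        df,
        float(ok["Qstar"].mean()) if len(ok) else None,
        float(ok["Nstar"].mean()) if len(ok) else None)


def classify_partitioning(nstar: float, qstar: float,
                          tol: float = PROPORTIONALITY_TOL) -> str:
    """'regular' if N* - Q* > tol, 'reverse' if < -tol, else
    'proportionate'; evaluated for the higher-flow daughter."""
    d = nstar - qstar
    if d > tol:
        return "regular"
    if d < -tol:
        return "reverse"
    return "proportionate"


def delta_NQ(normal: BifurcationRecord, stiffer: BifurcationRecord) -> float:
    """(N*-Q*)_stiffer - (N*-Q*)_normal for the matched daughter."""
    if normal.junction_id != stiffer.junction_id:
        raise ValueError("paired records must refer to the same junction")
    if None in (normal.Nstar, normal.Qstar, stiffer.Nstar, stiffer.Qstar):
        raise ValueError("undefined partitioning ratios")
    return (stiffer.Nstar - stiffer.Qstar) - (normal.Nstar - normal.Qstar)


def reverse_fraction(win: WindowedPartitioning) -> float:
    """Fraction of valid windows lying below the N* = Q* line."""
    ok = win.valid
    if not len(ok):
        raise ValueError("no valid windows")
    return float((ok["Nstar"] < ok["Qstar"]).sum() / len(ok))


def sigma_NQ(win: WindowedPartitioning) -> float:
    """sqrt( sum[(N*(t)-N*)^2 + (Q*(t)-Q*)^2] / M ) over valid windows."""
    ok = win.valid
    M = len(ok)
    if M < 2:
        raise ValueError("need at least two valid windows")
    dn = ok["Nstar"].to_numpy() - win.Nstar_mean
    dq = ok["Qstar"].to_numpy() - win.Qstar_mean
    return float(np.sqrt((dn ** 2 + dq ** 2).sum() / M))


def higher_flow_hematocrit(normal_H: dict[int, float],
                           stiffer_H: dict[int, float],
                           normal_rec: BifurcationRecord,
                           graph: NetworkGraph,
                           junction_id: int):
    """H^HF and Delta-H^HF for a junction.

    The higher-flow daughter is fixed from the NORMAL run's
    time-averaged Q* (so the comparison stays aligned even if the flow
    split flips in the stiffer run); the change is the absolute
    hematocrit difference in that daughter.
    """
    j = graph.junctions[junction_id]
    if normal_rec.Qstar is None:
        raise ValueError("undefined Q* in the normal run")
    d1 = normal_rec.daughter_segment_id
    others = [d for d in j.daughter_ids if d != d1]
    hf = d1 if normal_rec.Qstar >= 0.5 else others[0]
    h_n = normal_H.get(hf)
    h_s = stiffer_H.get(hf)
    if h_n is None or h_s is None:
        return None, None
    return float(h_n), float(h_s - h_n)


def build_bifurcation_record(events: pd.DataFrame, graph: NetworkGraph,
                             junction_id: int,
                             flows: dict[int, tuple[np.ndarray, np.ndarray]],
                             window_ms: float = DEFAULT_WINDOW_MS,
                             t_start: float = 0.0,
                             t_end: float | None = None,
                             daughter: int | None = None,
                             H_by_segment: dict[int, float] | None = None):
    """Assemble the partitioning summary of one bifurcation.

    ``flows`` maps segment ids to sampled (times, Q) series; the
    designated daughter defaults to the one with the higher mean flow.
    Mother crossings are counted at the mother's exit gate, daughter
    crossings at the daughter's entry gate.
    """
    j = graph.junctions[junction_id]
    if j.kind != "bifurcation":
        raise ValueError(f"junction {junction_id} is not a bifurcation")
    mother = j.mother_ids[0]
    d1, d2 = j.daughter_ids
    if daughter is None:
        q1 = np.mean(flows[d1][1]) if len(flows[d1][1]) else 0.0
        q2 = np.mean(flows[d2][1]) if len(flows[d2][1]) else 0.0
        daughter = d1 if q1 >= q2 else d2
    win = flux_ratios(events, f"seg{mother}:exit", f"seg{daughter}:entry",
                      flows[mother], flows[daughter], window_ms,
                      t_start, t_end)
    ok = win.valid
    rec = BifurcationRecord(
        junction_id=junction_id,
        feeder_diameter_um=graph.segments[mother].diameter,
        daughter_segment_id=daughter,
        Qstar=win.Qstar_mean, Nstar=win.Nstar_mean,
        classification=(classify_partitioning(win.Nstar_mean, win.Qstar_mean)
                        if win.Nstar_mean is not None else None),
        f_reverse=(reverse_fraction(win) if len(ok) else None),
        sigma=(sigma_NQ(win) if len(ok) >= 2 else None),
        n_windows=len(ok))
    if H_by_segment is not None and rec.Qstar is not None:
        hf = daughter if rec.Qstar >= 0.5 else \
            [d for d in j.daughter_ids if d != daughter][0]
        rec.H_HF = H_by_segment.get(hf)
    return rec, win
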