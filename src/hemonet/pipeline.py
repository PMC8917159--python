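"""Paired normal-vs-stiffer experiment orchestration.

The central experiment of the package: run the same network geometry,
boundary conditions, seeds and cadences twice — once with normal cells
(G_s = 5e-6 N/m) and once with stiffer cells (10x by default, all
other properties identical) — then compute every per-vessel,
per-bifurcation, lingering and wall-shear-stress statistic and their
paired changes, and write a comparison report.

``analyze_only`` runs the identical analysis stages on stored records
(or solver-free synthetic event streams), decoupling analysis from
simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import bifurcation_stats as bs
from . import lingering as lg
from . import vessel_stats as vs
from . import wss as ws
from .membrane import MembraneParams
from .networks import NetworkGraph, NetworkSpec, build_fixture, generate_network
from .solver import FlowDomain, SimConfig, SimulationRecord, run_simulation

__all__ = ["ExperimentConfig", "ComparisonReport", "run_paired_experiment",
           "analyze_only", "load_experiment_config"]


@dataclass
class ExperimentConfig:
    """Configuration of one paired experiment.

    The paired runs differ ONLY in the membrane shear modulus (the
    stiffer run multiplies it by ``stiffness_multiplier``); geometry,
    boundary conditions, seeds and cadences are shared.  ``time_scale``
    multiplies every physical cadence/duration (field 5 ms, shapes
    0.5 ms, windows 100 ms, warmup, duration) for quick desk-scale
    runs.
    """

    network: str = "y_bifurcation"          # fixture name | 'generated' | path.json
    network_params: dict = field(default_factory=dict)
    generations: int = 3                     # for 'generated'
    stiffness_multiplier: float = 10.0
    G_s_normal: float = 5.0e-6               # N/m
    target_hematocrit: float = 0.30
    seed: int = 0
    duration_ms: float = 200.0
    warmup_ms: float = 50.0
    window_ms: float = 100.0
    points_per_cell: float = 10.0
    time_scale: float = 1.0
    seed_inlet: bool = True
    out_dir: str = "results"

    def build_graph(self) -> NetworkGraph:
        if self.network == "generated":
            return generate_network(NetworkSpec(generations=self.generations,
                                                seed=self.seed))
        if self.network.endswith(".json"):
            return NetworkGraph.from_json(Path(self.network).read_text())
        return build_fixture(self.network, **self.network_params)

    def sim_config(self, stiff: bool) -> SimConfig:
        mult = self.stiffness_multiplier if stiff else 1.0
        mem = MembraneParams(G_s=self.G_s_normal * mult)
        ts = self.time_scale
        return SimConfig(
            duration_ms=self.duration_ms * ts,
            field_output_every_ms=5.0 * ts,
            shape_output_every_ms=0.5 * ts,
            warmup_ms=self.warmup_ms * ts,
            target_hematocrit=self.target_hematocrit,
            seed=self.seed,
            points_per_cell=self.points_per_cell,
            membrane=mem,
            seed_inlet=self.seed_inlet,
        )


@dataclass
class ComparisonReport:
    """All tables of a paired comparison."""

    vessels: pd.DataFrame            # per segment, both runs + deltas
    bifurcations: pd.DataFrame       # per junction, both runs + deltas
    wss_by_vessel: pd.DataFrame
    linkage_tallies: dict
    meta: dict

    def save(self, out_dir: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.vessels.to_csv(out / "vessels.csv", index=False)
        self.bifurcations.to_csv(out / "bifurcations.csv", index=False)
        self.wss_by_vessel.to_csv(out / "wss.csv", index=False)
        (out / "summary.json").write_text(json.dumps(
            {"meta": self.meta, "linkage_tallies": self.linkage_tallies},
            indent=1, default=str))

    def summary_text(self) -> str:
        lines = [f"paired comparison: {self.meta.get('network')}",
                 f"vessels: {len(self.vessels)}  "
                 f"bifurcations: {len(self.bifurcations)}"]
        v = self.vessels
        if "dH_pct" in v and v["dH_pct"].notna().any():
            lines.append(f"dH range: {v['dH_pct'].min():+.1f}% .. "
                         f"{v['dH_pct'].max():+.1f}%")
        if "dR_pct" in v and v["dR_pct"].notna().any():
            lines.append(f"dR range: {v['dR_pct'].min():+.1f}% .. "
                         f"{v['dR_pct'].max():+.1f}%")
        b = self.bifurcations
        if "delta_NQ" in b and b["delta_NQ"].notna().any():
            pos = (b["delta_NQ"] > bs.PROPORTIONALITY_TOL).mean()
            lines.append(f"delta_NQ > 0 at {pos:.0%} of bifurcations")
        return "\n".join(lines)


def _flows_by_segment(record: SimulationRecord, graph: NetworkGraph,
                      warmup_ms: float):
    flows = {}
    for sid in graph.segments:
        t, Q, *_ = vs.flow_series(record, graph, sid, warmup_ms)
        flows[sid] = (t, Q)
    return flows


def _analyze_run(record: SimulationRecord, graph: NetworkGraph,
                 warmup_ms: float, window_ms: float):
    """Per-run statistics: vessel records, bifurcation records, WSS."""
    vrecs = {sid: vs.build_vessel_record(record, graph, sid, warmup_ms)
             for sid in graph.segments}
    flows = {sid: (r.Q_times_ms, r.Q_t) for sid, r in vrecs.items()}
    H_by_seg = {sid: r.H_mean for sid, r in vrecs.items()}
    brecs, wins = {}, {}
    for jid, j in graph.junctions.items():
        if j.kind != "bifurcation":
            continue
        rec_j, win = bs.build_bifurcation_record(
            record.events, graph, jid, flows, window_ms, t_start=warmup_ms,
            t_end=max(record.cell_times) if record.cell_times else None,
            H_by_segment=H_by_seg)
        brecs[jid] = rec_j
        wins[jid] = win
    # lingering
    traj = record.trajectories()
    linger = {}
    for jid, j in graph.junctions.items():
        if j.kind != "bifurcation":
            continue
        mother = j.mother_ids[0]
        u_feed = None
        vr = vrecs[mother]
        if vr.Q_mean:
            u_feed = abs(vr.Q_mean) / graph.segments[mother].diameter
        if not u_feed:
            continue
        th = lg.default_thresholds(graph, jid, u_feed)
        evs, _gaps = lg.detect_lingering(traj, graph, jid, th, record.events)
        linger[jid] = lg.lingering_fraction(evs, record.events, graph, jid)
    # WSS
    wfield = None
    try:
        avg = ws.time_average_field(record, warmup_ms)
        from .networks import discretize_walls
        # reuse the record's graph geometry for the wall sampling
        walls = discretize_walls(
            graph, min(s.diameter for s in graph.segments.values()) / 4.0)
        wfield = ws.wall_traction(avg, walls)
    except (ValueError, Exception):
        wfield = None
    return vrecs, brecs, wins, linger, wfield


def _compare(graph, norm, stiff, warmup_ms):
    vrecs_n, brecs_n, _w_n, ling_n, wss_n = norm
    vrecs_s, brecs_s, _w_s, ling_s, wss_s = stiff

    vrows = []
    for sid in graph.segments:
        rn, rs = vrecs_n[sid], vrecs_s[sid]
        d = vs.delta_metrics(rn, rs)
        row = {**rn.to_row()}
        row.update({f"{k}_stiffer": v for k, v in rs.to_row().items()
                    if k not in ("segment_id", "d_um")})
        row.update(d.to_row())
        vrows.append(row)
    vessels = pd.DataFrame(vrows)

    brows = []
    H_n = {sid: vrecs_n[sid].H_mean for sid in graph.segments}
    H_s = {sid: vrecs_s[sid].H_mean for sid in graph.segments}
    for jid in brecs_n:
        rn, rs = brecs_n[jid], brecs_s.get(jid)
        row = rn.to_row()
        if rs is not None and None not in (rn.Nstar, rn.Qstar, rs.Nstar,
                                           rs.Qstar):
            row["delta_NQ"] = bs.delta_NQ(rn, rs)
            row["delta_f"] = (rs.f_reverse - rn.f_reverse
                              if None not in (rn.f_reverse, rs.f_reverse)
                              else None)
            _hf, dhf = bs.higher_flow_hematocrit(H_n, H_s, rn, graph, jid)
            row["delta_H_HF"] = dhf
        g_n = ling_n.get(jid)
        g_s = ling_s.get(jid)
        row["gamma_normal"] = g_n.gamma if g_n else None
        row["gamma_stiffer"] = g_s.gamma if g_s else None
        row["delta_gamma"] = (g_s.gamma - g_n.gamma
                              if g_n and g_s else None)
        brows.append(row)
    bifs = pd.DataFrame(brows)

    wrows = []
    if wss_n is not None and wss_s is not None:
        for sid in graph.segments:
            try:
                tn = ws.vessel_average_wss(wss_n, sid)
                ts_ = ws.vessel_average_wss(wss_s, sid)
                wrows.append({"segment_id": sid, "tau_normal_dyn_cm2": tn,
                              "tau_stiffer_dyn_cm2": ts_,
                              "delta_tau_pct": (ts_ - tn) / tn * 100.0
                              if tn else None})
            except ValueError:
                continue
    wss_tab = pd.DataFrame(wrows)

    tallies = {}
    if len(bifs) and "delta_NQ" in bifs and "delta_gamma" in bifs:
        sub = bifs[["junction_id", "delta_gamma", "delta_NQ"]
                   + (["delta_H_HF"] if "delta_H_HF" in bifs else [])].dropna(
            subset=["delta_gamma", "delta_NQ"])
        if len(sub):
            _, tallies = lg.linkage_tables(sub)
    return vessels, bifs, wss_tab, tallies


def run_paired_experiment(config: ExperimentConfig, progress: bool = False):
    """Run the normal and stiffer simulations on identical geometry and
    seeds, analyze both, and build the comparison report."""
    graph = config.build_graph()
    cfg_n = config.sim_config(stiff=False)
    cfg_s = config.sim_config(stiff=True)
    domain = FlowDomain(graph, cfg_n.h)
    rec_n = run_simulation(graph, None, cfg_n, domain=domain, progress=progress)
    rec_s = run_simulation(graph, None, cfg_s, domain=domain, progress=progress)
    n_n = rec_n.diagnostics.get("final_cell_count", 0)
    n_s = rec_s.diagnostics.get("final_cell_count", 0)
    if max(n_n, n_s) > 0 and abs(n_n - n_s) / max(n_n, n_s, 1) > 0.05:
        rec_n.diagnostics["cell_count_mismatch"] = True
    report = analyze_only(rec_n, rec_s, config)
    return rec_n, rec_s, report


def analyze_only(rec_normal: SimulationRecord, rec_stiffer: SimulationRecord,
                 config: ExperimentConfig) -> ComparisonReport:
    """Build the comparison report from two stored records (identical to
    the inline path given the same records)."""
    graph = rec_normal.graph()
    w = config.warmup_ms * config.time_scale
    win = config.window_ms * config.time_scale
    norm = _analyze_run(rec_normal, graph, w, win)
    stiff = _analyze_run(rec_stiffer, graph, w, win)
    vessels, bifs, wss_tab, tallies = _compare(graph, norm, stiff, w)
    meta = {"network": graph.name, "seed": config.seed,
            "stiffness_multiplier": config.stiffness_multiplier,
            "warmup_ms": w, "window_ms": win,
            "config": asdict(config)}
    return ComparisonReport(vessels, bifs, wss_tab, tallies, meta)


def load_experiment_config(path: str) -> ExperimentConfig:
    """Read an experiment config from TOML or YAML (by extension)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    if p.suffix in (".toml", ".tml"):
        import tomllib
        doc = tomllib.loads(p.read_text())
    else:
        import yaml
        doc = yaml.safe_load(p.read_text())
    known = {f.name for f in ExperimentConfig.__dataclass_fields__.values()}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**doc)
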