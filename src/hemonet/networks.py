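"""Synthetic capillary network geometries and ground-truthed test streams.

Capillary beds are modelled as planar graphs of winding vessel segments
joined at bifurcations (one mother, two daughters) and mergers (two
mothers, one daughter).  Vessel diameters are restricted to the
physiological capillary/arteriole range 5.5-24 um.  All coordinates are
in um, times in ms.

Besides geometry, this module generates ground-truthed synthetic inputs
for the analysis stages: gate-event streams with prescribed routing
probabilities and planted lingering episodes, and closed-form velocity
fields sampled on the staggered grid.  These let every downstream
statistic be validated without running the flow solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .grid import StaggeredGrid, FluidState
from .units import VISCOSITY_PA_S_TO_MODEL

DIAMETER_RANGE_UM = (5.5, 24.0)

__all__ = [
    "Node", "Segment", "Junction", "BoundaryCondition", "Gate",
    "NetworkGraph", "WallGeometry", "SyntheticEventSpec", "NetworkSpec",
    "build_fixture", "generate_network", "discretize_walls",
    "synthesize_event_stream", "synthesize_velocity_field",
    "NetworkError", "DIAMETER_RANGE_UM",
]


class NetworkError(ValueError):
    """Invalid network specification or geometry."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Node:
    id: int
    position: tuple[float, float]
    role: str  # 'inlet' | 'outlet' | 'junction'


@dataclass
class Segment:
    """A vessel segment with a polyline centerline, oriented tail -> head."""

    id: int
    tail: int
    head: int
    centerline: np.ndarray  # (n, 2) um
    diameter: float  # um
    generation: int = -1    # depth in the bifurcating half (generator only)

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def arclength(self) -> float:
        d = np.diff(self.centerline, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def chord(self) -> float:
        return float(np.hypot(*(self.centerline[-1] - self.centerline[0])))

    @property
    def tortuosity(self) -> float:
        c = self.chord
        return self.arclength / c if c > 0 else 1.0

    def point_at(self, s: float) -> np.ndarray:
        """Point at arclength ``s`` from the tail."""
        return self._interp(s)[0]

    def tangent_at(self, s: float) -> np.ndarray:
        return self._interp(s)[1]

    def _interp(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        pts = self.centerline
        seg = np.diff(pts, axis=0)
        ls = np.hypot(seg[:, 0], seg[:, 1])
        cs = np.concatenate([[0.0], np.cumsum(ls)])
        s = float(np.clip(s, 0.0, cs[-1]))
        k = int(np.searchsorted(cs[1:], s, side="left"))
        k = min(k, len(ls) - 1)
        t = seg[k] / ls[k]
        return pts[k] + (s - cs[k]) * t, t


@dataclass
class Junction:
    id: int
    kind: str  # 'bifurcation' | 'merger'
    mother_ids: list[int]
    daughter_ids: list[int]
    apex: tuple[float, float]
    node_id: int


@dataclass
class BoundaryCondition:
    """Pressure (mmHg or Pa) or per-depth flow rate (um^2/ms) at a port."""

    node_id: int
    kind: str  # 'pressure' | 'flow_rate'
    value: float
    units: str = "Pa"  # 'mmHg' | 'Pa' | 'um2/ms'

    def value_model(self) -> float:
        from .units import mmhg_to_pa
        if self.kind == "pressure":
            if self.units == "mmHg":
                return mmhg_to_pa(self.value)
            if self.units == "Pa":
                return self.value
            raise NetworkError(f"bad pressure units {self.units!r}")
        if self.units == "um2/ms":
            return self.value
        raise NetworkError(f"bad flow-rate units {self.units!r}")


@dataclass
class Gate:
    """A measurement cross-section: a point on a centerline plus flow direction."""

    gate_id: str
    segment_id: int
    kind: str  # 'entry' | 'mid' | 'exit'
    point: np.ndarray
    tangent: np.ndarray  # unit, along nominal flow direction (tail->head)
    width: float

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        n = np.array([-self.tangent[1], self.tangent[0]])
        return self.point - 0.5 * self.width * n, self.point + 0.5 * self.width * n


@dataclass
class NetworkGraph:
    """Planar vessel network: segments, junctions, ports with BCs."""

    nodes: dict[int, Node]
    segments: dict[int, Segment]
    junctions: dict[int, Junction]
    boundary_conditions: list[BoundaryCondition]
    name: str = "network"
    units: str = "um"

    # -- validation --------------------------------------------------------
    def validate(self, diameter_range=DIAMETER_RANGE_UM, enforce_diameters=True) -> None:
        lo, hi = diameter_range
        for s in self.segments.values():
            if enforce_diameters and not (lo - 1e-9 <= s.diameter <= hi + 1e-9):
                raise NetworkError(
                    f"segment {s.id}: diameter {s.diameter} um outside [{lo}, {hi}]")
            if s.arclength < s.chord - 1e-9:
                raise NetworkError(f"segment {s.id}: arclength < chord")
        for j in self.junctions.values():
            nm, nd = len(j.mother_ids), len(j.daughter_ids)
            if j.kind == "bifurcation" and (nm, nd) != (1, 2):
                raise NetworkError(f"junction {j.id}: bifurcation needs 1 mother, 2 daughters")
            if j.kind == "merger" and (nm, nd) != (2, 1):
                raise NetworkError(f"junction {j.id}: merger needs 2 mothers, 1 daughter")
        g = self.to_networkx()
        if g.number_of_nodes() and not nx.is_connected(g.to_undirected()):
            raise NetworkError("network graph is not connected")
        ports = {bc.node_id for bc in self.boundary_conditions}
        inlets = {n.id for n in self.nodes.values() if n.role == "inlet"}
        outlets = {n.id for n in self.nodes.values() if n.role == "outlet"}
        if not (ports & inlets) or not (ports & outlets):
            raise NetworkError("need boundary conditions on at least one inlet and one outlet")

    # -- queries -----------------------------------------------------------
    def inlet_segments(self) -> list[Segment]:
        inlets = {n.id for n in self.nodes.values() if n.role == "inlet"}
        return [s for s in self.segments.values() if s.tail in inlets]

    def outlet_segments(self) -> list[Segment]:
        outlets = {n.id for n in self.nodes.values() if n.role == "outlet"}
        return [s for s in self.segments.values() if s.head in outlets]

    def junction_of_node(self, node_id: int) -> Junction | None:
        for j in self.junctions.values():
            if j.node_id == node_id:
                return j
        return None

    def _blend_radius_at(self, node_id: int) -> float:
        """Junction blend disk radius at a node (0 if not a junction)."""
        j = self.junction_of_node(node_id)
        if j is None:
            return 0.0
        return max(self.segments[i].radius
                   for i in list(j.mother_ids) + list(j.daughter_ids))

    def gates(self) -> dict[str, Gate]:
        """Entry/mid/exit gate per segment.

        The entry gate sits one local radius downstream of the junction
        blend at the upstream node (so cells inside the blend cavity
        are not attributed to any segment); the exit gate symmetric at
        the downstream end; the mid gate at half arclength.
        """
        out: dict[str, Gate] = {}
        for s in self.segments.values():
            L = s.arclength
            r = s.radius
            off_in = self._blend_radius_at(s.tail) + r
            off_out = self._blend_radius_at(s.head) + r
            stations = {
                "entry": min(off_in, 0.4 * L),
                "mid": 0.5 * L,
                "exit": max(L - off_out, 0.6 * L),
            }
            for kind, sv in stations.items():
                p, t = s._interp(sv)
                gid = f"seg{s.id}:{kind}"
                out[gid] = Gate(gid, s.id, kind, p, t, s.diameter)
        return out

    def bounding_box(self, margin: float = 0.0) -> tuple[float, float, float, float]:
        pts = np.vstack([s.centerline for s in self.segments.values()])
        r = max(s.radius for s in self.segments.values())
        return (pts[:, 0].min() - r - margin, pts[:, 1].min() - r - margin,
                pts[:, 0].max() + r + margin, pts[:, 1].max() + r + margin)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "schema": "hemonet/network/1",
            "name": self.name,
            "units": {"length": "um", "pressure": "mmHg|Pa", "flow_rate": "um2/ms"},
            "nodes": [
                {"id": n.id, "position": list(n.position), "role": n.role}
                for n in self.nodes.values()
            ],
            "segments": [
                {"id": s.id, "tail": s.tail, "head": s.head,
                 "centerline": np.asarray(s.centerline).tolist(),
                 "diameter_um": s.diameter}
                for s in self.segments.values()
            ],
            "junctions": [
                {"id": j.id, "kind": j.kind, "mother_ids": j.mother_ids,
                 "daughter_ids": j.daughter_ids, "apex": list(j.apex),
                 "node_id": j.node_id}
                for j in self.junctions.values()
            ],
            "boundary_conditions": [
                {"node_id": b.node_id, "kind": b.kind, "value": b.value, "units": b.units}
                for b in self.boundary_conditions
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkGraph":
        doc = json.loads(text)
        nodes = {d["id"]: Node(d["id"], tuple(d["position"]), d["role"])
                 for d in doc["nodes"]}
        segments = {d["id"]: Segment(d["id"], d["tail"], d["head"],
                                     np.asarray(d["centerline"], dtype=float),
                                     float(d["diameter_um"]))
                    for d in doc["segments"]}
        junctions = {d["id"]: Junction(d["id"], d["kind"], list(d["mother_ids"]),
                                       list(d["daughter_ids"]), tuple(d["apex"]),
                                       d["node_id"])
                     for d in doc["junctions"]}
        bcs = [BoundaryCondition(d["node_id"], d["kind"], d["value"], d["units"])
               for d in doc["boundary_conditions"]]
        return cls(nodes, segments, junctions, bcs, name=doc.get("name", "network"))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, role=n.role, x=n.position[0], y=n.position[1])
        for s in self.segments.values():
            g.add_edge(s.tail, s.head, segment_id=s.id, diameter_um=s.diameter,
                       arclength_um=s.arclength)
        return g

    def to_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass
class WallGeometry:
    """Discretized lumen boundary with outward normals and ownership map."""

    polygon: Polygon
    rings: list[np.ndarray]            # closed polylines, each (n, 2), first != last
    normals: list[np.ndarray]          # outward unit normals per ring sample
    owners: list[np.ndarray]           # per sample: segment id, or -(junction id + 1)
    resolution: float

    def contains(self, x, y) -> np.ndarray:
        """Vectorized lumen-interior test."""
        return shapely.contains_xy(self.polygon, np.asarray(x, dtype=float),
                                   np.asarray(y, dtype=float))

    def all_samples(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenated (points, normals, owners) over all rings."""
        return (np.vstack(self.rings), np.vstack(self.normals),
                np.concatenate(self.owners))

    def total_length(self) -> float:
        return self.polygon.exterior.length + sum(r.length for r in self.polygon.interiors)

    def to_json(self) -> str:
        return json.dumps({
            "schema": "hemonet/walls/1",
            "units": {"length": "um"},
            "resolution_um": self.resolution,
            "rings": [r.tolist() for r in self.rings],
            "normals": [n.tolist() for n in self.normals],
            "owners": [o.tolist() for o in self.owners],
        })


@dataclass
class SyntheticEventSpec:
    """Ground truth for a solver-free bifurcation event stream."""

    junction_id: int = 1
    q_star_true: float = 0.5          # flow fraction of daughter 1
    p_route: float = 0.5              # probability a cell routes to daughter 1
    n_cells: int = 1000
    arrival_rate_per_ms: float = 0.05
    transit_time_ms: float = 10.0     # apex-free mother-gate -> daughter-gate time
    linger_episodes: tuple = ()       # iterable of (cell_id, duration_ms)
    q_mother: float = 10.0            # um^2/ms, mother flow rate
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_route <= 1.0 and 0.0 <= self.q_star_true <= 1.0):
            raise NetworkError("probabilities must lie in [0, 1]")
        for cid, dur in self.linger_episodes:
            if dur <= 0:
                raise NetworkError(f"lingering duration must be > 0 (cell {cid})")
        if self.n_cells < 0 or self.arrival_rate_per_ms <= 0:
            raise NetworkError("need n_cells >= 0 and a positive arrival rate")


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

_FIXTURES = ("straight_channel", "curved_channel", "y_bifurcation",
             "side_branch", "two_generation_net")


def _polyline(p0, p1, n=2) -> np.ndarray:
    t = np.linspace(0.0, 1.0, max(n, 2))[:, None]
    return np.asarray(p0) * (1 - t) + np.asarray(p1) * t


def _check_diameter(d: float) -> float:
    lo, hi = DIAMETER_RANGE_UM
    if not (lo <= d <= hi):
        raise NetworkError(f"diameter {d} um outside physiological range [{lo}, {hi}]")
    return float(d)


def build_fixture(name: str, **params) -> NetworkGraph:
    """Build one of the canonical test geometries.

    Fixtures: ``straight_channel`` (single segment), ``curved_channel``
    (constant-curvature arc), ``y_bifurcation`` (one bifurcation with
    controllable daughter diameters/angles), ``side_branch`` (a large
    feeder with a small side daughter) and ``two_generation_net``
    (two generations of bifurcations plus one merger).
    """
    if name == "straight_channel":
        g = _straight_channel(**params)
    elif name == "curved_channel":
        g = _curved_channel(**params)
    elif name == "y_bifurcation":
        g = _y_bifurcation(**params)
    elif name == "side_branch":
        g = _side_branch(**params)
    elif name == "two_generation_net":
        g = _two_generation_net(**params)
    else:
        raise NetworkError(f"unknown fixture {name!r}; choose from {_FIXTURES}")
    g.validate()
    return g


def _default_pressure_bcs(inlet_node, outlet_nodes, dp_pa):
    bcs = [BoundaryCondition(inlet_node, "pressure", float(dp_pa), "Pa")]
    for n in outlet_nodes:
        bcs.append(BoundaryCondition(n, "pressure", 0.0, "Pa"))
    return bcs


def _straight_channel(diameter: float = 12.0, length: float = 100.0,
                      dp_pa: float | None = None) -> NetworkGraph:
    d = _check_diameter(diameter)
    # default pressure drop drives ~1.5 um/ms mean speed in pure plasma
    mu = 0.0012 * VISCOSITY_PA_S_TO_MODEL
    dp = dp_pa if dp_pa is not None else 12.0 * mu * length * 1.5 / d ** 2
    nodes = {1: Node(1, (0.0, 0.0), "inlet"), 2: Node(2, (length, 0.0), "outlet")}
    segs = {1: Segment(1, 1, 2, _polyline((0, 0), (length, 0)), d)}
    return NetworkGraph(nodes, segs, {}, _default_pressure_bcs(1, [2], dp),
                        name="straight_channel")


def _curved_channel(diameter: float = 12.0, radius_of_curvature: float = 60.0,
                    arc_degrees: float = 120.0, dp_pa: float | None = None,
                    n_points: int = 64) -> NetworkGraph:
    d = _check_diameter(diameter)
    R = float(radius_of_curvature)
    if R <= d:
        raise NetworkError("radius of curvature must exceed the diameter")
    half = np.radians(arc_degrees) / 2.0
    th = np.linspace(-half, half, n_points)
    # arc opening upward, endpoints level
    pts = np.column_stack([R * np.sin(th), R * (1.0 - np.cos(th))])
    length = R * 2 * half
    mu = 0.0012 * VISCOSITY_PA_S_TO_MODEL
    dp = dp_pa if dp_pa is not None else 12.0 * mu * length * 1.5 / d ** 2
    nodes = {1: Node(1, tuple(pts[0]), "inlet"), 2: Node(2, tuple(pts[-1]), "outlet")}
    segs = {1: Segment(1, 1, 2, pts, d)}
    return NetworkGraph(nodes, segs, {}, _default_pressure_bcs(1, [2], dp),
                        name="curved_channel")


def _y_bifurcation(feeder_diameter: float = 12.0,
                   daughter_diameters: tuple[float, float] = (9.0, 9.0),
                   angles_deg: tuple[float, float] = (28.0, -28.0),
                   feeder_length: float = 50.0,
                   daughter_length: float = 50.0,
                   dp_pa: tuple[float, float] | None = None,
                   straighten_outlets: bool = False) -> NetworkGraph:
    df = _check_diameter(feeder_diameter)
    d1, d2 = (_check_diameter(x) for x in daughter_diameters)
    a1, a2 = np.radians(angles_deg)
    apex = np.array([feeder_length, 0.0])
    if straighten_outlets:
        # daughters leave at the given angles, then bend back to the
        # horizontal so the outlets open axially (flow-rate BC capable)
        mid1 = apex + 0.55 * daughter_length * np.array([np.cos(a1), np.sin(a1)])
        mid2 = apex + 0.55 * daughter_length * np.array([np.cos(a2), np.sin(a2)])
        e1 = mid1 + np.array([0.45 * daughter_length, 0.0])
        e2 = mid2 + np.array([0.45 * daughter_length, 0.0])
        cl1 = np.vstack([apex, mid1, e1])
        cl2 = np.vstack([apex, mid2, e2])
    else:
        e1 = apex + daughter_length * np.array([np.cos(a1), np.sin(a1)])
        e2 = apex + daughter_length * np.array([np.cos(a2), np.sin(a2)])
        cl1 = _polyline(apex, e1)
        cl2 = _polyline(apex, e2)
    nodes = {
        1: Node(1, (0.0, 0.0), "inlet"),
        2: Node(2, tuple(apex), "junction"),
        3: Node(3, tuple(e1), "outlet"),
        4: Node(4, tuple(e2), "outlet"),
    }
    segs = {
        1: Segment(1, 1, 2, _polyline((0, 0), apex), df),
        2: Segment(2, 2, 3, cl1, d1),
        3: Segment(3, 2, 4, cl2, d2),
    }
    juncs = {1: Junction(1, "bifurcation", [1], [2, 3], tuple(apex), 2)}
    mu = 0.0012 * VISCOSITY_PA_S_TO_MODEL
    dp_in = 12.0 * mu * (feeder_length + daughter_length) * 1.5 / df ** 2
    if dp_pa is None:
        bcs = _default_pressure_bcs(1, [3, 4], dp_in)
    else:
        bcs = [BoundaryCondition(1, "pressure", dp_in, "Pa"),
               BoundaryCondition(3, "pressure", float(dp_pa[0]), "Pa"),
               BoundaryCondition(4, "pressure", float(dp_pa[1]), "Pa")]
    return NetworkGraph(nodes, segs, juncs, bcs, name="y_bifurcation")


def _side_branch(feeder_diameter: float = 17.5, branch_diameter: float = 6.0,
                 branch_angle_deg: float = 75.0, feeder_length: float = 120.0,
                 branch_length: float = 40.0) -> NetworkGraph:
    df = _check_diameter(feeder_diameter)
    db = _check_diameter(branch_diameter)
    apex = np.array([0.5 * feeder_length, 0.0])
    a = np.radians(branch_angle_deg)
    eb = apex + branch_length * np.array([np.cos(a), np.sin(a)])
    nodes = {
        1: Node(1, (0.0, 0.0), "inlet"),
        2: Node(2, tuple(apex), "junction"),
        3: Node(3, (feeder_length, 0.0), "outlet"),
        4: Node(4, tuple(eb), "outlet"),
    }
    segs = {
        1: Segment(1, 1, 2, _polyline((0, 0), apex), df),
        2: Segment(2, 2, 3, _polyline(apex, (feeder_length, 0.0)), df),
        3: Segment(3, 2, 4, _polyline(apex, eb), db),
    }
    juncs = {1: Junction(1, "bifurcation", [1], [2, 3], tuple(apex), 2)}
    mu = 0.0012 * VISCOSITY_PA_S_TO_MODEL
    dp = 12.0 * mu * feeder_length * 2.0 / df ** 2
    return NetworkGraph(nodes, segs, juncs, _default_pressure_bcs(1, [3, 4], dp),
                        name="side_branch")


def _two_generation_net(inlet_diameter: float = 16.0) -> NetworkGraph:
    """Two generations of bifurcations plus one merger, two outlets.

    inlet -> bif A -> (bif B, pass-through C); B -> (outlet D, E);
    C -> E; merger at E -> outlet F.
    """
    d0 = _check_diameter(inlet_diameter)
    d1 = float(np.clip(0.80 * d0, *DIAMETER_RANGE_UM))
    d2 = float(np.clip(0.80 * d1, *DIAMETER_RANGE_UM))
    dm = float(np.clip(1.1 * d1, *DIAMETER_RANGE_UM))
    p = {1: (0.0, 0.0), 2: (45.0, 0.0), 3: (85.0, 30.0), 4: (85.0, -30.0),
         5: (130.0, 60.0), 6: (130.0, -5.0), 7: (175.0, -5.0)}
    nodes = {
        1: Node(1, p[1], "inlet"), 2: Node(2, p[2], "junction"),
        3: Node(3, p[3], "junction"), 4: Node(4, p[4], "junction"),
        5: Node(5, p[5], "outlet"), 6: Node(6, p[6], "junction"),
        7: Node(7, p[7], "outlet"),
    }
    segs = {
        1: Segment(1, 1, 2, _polyline(p[1], p[2]), d0),
        2: Segment(2, 2, 3, _polyline(p[2], p[3]), d1),
        3: Segment(3, 2, 4, _polyline(p[2], p[4]), d1),
        4: Segment(4, 3, 5, _polyline(p[3], p[5]), d2),
        5: Segment(5, 3, 6, _polyline(p[3], p[6]), d2),
        6: Segment(6, 4, 6, _polyline(p[4], p[6]), d1),
        7: Segment(7, 6, 7, _polyline(p[6], p[7]), dm),
    }
    juncs = {
        1: Junction(1, "bifurcation", [1], [2, 3], p[2], 2),
        2: Junction(2, "bifurcation", [2], [4, 5], p[3], 3),
        3: Junction(3, "merger", [5, 6], [7], p[6], 6),
    }
    mu = 0.0012 * VISCOSITY_PA_S_TO_MODEL
    dp = 12.0 * mu * 220.0 * 2.0 / d0 ** 2
    bcs = _default_pressure_bcs(1, [5, 7], dp)
    return NetworkGraph(nodes, segs, juncs, bcs, name="two_generation_net")


# --------------------------------------------------------------------------
# random network generator
# --------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Parameters for the random planar network generator.

    Defaults give a Horton-like tapering tree of bifurcations that
    reconverges through mergers to a single outlet, with sinusoidally
    winding centerlines.  Diameters are clipped to the physiological
    5.5-24 um range.
    """

    generations: int = 3
    inlet_diameter: float = 17.5
    taper_mean: float = 0.82          # daughter/mother diameter ratio
    taper_jitter: float = 0.06
    segment_length_mean: float = 60.0
    segment_length_jitter: float = 0.15
    branch_angle_deg: float = 30.0
    angle_jitter_deg: float = 8.0
    tortuosity_amplitude: float = 0.06   # sine amplitude / segment length
    seed: int = 0

    def validate(self) -> None:
        if self.generations < 1:
            raise NetworkError("need at least one generation")
        lo, hi = DIAMETER_RANGE_UM
        if not (lo <= self.inlet_diameter <= hi):
            raise NetworkError("inlet diameter outside physiological range")
        if not (0 < self.taper_mean <= 1.0):
            raise NetworkError("taper ratio must be in (0, 1]")


def _wind(p0: np.ndarray, p1: np.ndarray, amp_frac: float, phase: float,
          n: int = 24) -> np.ndarray:
    """Sinusoidally perturbed straight centerline (endpoints fixed)."""
    t = np.linspace(0.0, 1.0, n)
    base = p0[None, :] * (1 - t[:, None]) + p1[None, :] * t[:, None]
    d = p1 - p0
    L = np.hypot(*d)
    nrm = np.array([-d[1], d[0]]) / max(L, 1e-12)
    off = amp_frac * L * np.sin(np.pi * t) * np.sin(2 * np.pi * t + phase)
    return base + off[:, None] * nrm[None, :]


def generate_network(spec: NetworkSpec) -> NetworkGraph:
    """Generate a random planar network: a Horton-tapering tree of
    bifurcations that reconverges through pairwise mergers to a single
    outlet.  Same seed => identical graph.  Each expansion segment carries a
    ``generation`` index (0 for the inlet segment)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = DIAMETER_RANGE_UM

    nodes: dict[int, Node] = {}
    segs: dict[int, Segment] = {}
    juncs: dict[int, Junction] = {}
    counter = {"node": 0, "seg": 0, "junc": 0}

    def add_node(pos, role):
        counter["node"] += 1
        nid = counter["node"]
        nodes[nid] = Node(nid, (float(pos[0]), float(pos[1])), role)
        return nid

    def jitter_len():
        return spec.segment_length_mean * (
            1.0 + rng.uniform(-spec.segment_length_jitter, spec.segment_length_jitter))

    def add_seg(tail, head, d, gen=-1):
        counter["seg"] += 1
        sid = counter["seg"]
        p0 = np.asarray(nodes[tail].position)
        p1 = np.asarray(nodes[head].position)
        amp = spec.tortuosity_amplitude * rng.uniform(0.5, 1.0)
        segs[sid] = Segment(sid, tail, head,
                            _wind(p0, p1, amp, rng.uniform(0, 2 * np.pi)),
                            float(d), generation=gen)
        return sid

    def add_junction(kind, mothers, daughters, node_id):
        counter["junc"] += 1
        juncs[counter["junc"]] = Junction(counter["junc"], kind, mothers, daughters,
                                          nodes[node_id].position, node_id)

    G = spec.generations
    inlet = add_node((0.0, 0.0), "inlet")
    root_end = add_node((jitter_len(), 0.0), "junction")
    s_root = add_seg(inlet, root_end, spec.inlet_diameter, gen=0)

    # expanding half: G generations of bifurcations
    frontier = [(root_end, s_root, spec.inlet_diameter, 0.0)]
    for g in range(1, G + 1):
        new_frontier = []
        spread = 2.0 ** (G - g) * 0.45 * spec.segment_length_mean
        for (nid, sid, d, y) in frontier:
            x = nodes[nid].position[0]
            daughters = []
            for sgn in (+1, -1):
                ratio = float(np.clip(
                    spec.taper_mean + rng.uniform(-spec.taper_jitter,
                                                  spec.taper_jitter), 0.05, 1.0))
                dc = float(np.clip(d * ratio, lo, hi))
                cn = add_node((x + jitter_len(), y + sgn * spread), "junction")
                cs = add_seg(nid, cn, dc, gen=g)
                daughters.append(cs)
                new_frontier.append((cn, cs, dc, y + sgn * spread))
            add_junction("bifurcation", [sid], daughters, nid)
        frontier = new_frontier

    # contracting half: pairwise mergers back to one outlet
    while len(frontier) > 1:
        new_frontier = []
        last_level = len(frontier) == 2
        for k in range(0, len(frontier), 2):
            (n1, _s1, d1, y1), (n2, _s2, d2, y2) = frontier[k], frontier[k + 1]
            x = max(nodes[n1].position[0], nodes[n2].position[0])
            ym = 0.5 * (y1 + y2)
            mn = add_node((x + jitter_len(), ym), "junction")
            sa = add_seg(n1, mn, d1)
            sb = add_seg(n2, mn, d2)
            dm = float(np.clip(max(d1, d2) / max(spec.taper_mean, 0.05), lo, hi))
            on = add_node((nodes[mn].position[0] + jitter_len(), ym),
                          "outlet" if last_level else "junction")
            so = add_seg(mn, on, dm)
            add_junction("merger", [sa, sb], [so], mn)
            new_frontier.append((on, so, dm, ym))
        frontier = new_frontier

    mu = 0.0012 * VISCOSITY_PA_S_TO_MODEL
    total_x = max(n.position[0] for n in nodes.values())
    dp = 12.0 * mu * total_x * 1.5 / spec.inlet_diameter ** 2
    outlets = [n.id for n in nodes.values() if n.role == "outlet"]
    net = NetworkGraph(nodes, segs, juncs, _default_pressure_bcs(inlet, outlets, dp),
                       name=f"generated_g{spec.generations}_s{spec.seed}")
    _check_planarity(net)
    net.validate()
    return net


def _check_planarity(g: NetworkGraph) -> None:
    """Reject generated networks whose non-adjacent segments overlap."""
    items = list(g.segments.values())
    for i, a in enumerate(items):
        la = LineString(a.centerline)
        for b in items[i + 1:]:
            if {a.tail, a.head} & {b.tail, b.head}:
                continue
            if la.distance(LineString(b.centerline)) < a.radius + b.radius:
                raise NetworkError(
                    f"infeasible spec: segments {a.id} and {b.id} self-intersect")


# --------------------------------------------------------------------------
# wall discretization
# --------------------------------------------------------------------------

def discretize_walls(graph: NetworkGraph, resolution: float) -> WallGeometry:
    """Closed lumen boundary polylines with outward normals.

    The lumen is the union of constant-width strips swept along each
    centerline plus blending disks at junction nodes (giving the smooth
    junction fillets).  Port ends are cut flat.  ``resolution`` is the
    wall sample spacing in um and must not exceed the smallest
    diameter / 4.
    """
    dmin = min(s.diameter for s in graph.segments.values())
    if not (0 < resolution <= dmin / 4.0 + 1e-12):
        raise NetworkError(
            f"resolution must be in (0, {dmin / 4.0:.3g}] um (smallest diameter/4)")

    parts = []
    for s in graph.segments.values():
        parts.append(LineString(s.centerline).buffer(
            s.radius, cap_style="flat", join_style="round", quad_segs=32))
    blend_r: dict[int, float] = {}
    for j in graph.junctions.values():
        r = max(graph.segments[i].radius
                for i in list(j.mother_ids) + list(j.daughter_ids))
        blend_r[j.id] = r
        parts.append(Point(j.apex).buffer(r, quad_segs=32))
    # interior graph nodes that are not junction records (pass-through) also
    # need a blending disk so the lumen is watertight there
    junction_nodes = {j.node_id for j in graph.junctions.values()}
    for n in graph.nodes.values():
        if n.role == "junction" and n.id not in junction_nodes:
            r = max(s.radius for s in graph.segments.values()
                    if n.id in (s.tail, s.head))
            parts.append(Point(n.position).buffer(r, quad_segs=32))

    poly = unary_union(parts)
    if poly.geom_type == "MultiPolygon":
        raise NetworkError("wall blend produced a disconnected lumen; "
                           "check junction placement")
    poly = shapely.simplify(poly, resolution / 50.0)

    rings, normals, owners = [], [], []
    ring_geoms = [poly.exterior] + list(poly.interiors)
    centerlines = {s.id: LineString(s.centerline) for s in graph.segments.values()}
    for ring in ring_geoms:
        L = ring.length
        n = max(int(np.ceil(L / resolution)), 8)
        sv = np.linspace(0.0, L, n, endpoint=False)
        pts = np.array([ring.interpolate(t).coords[0] for t in sv])
        # tangent by central difference along the closed ring, normal = rot -90
        nxt = np.roll(pts, -1, axis=0)
        prv = np.roll(pts, 1, axis=0)
        tang = nxt - prv
        tang /= np.maximum(np.hypot(tang[:, 0], tang[:, 1]), 1e-12)[:, None]
        nrm = np.column_stack([tang[:, 1], -tang[:, 0]])
        # orient outward: probe a short step; flip rows that point inward
        probe = pts + nrm * (0.25 * resolution)
        inside = shapely.contains_xy(poly, probe[:, 0], probe[:, 1])
        nrm[inside] *= -1.0

        own = np.empty(len(pts), dtype=int)
        for k, pt in enumerate(pts):
            P = Point(pt)
            jid_owner = 0
            for j in graph.junctions.values():
                if P.distance(Point(j.apex)) <= blend_r[j.id] + 0.35 * resolution:
                    jid_owner = -(j.id + 0)  # junction region, encoded negative
                    break
            if jid_owner:
                own[k] = -(abs(jid_owner))
            else:
                best, bestd = 0, np.inf
                for sid, cl in centerlines.items():
                    dd = P.distance(cl)
                    if dd < bestd:
                        best, bestd = sid, dd
                own[k] = best
        rings.append(pts)
        normals.append(nrm)
        owners.append(own)

    wg = WallGeometry(polygon=poly, rings=rings, normals=normals, owners=owners,
                      resolution=float(resolution))
    # containment sanity: all centerline vertices must be inside the lumen
    # (port endpoints sit exactly on the flat caps, hence the tolerance)
    probe = shapely.buffer(poly, 1e-6)
    for s in graph.segments.values():
        ok = shapely.contains_xy(probe, s.centerline[:, 0], s.centerline[:, 1])
        if not ok.all():
            raise NetworkError(f"segment {s.id}: centerline escapes the lumen")
    return wg


# --------------------------------------------------------------------------
# synthetic event streams
# --------------------------------------------------------------------------

def synthesize_event_stream(spec: SyntheticEventSpec):
    """Emit gate events, trajectories and the ground-truth record.

    Returns ``(events, trajectories, truth)`` where ``events`` is a
    DataFrame (cell_id, gate_id, time_ms, direction), ``trajectories``
    a DataFrame (cell_id, t_ms, x, y) of straight-line cell paths
    through an idealized bifurcation at the origin (with planted apex
    stalls), and ``truth`` a dict with the planted routing probability,
    flow split and lingering episodes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    jid = spec.junction_id
    linger = dict(spec.linger_episodes)

    gaps = rng.exponential(1.0 / spec.arrival_rate_per_ms, size=spec.n_cells)
    t_mother = np.cumsum(gaps)
    route = rng.random(spec.n_cells) < spec.p_route  # True -> daughter 1

    # idealized geometry: mother gate at (-L, 0), apex at origin,
    # daughter gates at distance L along +-35 degrees
    L = 20.0
    ang = np.radians(35.0)
    d1_dir = np.array([np.cos(ang), np.sin(ang)])
    d2_dir = np.array([np.cos(ang), -np.sin(ang)])
    speed = 2 * L / spec.transit_time_ms  # um/ms over mother-gate->daughter-gate
    dt_samp = min(0.5, spec.transit_time_ms / 20.0)

    ev_rows, tr_rows = [], []
    episodes_truth = []
    for c in range(spec.n_cells):
        t0 = float(t_mother[c])
        stall = float(linger.get(c, 0.0))
        ddir = d1_dir if route[c] else d2_dir
        dgate = "d1" if route[c] else "d2"
        t_apex = t0 + L / speed
        t_exit = t_apex + stall + L / speed
        ev_rows.append((c, f"J{jid}:mother", t0, 1))
        ev_rows.append((c, f"J{jid}:{dgate}", t_exit, 1))
        if stall > 0:
            episodes_truth.append({"cell_id": c, "junction_id": jid,
                                   "t_start_ms": t_apex, "duration_ms": stall,
                                   "branch": dgate})
        # trajectory: mother approach, optional stall at apex, daughter exit
        ts = np.arange(t0, t_exit + dt_samp * 0.5, dt_samp)
        xy = np.empty((len(ts), 2))
        for k, t in enumerate(ts):
            if t < t_apex:
                xy[k] = np.array([-L, 0.0]) + (t - t0) * speed * np.array([1.0, 0.0])
            elif t < t_apex + stall:
                xy[k] = (0.0, 0.0)
            else:
                xy[k] = (t - t_apex - stall) * speed * ddir
        tr_rows.append(pd.DataFrame({"cell_id": c, "t_ms": ts,
                                     "x": xy[:, 0], "y": xy[:, 1]}))

    events = pd.DataFrame(ev_rows, columns=["cell_id", "gate_id", "time_ms",
                                            "direction"]).sort_values("time_ms",
                                                                      ignore_index=True)
    trajectories = (pd.concat(tr_rows, ignore_index=True) if tr_rows
                    else pd.DataFrame(columns=["cell_id", "t_ms", "x", "y"]))
    truth = {
        "junction_id": jid,
        "p_route": spec.p_route,
        "q_star_true": spec.q_star_true,
        "q_mother": spec.q_mother,
        "n_cells": spec.n_cells,
        "n_to_d1": int(route.sum()),
        "gamma_true": (len(episodes_truth) / spec.n_cells) if spec.n_cells else 0.0,
        "episodes": episodes_truth,
        "apex": (0.0, 0.0),
        "transit_time_ms": spec.transit_time_ms,
        "free_speed": speed,
    }
    return events, trajectories, truth


# --------------------------------------------------------------------------
# synthetic velocity fields
# --------------------------------------------------------------------------

def synthesize_velocity_field(profile: str, graph: NetworkGraph, *,
                              flow_rate: float = 18.0, skew: float = 0.0,
                              resolution: int = 16,
                              mu_plasma_pa_s: float = 0.0012) -> FluidState:
    """Closed-form channel flow sampled on the staggered grid.

    Only meaningful on the ``straight_channel`` fixture (axis-aligned).
    ``flow_rate`` is the per-depth flux in um^2/ms.  Profiles:

    - ``parabolic``: plane Poiseuille, centerline speed 3Q/(2w)
    - ``constant``: plug flow Q/w
    - ``skewed``: Poiseuille times (1 + skew*xi), renormalized to Q
    """
    if profile not in ("parabolic", "constant", "skewed"):
        raise NetworkError(f"unknown profile {profile!r}")
    seg = graph.segments[min(graph.segments)]
    if abs(seg.centerline[0][1] - seg.centerline[-1][1]) > 1e-9:
        raise NetworkError("synthesize_velocity_field requires an axis-aligned channel")
    w = seg.diameter
    Lx = seg.arclength
    h = w / resolution
    nx = int(round(Lx / h))
    g = StaggeredGrid(x0=float(seg.centerline[0][0]), y0=-w / 2.0, nx=nx,
                      ny=resolution, h=h)
    st = FluidState.zeros(g, mu_plasma_pa_s * VISCOSITY_PA_S_TO_MODEL)
    _, yu = g.u_coords()
    xi = yu / (w / 2.0)  # in (-1, 1) at u nodes
    U = flow_rate / w
    if profile == "constant":
        st.u[:] = U
    else:
        s = 0.0 if profile == "parabolic" else float(skew)
        prof = 1.5 * U * (1.0 - xi ** 2) * (1.0 + s * xi)
        # renormalize so the discrete flux matches flow_rate exactly
        q = prof[0].sum() * h
        st.u[:] = prof * (flow_rate / q)
    return st
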