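"""Red-blood-cell membrane geometry and elastic mechanics.

A resting RBC is a biconcave discocyte (Evans-Fung parameterization)
with a 7.8 um end-to-end distance.  The membrane resists shear and area
dilation through the Skalak strain-energy law and bending through the
Helfrich curvature energy with zero spontaneous curvature.

Two discretizations are provided:

* a closed triangulated surface (icosahedral subdivision; 20*4^n
  triangles) with a linear-triangle membrane FEM for the Skalak law and
  a cotangent-Laplacian discretization of the Helfrich energy — used
  for static validation of the 3D mechanics;
* a closed planar contour with an equivalent strain-hardening tension
  law T(lambda) = G_s (lambda - lambda^-3) and the 2D bending energy
  (kappa/2) * integral k^2 ds — the cell model advected by the 2D flow
  core.  The contour law is an analog of the 3D Skalak law, chosen to
  reproduce its strain-hardening character, not a literal reduction.

All forces are exact negative gradients of the discrete energies, so
the net force and net torque vanish identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .units import (BENDING_MODULUS_J_TO_MODEL, SHEAR_MODULUS_N_PER_M_TO_MODEL,
                    VISCOSITY_PA_S_TO_MODEL)

__all__ = [
    "MembraneParams", "MembraneMesh", "MembraneForces",
    "make_biconcave", "make_cell_contour_2d",
    "skalak_forces", "bending_forces", "cell_length",
    "MembraneError",
]

# Evans-Fung biconcave thickness polynomial (classic coefficients)
_EF_C0, _EF_C1, _EF_C2 = 0.207161, 2.002558, -1.122762


class MembraneError(ValueError):
    """Degenerate or invalid membrane mesh."""


@dataclass
class MembraneParams:
    """RBC membrane material parameters.

    Stored in the units the literature quotes: shear modulus ``G_s`` in
    N/m, bending modulus ``kappa_b`` in J, viscosities in Pa*s.  ``C``
    is the dimensionless area-dilation modulus ratio (the Skalak
    dilation term is ``C*G_s``); a large value makes the membrane
    nearly area-incompressible.  ``lambda_visc`` is the
    interior/exterior viscosity ratio.
    """

    G_s: float = 5.0e-6            # N/m; normal healthy cells
    C: float = 100.0               # dimensionless dilation ratio
    kappa_b: float = 2.0e-19       # J
    mu_interior: float = 0.006     # Pa*s (hemoglobin)
    mu_plasma: float = 0.0012      # Pa*s

    def __post_init__(self):
        for name in ("G_s", "C", "kappa_b", "mu_interior", "mu_plasma"):
            if getattr(self, name) <= 0:
                raise MembraneError(f"{name} must be positive")

    @property
    def lambda_visc(self) -> float:
        return self.mu_interior / self.mu_plasma

    @classmethod
    def normal(cls, **kw) -> "MembraneParams":
        return cls(**kw)

    @classmethod
    def stiffer(cls, multiplier: float = 10.0, **kw) -> "MembraneParams":
        """Reduced-deformability cells: ``multiplier`` times the normal shear
        modulus (default 10x), all other properties unchanged."""
        base = cls(**kw)
        base.G_s = base.G_s * multiplier
        return base

    # model-unit views (um / ms / Pa system)
    @property
    def Gs_model(self) -> float:
        return self.G_s * SHEAR_MODULUS_N_PER_M_TO_MODEL  # Pa*um

    @property
    def kappa_model_3d(self) -> float:
        return self.kappa_b * BENDING_MODULUS_J_TO_MODEL  # Pa*um^3

    @property
    def kappa_model_2d(self) -> float:
        """2D bending modulus per unit depth (Pa*um^3 per um of depth)."""
        return self.kappa_b * BENDING_MODULUS_J_TO_MODEL  # depth taken as 1 um

    @property
    def mu_interior_model(self) -> float:
        return self.mu_interior * VISCOSITY_PA_S_TO_MODEL

    @property
    def mu_plasma_model(self) -> float:
        return self.mu_plasma * VISCOSITY_PA_S_TO_MODEL


@dataclass
class MembraneMesh:
    """Discretized cell surface (3D triangles) or contour (2D polyline).

    ``vertices`` are current coordinates in um; ``ref_vertices`` the
    undeformed reference.  For 3D, ``faces`` indexes triangles; for 2D
    ``faces`` is None and the polyline is implicitly closed (vertex i
    connects to i+1 mod n).  Reference metrics are cached at build time.
    """

    vertices: np.ndarray
    faces: np.ndarray | None
    ref_vertices: np.ndarray
    _Bm: np.ndarray | None = field(default=None, repr=False)    # (m,2,2) 3D
    _Aref: np.ndarray | None = field(default=None, repr=False)  # (m,) 3D
    _l0: np.ndarray | None = field(default=None, repr=False)    # (n,) 2D

    @property
    def dim(self) -> int:
        return self.vertices.shape[1]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.ref_vertices = np.ascontiguousarray(self.ref_vertices, dtype=float)
        if self.faces is not None:
            self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.dim == 3 and self._Bm is None:
            self._build_ref_metrics_3d()
        elif self.dim == 2 and self._l0 is None:
            self._build_ref_metrics_2d()

    def _build_ref_metrics_3d(self):
        X = self.ref_vertices[self.faces]           # (m, 3, 3)
        e1 = X[:, 1] - X[:, 0]
        e2 = X[:, 2] - X[:, 0]
        n = np.cross(e1, e2)
        a2 = np.linalg.norm(n, axis=1)
        bad = np.flatnonzero(a2 < 1e-14)
        if bad.size:
            raise MembraneError(f"degenerate reference element(s): {bad[:5].tolist()}")
        t1 = e1 / np.linalg.norm(e1, axis=1)[:, None]
        nn = n / a2[:, None]
        t2 = np.cross(nn, t1)
        Dm = np.empty((len(X), 2, 2))
        Dm[:, 0, 0] = np.einsum("ij,ij->i", e1, t1)
        Dm[:, 0, 1] = np.einsum("ij,ij->i", e2, t1)
        Dm[:, 1, 0] = 0.0
        Dm[:, 1, 1] = np.einsum("ij,ij->i", e2, t2)
        det = Dm[:, 0, 0] * Dm[:, 1, 1]
        inv = np.empty_like(Dm)
        inv[:, 0, 0] = Dm[:, 1, 1] / det
        inv[:, 0, 1] = -Dm[:, 0, 1] / det
        inv[:, 1, 0] = 0.0
        inv[:, 1, 1] = Dm[:, 0, 0] / det
        self._Bm = inv
        self._Aref = 0.5 * a2

    def _build_ref_metrics_2d(self):
        e = np.roll(self.ref_vertices, -1, axis=0) - self.ref_vertices
        self._l0 = np.hypot(e[:, 0], e[:, 1])
        if (self._l0 < 1e-12).any():
            raise MembraneError("degenerate reference contour edge")

    # -- geometry helpers --------------------------------------------------
    def surface_area(self) -> float:
        if self.dim == 3:
            X = self.vertices[self.faces]
            return float(0.5 * np.linalg.norm(
                np.cross(X[:, 1] - X[:, 0], X[:, 2] - X[:, 0]), axis=1).sum())
        e = np.roll(self.vertices, -1, axis=0) - self.vertices
        return float(np.hypot(e[:, 0], e[:, 1]).sum())

    perimeter = surface_area  # 2D alias

    def enclosed_area(self) -> float:
        """Signed polygon area (2D contours only)."""
        if self.dim != 2:
            raise MembraneError("enclosed_area is for 2D contours")
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def copy(self) -> "MembraneMesh":
        return MembraneMesh(self.vertices.copy(),
                            None if self.faces is None else self.faces,
                            self.ref_vertices, self._Bm, self._Aref, self._l0)

    def is_simple(self) -> bool:
        """2D contour self-intersection test."""
        from shapely.geometry import Polygon
        return Polygon(self.vertices).is_valid

    # -- IO ----------------------------------------------------------------
    def to_trimesh(self):
        import trimesh
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def export(self, path: str) -> None:
        """Write OFF/PLY (3D) or JSON polyline (2D) by extension."""
        if self.dim == 3:
            self.to_trimesh().export(path)
        else:
            import json
            with open(path, "w") as f:
                json.dump({"schema": "hemonet/contour/1", "units": "um",
                           "vertices": self.vertices.tolist(),
                           "ref_vertices": self.ref_vertices.tolist()}, f)


@dataclass
class MembraneForces:
    """Per-vertex elastic and bending forces plus the total energy.

    Units: model system (see :mod:`hemonet.units`) — forces in Pa*um^2
    (3D, = pN) or Pa*um per unit depth (2D); energies Pa*um^3 (3D,
    = 1e-18 J) or Pa*um^2 per unit depth (2D).
    """

    forces: np.ndarray
    energy: float

    @property
    def net_force(self) -> np.ndarray:
        return self.forces.sum(axis=0)

    def net_torque(self, about: np.ndarray | None = None,
                   vertices: np.ndarray | None = None) -> np.ndarray:
        if vertices is None:
            raise MembraneError("net_torque needs the vertex positions")
        r = vertices - (vertices.mean(axis=0) if about is None else about)
        if vertices.shape[1] == 2:
            return np.array([np.sum(r[:, 0] * self.forces[:, 1]
                                    - r[:, 1] * self.forces[:, 0])])
        return np.cross(r, self.forces).sum(axis=0)


# --------------------------------------------------------------------------
# resting shapes
# --------------------------------------------------------------------------

def _evans_fung_z(rho: np.ndarray, R: float) -> np.ndarray:
    """Half-thickness of the biconcave profile at radial distance rho."""
    s2 = np.clip((rho / R) ** 2, 0.0, 1.0)
    return R * 0.5 * np.sqrt(1.0 - s2) * (_EF_C0 + _EF_C1 * s2 + _EF_C2 * s2 ** 2)


def make_biconcave(end_to_end: float = 7.8, subdivisions: int = 4) -> MembraneMesh:
    """Closed triangulated biconcave discocyte.

    Subdivided icosahedron (20*4^n triangles) mapped onto the
    Evans-Fung profile and scaled so the maximum pairwise vertex
    distance equals ``end_to_end`` (um).
    """
    import trimesh
    if end_to_end <= 0:
        raise MembraneError("end_to_end must be positive")
    if subdivisions < 0:
        raise MembraneError("subdivisions must be >= 0")
    sph = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    V = np.asarray(sph.vertices, dtype=float)
    R = end_to_end / 2.0
    rho = np.hypot(V[:, 0], V[:, 1]) * R
    X = np.empty_like(V)
    X[:, 0] = V[:, 0] * R
    X[:, 1] = V[:, 1] * R
    X[:, 2] = np.sign(V[:, 2]) * _evans_fung_z(rho, R)
    mesh = MembraneMesh(X, np.asarray(sph.faces), X.copy())
    # exact end-to-end rescale (max chord lies on the equator but the
    # discrete vertex set may fall slightly short)
    scale = end_to_end / cell_length(mesh)
    X *= scale
    return MembraneMesh(X, np.asarray(sph.faces), X.copy())


def make_cell_contour_2d(end_to_end: float = 7.8, n_nodes: int = 64) -> MembraneMesh:
    """Closed biconcave cross-section contour with equal reference arc
    spacing and maximum chord equal to ``end_to_end``."""
    if n_nodes < 16:
        raise MembraneError("need at least 16 contour nodes")
    R = end_to_end / 2.0
    xs = R * np.cos(np.linspace(0.0, np.pi, 2049))  # dense half-profile
    zs = _evans_fung_z(np.abs(xs), R)
    upper = np.column_stack([xs, zs])
    lower = np.column_stack([xs[::-1][1:-1], -zs[::-1][1:-1]])
    dense = np.vstack([upper, lower])
    d = np.diff(np.vstack([dense, dense[:1]]), axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])
    total = s[-1]
    tgt = np.linspace(0.0, total, n_nodes, endpoint=False)
    ring = np.vstack([dense, dense[:1]])
    X = np.column_stack([np.interp(tgt, s, ring[:, 0]),
                         np.interp(tgt, s, ring[:, 1])])
    # exact max-chord rescale
    dmax = _max_pairwise(X)
    X *= end_to_end / dmax
    return MembraneMesh(X, None, X.copy())


def _max_pairwise(pts: np.ndarray) -> float:
    q = pts
    if len(q) > 400:
        try:
            q = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    d2 = ((q[:, None, :] - q[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def cell_length(mesh: MembraneMesh | np.ndarray) -> float:
    """Maximum pairwise vertex distance (the end-to-end cell length)."""
    pts = mesh.vertices if isinstance(mesh, MembraneMesh) else np.asarray(mesh, float)
    if len(pts) < 2:
        raise MembraneError("need at least two vertices")
    return _max_pairwise(pts)


# --------------------------------------------------------------------------
# Skalak shear/dilation forces
# --------------------------------------------------------------------------

def skalak_forces(mesh: MembraneMesh, params: MembraneParams) -> MembraneForces:
    """Skalak strain-energy forces.

    3D: per-triangle membrane FEM of
    ``W = (G_s/4)(I1^2 + 2 I1 - 2 I2) + (C G_s/4) I2^2`` with
    ``I1 = l1^2 + l2^2 - 2``, ``I2 = (l1 l2)^2 - 1``.  2D contours use
    the strain-hardening tension analog ``T = G_s (lambda -
    lambda^-3)``.  Forces are the exact negative energy gradient.
    """
    if mesh.dim == 3:
        return _skalak_3d(mesh, params)
    return _skalak_2d(mesh, params)


def _skalak_3d(mesh: MembraneMesh, params: MembraneParams) -> MembraneForces:
    Gs = params.Gs_model
    Cd = params.C
    F_idx = mesh.faces
    x = mesh.vertices[F_idx]                      # (m, 3 verts, 3)
    a = x[:, 1] - x[:, 0]
    b = x[:, 2] - x[:, 0]
    Ds = np.stack([a, b], axis=2)                 # (m, 3, 2)
    Fg = Ds @ mesh._Bm                            # (m, 3, 2) deformation gradient
    C = np.einsum("mki,mkj->mij", Fg, Fg)         # (m, 2, 2)
    trC = C[:, 0, 0] + C[:, 1, 1]
    detC = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
    I1 = trC - 2.0
    I2 = detC - 1.0
    W = Gs / 4.0 * (I1 ** 2 + 2.0 * I1 - 2.0 * I2) + Cd * Gs / 4.0 * I2 ** 2
    w1 = Gs / 2.0 * (I1 + 1.0)
    w2 = -Gs / 2.0 + Cd * Gs / 2.0 * I2
    adjC = np.empty_like(C)
    adjC[:, 0, 0] = C[:, 1, 1]
    adjC[:, 1, 1] = C[:, 0, 0]
    adjC[:, 0, 1] = -C[:, 0, 1]
    adjC[:, 1, 0] = -C[:, 1, 0]
    dWdC = w1[:, None, None] * np.eye(2)[None] + w2[:, None, None] * adjC
    P = 2.0 * Fg @ dWdC                            # (m, 3, 2) first PK stress
    G = (mesh._Aref[:, None, None] * P) @ np.transpose(mesh._Bm, (0, 2, 1))
    forces = np.zeros_like(mesh.vertices)
    np.add.at(forces, F_idx[:, 1], -G[:, :, 0])
    np.add.at(forces, F_idx[:, 2], -G[:, :, 1])
    np.add.at(forces, F_idx[:, 0], G[:, :, 0] + G[:, :, 1])
    energy = float((W * mesh._Aref).sum())
    return MembraneForces(forces, energy)


def _skalak_2d(mesh: MembraneMesh, params: MembraneParams) -> MembraneForces:
    Gs = params.Gs_model
    X = mesh.vertices
    e = np.roll(X, -1, axis=0) - X                 # edge i: i -> i+1
    l = np.hypot(e[:, 0], e[:, 1])
    if (l < 1e-12).any():
        raise MembraneError(f"degenerate contour edge {int(np.argmin(l))}")
    lam = l / mesh._l0
    # w(lambda) with w' = Gs (lambda - lambda^-3); zero at reference
    w = Gs * 0.5 * (lam ** 2 + lam ** -2 - 2.0)
    T = Gs * (lam - lam ** -3)
    that = e / l[:, None]
    g = (T * mesh._l0 / mesh._l0)[:, None] * that  # dE/d(head) per edge = T*that
    forces = np.zeros_like(X)
    np.add.at(forces, (np.arange(len(X)) + 1) % len(X), -g)
    np.add.at(forces, np.arange(len(X)), g)
    energy = float((w * mesh._l0).sum())
    return MembraneForces(forces, energy)


# --------------------------------------------------------------------------
# Helfrich bending forces
# --------------------------------------------------------------------------

def bending_forces(mesh: MembraneMesh, params: MembraneParams) -> MembraneForces:
    """Helfrich bending forces with zero spontaneous curvature.

    3D: ``E = 2 kappa_b * sum_v H_v^2 A_v`` with the cotangent-Laplacian
    mean curvature and barycentric vertex areas; equivalently ``E =
    (kappa_b/2) sum_v |m_v|^2 / A_v`` where ``m_v`` is the integrated
    mean-curvature vector.  2D: ``E = (kappa_b/2) * sum_i phi_i^2 /
    lbar_i`` (turning angle / mean adjacent edge length), the discrete
    ``(kappa/2) integral k^2 ds``.  Forces are exact gradients.
    """
    if mesh.dim == 3:
        return _bending_3d(mesh, params)
    return _bending_2d(mesh, params)


def _bending_3d(mesh: MembraneMesh, params: MembraneParams) -> MembraneForces:
    kappa = params.kappa_model_3d
    V = mesh.vertices
    F = mesh.faces
    nV = len(V)
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise MembraneError("bending requires a closed, manifold mesh")

    x = V[F]                                        # (m, 3, 3)
    m_acc = np.zeros((nV, 3))
    A_acc = np.zeros(nV)

    # per-corner cotangents; corner c is opposite edge (a, b)
    corner = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]      # (c, a, b)
    cots = []
    tri_data = []
    n = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    nrm = np.linalg.norm(n, axis=1)
    if (nrm < 1e-14).any():
        raise MembraneError("degenerate triangle in bending computation")
    At = 0.5 * nrm
    for (c, ai, bi) in corner:
        u = x[:, ai] - x[:, c]
        v = x[:, bi] - x[:, c]
        w = np.cross(u, v)
        wn = np.linalg.norm(w, axis=1)
        cot = np.einsum("ij,ij->i", u, v) / wn
        cots.append(cot)
        d = x[:, ai] - x[:, bi]
        half = 0.5 * cot[:, None] * d
        np.add.at(m_acc, F[:, ai], half)
        np.add.at(m_acc, F[:, bi], -half)
        tri_data.append((u, v, w, wn, cot, d))
    np.add.at(A_acc, F.ravel(), np.repeat(At / 3.0, 3))

    E = 0.5 * kappa * float((np.einsum("ij,ij->i", m_acc, m_acc) / A_acc).sum())
    gm = kappa * m_acc / A_acc[:, None]                       # dE/dm_v
    ga = -0.5 * kappa * np.einsum("ij,ij->i", m_acc, m_acc) / A_acc ** 2  # dE/dA_v

    grad = np.zeros((nV, 3))
    # area part: A_v += At/3 for each corner; grad At wrt vertices
    nh = n / nrm[:, None]
    gA = [0.5 * np.cross(x[:, 1] - x[:, 2], nh),
          0.5 * np.cross(x[:, 2] - x[:, 0], nh),
          0.5 * np.cross(x[:, 0] - x[:, 1], nh)]
    ga_tri = (ga[F[:, 0]] + ga[F[:, 1]] + ga[F[:, 2]]) / 3.0  # (m,)
    for p in range(3):
        np.add.at(grad, F[:, p], ga_tri[:, None] * gA[p])

    # curvature-vector part
    for (c, ai, bi), (u, v, w, wn, cot, d) in zip(corner, tri_data):
        gd = gm[F[:, ai]] - gm[F[:, bi]]            # (m, 3)
        # (i) explicit d dependence: +/- 0.5 * cot * gd
        np.add.at(grad, F[:, ai], 0.5 * cot[:, None] * gd)
        np.add.at(grad, F[:, bi], -0.5 * cot[:, None] * gd)
        # (ii) cot dependence: 0.5 * (gd . d) * grad(cot)
        s = 0.5 * np.einsum("ij,ij->i", gd, d)      # (m,)
        what = w / wn[:, None]
        dcot_du = (v - cot[:, None] * np.cross(v, what)) / wn[:, None]
        dcot_dv = (u - cot[:, None] * np.cross(what, u)) / wn[:, None]
        np.add.at(grad, F[:, ai], s[:, None] * dcot_du)
        np.add.at(grad, F[:, bi], s[:, None] * dcot_dv)
        np.add.at(grad, F[:, c], -s[:, None] * (dcot_du + dcot_dv))

    return MembraneForces(-grad, E)


def _bending_2d(mesh: MembraneMesh, params: MembraneParams) -> MembraneForces:
    kappa = params.kappa_model_2d
    X = mesh.vertices
    n = len(X)
    e = np.roll(X, -1, axis=0) - X                  # edge i: i -> i+1
    l = np.hypot(e[:, 0], e[:, 1])
    if (l < 1e-12).any():
        raise MembraneError("degenerate contour edge")
    eprev = np.roll(e, 1, axis=0)                   # edge into node i
    lprev = np.roll(l, 1)
    cross = eprev[:, 0] * e[:, 1] - eprev[:, 1] * e[:, 0]
    dot = np.einsum("ij,ij->i", eprev, e)
    phi = np.arctan2(cross, dot)                    # turning angle at node i
    lbar = 0.5 * (lprev + l)
    E = 0.5 * kappa * float((phi ** 2 / lbar).sum())

    dE_dphi = kappa * phi / lbar                    # (n,)
    dE_dlbar = -0.5 * kappa * phi ** 2 / lbar ** 2
    # lbar_i = (l_{i-1} + l_i)/2 -> dE/dl_i = (dE_dlbar_i + dE_dlbar_{i+1})/2
    dE_dl = 0.5 * (dE_dlbar + np.roll(dE_dlbar, -1))

    # phi_i depends on eprev=e_{i-1} and e_i
    du = np.column_stack([eprev[:, 1], -eprev[:, 0]]) / (lprev ** 2)[:, None]
    dv = np.column_stack([-e[:, 1], e[:, 0]]) / (l ** 2)[:, None]
    grad_e = np.zeros_like(X)                       # dE/d(e_i)
    grad_e += dE_dphi[:, None] * dv                 # via phi_i
    grad_e += np.roll(dE_dphi, -1)[:, None] * np.roll(du, -1, axis=0)  # via phi_{i+1}
    grad_e += dE_dl[:, None] * (e / l[:, None])     # via l_i
    grad = np.zeros_like(X)
    idx = np.arange(n)
    np.add.at(grad, (idx + 1) % n, grad_e)
    np.add.at(grad, idx, -grad_e)
    return MembraneForces(-grad, E)
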