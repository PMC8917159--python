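"""Membrane mechanics: resting shapes, Skalak and Helfrich forces
validated against closed forms and finite-difference energy gradients."""

import numpy as np
import pytest
import trimesh

from hemonet.membrane import (MembraneError, MembraneMesh, MembraneParams,
                              bending_forces, cell_length, make_biconcave,
                              make_cell_contour_2d, skalak_forces)


def fd_gradient(fn, X, indices, eps=1e-6):
    """Central-difference gradient of an energy functional at selected
    vertex indices."""
    g = np.zeros((len(indices), X.shape[1]))
    for a, i in enumerate(indices):
        for d in range(X.shape[1]):
            Xp, Xm = X.copy(), X.copy()
            Xp[i, d] += eps
            Xm[i, d] -= eps
            g[a, d] = (fn(Xp) - fn(Xm)) / (2 * eps)
    return g


# --------------------------------------------------------------------------
# resting shapes
# --------------------------------------------------------------------------

class TestRestingShapes:
    def test_biconcave_triangle_count_and_length(self):
        m = make_biconcave(7.8, 4)
        assert len(m.faces) == 5120
        assert cell_length(m) == pytest.approx(7.8, rel=1e-9)

    def test_icosahedron_base(self):
        assert len(make_biconcave(7.8, 0).faces) == 20

    def test_biconcave_closed_manifold(self):
        tm = make_biconcave(7.8, 3).to_trimesh()
        assert tm.is_watertight and tm.euler_number == 2

    def test_contour_max_chord_and_simplicity(self):
        c = make_cell_contour_2d(7.8, 64)
        assert cell_length(c) == pytest.approx(7.8, rel=1e-9)
        assert c.is_simple()

    def test_contour_perimeter_refinement_converges(self):
        p1 = make_cell_contour_2d(7.8, 512).perimeter()
        p2 = make_cell_contour_2d(7.8, 4096).perimeter()
        assert abs(p1 - p2) / p2 < 0.005

    def test_contour_rejects_too_few_nodes(self):
        with pytest.raises(MembraneError):
            make_cell_contour_2d(7.8, 8)


class TestCellLength:
    def test_two_points(self):
        assert cell_length(np.array([[0.0, 0.0], [3.0, 4.0]])) == 5.0

    def test_rotation_invariance(self):
        m = make_biconcave(7.8, 2)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        assert cell_length(m.vertices @ R.T) == pytest.approx(
            cell_length(m), rel=1e-12)


# --------------------------------------------------------------------------
# material defaults
# --------------------------------------------------------------------------

class TestParams:
    def test_normal_and_stiffer_defaults(self):
        n = MembraneParams.normal()
        s = MembraneParams.stiffer()
        assert n.G_s == pytest.approx(5e-6)
        assert s.G_s / n.G_s == pytest.approx(10.0)
        assert n.lambda_visc == pytest.approx(5.0)
        assert n.mu_interior == pytest.approx(0.006)
        assert n.mu_plasma == pytest.approx(0.0012)

    def test_rejects_nonpositive(self):
        with pytest.raises(MembraneError):
            MembraneParams(G_s=-1.0)


# --------------------------------------------------------------------------
# Skalak forces
# --------------------------------------------------------------------------

class TestSkalak:
    def test_reference_state_zero(self):
        m = make_biconcave(7.8, 2)
        p = MembraneParams()
        out = skalak_forces(m, p)
        scale = p.Gs_model * m.surface_area()  # natural energy scale
        assert abs(out.energy) < 1e-12 * scale
        assert np.abs(out.forces).max() < 1e-10 * p.Gs_model

    def test_equibiaxial_patch_matches_closed_form(self):
        """A flat patch stretched by l1 = l2 = 1.1 must carry exactly the
        Skalak density W(l, l) per unit reference area."""
        lam = 1.1
        p = MembraneParams(C=3.0)
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        cur = ref.copy()
        cur[:, :2] *= lam
        m = MembraneMesh(cur, faces, ref)
        out = skalak_forces(m, p)
        I1 = 2 * lam ** 2 - 2
        I2 = lam ** 4 - 1
        Gs = p.Gs_model
        W = Gs / 4 * (I1 ** 2 + 2 * I1 - 2 * I2) + p.C * Gs / 4 * I2 ** 2
        assert out.energy == pytest.approx(W * 1.0, rel=1e-12)  # area = 1

    @pytest.mark.parametrize("dim", ["3d", "2d"])
    def test_forces_match_fd_gradient(self, dim):
        rng = np.random.default_rng(0)
        p = MembraneParams()
        if dim == "3d":
            s = trimesh.creation.icosphere(subdivisions=1, radius=2.0)
            ref = np.array(s.vertices)
            faces = np.array(s.faces)
            cur = ref * 1.05 + 0.05 * rng.standard_normal(ref.shape)
            mk = lambda X: MembraneMesh(X, faces, ref)
        else:
            base = make_cell_contour_2d(7.8, 48)
            ref = base.ref_vertices
            cur = ref * 1.03 + 0.04 * rng.standard_normal(ref.shape)
            mk = lambda X: MembraneMesh(X, None, ref)
        out = skalak_forces(mk(cur), p)
        idx = range(0, len(cur), 5)
        fd = fd_gradient(lambda X: skalak_forces(mk(X), p).energy, cur, idx)
        scale = max(np.abs(fd).max(), 1e-30)
        assert np.abs(fd + out.forces[list(idx)]).max() / scale < 1e-4

    def test_energy_nonnegative_random_deformations(self):
        rng = np.random.default_rng(1)
        base = make_cell_contour_2d(7.8, 48)
        p = MembraneParams()
        for _ in range(10):
            X = base.ref_vertices * (1 + 0.1 * rng.standard_normal())
            X = X + 0.05 * rng.standard_normal(X.shape)
            e = skalak_forces(MembraneMesh(X, None, base.ref_vertices), p).energy
            assert e >= 0.0


# --------------------------------------------------------------------------
# Helfrich bending
# --------------------------------------------------------------------------

class TestBending:
    def test_sphere_energy_approaches_8_pi_kappa(self):
        p = MembraneParams()
        errs = []
        for sub in (2, 3, 4):
            s = trimesh.creation.icosphere(subdivisions=sub, radius=3.0)
            m = MembraneMesh(np.array(s.vertices), np.array(s.faces),
                             np.array(s.vertices))
            E = bending_forces(m, p).energy
            errs.append(abs(E / (8 * np.pi * p.kappa_model_3d) - 1.0))
        assert errs[-1] < 0.03
        assert errs[0] > errs[1] > errs[2]  # refinement convergence

    def test_circle_energy_closed_form(self):
        p = MembraneParams()
        R = 3.0
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        X = np.column_stack([R * np.cos(th), R * np.sin(th)])
        E = bending_forces(MembraneMesh(X, None, X.copy()), p).energy
        assert E == pytest.approx(np.pi * p.kappa_model_2d / R, rel=1e-3)

    @pytest.mark.parametrize("dim", ["3d", "2d"])
    def test_forces_match_fd_gradient(self, dim):
        rng = np.random.default_rng(2)
        p = MembraneParams()
        if dim == "3d":
            s = trimesh.creation.icosphere(subdivisions=1, radius=2.0)
            ref = np.array(s.vertices)
            faces = np.array(s.faces)
            cur = ref + 0.08 * rng.standard_normal(ref.shape)
            mk = lambda X: MembraneMesh(X, faces, ref)
        else:
            base = make_cell_contour_2d(7.8, 48)
            ref = base.ref_vertices
            cur = ref + 0.05 * rng.standard_normal(ref.shape)
            mk = lambda X: MembraneMesh(X, None, ref)
        out = bending_forces(mk(cur), p)
        idx = range(0, len(cur), 5)
        fd = fd_gradient(lambda X: bending_forces(mk(X), p).energy, cur, idx)
        scale = max(np.abs(fd).max(), 1e-30)
        assert np.abs(fd + out.forces[list(idx)]).max() / scale < 1e-4

    def test_open_mesh_rejected(self):
        s = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
        faces = np.array(s.faces)[:-2]  # puncture the surface
        m = MembraneMesh(np.array(s.vertices), faces, np.array(s.vertices))
        with pytest.raises(MembraneError):
            bending_forces(m, MembraneParams())


# --------------------------------------------------------------------------
# conservation invariants
# --------------------------------------------------------------------------

@pytest.mark.parametrize("force_fn", [skalak_forces, bending_forces])
@pytest.mark.parametrize("dim", ["3d", "2d"])
def test_net_force_and_torque_vanish(force_fn, dim):
    """Translation invariance of the energies makes the net force zero
    to machine precision; rotation invariance bounds the net torque."""
    rng = np.random.default_rng(3)
    if dim == "3d":
        s = trimesh.creation.icosphere(subdivisions=2, radius=3.0)
        ref = np.array(s.vertices)
        cur = ref * 1.04 + 0.05 * rng.standard_normal(ref.shape)
        m = MembraneMesh(cur, np.array(s.faces), ref)
    else:
        base = make_cell_contour_2d(7.8, 64)
        ref = base.ref_vertices
        cur = ref * 1.02 + 0.05 * rng.standard_normal(ref.shape)
        m = MembraneMesh(cur, None, ref)
    out = force_fn(m, MembraneParams())
    fscale = max(np.abs(out.forces).max(), 1e-30)
    assert np.abs(out.net_force).max() / fscale < 1e-10
    torque = out.net_torque(vertices=cur)
    tscale = fscale * np.abs(cur).max()
    assert np.abs(torque).max() / tscale < 1e-8
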