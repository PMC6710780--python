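"""Hexahedral element and plate-assembly audits."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from cellorigami import plate_fem as pf

UNIT_CUBE = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)


def _oracle_trilinear_stiffness(coords, E, nu):
    """Independent hex8 stiffness: shape-function gradients by central
    finite differences of the trilinear basis (exact for linear functions),
    assembled index-by-index without the production B-matrix code."""
    signs = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                      [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)

    def shape(xi):
        return 0.125 * np.prod(1 + signs * xi, axis=1)

    def grad(xi):
        h = 1e-6
        g = np.empty((8, 3))
        for c in range(3):
            e = np.zeros(3)
            e[c] = h
            g[:, c] = (shape(xi + e) - shape(xi - e)) / (2 * h)
        return g

    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    gp = np.array([-1, 1]) / np.sqrt(3)
    K = np.zeros((24, 24))
    for gx in gp:
        for gy in gp:
            for gz in gp:
                xi = np.array([gx, gy, gz])
                J = grad(xi).T @ coords
                dNdx = grad(xi) @ np.linalg.inv(J).T
                w = np.linalg.det(J)
                for a in range(8):
                    for b in range(8):
                        for i in range(3):
                            for j in range(3):
                                kab = (lam * dNdx[a, i] * dNdx[b, j]
                                       + mu * dNdx[a, j] * dNdx[b, i])
                                if i == j:
                                    kab += mu * float(dNdx[a] @ dNdx[b])
                                K[3 * a + i, 3 * b + j] += kab * w
    return K


@pytest.mark.parametrize("formulation", ["trilinear", "incompatible"])
def test_hex8_rigid_body_modes(formulation):
    K = pf.hex8_stiffness(UNIT_CUBE, pf.ElasticMaterial(1.0, 0.3), formulation)
    assert np.allclose(K, K.T, atol=1e-12)
    w = np.linalg.eigvalsh(K)
    assert np.sum(np.abs(w) < 1e-10) == 6
    assert w[6] > 1e-3
    # explicit rigid translation carries zero force
    for c in range(3):
        u = np.zeros(24)
        u[c::3] = 1.0
        assert np.abs(K @ u).max() < 1e-12


def test_hex8_matches_independent_quadrature_oracle():
    K = pf.hex8_stiffness(UNIT_CUBE, pf.ElasticMaterial(1.0, 0.0), "trilinear")
    K_oracle = _oracle_trilinear_stiffness(UNIT_CUBE, 1.0, 0.0)
    assert np.abs(K - K_oracle).max() < 1e-9  # FD-limited oracle accuracy


def test_hex8_rejects_inverted_element():
    bad = UNIT_CUBE.copy()
    bad[[0, 1]] = bad[[1, 0]]
    with pytest.raises(ValueError, match="[Ii]nverted"):
        pf.hex8_stiffness(bad, pf.ElasticMaterial(1.0, 0.3))


@pytest.mark.parametrize("formulation", ["trilinear", "incompatible"])
def test_patch_test_constant_strain(formulation):
    """A linear displacement field imposed on a 2x2x2-element patch with a
    distorted interior node produces zero residual at that node (constant
    strain is reproduced exactly)."""
    grid = [0.0, 1.0, 2.0]
    nodes = np.array([(x, y, z) for x in grid for y in grid for z in grid])
    center = int(np.flatnonzero(np.all(np.abs(nodes - 1.0) < 1e-9, axis=1))[0])
    nodes[center] += (0.13, -0.09, 0.11)

    def sel(p):
        return int(np.flatnonzero(np.all(np.abs(nodes - p) < 0.4, axis=1))[0])

    elems = []
    for i in range(2):
        for j in range(2):
            for k in range(2):
                x0, x1 = grid[i], grid[i + 1]
                y0, y1 = grid[j], grid[j + 1]
                z0, z1 = grid[k], grid[k + 1]
                elems.append([sel((x0, y0, z0)), sel((x1, y0, z0)),
                              sel((x1, y1, z0)), sel((x0, y1, z0)),
                              sel((x0, y0, z1)), sel((x1, y0, z1)),
                              sel((x1, y1, z1)), sel((x0, y1, z1))])
    mesh = pf.HexMesh(nodes, np.array(elems), np.array(["plate"] * 8))
    K = pf.assemble_stiffness(mesh, {"plate": pf.ElasticMaterial(1.0, 0.3)},
                              formulation)
    A = np.array([[0.01, 0.004, -0.002], [0.003, -0.01, 0.005],
                  [0.001, 0.002, 0.02]])
    u = (nodes @ A.T).ravel()
    f = K @ u
    assert np.abs(f[3 * center:3 * center + 3]).max() < 1e-12


def test_mesh_plate_with_joint_audits():
    asm = pf.mesh_plate_with_joint()
    b, h, w, t = asm.geometry
    assert (b, h, w, t) == (30.0, 2.7, 6.0, 0.3)
    # volume = plate + joint, positive Jacobians everywhere
    assert pf.mesh_volume(asm.mesh) == pytest.approx(b * b * h + b * w * t, rel=1e-9)
    assert pf.min_jacobian(asm.mesh) > 0
    # joint spans exactly t through-thickness, with >= 2 elements
    joint_nodes = asm.mesh.nodes[np.unique(asm.mesh.elements[asm.mesh.region == "joint"])]
    assert joint_nodes[:, 2].min() == pytest.approx(-t)
    assert joint_nodes[:, 2].max() == pytest.approx(0.0)
    joint_zs = np.unique(np.round(joint_nodes[:, 2], 9))
    assert len(joint_zs) >= 3
    plate_nodes = asm.mesh.nodes[np.unique(asm.mesh.elements[asm.mesh.region == "plate"])]
    assert plate_nodes[:, 2].min() == pytest.approx(-h)
    # anchored set nonempty, strict subset; top surfaces flush at z = 0
    assert 0 < len(asm.anchored_dofs) < asm.mesh.n_dofs
    assert np.all(np.abs(asm.mesh.nodes[asm.top_surface_nodes, 2]) < 1e-9)
    assert np.all(asm.mesh.nodes[asm.top_surface_nodes, 0] >= -1e-9)


def test_mesh_plate_rejects_bad_input():
    with pytest.raises(ValueError):
        pf.mesh_plate_with_joint((30.0, 2.7, 0.0, 0.3))
    with pytest.raises(ValueError):
        pf.mesh_plate_with_joint(resolution=10.0)  # > w/2


def test_anchored_plate_zero_load_zero_displacement():
    asm = pf.mesh_plate_with_joint(resolution=3.0)
    K = pf.assemble_stiffness(asm.mesh, {"plate": pf.ElasticMaterial(4e6, 0.3),
                                         "joint": pf.ElasticMaterial(4e6, 0.3)})
    fixed = pf.apply_anchor_constraints(asm)
    free = np.setdiff1d(np.arange(asm.mesh.n_dofs), fixed)
    u = spla.spsolve(K[free][:, free].tocsc(), np.zeros(len(free)))
    assert np.abs(u).max() == 0.0
    # symmetric; positive definite once anchored (checked on a small box)
    assert np.abs((K - K.T).data).max() < 1e-6 if (K - K.T).nnz else True
    small = pf.mesh_box((4.0, 2.0, 1.0), (3, 2, 2))
    Ks = pf.assemble_stiffness(small, {"plate": pf.ElasticMaterial(1.0, 0.3)})
    clamped = np.flatnonzero(np.abs(small.nodes[:, 0]) < 1e-9)
    cdofs = (3 * clamped[:, None] + np.arange(3)).ravel()
    keep = np.setdiff1d(np.arange(small.n_dofs), cdofs)
    w = np.linalg.eigvalsh(Ks[keep][:, keep].toarray())
    assert w.min() > 0


def test_unconstrained_stiffness_rank_deficiency():
    """Without anchors the assembled stiffness carries exactly the six
    rigid-body zero-energy modes (rank check)."""
    mesh = pf.mesh_box((2.0, 1.0, 1.0), (2, 1, 1))
    K = pf.assemble_stiffness(mesh, {"plate": pf.ElasticMaterial(1.0, 0.3)})
    w = np.linalg.eigvalsh(K.toarray())
    assert np.sum(np.abs(w) < 1e-9 * w.max()) == 6


def test_cantilever_matches_beam_theory_and_converges():
    """Clamped plate strip under end load: tip deflection within 10% of
    P L^3/(3 E I), approaching it monotonically from below under refinement
    (trilinear bricks lock more on coarse meshes)."""
    b, h, E, nu, P = 30.0, 2.7, 4e6, 0.3, 100.0

    def tip_deflection(divs, formulation):
        mesh = pf.mesh_box((b, b, h), divs)
        K = pf.assemble_stiffness(mesh, {"plate": pf.ElasticMaterial(E, nu)},
                                  formulation)
        fixed = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-9)
        fdofs = (3 * fixed[:, None] + np.arange(3)).ravel()
        free = np.setdiff1d(np.arange(mesh.n_dofs), fdofs)
        tip = np.flatnonzero(np.abs(mesh.nodes[:, 0] - b) < 1e-9)
        f = np.zeros(mesh.n_dofs)
        f[3 * tip + 2] = P / len(tip)
        u = np.zeros(mesh.n_dofs)
        u[free] = spla.spsolve(K[free][:, free].tocsc(), f[free])
        return u[3 * tip + 2].mean()

    beam = P * b**3 / (3 * E * (b * h**3 / 12))
    w_default = tip_deflection((20, 10, 2), "incompatible")
    assert abs(w_default - beam) / beam < 0.10
    w_tri_coarse = tip_deflection((10, 5, 2), "trilinear")
    w_tri_fine = tip_deflection((20, 10, 4), "trilinear")
    assert w_tri_coarse < w_tri_fine < beam * 1.02


def test_mesh_box_vtk_export(tmp_path):
    mesh = pf.mesh_box((2.0, 1.0, 1.0), (2, 1, 1))
    pf.mesh_to_vtk(mesh, tmp_path / "box.vtk")
    text = (tmp_path / "box.vtk").read_text()
    assert "CELL_TYPES 2" in text and "12" in text
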