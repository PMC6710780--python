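"""Microplate + flexible joint as an isotropic linear-elastic hexahedral mesh.

Layout (lengths in um): the folding plate occupies x in [0, b], y in
[-b/2, b/2], z in [-h, 0]; the flexible joint strip occupies x in [-w, 0],
z in [-t, 0] with its top surface flush with the plate top at z = 0.  The
joint's far face (x = -w) is the anchored region: it represents the rigidly
fixed, substrate-bound side of the assembly and is constrained in all
degrees of freedom.  The two structured grids conform: the joint's z-levels
(0, -t/2, -t) are a subset of the plate's, and coincident nodes on the
shared x = 0 face are merged.

Elements are 8-node trilinear hexahedra with 2x2x2 Gauss quadrature.  The
default formulation adds Wilson incompatible bending modes (statically
condensed); fully integrated trilinear bricks shear-lock badly on the thin
joint (aspect ratio ~ 20), while the incompatible-modes element reproduces
thin-plate bending within a few percent and passes the patch test exactly on
the rectangular elements produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ElasticMaterial",
    "HexMesh",
    "PlateAssembly",
    "mesh_plate_with_joint",
    "mesh_box",
    "hex8_stiffness",
    "assemble_stiffness",
    "apply_anchor_constraints",
    "mesh_volume",
    "min_jacobian",
]

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
# node order: bottom face (z-) counterclockwise, then top face (z+)
_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear elasticity; E in internal kPa (nN/um^2)."""

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")

    @property
    def D(self) -> np.ndarray:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


@dataclass
class HexMesh:
    nodes: np.ndarray          # (N, 3)
    elements: np.ndarray       # (E, 8) int
    region: np.ndarray         # (E,) str: "plate" | "joint"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_dofs(self) -> int:
        return 3 * len(self.nodes)


@dataclass
class PlateAssembly:
    mesh: HexMesh
    anchored_nodes: np.ndarray
    anchored_dofs: np.ndarray
    top_surface_nodes: np.ndarray       # folding-plate upper face (x >= 0, z = 0)
    adhesion_surface_nodes: np.ndarray  # whole upper face incl. joint (z = 0)
    geometry: tuple[float, float, float, float]  # (b, h, w, t) um


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def _grid_hexes(xs, ys, zs, node_index):
    """Connectivity of a structured grid through a global coordinate->id map."""
    elems = []
    for i in range(len(xs) - 1):
        for j in range(len(ys) - 1):
            for k in range(len(zs) - 1):
                x0, x1 = xs[i], xs[i + 1]
                y0, y1 = ys[j], ys[j + 1]
                z0, z1 = zs[k], zs[k + 1]
                corners = [(x0, y0, z0), (x1, y0, z0), (x1, y1, z0), (x0, y1, z0),
                           (x0, y0, z1), (x1, y0, z1), (x1, y1, z1), (x0, y1, z1)]
                elems.append([node_index[c] for c in corners])
    return elems


def _key(x, y, z):
    return (round(float(x), 9), round(float(y), 9), round(float(z), 9))


def mesh_plate_with_joint(geometry=(30.0, 2.7, 6.0, 0.3),
                          resolution: float = 3.0) -> PlateAssembly:
    """Conforming hex mesh of the folding plate and the flexible joint.

    ``geometry`` = (b, h, w, t) um; ``resolution`` is the target in-plane
    element size.  The joint always has >= 2 elements through its thickness.
    """
    b, h, w, t = geometry
    if min(b, h, w, t) <= 0:
        raise ValueError("all dimensions must be positive")
    if t >= h:
        raise ValueError("joint thickness t must be smaller than plate thickness h")
    if resolution > w / 2 + 1e-12:
        raise ValueError("resolution must be <= w/2 so the joint is resolved")

    ny = max(2, round(b / resolution))
    nx = max(2, round(b / resolution))
    njx = max(2, round(w / resolution))
    npz = max(2, round((h - t) / resolution))

    ys = np.linspace(-b / 2, b / 2, ny + 1)
    xs_plate = np.linspace(0.0, b, nx + 1)
    xs_joint = np.linspace(-w, 0.0, njx + 1)
    zs_joint = np.array([-t, -t / 2, 0.0])
    zs_plate = np.concatenate([np.linspace(-h, -t, npz + 1), [-t / 2, 0.0]])
    zs_plate = np.unique(np.round(zs_plate, 12))

    node_index: dict = {}
    coords: list = []

    def register(xs, ys, zs):
        for x in xs:
            for y in ys:
                for z in zs:
                    k = _key(x, y, z)
                    if k not in node_index:
                        node_index[k] = len(coords)
                        coords.append(k)

    register(xs_plate, ys, zs_plate)
    register(xs_joint, ys, zs_joint)

    idx = {k: i for k, i in node_index.items()}
    plate_elems = _grid_hexes(xs_plate, ys, zs_plate, {k: idx[_key(*k)] for k in
                              [(x, y, z) for x in xs_plate for y in ys for z in zs_plate]})
    joint_elems = _grid_hexes(xs_joint, ys, zs_joint, {k: idx[_key(*k)] for k in
                              [(x, y, z) for x in xs_joint for y in ys for z in zs_joint]})

    nodes = np.array(coords, dtype=float)
    elements = np.array(plate_elems + joint_elems, dtype=int)
    region = np.array(["plate"] * len(plate_elems) + ["joint"] * len(joint_elems))
    mesh = HexMesh(nodes, elements, region)

    tol = 1e-9
    anchored_nodes = np.flatnonzero(np.abs(nodes[:, 0] + w) < tol)
    anchored_dofs = (3 * anchored_nodes[:, None] + np.arange(3)).ravel()
    top = np.abs(nodes[:, 2]) < tol
    top_surface_nodes = np.flatnonzero(top & (nodes[:, 0] >= -tol))
    adhesion_surface_nodes = np.flatnonzero(top)
    return PlateAssembly(mesh, anchored_nodes, anchored_dofs,
                         top_surface_nodes, adhesion_surface_nodes,
                         (b, h, w, t))


def mesh_box(dims, divisions) -> HexMesh:
    """Plain structured box [0,lx]x[0,ly]x[-lz,0]; used by benchmarks."""
    lx, ly, lz = dims
    nx, ny, nz = divisions
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(-lz, 0, nz + 1)
    node_index = {}
    coords = []
    for x in xs:
        for y in ys:
            for z in zs:
                k = _key(x, y, z)
                node_index[k] = len(coords)
                coords.append(k)
    elems = _grid_hexes(xs, ys, zs, {(x, y, z): node_index[_key(x, y, z)]
                                     for x in xs for y in ys for z in zs})
    return HexMesh(np.array(coords, float), np.array(elems, int),
                   np.array(["plate"] * len(elems)))


# ---------------------------------------------------------------------------
# element stiffness
# ---------------------------------------------------------------------------

def _shape_gradients(xi):
    """dN/dxi (8, 3) at a natural-coordinate point."""
    g = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI[a]
        g[a] = [
            0.125 * xa * (1 + ya * xi[1]) * (1 + za * xi[2]),
            0.125 * ya * (1 + xa * xi[0]) * (1 + za * xi[2]),
            0.125 * za * (1 + xa * xi[0]) * (1 + ya * xi[1]),
        ]
    return g


def _b_matrix(dNdx):
    """Strain-displacement matrix (6, 3*n) in Voigt order xx,yy,zz,yz,xz,xy."""
    n = dNdx.shape[0]
    B = np.zeros((6, 3 * n))
    B[0, 0::3] = dNdx[:, 0]
    B[1, 1::3] = dNdx[:, 1]
    B[2, 2::3] = dNdx[:, 2]
    B[3, 1::3] = dNdx[:, 2]
    B[3, 2::3] = dNdx[:, 1]
    B[4, 0::3] = dNdx[:, 2]
    B[4, 2::3] = dNdx[:, 0]
    B[5, 0::3] = dNdx[:, 1]
    B[5, 1::3] = dNdx[:, 0]
    return B


def hex8_stiffness(coords: np.ndarray, material: ElasticMaterial,
                   formulation: str = "incompatible") -> np.ndarray:
    """24x24 stiffness of an 8-node hexahedron (2x2x2 Gauss).

    ``formulation`` is "trilinear" (standard fully integrated brick) or
    "incompatible" (adds 9 Wilson bending modes, statically condensed, with
    the centroid-Jacobian correction so the patch test is preserved).
    """
    coords = np.asarray(coords, dtype=float)
    D = material.D
    # J rows are d(x)/d(xi_i); gradients map through the inverse transpose
    J0 = _shape_gradients(np.zeros(3)).T @ coords  # centroid Jacobian
    detJ0 = np.linalg.det(J0)
    if detJ0 <= 0:
        raise ValueError("inverted element (non-positive centroid Jacobian)")
    J0invT = np.linalg.inv(J0).T

    Kuu = np.zeros((24, 24))
    Kua = np.zeros((24, 9))
    Kaa = np.zeros((9, 9))
    incompat = formulation == "incompatible"
    if formulation not in ("trilinear", "incompatible"):
        raise ValueError(f"unknown formulation {formulation!r}")

    for gx in _GP:
        for gy in _GP:
            for gz in _GP:
                xi = np.array([gx, gy, gz])
                dNdxi = _shape_gradients(xi)
                J = dNdxi.T @ coords
                detJ = np.linalg.det(J)
                if detJ <= 0:
                    raise ValueError("inverted element (non-positive Jacobian)")
                dNdx = dNdxi @ np.linalg.inv(J).T
                B = _b_matrix(dNdx)
                wdet = detJ
                Kuu += B.T @ D @ B * wdet
                if incompat:
                    # incompatible modes 1-xi^2 etc.; gradients mapped through
                    # the centroid Jacobian, scaled by detJ0/detJ (Taylor)
                    dMdxi = np.array([[-2 * gx, 0, 0], [0, -2 * gy, 0], [0, 0, -2 * gz]])
                    dMdx = dMdxi @ J0invT * (detJ0 / detJ)
                    G = _b_matrix(dMdx)
                    Kua += B.T @ D @ G * wdet
                    Kaa += G.T @ D @ G * wdet
    if incompat:
        Kuu -= Kua @ np.linalg.solve(Kaa, Kua.T)
    return Kuu


# ---------------------------------------------------------------------------
# assembly and audits
# ---------------------------------------------------------------------------

def assemble_stiffness(mesh: HexMesh, materials: dict,
                       formulation: str = "incompatible") -> sp.csr_matrix:
    """Assemble the global stiffness; ``materials`` maps region -> ElasticMaterial.

    Identical element shapes share one stiffness evaluation (the structured
    grids here contain only a handful of distinct shapes).
    """
    rows, cols, vals = [], [], []
    cache: dict = {}
    for e, conn in enumerate(mesh.elements):
        coords = mesh.nodes[conn]
        mat = materials[mesh.region[e]]
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        box = lo + 0.5 * (_XI + 1.0) * (hi - lo)
        if np.allclose(coords, box, atol=1e-9):
            # axis-aligned rectangular element: shape-identical blocks share
            # one stiffness evaluation
            key = (tuple(np.round(hi - lo, 12)), mat.E, mat.nu)
            if key not in cache:
                cache[key] = hex8_stiffness(coords, mat, formulation)
            Ke = cache[key]
        else:
            Ke = hex8_stiffness(coords, mat, formulation)
        dofs = (3 * conn[:, None] + np.arange(3)).ravel()
        rows.append(np.repeat(dofs, 24))
        cols.append(np.tile(dofs, 24))
        vals.append(Ke.ravel())
    n = mesh.n_dofs
    K = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()
    return K


def apply_anchor_constraints(assembly: PlateAssembly) -> np.ndarray:
    """All DOFs of the anchored-region nodes, as a sorted index array."""
    if len(assembly.anchored_nodes) == 0:
        raise ValueError("anchored region is empty")
    return np.sort(assembly.anchored_dofs)


def mesh_volume(mesh: HexMesh) -> float:
    vol = 0.0
    for conn in mesh.elements:
        coords = mesh.nodes[conn]
        for gx in _GP:
            for gy in _GP:
                for gz in _GP:
                    J = _shape_gradients(np.array([gx, gy, gz])).T @ coords
                    vol += np.linalg.det(J)
    return vol


def min_jacobian(mesh: HexMesh) -> float:
    best = np.inf
    for conn in mesh.elements:
        coords = mesh.nodes[conn]
        for gx in _GP:
            for gy in _GP:
                for gz in _GP:
                    J = _shape_gradients(np.array([gx, gy, gz])).T @ coords
                    best = min(best, float(np.linalg.det(J)))
    return best


def mesh_to_vtk(mesh: HexMesh, path, point_data=None) -> None:
    from .vtk_io import write_vtk_hexes

    region_id = np.where(mesh.region == "plate", 0, 1)
    write_vtk_hexes(path, mesh.nodes, mesh.elements,
                    point_data=point_data, cell_data={"region": region_id})
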