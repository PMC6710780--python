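"""Tensegrity geometry for adherent-cell models.

The cytoskeleton (CSK) is a flat, polyhedron-derived tensegrity resting on the
microplate plane z = 0:

* 12-node CSK: the classic 6-strut tensegrity on the icosahedron edge graph
  (expanded octahedron) - 6 parallel-pair edges act as microtubule (MT)
  struts, the remaining 24 edges as microfilament (MF) cables - oriented so
  an all-cable triangular face forms the basal adhesion ring (3 nodes, 3
  cables at z = 0), then flattened anisotropically.
* 24-node CSK: the truncated-octahedron vertex set; its 36 edges are MF
  cables and the 12 antipodal diagonals are MT struts; a square face forms
  the basal ring (4 nodes, 4 cables).

Intermediate filaments (IFs) are radial cables from the structure's centre:
to a central particle in the CSK-only models, or to the nucleoskeleton (NSK)
as linkers in the coupled models.  The NSK is a sphere-like tensegrity:
cuboctahedron (12 nodes, 24 chromatin cables, 6 lamina struts) or truncated
octahedron (24 / 36 / 12), centred on the CSK centroid.

Node ordering, element ordering and therefore entire structures are
deterministic functions of the inputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "Node3D",
    "ElementSpec",
    "TensegrityStructure",
    "InterfaceSets",
    "build_flat_csk",
    "add_central_if_cables",
    "build_spherical_nsk",
    "attach_nsk",
    "classify_interface",
    "structure_to_csv",
    "structure_to_vtk",
    "UnsupportedComplexityError",
    "DuplicateLinkageError",
    "CenterMismatchError",
    "EmptyInterfaceError",
]

STRUT_KINDS = ("MT_strut", "lamina_strut")
CABLE_KINDS = ("MF_cable", "IF_cable", "chromatin_cable")
_KIND_ORDER = {k: i for i, k in enumerate(STRUT_KINDS + CABLE_KINDS)}


class UnsupportedComplexityError(ValueError):
    """Requested tensegrity complexity is not one of the supported levels."""


class DuplicateLinkageError(ValueError):
    """Radial IF cables are already present on this structure."""


class CenterMismatchError(ValueError):
    """NSK centre does not coincide with the CSK centre."""


class EmptyInterfaceError(ValueError):
    """No node lies on the microplate plane within tolerance."""


@dataclass(frozen=True)
class Node3D:
    id: int
    position: tuple[float, float, float]
    role: str  # csk | nsk | center_particle

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class ElementSpec:
    kind: str
    nodes: tuple[int, int]
    material_key: str

    def __post_init__(self):
        if self.nodes[0] == self.nodes[1]:
            raise ValueError("element endpoints must differ")
        if self.kind not in _KIND_ORDER:
            raise ValueError(f"unknown element kind {self.kind!r}")

    @property
    def is_strut(self) -> bool:
        return self.kind in STRUT_KINDS


@dataclass(frozen=True)
class TensegrityStructure:
    nodes: tuple[Node3D, ...]
    elements: tuple[ElementSpec, ...]
    complexity: int
    has_nsk: bool = False

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes], dtype=float)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.elements if e.kind == kind)

    @property
    def n_struts(self) -> int:
        return sum(1 for e in self.elements if e.is_strut)

    @property
    def n_cables(self) -> int:
        return sum(1 for e in self.elements if not e.is_strut)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(n.id for n in self.nodes)
        g.add_edges_from(e.nodes for e in self.elements)
        return g

    def element_lengths(self) -> np.ndarray:
        p = self.positions()
        idx = np.array([e.nodes for e in self.elements])
        return np.linalg.norm(p[idx[:, 1]] - p[idx[:, 0]], axis=1)

    def centroid(self, roles: tuple[str, ...] = ("csk",)) -> np.ndarray:
        pts = np.array([n.position for n in self.nodes if n.role in roles])
        return pts.mean(axis=0)

    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if ids != list(range(len(ids))):
            raise ValueError("node ids must be contiguous from 0")
        seen = set()
        for e in self.elements:
            key = tuple(sorted(e.nodes))
            if key in seen:
                raise ValueError(f"duplicate element {key}")
            seen.add(key)
            if not (0 <= e.nodes[0] < len(ids) and 0 <= e.nodes[1] < len(ids)):
                raise ValueError("element references unknown node")


@dataclass(frozen=True)
class InterfaceSets:
    pinned_nodes: tuple[int, ...]
    spring_nodes: tuple[int, ...]
    on_plate_cables: tuple[int, ...]

    def __post_init__(self):
        if set(self.pinned_nodes) & set(self.spring_nodes):
            raise ValueError("pinned and spring node sets must be disjoint")


# ---------------------------------------------------------------------------
# polyhedral seeds
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, list[tuple[int, int]], list[tuple[int, int]]]:
    """Vertices, strut edges and cable edges of the 6-strut tensegrity on the
    icosahedron edge graph.  Struts are the 6 edges joining vertices that
    differ only in the sign of their unit coordinate."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = []
    for a, b in itertools.product((-1.0, 1.0), repeat=2):
        verts.append((0.0, a, b * phi))
        verts.append((a, b * phi, 0.0))
        verts.append((a * phi, 0.0, b))
    V = np.array(verts)
    edges, struts = [], []
    for i in range(12):
        for j in range(i + 1, 12):
            d2 = float(np.sum((V[i] - V[j]) ** 2))
            if abs(d2 - 4.0) < 1e-9:
                # parallel-pair edge <=> endpoints are mirror images in one axis
                if np.allclose(np.abs(V[i]), np.abs(V[j]), atol=1e-12):
                    struts.append((i, j))
                else:
                    edges.append((i, j))
    assert len(struts) == 6 and len(edges) == 24
    return V, struts, edges


def _truncated_octahedron() -> tuple[np.ndarray, list[tuple[int, int]], list[tuple[int, int]]]:
    """Vertices (all permutations of (0, +-1, +-2)), 12 antipodal strut
    diagonals and 36 edge cables."""
    verts = set()
    for perm in itertools.permutations((0, 1, 2)):
        for s1, s2 in itertools.product((-1, 1), repeat=2):
            v = [0.0, 0.0, 0.0]
            v[perm[0]] = 0.0
            v[perm[1]] = s1 * 1.0
            v[perm[2]] = s2 * 2.0
            verts.add(tuple(v))
    V = np.array(sorted(verts))
    assert len(V) == 24
    edges, struts = [], []
    for i in range(24):
        for j in range(i + 1, 24):
            d2 = float(np.sum((V[i] - V[j]) ** 2))
            if abs(d2 - 2.0) < 1e-9:
                edges.append((i, j))
            elif np.allclose(V[i], -V[j], atol=1e-12):
                struts.append((i, j))
    assert len(edges) == 36 and len(struts) == 12
    return V, struts, edges


def _cuboctahedron() -> tuple[np.ndarray, list[tuple[int, int]], list[tuple[int, int]]]:
    """Vertices (permutations of (+-1, +-1, 0)), 6 antipodal strut diagonals
    and 24 edge cables."""
    verts = set()
    for perm in itertools.permutations((0, 1, 2)):
        for s1, s2 in itertools.product((-1, 1), repeat=2):
            v = [0.0, 0.0, 0.0]
            v[perm[0]] = 0.0
            v[perm[1]] = s1 * 1.0
            v[perm[2]] = s2 * 1.0
            verts.add(tuple(v))
    V = np.array(sorted(verts))
    assert len(V) == 12
    edges, struts = [], []
    for i in range(12):
        for j in range(i + 1, 12):
            d2 = float(np.sum((V[i] - V[j]) ** 2))
            if abs(d2 - 2.0) < 1e-9:
                edges.append((i, j))
            elif np.allclose(V[i], -V[j], atol=1e-12):
                struts.append((i, j))
    assert len(edges) == 24 and len(struts) == 6
    return V, struts, edges


def _rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector u onto unit vector v (Rodrigues)."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        # pick any axis orthogonal to u
        a = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(a) < 1e-8:
            a = np.cross(u, [0.0, 1.0, 0.0])
        a /= np.linalg.norm(a)
        return 2.0 * np.outer(a, a) - np.eye(3)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _canonical_structure(V, struts, cables, strut_kind, cable_kind, roles, complexity,
                         has_nsk=False, extra_nodes=(), extra_elements=()):
    """Renumber nodes in a deterministic (z, x, y) lexicographic order and
    sort elements; returns a validated structure."""
    key = np.round(V, 9)
    order = np.lexsort((key[:, 1], key[:, 0], key[:, 2]))
    remap = {int(old): new for new, old in enumerate(order)}
    nodes = [Node3D(new, tuple(np.round(V[old], 12)), roles[old] if isinstance(roles, (list, tuple)) else roles)
             for new, old in enumerate(order)]
    elements = []
    for (i, j) in struts:
        a, b = sorted((remap[i], remap[j]))
        elements.append(ElementSpec(strut_kind, (a, b), strut_kind))
    for (i, j) in cables:
        a, b = sorted((remap[i], remap[j]))
        elements.append(ElementSpec(cable_kind, (a, b), cable_kind))
    elements.extend(extra_elements)
    nodes.extend(extra_nodes)
    elements.sort(key=lambda e: (_KIND_ORDER[e.kind], e.nodes))
    s = TensegrityStructure(tuple(nodes), tuple(elements), complexity, has_nsk)
    s.validate()
    return s


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

def build_flat_csk(n_nodes: int, footprint_radius: float = 12.0,
                   height: float = 6.0) -> TensegrityStructure:
    """Flat CSK tensegrity resting on z = 0, with MT struts and MF cables and
    a central particle (for later IF attachment).

    ``footprint_radius`` is the maximum horizontal radius of the cell (um),
    so the default 12 um cell fits the 30 um plate; ``height`` the apex
    height (um).  12 nodes give 6 struts / 24 MF cables with 3 basal nodes +
    3 basal cables; 24 nodes give 12 / 36 with 4 + 4.
    """
    if n_nodes not in (12, 24):
        raise UnsupportedComplexityError(f"unsupported CSK complexity {n_nodes}; choose 12 or 24")
    if footprint_radius <= 0 or height <= 0:
        raise ValueError("footprint_radius and height must be positive")

    if n_nodes == 12:
        V, struts, cables = _icosahedron()
        # put the all-cable face {(0,1,phi),(phi,0,1),(1,phi,0)} at the bottom
        R = _rotation_aligning(np.array([1.0, 1.0, 1.0]), np.array([0.0, 0.0, -1.0]))
        V = V @ R.T
    else:
        V, struts, cables = _truncated_octahedron()
        # square face at z = -2 is already the bottom

    V = V.copy()
    V[:, 2] -= V[:, 2].min()
    zb = V[:, 2] < 1e-9
    base_xy = V[zb, :2].mean(axis=0)
    V[:, :2] -= base_xy
    max_r = float(np.linalg.norm(V[:, :2], axis=1).max())
    V[:, :2] *= footprint_radius / max_r
    V[:, 2] *= height / V[:, 2].max()

    # in-plane orientation: rotate so one basal node points along -x (toward
    # the anchored side of the plate assembly)
    base_idx = np.flatnonzero(zb)
    angles = np.arctan2(V[base_idx, 1], V[base_idx, 0])
    # choose the basal node whose angle is closest to pi and rotate it onto pi
    target = angles[np.argmin(np.abs(np.abs(angles) - math.pi))]
    rot = math.pi - target
    c, s = math.cos(rot), math.sin(rot)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    V = V @ Rz.T

    struct = _canonical_structure(V, struts, cables, "MT_strut", "MF_cable",
                                  "csk", n_nodes)
    # central particle appended last so csk node ids stay contiguous
    center = struct.positions().mean(axis=0)
    particle = Node3D(len(struct.nodes), tuple(np.round(center, 12)), "center_particle")
    return replace(struct, nodes=struct.nodes + (particle,))


def add_central_if_cables(csk: TensegrityStructure) -> TensegrityStructure:
    """Attach one radial IF cable from every CSK node to the central particle."""
    if any(e.kind == "IF_cable" for e in csk.elements):
        raise DuplicateLinkageError("structure already carries IF cables")
    particles = [n for n in csk.nodes if n.role == "center_particle"]
    if len(particles) != 1:
        raise ValueError("structure must carry exactly one central particle")
    pid = particles[0].id
    new = [ElementSpec("IF_cable", (n.id, pid), "IF_cable")
           for n in csk.nodes if n.role == "csk"]
    elements = tuple(sorted(csk.elements + tuple(new),
                            key=lambda e: (_KIND_ORDER[e.kind], e.nodes)))
    out = replace(csk, elements=elements)
    out.validate()
    return out


def build_spherical_nsk(n_nodes: int, radius: float,
                        center=(0.0, 0.0, 0.0)) -> TensegrityStructure:
    """Sphere-like NSK tensegrity: lamina struts + chromatin cables.

    12 nodes: cuboctahedron (6 struts, 24 cables); 24 nodes: truncated
    octahedron (12 struts, 36 cables).  All nodes lie at ``radius`` from
    ``center``.
    """
    if n_nodes not in (12, 24):
        raise UnsupportedComplexityError(f"unsupported NSK complexity {n_nodes}; choose 12 or 24")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_nodes == 12:
        V, struts, cables = _cuboctahedron()
    else:
        V, struts, cables = _truncated_octahedron()
    V = V * (radius / np.linalg.norm(V[0]))
    V = V + np.asarray(center, dtype=float)
    return _canonical_structure(V, struts, cables, "lamina_strut",
                                "chromatin_cable", "nsk", n_nodes)


def attach_nsk(csk: TensegrityStructure, nsk: TensegrityStructure,
               center_tol: float = 1e-6) -> TensegrityStructure:
    """Couple an NSK into a CSK with one IF linker cable per NSK node.

    Each NSK node links to the CSK node pointing the same direction from the
    shared centre (maximal cosine similarity; ties broken toward the lowest
    CSK node id).  The CSK central particle, if present and unused, is
    removed: the NSK replaces the point-nucleus.
    """
    if csk.complexity != nsk.complexity:
        raise ValueError(f"complexity mismatch: CSK {csk.complexity} vs NSK {nsk.complexity}")
    if any(e.kind == "IF_cable" for e in csk.elements):
        raise DuplicateLinkageError("CSK already carries IF cables; build it without "
                                    "central IFs before attaching an NSK")
    csk_center = csk.centroid(roles=("csk",))
    nsk_center = nsk.centroid(roles=("nsk",))
    if np.linalg.norm(csk_center - nsk_center) > center_tol:
        raise CenterMismatchError(
            f"NSK centre {nsk_center} does not coincide with CSK centre {csk_center}")

    # drop the (unconnected) central particle
    used = {i for e in csk.elements for i in e.nodes}
    keep = [n for n in csk.nodes if n.role != "center_particle" or n.id in used]
    remap = {n.id: k for k, n in enumerate(keep)}
    csk_nodes = [Node3D(remap[n.id], n.position, n.role) for n in keep]
    csk_elems = [ElementSpec(e.kind, tuple(sorted((remap[e.nodes[0]], remap[e.nodes[1]]))),
                             e.material_key) for e in csk.elements]

    off = len(csk_nodes)
    nsk_nodes = [Node3D(n.id + off, n.position, n.role) for n in nsk.nodes]
    nsk_elems = [ElementSpec(e.kind, (e.nodes[0] + off, e.nodes[1] + off), e.material_key)
                 for e in nsk.elements]

    csk_dirs = np.array([n.position for n in csk_nodes if n.role == "csk"]) - csk_center
    csk_dirs /= np.linalg.norm(csk_dirs, axis=1, keepdims=True)
    csk_ids = [n.id for n in csk_nodes if n.role == "csk"]

    linkers = []
    for n in nsk_nodes:
        d = n.xyz - nsk_center
        d /= np.linalg.norm(d)
        cos = csk_dirs @ d
        best = float(cos.max())
        # deterministic tie-break: lowest node id among (near-)maximal matches
        cand = [csk_ids[k] for k in np.flatnonzero(cos >= best - 1e-12)]
        linkers.append(ElementSpec("IF_cable", tuple(sorted((min(cand), n.id))), "IF_cable"))

    nodes = tuple(csk_nodes + nsk_nodes)
    elements = tuple(sorted(csk_elems + nsk_elems + linkers,
                            key=lambda e: (_KIND_ORDER[e.kind], e.nodes)))
    out = TensegrityStructure(nodes, elements, csk.complexity, has_nsk=True)
    out.validate()
    return out


def classify_interface(structure: TensegrityStructure, z_tol: float = 1e-6) -> InterfaceSets:
    """Split the basal interface: pinned nodes at z = 0, basal cables between
    them, and the next z-tier of CSK nodes as spring-anchored nodes."""
    pinned = tuple(sorted(n.id for n in structure.nodes
                          if n.role == "csk" and abs(n.position[2]) <= z_tol))
    if not pinned:
        raise EmptyInterfaceError("no CSK node lies on the plate plane within z_tol")
    pset = set(pinned)
    on_plate = tuple(i for i, e in enumerate(structure.elements)
                     if not e.is_strut and set(e.nodes) <= pset)
    rest = [n for n in structure.nodes if n.role == "csk" and n.id not in pset]
    z_next = min(n.position[2] for n in rest)
    spring = tuple(sorted(n.id for n in rest
                          if n.position[2] <= z_next + max(z_tol, 1e-9 * z_next)))
    return InterfaceSets(pinned, spring, on_plate)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def structure_to_csv(structure: TensegrityStructure, path, rest_lengths=None) -> None:
    """Plain edge list: element id, kind, node ids, initial and rest length."""
    import pandas as pd

    lengths = structure.element_lengths()
    if rest_lengths is None:
        rest_lengths = [math.nan] * len(structure.elements)
    df = pd.DataFrame({
        "element": range(len(structure.elements)),
        "kind": [e.kind for e in structure.elements],
        "node_i": [e.nodes[0] for e in structure.elements],
        "node_j": [e.nodes[1] for e in structure.elements],
        "length0_um": lengths,
        "rest_length_um": rest_lengths,
    })
    df.to_csv(path, index=False)


def structure_to_vtk(structure: TensegrityStructure, path) -> None:
    """Legacy-ASCII VTK unstructured grid: line cells, node-role point data."""
    from .vtk_io import write_vtk_lines

    roles = {"csk": 0, "nsk": 1, "center_particle": 2}
    write_vtk_lines(
        path,
        structure.positions(),
        [e.nodes for e in structure.elements],
        point_data={"role": np.array([roles[n.role] for n in structure.nodes])},
        cell_data={"is_strut": np.array([int(e.is_strut) for e in structure.elements])},
    )
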