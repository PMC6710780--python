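"""Element-level constitutive laws for the cell truss and its adhesions.

Cables (actin microfilaments, intermediate filaments, chromatin) are
tension-only, prestressed axial elements: with current length ``l``,
initial length ``l0`` and resting length ``lr <= l0``,

    F(l) = F0 + Ea*Aa*(l - l0)/lr   for l > lr,      F = 0 for l <= lr,
    F0   = Ea*Aa*(l0 - lr)/lr,

which is continuous at the slack transition (F(lr) = 0) and equals the
initial tension F0 at l = l0.  Struts (microtubules, nuclear lamina) carry
compression only and mirror the cable law with resting length ``Lr >= L0``:

    P(L) = P0 + Es*As*(L0 - L)/Lr   for L < Lr,      P = 0 for L >= Lr,
    P0   = Es*As*(Lr - L0)/Lr,

capped at the Euler axial thrust P_c = pi^2 * B_s / Lr^2 of a pinned strut:
beyond the cap the strut is flagged "buckled" and pushes back with the
constant plateau force P_c (a perfectly-plastic post-buckling idealisation
that keeps static equilibrium well-posed).  Focal-adhesion bonds are linear
bilateral springs of stiffness k_b.

All quantities are in the internal um-nN-kPa system (see :mod:`.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units

__all__ = [
    "CableLaw",
    "StrutLaw",
    "SpringLaw",
    "MaterialTable",
    "default_materials",
    "cable_initial_tension",
    "cable_force",
    "cable_energy",
    "strut_initial_compression",
    "strut_critical_load",
    "strut_force",
    "strut_energy",
    "section_bending_stiffness",
    "spring_force",
    "element_tangent_stiffness",
    "axial_force",
    "axial_stiffness_dNdl",
]

CABLE_KINDS = frozenset({"MF_cable", "IF_cable", "chromatin_cable"})
STRUT_KINDS = frozenset({"MT_strut", "lamina_strut"})


def section_bending_stiffness(E_s: float, A_s: float) -> float:
    """Bending stiffness Es*I of a solid circular section of area As.

    I = pi r^4 / 4 with A = pi r^2 gives I = A^2/(4 pi), hence
    B_s = Es * As^2 / (4 pi).  Units follow the inputs (kPa * um^4 = nN um^2).
    """
    if E_s <= 0 or A_s <= 0:
        raise ValueError("E_s and A_s must be positive")
    return E_s * A_s * A_s / (4.0 * math.pi)


@dataclass(frozen=True)
class CableLaw:
    """Tension-only prestressed cable; lengths in um, E in kPa, A in um^2."""

    E_a: float
    A_a: float
    l_0: float
    l_r: float

    def __post_init__(self):
        if self.l_r <= 0 or self.l_0 <= 0:
            raise ValueError("cable lengths must be positive")
        if self.l_r > self.l_0 + 1e-12 * self.l_0:
            raise ValueError("prestressed cable requires l_r <= l_0")

    @property
    def F_0(self) -> float:
        return cable_initial_tension(self)

    @property
    def axial_rigidity(self) -> float:
        """EA in nN."""
        return self.E_a * self.A_a


@dataclass(frozen=True)
class StrutLaw:
    """Compression-only strut with Euler buckling cap."""

    E_s: float
    A_s: float
    L_0: float
    L_r: float
    B_s: float | None = None  # nN um^2; derived from the section when omitted

    def __post_init__(self):
        if self.L_r <= 0 or self.L_0 <= 0:
            raise ValueError("strut lengths must be positive")
        if self.L_0 > self.L_r + 1e-12 * self.L_r:
            raise ValueError("precompressed strut requires L_0 <= L_r")
        if self.B_s is None:
            object.__setattr__(self, "B_s", section_bending_stiffness(self.E_s, self.A_s))
        elif self.B_s <= 0:
            raise ValueError("B_s must be positive")

    @property
    def P_0(self) -> float:
        return strut_initial_compression(self)

    @property
    def P_c(self) -> float:
        return strut_critical_load(self)

    @property
    def axial_rigidity(self) -> float:
        return self.E_s * self.A_s


@dataclass(frozen=True)
class SpringLaw:
    """Linear bilateral focal-adhesion bond, k_b in nN/um."""

    k_b: float

    def __post_init__(self):
        if self.k_b <= 0:
            raise ValueError("k_b must be positive")


def cable_initial_tension(law: CableLaw) -> float:
    """F0 = Ea*Aa*(l0 - lr)/lr; zero for an unstrained cable."""
    if law.l_r <= 0:
        raise ValueError("resting length must be positive")
    return law.axial_rigidity * (law.l_0 - law.l_r) / law.l_r


def cable_force(l: float, law: CableLaw) -> float:
    """Tension at current length l: F0 + EA*(l-l0)/lr when taut, else 0."""
    if l <= 0:
        raise ValueError("current length must be positive")
    if l <= law.l_r:
        return 0.0
    return law.F_0 + law.axial_rigidity * (l - law.l_0) / law.l_r


def cable_energy(l: float, law: CableLaw) -> float:
    """Stored elastic energy (nN um); quadratic in the stretch beyond lr."""
    if l <= law.l_r:
        return 0.0
    e = l - law.l_r
    return 0.5 * law.axial_rigidity * e * e / law.l_r


def strut_initial_compression(law: StrutLaw) -> float:
    """P0 = Es*As*(Lr - L0)/Lr."""
    return law.axial_rigidity * (law.L_r - law.L_0) / law.L_r


def strut_critical_load(law: StrutLaw) -> float:
    """Euler axial thrust of a pinned strut, P_c = pi^2 B_s / Lr^2."""
    if law.L_r <= 0 or law.B_s <= 0:
        raise ValueError("L_r and B_s must be positive")
    return math.pi**2 * law.B_s / law.L_r**2


def strut_force(L: float, law: StrutLaw) -> float:
    """Compression (positive) at current length L, capped at P_c."""
    if L <= 0:
        raise ValueError("current length must be positive")
    if L >= law.L_r:
        return 0.0
    P = law.axial_rigidity * (law.L_r - L) / law.L_r
    return min(P, law.P_c)


def strut_is_buckled(L: float, law: StrutLaw) -> bool:
    if L >= law.L_r:
        return False
    return law.axial_rigidity * (law.L_r - L) / law.L_r >= law.P_c


def strut_energy(L: float, law: StrutLaw) -> float:
    """Quadratic up to the buckling shortening, then a constant-force plateau."""
    if L >= law.L_r:
        return 0.0
    ea = law.axial_rigidity
    # shortening at which P reaches the cap
    d_c = law.P_c * law.L_r / ea
    d = law.L_r - L
    if d <= d_c:
        return 0.5 * ea * d * d / law.L_r
    return 0.5 * ea * d_c * d_c / law.L_r + law.P_c * (d - d_c)


def spring_force(extension: float, law: SpringLaw) -> float:
    """Linear bond force k_b * extension (sign follows the extension)."""
    return law.k_b * extension


# ---------------------------------------------------------------------------
# signed axial interface used by the solver: N > 0 means the element pulls its
# end nodes together (tension); struts produce N = -P <= 0.
# ---------------------------------------------------------------------------

def axial_force(kind: str, length: float, law) -> float:
    if kind in CABLE_KINDS:
        return cable_force(length, law)
    if kind in STRUT_KINDS:
        return -strut_force(length, law)
    raise ValueError(f"unknown element kind {kind!r}")


def axial_stiffness_dNdl(kind: str, length: float, law) -> float:
    """dN/dl of the signed axial force at the current length."""
    if kind in CABLE_KINDS:
        return 0.0 if length <= law.l_r else law.axial_rigidity / law.l_r
    if kind in STRUT_KINDS:
        if length >= law.L_r or strut_is_buckled(length, law):
            return 0.0
        return law.axial_rigidity / law.L_r
    raise ValueError(f"unknown element kind {kind!r}")


def element_state(kind: str, length: float, law) -> str:
    if kind in CABLE_KINDS:
        return "slack" if length <= law.l_r else "taut"
    if kind in STRUT_KINDS:
        if length >= law.L_r:
            return "slack"
        return "buckled" if strut_is_buckled(length, law) else "compressed"
    raise ValueError(f"unknown element kind {kind!r}")


def element_tangent_stiffness(kind: str, law, x_i: np.ndarray, x_j: np.ndarray) -> np.ndarray:
    """Consistent 6x6 tangent of a 3D two-node axial element at the current
    geometry, material plus geometric part:

        k = (dN/dl) n n^T + (N/l) (I - n n^T),   K = [[k, -k], [-k, k]].

    Slack cables contribute an exact zero block.
    """
    d = np.asarray(x_j, dtype=float) - np.asarray(x_i, dtype=float)
    l = float(np.linalg.norm(d))
    if l <= 0:
        raise ValueError("degenerate (zero-length) element")
    n = d / l
    N = axial_force(kind, l, law)
    dNdl = axial_stiffness_dNdl(kind, l, law)
    nnT = np.outer(n, n)
    k = dNdl * nnT + (N / l) * (np.eye(3) - nnT)
    K = np.empty((6, 6))
    K[:3, :3] = k
    K[3:, 3:] = k
    K[:3, 3:] = -k
    K[3:, :3] = -k
    return K


def element_internal_forces(kind: str, law, x_i: np.ndarray, x_j: np.ndarray) -> np.ndarray:
    """Nodal force 6-vector the element exerts *internally* (to be balanced by
    external loads): a taut element pulls node i toward node j."""
    d = np.asarray(x_j, dtype=float) - np.asarray(x_i, dtype=float)
    l = float(np.linalg.norm(d))
    if l <= 0:
        raise ValueError("degenerate (zero-length) element")
    n = d / l
    N = axial_force(kind, l, law)
    f = np.empty(6)
    f[:3] = -N * n
    f[3:] = N * n
    return f


# ---------------------------------------------------------------------------
# material registry (published values; converted to internal units on access)
# ---------------------------------------------------------------------------

@dataclass
class MaterialTable:
    """Registry of published material parameters.

    ``filaments`` maps element kind -> (E in Pa, Poisson ratio, A in nm^2);
    ``solids`` maps region name -> (E in Pa, Poisson ratio).  The defaults
    reproduce the published table exactly (microtubules 1.2e9 Pa / 190 nm^2,
    microfilaments 2.6e9 / 19, intermediate filaments 2e9 / 100, nuclear
    lamina 1.4e6 / 78.5, chromatin 244e6 / 1.13; plate and joint 4e9 Pa,
    nu = 0.3; bond stiffness 0.025 nN/um).
    """

    filaments: dict = field(default_factory=dict)
    solids: dict = field(default_factory=dict)
    k_b: float = 0.025  # nN/um

    def internal_EA(self, kind: str) -> tuple[float, float]:
        """(E in kPa, A in um^2) for a filament kind."""
        E_pa, _nu, A_nm2 = self.filaments[kind]
        return E_pa * units.PA_TO_KPA, A_nm2 * units.NM2_TO_UM2

    def cable_law(self, kind: str, l_0: float, prestrain: float) -> CableLaw:
        """Cable with resting length lr = (1 - prestrain) * l0."""
        if not 0 <= prestrain < 1:
            raise ValueError("cable prestrain must lie in [0, 1)")
        E, A = self.internal_EA(kind)
        return CableLaw(E_a=E, A_a=A, l_0=l_0, l_r=(1.0 - prestrain) * l_0)

    def strut_law(self, kind: str, L_0: float, prestrain: float) -> StrutLaw:
        """Strut with resting length Lr = (1 + prestrain) * L0."""
        if prestrain < 0:
            raise ValueError("strut prestrain must be non-negative")
        E, A = self.internal_EA(kind)
        return StrutLaw(E_s=E, A_s=A, L_0=L_0, L_r=(1.0 + prestrain) * L_0)

    def spring_law(self) -> SpringLaw:
        return SpringLaw(k_b=self.k_b)

    def solid(self, region: str):
        """(E in kPa, nu) for a solid region (plate / joint)."""
        E_pa, nu = self.solids[region]
        return E_pa * units.PA_TO_KPA, nu


def default_materials() -> MaterialTable:
    return MaterialTable(
        filaments={
            "MT_strut": (1.2e9, 0.3, 190.0),
            "MF_cable": (2.6e9, 0.3, 19.0),
            "IF_cable": (2.0e9, 0.3, 100.0),
            "lamina_strut": (1.4e6, 0.3, 78.5),
            "chromatin_cable": (244e6, 0.3, 1.13),
        },
        solids={
            "plate": (4e9, 0.3),
            "joint": (4e9, 0.3),
        },
        k_b=0.025,
    )
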