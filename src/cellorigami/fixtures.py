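"""Deterministic small instances with closed-form or self-audit expectations.

These are the benchmark problems behind the `validate` command and the
solver unit tests:

* ``unit_cable``   - one prestressed cable under axial load; elongation has
  a closed form (the inverse of the cable law).
* ``unit_strut``   - one precompressed strut; force follows the capped law.
* ``simplex3``     - the minimal three-strut tensegrity prism (6 nodes,
  9 cables, 3 struts) at its equilibrium twist, which possesses a
  self-stress state: prestress equilibration must converge to a fully taut,
  compressed configuration with a near-zero residual.
* ``cantilever_plate`` - plate strip clamped on one edge under an end load;
  tip deflection approaches the Euler-Bernoulli value P L^3 / (3 E I).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ElementSpec, Node3D, TensegrityStructure
from .mechanics import CableLaw, StrutLaw
from .solver import ElementLaws

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("unit_cable", "unit_strut", "simplex3", "cantilever_plate")


@dataclass
class Fixture:
    name: str
    params: dict
    expected: dict
    structure: TensegrityStructure | None = None
    laws: ElementLaws | None = None


def _cable(l0, eps, E=2.6e6, A=19e-6):
    # internal units: kPa, um^2
    return CableLaw(E_a=E, A_a=A, l_0=l0, l_r=(1 - eps) * l0)


def _stiff_strut(L0, eps, E=1.2e6, A=190e-6):
    # B_s chosen large so the Euler cap stays inactive in benchmark runs
    return StrutLaw(E_s=E, A_s=A, L_0=L0, L_r=(1 + eps) * L0, B_s=1e3)


def make_fixture(name: str) -> Fixture:
    if name == "unit_cable":
        l0, eps, F = 2.0, 0.05, 5.0
        law = _cable(l0, eps)
        nodes = (Node3D(0, (0.0, 0.0, 0.0), "csk"), Node3D(1, (l0, 0.0, 0.0), "csk"))
        elems = (ElementSpec("MF_cable", (0, 1), "MF_cable"),)
        s = TensegrityStructure(nodes, elems, 12)
        l_exact = law.l_0 + (F - law.F_0) * law.l_r / law.axial_rigidity
        return Fixture(name, {"load_nN": F},
                       {"length_um": l_exact, "initial_tension_nN": law.F_0},
                       s, ElementLaws([law], ["MF_cable"]))

    if name == "unit_strut":
        L0, eps = 2.0, 0.05
        law = _stiff_strut(L0, eps)
        nodes = (Node3D(0, (0.0, 0.0, 0.0), "csk"), Node3D(1, (L0, 0.0, 0.0), "csk"))
        elems = (ElementSpec("MT_strut", (0, 1), "MT_strut"),)
        s = TensegrityStructure(nodes, elems, 12)
        return Fixture(name, {"prestrain": eps},
                       {"initial_compression_nN": law.P_0, "critical_nN": law.P_c},
                       s, ElementLaws([law], ["MT_strut"]))

    if name == "simplex3":
        # triangular tensegrity prism at its equilibrium twist (pi/6 with
        # this diagonal convention; the familiar 5*pi/6 under the other)
        r, hgt, twist = 1.0, 1.2, math.radians(30.0)
        bot = [(r * math.cos(a), r * math.sin(a), 0.0)
               for a in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)]
        top = [(r * math.cos(a + twist), r * math.sin(a + twist), hgt)
               for a in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)]
        nodes = tuple(Node3D(i, p, "csk") for i, p in enumerate(bot + top))
        cables = ([("MF_cable", (i, (i + 1) % 3)) for i in range(3)] +          # bottom
                  [("MF_cable", (3 + i, 3 + (i + 1) % 3)) for i in range(3)] +  # top
                  [("MF_cable", (i, 3 + i)) for i in range(3)])                 # saddle
        struts = [("MT_strut", (i, 3 + (i + 1) % 3)) for i in range(3)]
        elems = tuple(ElementSpec(k, tuple(sorted(n)), k) for k, n in struts + cables)
        s = TensegrityStructure(nodes, elems, 12)
        # cables shortened 2%, strut resting lengths unchanged: the prism
        # cannot accommodate both, so a genuine self-stress develops
        eps = 0.02
        laws, kinds = [], []
        for e, l0 in zip(s.elements, s.element_lengths()):
            if e.is_strut:
                laws.append(_stiff_strut(float(l0), 0.0))
            else:
                laws.append(_cable(float(l0), eps))
            kinds.append(e.kind)
        return Fixture(name, {"cable_prestrain": eps}, {"max_rel_residual": 1e-8},
                       s, ElementLaws(laws, kinds))

    if name == "cantilever_plate":
        b, h = 30.0, 2.7
        E, nu, P = 4e6, 0.3, 100.0   # kPa, -, nN
        I = b * h**3 / 12.0
        return Fixture(name,
                       {"dims": (b, b, h), "divisions": (20, 10, 2),
                        "E_kPa": E, "nu": nu, "load_nN": P},
                       {"tip_deflection_um": P * b**3 / (3 * E * I),
                        "rel_tolerance": 0.10})

    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
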