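"""Nonlinear solver: closed-form oracles, equilibrium audits, coupling rules."""

import numpy as np
import pytest
from scipy.optimize import brentq

from cellorigami import geometry as geo
from cellorigami import mechanics as mech
from cellorigami import solver as sv
from cellorigami.fixtures import make_fixture
from cellorigami.origami import build_variant_structure
from cellorigami.plate_fem import mesh_plate_with_joint


def two_node_cable(l0=2.0, eps=0.05):
    nodes = (geo.Node3D(0, (0.0, 0.0, 0.0), "csk"), geo.Node3D(1, (l0, 0.0, 0.0), "csk"))
    elems = (geo.ElementSpec("MF_cable", (0, 1), "MF_cable"),)
    s = geo.TensegrityStructure(nodes, elems, 12)
    return s, sv.assign_element_laws(s, mech.default_materials(), eps, 0.0)


def test_single_cable_matches_closed_form():
    """Axially loaded prestressed cable: elongation equals the closed-form
    inverse of the tension law."""
    f = make_fixture("unit_cable")
    model = sv.CoupledModel(cell=f.structure, laws=f.laws, plate=None, plate_K=None,
                            ties=[], springs=[],
                            loads={1: np.array([f.params["load_nN"], 0.0, 0.0])},
                            extra_fixed_cell={0: (0, 1, 2), 1: (1, 2)})
    res = sv.solve_static(model)
    assert res.converged
    l_num = f.structure.positions()[1, 0] + res.cell_displacements[1, 0]
    assert abs(l_num - f.expected["length_um"]) / f.expected["length_um"] < 1e-6
    assert res.element_states == ["taut"]


def test_two_bar_truss_matches_geometric_nonlinear_closed_form():
    """Symmetric two-bar truss under a vertical apex load: the apex height
    solves the scalar large-displacement equilibrium equation (independent
    1D root-find oracle)."""
    a, h0, P = 10.0, 1.0, 2.0
    nodes = (geo.Node3D(0, (-a, 0.0, 0.0), "csk"), geo.Node3D(1, (a, 0.0, 0.0), "csk"),
             geo.Node3D(2, (0.0, 0.0, h0), "csk"))
    elems = (geo.ElementSpec("MF_cable", (0, 2), "MF_cable"),
             geo.ElementSpec("MF_cable", (1, 2), "MF_cable"))
    s = geo.TensegrityStructure(nodes, elems, 12)
    laws = sv.assign_element_laws(s, mech.default_materials(), 0.3, 0.0)
    model = sv.CoupledModel(cell=s, laws=laws, plate=None, plate_K=None,
                            ties=[], springs=[], loads={2: np.array([0.0, 0.0, P])},
                            extra_fixed_cell={0: (0, 1, 2), 1: (0, 1, 2), 2: (1,)})
    res = sv.solve_static(model)
    assert res.converged

    law = laws.laws[0]

    def balance(z):
        l = np.hypot(a, z)
        N = law.axial_rigidity * (l - law.l_r) / law.l_r if l > law.l_r else 0.0
        return 2 * N * z / l - P

    z_exact = brentq(balance, 1e-3, 5.0, xtol=1e-14)
    z_num = h0 + res.cell_displacements[2, 2]
    assert abs(z_num - z_exact) / z_exact < 1e-6


def test_equilibrate_zero_prestrain_is_stress_free():
    f = make_fixture("simplex3")
    laws = sv.ElementLaws(
        [mech.CableLaw(E_a=l.E_a, A_a=l.A_a, l_0=l.l_0, l_r=l.l_0)
         if isinstance(l, mech.CableLaw) else
         mech.StrutLaw(E_s=l.E_s, A_s=l.A_s, L_0=l.L_0, L_r=l.L_0, B_s=l.B_s)
         for l in f.laws.laws], f.laws.kinds)
    res = sv.equilibrate_prestress(f.structure, laws)
    assert np.abs(res.cell_displacements).max() < 1e-9
    assert np.abs(res.element_forces).max() < 1e-12


def test_equilibrate_simplex3_self_stress():
    f = make_fixture("simplex3")
    res = sv.equilibrate_prestress(f.structure, f.laws,
                                   sv.SolverSettings(residual_tol=1e-9))
    assert res.residual_norm <= 1e-8
    assert all(n < 0 for n in res.element_forces[:3])     # struts compressed
    assert all(n > 0 for n in res.element_forces[3:])     # cables taut
    # residual audit is its own oracle
    _, rel = sv.residual(res.model, res.u_expanded)
    assert rel <= 1e-8


def test_equilibrate_reports_mechanism_for_stress_free_relaxation():
    """A prestrained structure that can relax to a compatible slack state
    carries no self-stress; the solver must say so rather than return a
    silent zero."""
    f = make_fixture("simplex3")
    # drop the struts: the remaining cable net can shrink uniformly to its
    # resting lengths and carries no self-stress
    keep = [k for k, e in enumerate(f.structure.elements) if not e.is_strut]
    cables_only = geo.TensegrityStructure(
        f.structure.nodes,
        tuple(f.structure.elements[k] for k in keep), 12)
    laws = sv.ElementLaws([f.laws.laws[k] for k in keep],
                          [f.laws.kinds[k] for k in keep])
    with pytest.raises(sv.NonConvergenceError, match="mechanism"):
        sv.equilibrate_prestress(cables_only, laws)


def test_residual_matches_elementwise_gather():
    """The assembled residual equals a node-wise gather of per-element
    internal forces computed through the scalar mechanics API."""
    s, laws = two_node_cable()
    cell = build_variant_structure("CSK12")
    laws = sv.assign_element_laws(cell, mech.default_materials(), 0.2, 0.2)
    model = sv.CoupledModel(cell=cell, laws=laws, plate=None, plate_K=None,
                            ties=[], springs=[], loads={},
                            extra_fixed_cell={0: (0, 1, 2), 1: (1, 2), 2: (2,)})
    rng = np.random.default_rng(7)
    u = rng.normal(0.0, 0.05, model.n_expanded)
    r, _ = sv.residual(model, u)
    pos = cell.positions() + u.reshape(-1, 3)
    gathered = np.zeros_like(pos)
    for e, law in zip(cell.elements, laws.laws):
        i, j = e.nodes
        fe = mech.element_internal_forces(e.kind, law, pos[i], pos[j])
        gathered[i] += fe[:3]   # gradient convention: r = dE/du
        gathered[j] += fe[3:]
    assert np.abs(r - gathered.ravel()).max() < 1e-12


def test_coupling_counts_and_errors(materials):
    plate = mesh_plate_with_joint()
    for variant, n_tied in (("CSK12", 3), ("CSK24", 4)):
        cell = build_variant_structure(variant)
        laws = sv.assign_element_laws(cell, materials, 0.1, 0.1)
        model = sv.couple(cell, plate, materials.spring_law(), laws, materials)
        assert len(model.ties) == n_tied
        assert len(model.springs) >= 3
    # a far-away cell has no surface node in range
    cell = build_variant_structure("CSK12")
    moved = geo.TensegrityStructure(
        tuple(geo.Node3D(n.id, (n.position[0], n.position[1] + 100.0, n.position[2]),
                         n.role) for n in cell.nodes), cell.elements, 12)
    laws = sv.assign_element_laws(moved, materials, 0.1, 0.1)
    with pytest.raises(sv.CouplingError):
        sv.couple(moved, plate, materials.spring_law(), laws, materials)


def test_traction_loads_parallel_and_balanced(materials):
    cell = build_variant_structure("CSK12")
    laws = sv.assign_element_laws(cell, materials, 0.1, 0.1)
    plate = mesh_plate_with_joint()
    model = sv.couple(cell, plate, materials.spring_law(), laws, materials)
    model = sv.apply_traction_loads(model, 0.01)
    vecs = np.array(list(model.loads.values()))
    assert len(vecs) >= 3
    assert np.abs(vecs[:, 2]).max() == 0.0             # parallel to the plate
    assert np.allclose(np.abs(np.linalg.norm(vecs, axis=1)), 0.01)
    assert np.abs(vecs.sum(axis=0)).max() < 1e-12      # symmetric set sums to zero


def test_global_reaction_balance(csk12_default_result):
    res = csk12_default_result.result
    imbalance = res.global_balance()
    scale = np.abs(res.reactions()).max()
    assert np.abs(imbalance).max() / scale < 1e-8


def test_slack_cables_report_zero_force_and_struts_capped(csk12_default_result):
    res = csk12_default_result.result
    laws = res.model.laws.laws
    for N, state, law in zip(res.element_forces, res.element_states, laws):
        if state == "slack":
            assert N == 0.0
        if isinstance(law, mech.StrutLaw):
            assert -N <= law.P_c + 1e-12


def test_load_step_invariance(materials):
    """Halving the number of load steps leaves the converged fold unchanged
    (conservative system, path independence)."""
    from cellorigami.origami import FoldConfig, run_variant

    a = run_variant(FoldConfig(settings=sv.SolverSettings(n_load_steps=10)))
    b = run_variant(FoldConfig(settings=sv.SolverSettings(n_load_steps=5)))
    assert a.converged and b.converged
    assert abs(a.theta - b.theta) / a.theta < 1e-3


def test_strain_energy_nonnegative(csk12_default_result):
    res = csk12_default_result.result
    prob = sv._ReducedProblem(res.model)
    arrays = sv._element_arrays(res.model, res.model.laws.ramped(1.0))
    lengths = np.linalg.norm(
        np.diff((res.model.cell.positions() + res.cell_displacements)[prob.idx],
                axis=1).squeeze(axis=1), axis=1)
    idx, ea, lr, Pc, is_strut = arrays
    E = sv._truss_energy(lengths, ea, lr, Pc, is_strut)
    assert E >= 0.0
    # slack elements contribute nothing
    slack = np.array([st == "slack" for st in res.element_states])
    E_active = sv._truss_energy(np.where(slack, lr * 0.5, lengths), ea, lr, Pc, is_strut)
    assert E_active == pytest.approx(E)
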