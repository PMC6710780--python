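# Methods

## Model overview

An adherent cell is idealised as a prestressed tensegrity truss coupled to
an elastic microplate.  Three ingredients define the mechanics:

1. **Element laws.**  Cables (actin microfilaments, intermediate filaments,
   chromatin) carry tension only; with initial length `l0` and resting
   length `lr = (1 - eps_c) l0` the tension is `F = EA (l - lr)/lr` for
   `l > lr` and zero otherwise, which equals `F0 + EA (l - l0)/lr` with the
   initial tension `F0 = EA (l0 - lr)/lr` and is continuous at the slack
   transition.  Struts (microtubules, nuclear lamina) mirror the law in
   compression with `Lr = (1 + eps_s) L0`, capped at the Euler axial thrust
   `P_c = pi^2 B_s / Lr^2` of a pinned column.  Beyond the cap the element
   is flagged buckled and exerts the constant plateau force `P_c` — a
   perfectly-plastic post-buckling idealisation that keeps static
   equilibrium well-posed without modelling post-buckling shapes.  The
   bending stiffness `B_s = E A^2/(4 pi)` is derived from the cross-section
   as a solid circular rod (overridable per element).  Focal-adhesion
   bonds are linear bilateral springs (`k_b = 0.025 nN/um`) acting on the
   displacement difference between a cell node and its plate anchor.

2. **Geometry.**  Flat cytoskeletons rest on the plate plane `z = 0`: the
   12-node cell is the classic 6-strut tensegrity on the icosahedron edge
   graph, oriented with an all-cable triangular face down (3 basal nodes +
   3 basal cables); the 24-node cell is the truncated-octahedron vertex set
   (36 edges as cables, 12 antipodal diagonals as struts) with a square
   face down (4 + 4).  Both are scaled to a 12 um maximum horizontal radius
   and flattened to 6 um apex height so the cell fits the 30 um plate.
   Nucleoskeletons are sphere-like: cuboctahedron (12 nodes, 6 struts, 24
   cables) or truncated octahedron (24, 12, 36), centred on the
   cytoskeleton centroid.  Exact node coordinates for these flat
   tensegrities are not published anywhere we know of; correctness is
   therefore audited by element counts, interface counts, connectivity,
   point-group symmetry of the nucleoskeletons and self-stress
   equilibration, not by coordinate comparison.

3. **Plate.**  The microplate (b x b x h = 30 x 30 x 2.7 um) and flexible
   joint (b x w x t = 30 x 6 x 0.3 um, top surfaces flush) are isotropic
   linear-elastic (E = 4 GPa, nu = 0.3) 8-node hexahedra with 2x2x2 Gauss
   quadrature.  Fully integrated trilinear bricks shear-lock severely on
   the thin joint (element aspect ratio ~ 20), so the default element adds
   Wilson incompatible bending modes, statically condensed with the
   centroid-Jacobian correction; the meshes here are rectangular, for which
   this element passes the constant-strain patch test exactly.  The joint's
   far face (x = -w) is clamped: it stands for the rigidly anchored,
   substrate-bound side of the assembly.  Plate kinematics are linear
   small-strain (folds stay well under the 120-degree ceiling and the
   measured angles here are <= ~13 degrees); the cell truss is fully
   geometrically nonlinear (total-Lagrangian).

## Coupling and loads

Basal cell nodes (`|z| <= 1e-6 um`) are pinned: each shares displacements
with the nearest top-surface mesh node of the joint+plate (tie-break:
lowest node id; the small in-plane offset to the nearest grid node is
accepted and logged).  A node whose footprint lies over the clamped
half-space (x <= -w) pins to rigid ground instead — this is what gives the
cell a force path across the hinge; a self-equilibrated force system applied
entirely to the free plate transmits zero net moment through the joint and
nothing would fold.  The next z-tier of cytoskeleton nodes (3 for the
12-node cell, 4 for the 24-node) attaches through zero-rest-length
focal-adhesion springs.  A concentrated contractile force of 10 pN per node
is applied at the cell nodes farthest from the plate (maximal z), directed
parallel to the plate toward the cell's central axis.

## Solution scheme

The plate is linear, so its (constant) stiffness is condensed exactly — a
one-time sparse factorisation and Schur complement onto the ~100-150
degrees of freedom that the truss and springs touch.  The remaining small
dense nonlinear system is solved by Levenberg-regularised Newton with the
consistent tangent (material + geometric); when slack cables and
force-capped buckled struts drive the tangent towards singularity (the
structure degenerates into a cable net with constant-force props), the step
falls back to diagonally preconditioned L-BFGS descent on the total
potential energy — the classic robust treatment of prestressed cable-net
equilibrium — and Newton then polishes the result.  Convergence demands a
relative residual (infinity norm over free DOFs, scaled by the larger of
the external-load scale and the mean element force) below `1e-6`.

Prestrain is a *state* (a resting-length misfit), not a load, and is
applied in full from the first increment; only the external traction ramps
over the (default 10) load steps, with adaptive bisection on failure.
Ramping the resting lengths as well is available as an option
(`SolverSettings.ramp_prestrain`) but keeps many cables exactly at their
slack kink along the whole path — a degenerate manifold that slows every
iteration scheme; both paths reach the same equilibrium to all printed
digits, as expected for a conservative system, and the test suite checks
load-step invariance explicitly.  A stabilisation stiffness of `1e-8` times
the stiffest element's `EA/lr` enters the Newton direction only; residuals,
equilibria and audits are computed without it.  Nothing in the pipeline is
random.

## Folding angle and its ceiling

`theta` is obtained from a least-squares plane fit to the deformed top
surface of the folding plate, parametrised by the material (initial)
in-plane coordinates so the measure stays single-valued at arbitrary
rotations; the reported angle is the tilt of the fitted plane about the
joint axis, positive toward the cell.  The plate's own slight bending is
thereby averaged; per-node deviations remain available from the
displacement field.  The analytic ceiling `theta_max = w/(h + t/2)`
(~120.6 degrees for the default joint, quoted as 120 degrees) marks
plate-base contact; the synthetic rigid-rotation tests confirm the measure
reproduces imposed angles to 1e-9 degree and agrees with the ceiling at the
contact configuration.

## Calibration: the one free parameter

The published tables fix every stiffness and geometry except the
cytoskeletal resting lengths, i.e. the prestress.  A single scalar
prestrain (`eps_c = eps_s`, cables shortened and struts lengthened by the
same fraction) is the model's one free parameter, found by a Brent
root-find so the 12-node cytoskeleton model folds 12.4 degrees; the shipped
default is `0.9995430545892622`.  The other three variants run with the
identical configuration and are predictions.

The calibrated value is extreme, and deliberately so: it is an *effective*
parameter absorbing everything the published description leaves open.
Folding a 4 GPa, 0.3 um-thick joint by 12.4 degrees requires a moment of
roughly `E I theta / w ~ 1e4 nN um`, i.e. of order 1 uN of traction at the
adhesion sites — orders of magnitude beyond both the 10 pN applied loads
and the Euler-capped strut forces (`P_c ~ 1e-4 nN` at cell scale, so the
struts buckle immediately and the free-floating prestressed cell cannot
hold large self-stress).  Only the cable prestress, whose initial tension
`F0 = EA eps/(1 - eps)` is unbounded as `eps -> 1`, can supply the moment
through the adhesion anchors, and the root-find correspondingly drives
`eps` close to 1.  The fold amplitude is therefore best read as calibrated,
and the cross-variant *comparisons* as the model's content.

## Model comparison and a known divergence

Under the shared calibrated configuration the four variants fold

| variant | theta (deg) |
|---|---|
| 12-node CSK | 12.40 |
| 24-node CSK | 2.46 |
| 12-node CSK + NSK | 6.67 |
| 24-node CSK + NSK | 1.51 |

Two robust orderings hold across a wide prestrain band: higher complexity
folds less (the 24-node structures distribute prestress over more elements
and more degrees of freedom), and every fold stays far below the contact
ceiling.

The nucleoskeleton effect comes out with the opposite sign to the reported
finding that a nucleoskeleton *increases* the fold.  In this architecture
the only difference between the variants is the nucleus representation: a
free point particle receiving all radial intermediate filaments, versus a
deformable shell whose chromatin cables have EA = 0.28 nN and whose lamina
struts are Euler-capped at ~1e-6 nN.  Each linker pulls its cytoskeleton
node along exactly the same line as the point-nucleus filament would (the
matched shell node lies on the ray to the centre), but the weak shell
yields where the point hub merely redistributes, and the fold decreases for
every shell radius tested, approaching the cytoskeleton-only value from
below as the radius shrinks to zero.  With the published chromatin/lamina
stiffnesses we found no parameter-free reading of the geometry that
reverses this, and we chose not to tune hidden parameters toward the
reported ordering; the corresponding acceptance test is left failing with
this analysis as its record.

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| plate b, h | 30, 2.7 um | published microplate dimensions |
| joint w, t | 6, 0.3 um | published joint dimensions |
| cell footprint radius | 12 um | cell fits the 30 um plate |
| cell height | 6 um | flat adherent morphology, h/R = 0.5 |
| NSK radius | min(footprint/3, 0.45 x height) = 2.7 um | nucleus contained inside the cell volume |
| traction | 0.01 nN/node | published 10 pN concentrated force |
| k_b | 0.025 nN/um | published bond stiffness |
| prestrain | 0.99954... | calibrated (see above) |
| mesh resolution | 3 um | ~500 hexes; cantilever benchmark within 10% of beam theory |
| residual tol | 1e-6 relative | comfortably below any reported digit |

## Numerical choices, degenerate inputs, limitations

* Ties/ground couplings are resolved by nearest-neighbour with a
  lowest-id tie-break; coupling fails loudly when no surface node lies
  within twice the local mesh spacing.
* Slack/taut and intact/buckled branch points are continuous in force;
  tangents are discontinuous there, which the Levenberg regularisation and
  energy descent absorb.
* A prestrained structure that relaxes to a compatible stress-free state
  (a finite mechanism) is reported as such by `equilibrate_prestress`
  rather than returned as a silent zero.
* Zero-length elements, inverted hexahedra, empty interfaces, unknown
  complexities and malformed configurations raise typed errors.
* Limitations: linear-elastic constituents only (no viscoelasticity or
  strain-stiffening), no post-buckling strut shapes, no plate self-contact
  at large folds, no substrate contact below z = 0, single cells only.
  The plate is geometrically linear; at the measured angles (<= ~13 deg)
  the rotation error is < 1-2%, but the folding-angle measure itself
  remains valid to the 120-degree ceiling.

## What the benchmarks do and do not show

The test suite validates each tier against independent oracles: scalar
closed forms for single elements, a 1D root-find for the geometrically
nonlinear two-bar truss, the three-strut tensegrity prism's self-stress,
an independently coded quadrature oracle and constant-strain patch test
for the hexahedron, Euler-Bernoulli beam theory for the cantilevered
plate, and global reaction/load balance and load-step invariance for the
coupled solve.  These demonstrate that the implemented equations are
solved correctly; they do not validate the tensegrity idealisation of a
real cell, for which the unpublished coordinates, prestress distribution
and adhesion layout remain modelling choices.
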