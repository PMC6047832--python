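# Methods

## Model

The package simulates the mechanochemical patterning of an early embryonic
tissue sphere (blastula): a hollow, one-cell-thick spherical wall of
biological cells in which

1. a single diffusing morphogen at concentration `C` induces active apical
   or basal constriction of each biological cell, and
2. local tissue stretch induces morphogen production.

Together these form a positive feedback loop with mechanics supplying the
long-range inhibition (a constricting, curving patch forces its
surroundings to bend the other way, where stretch — and hence production —
vanishes).  No diffusing inhibitor is needed; regular morphogen/curvature
patches or a single gastrulation-like invagination emerge spontaneously
from noisy initial conditions.

### Mechanics

The tissue is a compressible, isotropic Saint-Venant-Kirchhoff solid on the
reference (Lagrangian) domain, with the multiplicative active-strain split

    F = Fe Fa,      Ee = (Fe^T Fe - I)/2,
    Sigma_e = lambda tr(Ee) I + 2 mu Ee,
    Sigma   = Ja Fa^-1 Sigma_e Fa^-T,      P = F Sigma,

so only the elastic accommodation `Fe` generates stress; the intermediate
configuration produced by `Fa` is stress-free.  Quasi-static balance
`-div(F Sigma) = 0` holds with zero-traction boundaries on both wall
surfaces.

The active tensor is defined per biological cell in the cell's local frame
(origin at the cell centroid `m`, rotation `Q` whose third axis points
radially outward):

    Fa_hat = I + k C B(X_hat),    B = [[X2, 0, X0], [0, X2, X1], [0, 0, 0]],
    Fa     = Q^T Fa_hat(Q X - Q m, C) Q.

`Fa_hat` is the gradient of the wedge-shaping map
`(X0 (1+kCX2), X1 (1+kCX2), X2)`: with `k > 0` the tangential extent
shrinks on the lumen-facing side (apical constriction), with `k < 0` on the
outward side (basal).  `det Fa_hat = (1 + kCX2)^2`, so the cell-integrated
active volume change cancels at first order in `kC` (the centroid sits at
the local origin); the exact residual defect is `(kC)^2 <X2^2>`, bounded by
`(kC h/2)^2` for radial cell extent `h`.  The derivation that drops this
quadratic term treats the construction as exactly volume-preserving; the
implementation and its property tests treat preservation as first-order
only, which is what actually holds.

A one-sided variant (`volume_preserving = False`) clamps the tangential
factor at 1: the constricting half of the cell behaves as above while the
other half stays passive (`det Fa <= 1` where active).  Equivalently, the
active map only acts at points where it would constrict.

An empirical note on sign conventions: with the radially-outward local
axis, constriction of one cell side bends the tissue patch toward the
constricted side.  Basal (`k < 0`) morphogen patches therefore deform
*inward* (toward the lumen), and apical coupling drives outward-directed
patch deformation whose complement develops into the inward invagination,
with morphogen concentrated in a ring around it.

### Chemistry

Transport is formulated on the reference domain (Lagrangian form of mass
conservation in the deforming tissue):

    J dC/dt - div( J F^-1 D F^-T grad C ) - J R = 0,

with homogeneous Neumann boundaries.  The diffusion tensor is radially
anisotropic,

    D(X) = D_N N N^T + D_T (I - N N^T),      N = X/|X|,

fast along the apico-basal cell axis (`D_N`, intracellular) and slow
tangentially (`D_T`, across cell boundaries).  The projector form is used
as the canonical implementation because it involves no arbitrary choice of
tangential basis; the equivalent rotation-matrix construction is kept as an
independent cross-check.

The reaction couples the volume-change invariant `I3(F) = det F` to
production through saturating Michaelis-Menten kinetics:

    R = k2 * s/(km + s) - k1 C,      s = max(I3(F) - 1, 0).

Production is off under compression, reaches `k2/2` at `s = km` and
saturates at `k2`.  The reaction hook also accepts a precomputed scalar
mechanical cue so alternative invariant feedbacks can be plugged in;
feedbacks on the (discontinuous) stress invariants would require adaptive
meshing and are out of scope.

## Geometry and discretisation

The wall is meshed as a cubed sphere: 6 patches x `n_face`^2 biological
cells, each cell `refine`^3 trilinear hexahedra (one cell thick radially;
`refine + 1` uniformly spaced radial node layers between `r_inner` and
`r_outer`).  Cube surface points are projected by radial normalisation of
an equally spaced cube grid.  Seam nodes are merged exactly via integer
lattice keys, so meshing is bit-deterministic; node counts follow
`(6 (n_face*refine)^2 + 2)(refine + 1)`.  The standard discretisation
(`n_face = 16, refine = 4`, radii 150/135 um) has 1536 biological cells,
98304 elements and 122890 nodes; the verification refinement
(`refine = 8`) has 786432 elements.  Element-local node ordering follows
the standard VTK 8-node hexahedron convention (bottom quad counter-
clockwise seen from the outward layer, then top quad), which is also what
the VTU writer emits.

Q1 isoparametric elements with 2x2x2 Gauss quadrature carry both the
vector displacement and the scalar concentration; a triquadratic Q2 space
(27-node elements, 3x3x3 quadrature, mid-nodes placed exactly by the
cube-to-sphere chart) exists for verification studies only.

Time stepping: implicit Euler for transport; the quasi-static structural
equation is stabilised by a pseudo-inertial term `rho_stab u_tt`
discretised with the three-level variable-step second difference, plus a
velocity-damping companion term `rho_stab * gamma * (u^n - u^{n-1})/dt^2`
(`gamma = 1` by default).  The damping removes the slow ringing of
long-wavelength elastic modes that the plain second difference leaves
under-damped; both terms vanish identically at stationarity, so stationary
patterns solve the quasi-static problem.  `rho_stab` defaults to
`E (dt_target / r_outer)^2`, i.e. the elastic timescale
`sqrt(rho/E) r_outer` equals one target time step: elastic transients relax
within a step and the six rigid-body modes of the pure-Neumann structural
block remain regularised.

The monolithic Newton linearisation is analytic and consistent, including
both coupling blocks (structure w.r.t. `C` through `Fa(C)`; transport
w.r.t. `u` through `J`, `F^-1 D F^-T` and `I3(F)`), and is verified against
finite differences to 1e-8 relative error.  Linear systems are solved by
sparse LU after symmetric diagonal equilibration (mixing Pa-scale and
concentration-scale rows otherwise forces off-diagonal pivoting and
catastrophic fill).  Across time steps the factorisation is reused (chord
Newton) and refreshed on slow contraction, on dt changes, or every
`refresh_every` steps; a linear predictor extrapolates the previous step as
the Newton start guess.  The start-up phase (incompatible initial data
u = 0, C = C0) holds a small `dt_initial` for `n_startup_steps` steps, then
dt grows geometrically to `dt_target` on fast convergence and halves on
slow convergence.

Negative concentrations from discretisation undershoot are clipped to zero
after each accepted step and the clipped mass is logged in the trajectory.

## Units and parameters

Internal units: micrometre, second, pascal.  Concentrations are rescaled
to O(1) (the physical scale, up to 1e9 mol m^-3, is immaterial: only the
product `k C` enters the mechanics).  Defaults:

| parameter | value | meaning |
|---|---|---|
| E, nu | 100 Pa, 0.4 | Young's modulus, Poisson ratio (material scale drops out of the stationary patterns) |
| D_N | 1 um^2/s (1e-12 m^2/s) | radial (intracellular) diffusivity |
| D_T | 0.01 um^2/s (1e-14 m^2/s) | tangential (cell-to-cell) diffusivity |
| k1 | 1e-4 /s | morphogen degradation |
| k2 | 0.01 /s (1e7 mol m^-3 s^-1 at the 1e9 scale) | maximal stretch-induced production |
| km | 2.0 | half-saturation of the production argument s = I3(F) - 1 |
| k_couple | -0.01 /um (basal) | concentration-to-constriction coupling |

On `km`: the production term is implemented exactly as the saturating form
above, so half production occurs at `s = km`; a textual statement that half
production is reached at a stretch invariant of 2.0 is read as the
production argument reaching `km`.

On `k_couple`: the printed coupling constant (order 1e-6 in mol^-1 m) is
not dimensionally consistent with `k C X2` being dimensionless, and its
naive rescaling (k ~ 1e-3 /um at O(1) concentrations) leaves the feedback
loop subcritical — morphogen decays and no pattern forms.  Since only the
scale of the product `k C X2` is meaningful, the default was calibrated
once by scanning k over {1e-3, 4e-3, 1e-2} /um on the reduced basal
scenario: 1e-2 /um is supercritical and saturates at `C_max ~ 6`, keeping
the admissibility margin `|k C| h/2 ~ 0.45 < 1` while producing ~10
regular patches.  The magnitude 0.01 /um is the package default for both
signs of the coupling.

## Scenarios

Presets reproduce the study's experiments: `fig2_basal` (basal
constriction, random per-cell initial morphogen, regular patches),
`fig3_apical` (apical coupling, gastrulation-like invagination that ends in
Newton breakdown — reported as a graceful `mechanical_collapse` exit with
the last valid state preserved), and the robustness variants
`fig4a`/`fig4b` (doubled/halved thickness: r_inner 120/142.5 um),
`fig4c` (384 biological cells at half radius), `fig4d`/`fig4e` (tangential
diffusion quartered/zero) and `fig4f` (one-sided, non-volume-preserving
constriction).

Initial conditions: `random-per-cell` (one uniform draw in [0, amplitude]
per biological cell; cell-boundary nodes take the mean of the adjacent
cells' draws), `spot` (one polar cell at amplitude), `gradient` (linear in
z).  One master seed drives all randomness through spawned child streams.

### Reduced (desk-scale) variants

Every preset has a `*_reduced` variant used by the test suite: the mesh
shrinks to `n_face = 8, refine = 2` (384 biological cells, 3072 elements,
18456 unknowns), the target step grows to `dt_target = 4000 s` (the fully
implicit discretisation tolerates it; patterns saturate after ~5 model
days), Newton solves to a correspondingly coarser tolerance (relative 1e-2
with an absolute floor of 1e-6 on the scaled residual, both well below
the implicit-Euler truncation error at this step size), and stationarity is declared when the relative
change of both ||u|| and ||C|| stays below 5e-3 over a 25-step (~1.2 model
day) window.  These are numerical-budget choices, not physics changes; all
physical parameters keep their defaults.  A reduced basal run reaches a
stationary pattern of 11-12 patches in roughly 200-350 steps (a few
minutes on one CPU).

## What the experiments do and do not show

The reduced runs demonstrate the qualitative claims — spontaneous
patterning, robustness to seeds and initial conditions, patch-size control
by tangential diffusion, thickness-wavelength trend, and apical
invagination — on a coarse mesh with large time steps.  They do not
reproduce paper-scale patch counts (a 1536-cell sphere at dt = 20 s resolves
finer patterns), quantitative wavelengths, or any biological tissue's
parameters; the synthetic initial conditions are uncorrelated per-cell
noise, not measured morphogen fields.  Mesh-construction counts, kernel
oracles, conservation and convergence checks, by contrast, are exact or
asymptotic statements about the discretisation itself.

## Numerical edge cases

* `1 + k C X2 <= 0` inverts the active map; assembly raises a diagnostic
  naming the biological cell, and the Newton line search treats such trial
  states as inadmissible.
* `det F <= 0` (element inversion) likewise rejects the trial state; if no
  admissible step exists even at the minimum dt the run exits with
  `mechanical_collapse`, preserving the last valid state — this is the
  expected end of strong-coupling apical runs.
* Patch detection thresholds at the midpoint of the field's min/max by
  default (shift-invariant); patch areas use barycentric vertex areas on
  the fixed-diagonal triangulation of the surface quads.  Discrete mean
  curvature (cotangent Laplacian) is accurate to a few percent on the
  reference sphere away from the eight cubed-sphere corner vertices.
* Correlation of fields with (numerically) zero variance raises an
  undefined-correlation error rather than returning a value.

## Known limitations

* No reference-configuration updating ("cell memory" relaxation): cells
  remember their initial shape indefinitely.
* No inner-volume (lumen) constraint; deep invaginations therefore always
  end in breakdown rather than stabilising.
* The paper-scale presets (85000+ steps) are provided but take CPU-days;
  the test suite only exercises the reduced variants.
* Single-threaded: no MPI, multigrid or parallel ILU; the sparse direct
  solver limits feasible meshes to ~10^5 unknowns.
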