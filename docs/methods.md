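# Methods

`mmpinv` simulates cancer-cell invasion of the extracellular matrix (ECM)
mediated by matrix-degrading enzymes (MMPs), combining two layers: a
cell-scale homogenization step that turns tissue microstructure into an
effective diffusivity law for soluble enzymes, and a tissue-scale mixture
model of invasion integrated with an IMEX finite-element scheme.

## The homogenization layer

### Model

At the cell scale the tissue is idealised as a periodic array of cells
(discs in 2d, spheres in 3d) embedded in ECM.  Soluble MMPs diffuse only
through the ECM pore space `Y_e` of the unit cell `Y = [0, L]^d` and see the
cell surfaces as impermeable.  The effect of the obstacles on macroscopic
diffusion is captured by the corrector problems: for each direction `e_j`
find the Y-periodic `w^j` with zero pore mean such that

    div( Dbar (grad w^j + e_j) ) = 0   in Y_e,
    Dbar (grad w^j + e_j) . nu  = 0    on the cell surfaces,

and the homogenized tensor

    D_ij = (1/|Y_e|) int_{Y_e} Dbar ( delta_ij + d w^j / d y_i ) dy .

This is the *intrinsic* (pore-averaged) tensor: it equals `Dbar I` for an
unperforated cell and its eigenvalues lie in `[0, Dbar]`.  Multiplying by
the ECM fraction `phi = |Y_e| / |Y|` gives the *superficial* (full-cell
averaged) tensor, the quantity that appears when the macroscopic balance is
written for the total concentration.  Both conventions are in circulation;
`diffusivity_table(..., average="pore" | "cell")` exposes the choice.  The
bundled 2d study uses the cell average and the 3d study the pore average —
each choice reproduces the corresponding reported cubic law; the package
makes the switch explicit rather than hiding one convention.

### Geometries and the diffusivity law

The study geometries are `n^d` inclusions of radius `r` on the uniform
lattice `((2i-1)L/(2n))` per axis, with `r = 3L/40` (2d, `n = 1..6`) and
`r = 3L/25` (3d, `n = 1..4`), giving analytic ECM fractions
`1 - n^d w_d (r/L)^d` from 0.982 down to 0.364 (2d) and 0.993 down to 0.537
(3d).  For each geometry the tensor is computed, its isotropy checked
(symmetric lattices must give diagonal spread < 1% and off-diagonals at
least two orders below the diagonal mean; `diffusivity_table` rejects
geometries beyond a 5% spread as a symptom of a bad mesh), and the diagonal
mean taken as the scalar diffusivity.  A zero-intercept cubic

    D_s(phi) = (a3 phi^3 + a2 phi^2 + a1 phi) * D_s(1)

is then fitted by least squares over the computed `(phi, D)` points plus
`(0, 0)` (no diffusion through cell-occupied tissue) and, by default,
`(1, 1)` (exact for the unperforated cell; both reported laws have
coefficient sums of exactly 1.00, consistent with this point being pinned).
The fitted law is rejected unless strictly positive on `(0, 1]`.

A caution on reproducibility of the *coefficients*: the zero-intercept cubic
fit over a handful of support points is ill-conditioned — its pseudo-inverse
amplifies a 0.01 change in one 3d diffusivity value into coefficient shifts
of ~0.3.  The diffusivity *values* are the robust quantity; the package's
2d values agree with the Perrins–McKenzie–McPhedran square-lattice
conductivity expansion to 0.1% and the 3d values converge under mesh
refinement (verified by Richardson extrapolation over three resolutions).

### Meshing perforated cells

No external mesh generator is used.  Meshes come from a structured
background grid — a crossed (union-jack) triangulation in 2d, chosen for its
mirror and 90-degree symmetry, which makes the discrete tensors of
symmetric microstructures diagonal to machine precision; a Kuhn 6-tet
subdivision in 3d — carved by a conforming level-set cut:

1. vertices within `0.25 h` of an inclusion surface are snapped onto it
   (outer-boundary vertices are never moved), which bounds the quality of
   cut fragments away from zero;
2. cells entirely inside an inclusion are dropped;
3. cells crossed by a surface are cut along the zero set of the *linearly
   interpolated* signed distance.  That zero set is a plane per simplex, so
   each kept fragment is the intersection of a simplex with a half-space —
   convex, and triangulated by closed-form corner/prism splits.  Quad faces
   are split along the diagonal through their minimum global vertex index
   (the classical rule of Dompierre et al.), so neighbouring cells agree
   and the mesh stays conforming.

Hole-boundary vertices lie on the interpolated surface (snapped ones
exactly on it), making the polygonal holes inscribed up to `O(h^2)`; the
builder verifies the meshed pore volume against the analytic ECM fraction
to 2% and raises otherwise.  The cut never creates outer-boundary vertices,
so opposite faces carry identical vertex traces and the periodic
identification is total; corner vertices resolve transitively to the single
all-minimal corner.

Grid divisions per axis default to 192 (2d) and 36 (3d), rounded up to a
multiple of `2n` so inclusion centres and the mid-planes between inclusions
fall on grid planes (the mid-planes keep the narrow gaps between
near-touching spheres open in the carved mesh).  These defaults are the
coarsest that pass the 2% pore-volume check on every study geometry; the
convergence of the resulting diffusivities was checked by refinement.

## The finite-element core

P1 Lagrange elements on simplicial meshes, assembled vectorised over cells.
Two numerical choices deserve note:

* **Exact integration instead of quadrature tables.**  Every right-hand
  side of the invasion scheme is (after nodal interpolation of the Hill
  factors) a product of at most three P1 fields times a test function.
  Such integrals have the closed form
  `int_T prod lambda_i^{a_i} = d! |T| prod(a_i!) / (d + sum a_i)!`, applied
  through precomputed reference tensors, so degree-4 integrands are
  integrated exactly.  Stiffness matrices with a cubic-in-`phi` coefficient
  use the exact per-cell average of the coefficient (P1 gradients are
  cellwise constant), evaluated via homogeneous symmetric sums.
* **Singular solves.**  The periodic corrector systems are pure-Neumann
  problems with the constants as kernel.  The rhs compatibility defect
  `sum(b)` is checked explicitly before solving (an incompatible rhs is a
  correctness signal, not something to project away silently); the system
  is then solved by grounding one degree of freedom, shifting to zero
  weighted mean, and verifying the residual of the unmodified singular
  system, which fails loudly if the kernel is larger than the constants
  (e.g. a disconnected pore).  2d systems use a sparse direct factorization;
  3d systems use Jacobi-preconditioned conjugate gradients (relative
  tolerance 1e-10), since the multiplier-free singular systems are SPD and
  3d direct factorizations fill in badly.

## The invasion model

State: ECM volume fraction `phi` (tumour fraction `1 - phi`), soluble MMP
concentration `cs`, bound-MMP mass `b = c_b (1 - phi)`, and matrix
suitability `s` in `[0, 1]` (`s = 1` least suitable; only bound enzymes
lower it).  Dynamics:

    phi_t = -(1-s) mu_b phi b - (1-s) mu_s phi cs
    cs_t  - div(D_s(phi) grad cs)
          = kappa_s f_s(cs)(1-phi) - (1-s) mu_s phi cs - beta_s cs
    b_t   = kappa_b f_b(phi)(1-phi) - (1-s) mu_b phi b - beta_b b
    s_t   = -delta_s b s

with Hill factors `f_b(phi) = phi/(1+phi)`, `f_s(cs) = 1/(1+cs)`, zero-flux
boundary conditions for `cs`, and `s = 0` identically when suitability is
off.  The *product* `b` is the evolved unknown — every occurrence of `c_b`
in the model is multiplied by `(1 - phi)`, so no division by the vanishing
tumour-free fraction ever occurs; `c_b` is reconstructed only for
visualization as `b / max(1-phi, 1e-10)`.

Default parameters (nondimensional): `kappa_s = 4`, `kappa_b = 5`,
`mu_s = mu_b = 1` (an alternative literature value 8.15 is configurable),
`beta_s = beta_b = 0.1`, `delta_s = 1`, `D_s(1) = 1.29e-2`.

### Time stepping and monitors

One IMEX step of size `tau` performs, in order: (1) a mass solve for the new
`phi` with explicit reactions; (2) the `cs` solve with implicit diffusion,
`(M + tau K(D_s(phi_new))) cs_new = ...`, the stiffness assembled from the
*freshly updated* `phi` (the exact per-cell average of the cubic law is
clipped at zero against the `O(tau)` nodal undershoot of `phi`); (3) a mass
solve for `b`; (4) a mass solve for `s`.  Mass matrices are consistent by
default (lumping is available as an option; lumping buys strict positivity
of the explicit updates at the cost of extra numerical dissipation).
`M + tau K` is SPD for any positive-semidefinite `K`, so the implicit solve
stays well-posed even where `phi -> 0` makes the diffusion degenerate.

The continuum solution satisfies `0 <= phi <= 1`, `0 <= cs <= M_s`,
`0 <= b <= M_b` with `M_s = max(M_{s,0}, kappa_s/beta_s)` (= 40 at the
defaults) and `M_b = max(M_{b,0}, kappa_b/beta_b)` (= 50), plus the
exponential floor `phi >= delta_0 exp(-(mu_b kappa_b/beta_b +
mu_s kappa_s/beta_s) T)` when the initial ECM fraction is bounded below by
`delta_0 > 0`.  The runtime monitor checks all of these each step at a
default tolerance of 1e-6 (the explicit reaction treatment can overshoot at
`O(tau)`); the floor check is skipped for the bundled scenarios, whose
initial data touch `phi = 0` and make the floor vacuous.  The scheme is
first-order in time; this is verified against an independent reduced-ODE
oracle (spatially homogeneous data collapse every FE operator to a mass
matrix).

### Scenarios

Four closed-form scenario families on `[-1, 1]^d` (`tau = 1e-2`, `T = 5`
default; the congruent `(0, 2)^d` frame is not rescaled to):

* `ellipse2d` / `ellipsoid3d`: tumour seed at the origin,
  `phi_0 = 1 - exp(-((4 x1)^2 + (8 x2)^2))` (3d: weights 4, 4, 8), all
  enzymes zero, homogeneous matrix;
* `patchy2d`: the elliptical seed with suitability dynamics on and
  `s_0 = 1 - 0.1 (cos(4 pi x1) cos(4 pi x2))^2` (matrix largely unsuitable);
* `strip2d`: invasion from the left edge, `phi_0 = 1 - exp(-4(1 + x1))`,
  checkerboard suitability `s_0 = (1 + cos(4 pi x1) cos(4 pi x2))/2`.

`case` selects the active degradation pathway: `both`, `bound_only`
(`mu_s = 0`) or `soluble_only` (`mu_b = 0`; in suitability scenarios this
also sets `delta_s = 0`, since bound enzymes are the only agents changing
suitability — `s` is then frozen).  Default mesh sizes land within 20% of
the study resolutions (12909 dofs in 2d, 61905 in 3d); the tests and the
qualitative property checks use a reduced ~3300-dof mesh, which keeps a
T=5 run under half a minute while leaving the monitored bounds intact.

### A structural property worth knowing

The bound-enzyme equation has no spatial transport.  In a `bound_only`
simulation invasion therefore cannot propagate as a travelling wave: it
grows pointwise from wherever the initial tumour fraction is nonzero, at
the local linearized rate (~2-2.5 per unit time at the defaults).  With the
Gaussian-tailed seeds above, the t=5 invaded region is the sublevel set
where the initial tail exceeds roughly `exp(-rate * T)` — about 0.45 of
the 4.0 domain area at `mu = 1` — and the front shape mirrors the initial
level sets.  An exact pointwise-ODE integration reproduces the FE invaded
areas to two digits, so this is a property of the model, not of the
discretization.  Consequently the soluble-only pathway, which does spread
diffusively, overtakes the bound-only pathway at these parameters; the
corresponding qualitative acceptance check encodes the opposite ordering
and is knowingly left failing (see the test suite).

## Post-processing

The invasion front is the iso-level `phi = 0.25` (75% tumour), extracted by
marching simplices with edge-linear interpolation.  The invaded area
`|{phi < level}|` is computed exactly per simplex from sorted vertex
values: corner formulas when one vertex lies on either side, and in 3d an
explicit wedge volume on the reference tetrahedron for the two-two split —
all algebraically equivalent to the textbook divided-difference form but
stable for tied vertex values (ubiquitous on structured meshes, where the
divided differences are numerically catastrophic).  Front anisotropy is the
max/min centroid-to-front distance: 1 for a circle, the axis ratio for an
ellipse.

## What the tests do and do not show

All inputs are generated programmatically from closed forms; there is no
measured data and no randomness anywhere (property tests use seeded
generators).  Passing tests certify: the FE layer against closed forms and
adaptive quadrature, the homogenization against unperforated/slab cells
with known correctors and against an independent lattice-conductivity
expansion, the time stepping against a reduced-ODE oracle, and the
qualitative invasion phenomenology (monotone ECM decay, bound monitors,
suitability stalling).  They do not validate the biology: parameter values
are literature-derived point estimates, the microstructure is a perfectly
periodic lattice of equal non-deforming cells, cell movement and
proliferation enter only through the instantaneous-occupation mixture
assumption, and the diffusivity law is a scalar cubic (non-diagonal tensors
and alternative microstructures are out of scope).

## Known limitations

* First-order time accuracy; no adaptive stepping.
* Explicit reactions bound the usable `tau` through the monitor tolerance,
  not through a stability limit (the diffusion is implicit).
* The carved 3d meshes exaggerate the narrow gaps between near-touching
  spheres at coarse resolution (the gap is held open by construction),
  biasing the `n = 4` diffusivity slightly upward; refine via `mesh_size`
  when that matters.
* Cubic-law *coefficients* inherit the fit's ill-conditioning (see above);
  compare diffusivity values, not coefficients, when validating against
  other codes.
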