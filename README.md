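# mmpinv

Multiscale finite-element machinery for studying how matrix-degrading
enzymes (MMPs) drive cancer-cell invasion of the extracellular matrix
(ECM).  The package is aimed at mathematical-oncology modellers who want a
self-contained, dependency-light implementation of the two coupled layers
of this problem:

1. **Cell scale — periodic homogenization.**  Soluble MMPs diffuse through
   the ECM pore space of a periodic unit cell `Y = [0, L]^d` perforated by
   a lattice of cells (discs/spheres).  Solving the corrector problems

       div( Dbar (grad w^j + e_j) ) = 0  in Y_e,   zero flux on cell surfaces,
       w^j Y-periodic with zero pore mean,

   yields the effective diffusion tensor
   `D_ij = (1/|Y_e|) ∫_{Y_e} Dbar (δ_ij + ∂w^j/∂y_i) dy`.  Repeating over
   geometries with different ECM fractions `φ` and fitting a zero-intercept
   cubic gives the diffusivity law `D_s(φ) = (a3 φ³ + a2 φ² + a1 φ) D_s(1)`.

2. **Tissue scale — an ODE–PDE mixture model of invasion.**  With tumour
   fraction `1 − φ`, soluble concentration `c_s`, bound-enzyme mass
   `b = c_b(1 − φ)` and matrix suitability `s ∈ [0, 1]`:

       ∂t φ  = −(1−s) μ_b φ b − (1−s) μ_s φ c_s
       ∂t c_s − div(D_s(φ) ∇c_s)
             = κ_s f_s(c_s)(1−φ) − (1−s) μ_s φ c_s − β_s c_s
       ∂t b  = κ_b f_b(φ)(1−φ) − (1−s) μ_b φ b − β_b b
       ∂t s  = −δ_s b s

   with Hill factors `f_b(φ) = φ/(1+φ)`, `f_s(c) = 1/(1+c)`, integrated by
   an IMEX P1 finite-element scheme (explicit reactions, implicit
   degenerate diffusion) with runtime monitoring of the a-priori bounds
   `0 ≤ φ ≤ 1`, `0 ≤ c_s ≤ κ_s/β_s`, `0 ≤ b ≤ κ_b/β_b`.

Everything — P1 assembly, conforming cut-cell meshing of perforated unit
cells, periodic constraints, front extraction — is implemented on top of
numpy/scipy only.  All inputs are closed-form; there is no randomness.
See `docs/methods.md` for the numerics and modelling assumptions.

## Worked example

Compute effective diffusivities for two disc-lattice microstructures, fit
the cubic law, and run a short 2d invasion simulation:

```sh
$ mmpinv cellproblem --dim 2 --n 2 --n 4 --r 0.075 --h 0.02 \
        --average cell --out table.csv
$ cat table.csv
phi,D,diag_spread_pct,offdiag_ratio
0.9293141652942296,0.8697460248048954,2.3736939481026895e-14,3.806723215516067e-17
0.7172566611769187,0.5631684175184036,1.190835693769484e-12,3.204526996333272e-17
```

At ECM fraction 0.93 (a 2×2 lattice of radius-0.075 discs) diffusion is
reduced to 87% of the free value, at 0.72 to 56%; the spread and
off-diagonal columns confirm the tensors are isotropic to machine
precision, as the lattice symmetry demands.

```sh
$ mmpinv fit-diffusivity --table table.csv --ds1 1.29e-2 --out law.json
INFO mmpinv: fitted law a3=0.6933 a2=-0.4307 a1=0.7374
$ mmpinv simulate --scenario ellipse2d:both --T 1 --tau 1e-2 \
        --mesh-size 0.05 --out run1
INFO mmpinv: running ellipse2d to T=1 with tau=0.01
INFO mmpinv: done: t=1 invaded_area=0.0865 bounds_ok=True
```

The run directory contains VTU snapshots, a `manifest.json` with full
provenance, and `monitors.csv` with per-step field extrema and front
metrics; the final row

```text
t,phi_min,phi_max,cs_min,cs_max,...,bounds_ok,invaded_area,front_anisotropy
1.0,2.9e-05,0.99999,4.1e-12,1.9333,...,True,0.08646,2.0112
```

says the invaded region `{φ < 0.25}` grew from 0.027 to 0.086 (of the
4.0-area domain) by `t = 1`, the front is still elliptical with axis ratio
≈ 2 inherited from the seed, and every a-priori bound held.  Scenario cases
`ellipse2d:bound_only` (`μ_s = 0`) and `ellipse2d:soluble_only` (`μ_b = 0`)
isolate the two degradation pathways; `patchy2d` and `strip2d` add
heterogeneous matrix suitability.

The same is available as a library:

```python
from mmpinv import (UnitCellSpec, diffusivity_table, fit_diffusivity,
                    get_scenario, run_simulation, invaded_area)

table, reports = diffusivity_table(
    [UnitCellSpec(2, n, 3/40) for n in range(1, 7)], average="cell")
law = fit_diffusivity(table, include_unit=True, Ds1=1.29e-2)
traj = run_simulation(get_scenario("ellipse2d:both"), T=5.0, tau=1e-2,
                      observers=[lambda s: {"A": invaded_area(s.phi)}])
```

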