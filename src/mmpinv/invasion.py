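"""Macroscopic invasion dynamics and the IMEX P1 finite-element scheme.

State variables (all nodal fields on one mesh):

* ``phi``  — ECM volume fraction; the tumour fraction is ``1 - phi``,
* ``cs``   — soluble MMP concentration,
* ``b``    — bound-MMP mass ``c_b (1 - phi)`` (the product is the evolved
  unknown, so no division by ``1 - phi`` ever occurs),
* ``s``    — matrix suitability in [0, 1] (1 = least suitable); ``s = 0``
  identically when suitability is switched off.

Continuous model (suitability factors multiply the degradation terms):

    d phi / dt = -(1-s) mu_b phi b - (1-s) mu_s phi cs
    d cs / dt - div( D_s(phi) grad cs )
             = kappa_s f_s(cs) (1-phi) - (1-s) mu_s phi cs - beta_s cs
    d b / dt = kappa_b f_b(phi) (1-phi) - (1-s) mu_b phi b - beta_b b
    d s / dt = -delta_s b s

with Hill production factors ``f_b(phi) = phi / (1 + phi)`` and
``f_s(cs) = 1 / (1 + cs)``, zero-flux boundary conditions for ``cs``, and the
ECM-fraction-dependent diffusivity ``D_s(phi)`` from the homogenization step.

One IMEX step treats every reaction explicitly and the diffusion implicitly,
in the order: (1) phi update (mass solve), (2) cs solve with the stiffness
assembled from ``D_s`` of the *fresh* phi, (3) b update (mass solve),
(4) s update (mass solve).  The continuum solution satisfies
``0 <= phi <= 1``, ``0 <= cs <= M_s``, ``0 <= b <= M_b`` with
``M_s = max(M_s0, kappa_s / beta_s)`` and ``M_b = max(M_b0,
kappa_b / beta_b)``; the scheme is monitored against these bounds at run
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import exp

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import assemble_load, assemble_mass, assemble_stiffness, \
    cell_average_poly
from .homogenize import DiffusivityLaw
from .mesh import NodalField, SimplicialMesh


def hill_fb(phi):
    """Bound-MMP production factor ``phi / (1 + phi)``; in [0, 1/2] on [0, 1]."""
    phi = np.asarray(phi, dtype=float)
    return phi / (1.0 + phi)


def hill_fs(c):
    """Soluble-MMP production factor ``1 / (1 + c)``; in (0, 1] for c >= 0."""
    c = np.asarray(c, dtype=float)
    return 1.0 / (1.0 + c)


@dataclass
class ModelParams:
    """Reaction/degradation rates (nondimensional defaults of the study).

    ``kappa_*`` production, ``mu_*`` ECM-degradation coupling, ``beta_*``
    linear decay, ``delta_s`` suitability decay driven by bound MMPs.
    """

    kappa_s: float = 4.0
    kappa_b: float = 5.0
    mu_s: float = 1.0
    mu_b: float = 1.0
    beta_s: float = 0.1
    beta_b: float = 0.1
    delta_s: float = 1.0
    diffusivity: DiffusivityLaw = field(
        default_factory=lambda: DiffusivityLaw(0.25, 0.33, 0.42, 1.29e-2, 2))
    suitability_on: bool = False

    def __post_init__(self) -> None:
        for name in ("kappa_s", "kappa_b", "mu_s", "mu_b",
                     "beta_s", "beta_b", "delta_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def bound_ms(self, cs0_max: float = 0.0) -> float:
        if self.beta_s <= 0:
            raise ValueError("M_s bound requires beta_s > 0")
        return max(cs0_max, self.kappa_s / self.beta_s)

    def bound_mb(self, b0_max: float = 0.0) -> float:
        if self.beta_b <= 0:
            raise ValueError("M_b bound requires beta_b > 0")
        return max(b0_max, self.kappa_b / self.beta_b)

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class SimState:
    """Nodal fields at one time level."""

    t: float
    phi: NodalField
    cs: NodalField
    b: NodalField
    s: NodalField

    @property
    def mesh(self) -> SimplicialMesh:
        return self.phi.mesh

    def cb_reconstructed(self, eps_div: float = 1e-10) -> NodalField:
        """Bound-MMP surface density ``b / (1 - phi)`` for visualization only."""
        denom = np.maximum(1.0 - self.phi.values, eps_div)
        return NodalField(self.mesh, self.b.values / denom)


class FemContext:
    """Per-mesh matrices shared by all IMEX steps."""

    def __init__(self, mesh: SimplicialMesh, lumped: bool = False):
        self.mesh = mesh
        self.M = assemble_mass(mesh, lumped=lumped)
        self._M_lu = spla.splu(sp.csc_matrix(self.M))
        self.lumped = lumped

    def mass_solve(self, rhs: np.ndarray) -> np.ndarray:
        return self._M_lu.solve(rhs)


def imex_step(state: SimState, params: ModelParams, tau: float,
              ctx: FemContext) -> SimState:
    """One IMEX step of size ``tau``: explicit reactions, implicit diffusion.

    The diffusion stiffness uses ``D_s`` evaluated (exactly, per cell) from
    the freshly updated ECM fraction.  Raises on non-finite values or solver
    failure.
    """
    if tau <= 0:
        raise ValueError("time step must be positive")
    mesh, M = ctx.mesh, ctx.M
    phi, cs, b = state.phi.values, state.cs.values, state.b.values
    s = state.s.values if params.suitability_on else np.zeros_like(phi)
    one_minus_s = 1.0 - s
    one_minus_phi = 1.0 - phi
    p = params

    # (1) ECM fraction: M phi_new = M phi - tau [ (1-s) mu_s phi cs
    #                                           + (1-s) mu_b phi b ]
    sink = np.zeros(mesh.num_vertices)
    if p.mu_s:
        sink += assemble_load(mesh, one_minus_s, phi, cs, scale=p.mu_s)
    if p.mu_b:
        sink += assemble_load(mesh, one_minus_s, phi, b, scale=p.mu_b)
    phi_new = ctx.mass_solve(M @ phi - tau * sink)

    # (2) soluble MMPs: (M + tau K(D_s(phi_new))) cs_new = M cs + tau R
    coeff = cell_average_poly(mesh, phi_new, p.diffusivity.poly4())
    coeff = np.maximum(coeff, 0.0)  # clip O(tau) nodal undershoot of phi
    K = assemble_stiffness(mesh, coeff)
    rhs = (M @ cs
           + tau * assemble_load(mesh, hill_fs(cs), one_minus_phi,
                                 scale=p.kappa_s)
           - tau * assemble_load(mesh, one_minus_s, phi, cs, scale=p.mu_s)
           - tau * p.beta_s * (M @ cs))
    try:
        cs_new = spla.splu(sp.csc_matrix(M + tau * K)).solve(rhs)
    except RuntimeError as exc:  # pragma: no cover - singular factorization
        raise RuntimeError(f"diffusion solve failed at t={state.t:g}: {exc}")

    # (3) bound-MMP mass: every c_b occurrence enters as b = c_b (1 - phi)
    rhs_b = (M @ b
             + tau * assemble_load(mesh, hill_fb(phi), one_minus_phi,
                                   scale=p.kappa_b)
             - tau * assemble_load(mesh, one_minus_s, phi, b, scale=p.mu_b)
             - tau * p.beta_b * (M @ b))
    b_new = ctx.mass_solve(rhs_b)

    # (4) suitability: M s_new = M s - tau delta_s <b s, psi>
    if params.suitability_on:
        s_new = ctx.mass_solve(M @ s - tau * assemble_load(
            mesh, b, s, scale=p.delta_s))
    else:
        s_new = s

    out = np.stack([phi_new, cs_new, b_new, s_new])
    if not np.all(np.isfinite(out)):
        raise RuntimeError(f"non-finite field values after step at "
                           f"t={state.t + tau:g}")
    return SimState(state.t + tau,
                    NodalField(mesh, phi_new), NodalField(mesh, cs_new),
                    NodalField(mesh, b_new), NodalField(mesh, s_new))


# --------------------------------------------------------------------------
# invariant monitoring
# --------------------------------------------------------------------------

def lower_phi_bound(delta0: float, params: ModelParams, T: float) -> float:
    """A-priori lower bound ``delta0 exp(-(mu_b kappa_b / beta_b
    + mu_s kappa_s / beta_s) T)`` for the ECM fraction on [0, T]."""
    rate = (params.mu_b * params.kappa_b / params.beta_b
            + params.mu_s * params.kappa_s / params.beta_s)
    return delta0 * exp(-rate * T)


@dataclass
class MonitorReport:
    extrema: dict[str, tuple[float, float]]
    Ms: float
    Mb: float
    phi_floor: float | None
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def invariant_monitor(state: SimState, params: ModelParams,
                      Ms: float | None = None, Mb: float | None = None,
                      delta0: float | None = None, T: float | None = None,
                      tol: float = 1e-6) -> MonitorReport:
    """Check the a-priori solution bounds at scheme level.

    Flags ``phi`` outside ``[-tol, 1+tol]``, ``cs`` outside ``[-tol,
    M_s+tol]``, ``b`` outside ``[-tol, M_b+tol]``, ``s`` outside
    ``[-tol, 1+tol]`` and, when ``delta0 > 0`` and ``T`` are supplied, the
    exponential ECM floor.  The floor is informational only when the initial
    ECM fraction vanishes somewhere (``delta0 = 0``).
    """
    if Ms is None:
        Ms = params.bound_ms()
    if Mb is None:
        Mb = params.bound_mb()
    ex = {name: (float(f.values.min()), float(f.values.max()))
          for name, f in (("phi", state.phi), ("cs", state.cs),
                          ("b", state.b), ("s", state.s))}
    violations = []
    for name, hi in (("phi", 1.0), ("cs", Ms), ("b", Mb), ("s", 1.0)):
        lo_v, hi_v = ex[name]
        if lo_v < -tol:
            violations.append(f"{name} min {lo_v:g} < 0")
        if hi_v > hi + tol:
            violations.append(f"{name} max {hi_v:g} > {hi:g}")
    floor = None
    if delta0 is not None and T is not None and delta0 > 0:
        floor = lower_phi_bound(delta0, params, T)
        if ex["phi"][0] < floor - tol:
            violations.append(
                f"phi min {ex['phi'][0]:g} below a-priori floor {floor:g}")
    return MonitorReport(ex, Ms, Mb, floor, violations)


# --------------------------------------------------------------------------
# time loop
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    times: np.ndarray
    monitors: list[dict]
    snapshots: list[SimState]
    final: SimState


def run_simulation(scenario, T: float, tau: float,
                   snapshot_times=(), mesh: SimplicialMesh | None = None,
                   on_violation: str = "warn",
                   observers=None, lumped: bool = False) -> Trajectory:
    """Integrate a scenario to time ``T`` with uniform step ``tau``.

    ``T`` must be an integer multiple of ``tau``.  Per step the field extrema
    are recorded and checked against the a-priori bounds (``on_violation``:
    "warn", "abort" or "ignore").  ``observers`` is an optional list of
    callables ``obs(state) -> dict`` merged into the per-step monitor rows.
    Snapshots are stored at the requested times (matched to the nearest
    step).  Deterministic: no randomness anywhere.
    """
    N = int(round(T / tau)) if T > 0 else 0
    if T > 0 and abs(N * tau - T) > 1e-9 * max(T, 1.0):
        raise ValueError("T must be an integer multiple of tau")
    if mesh is None:
        mesh = scenario.build_mesh()
    params = scenario.params
    state = scenario.initial_state(mesh)
    delta0 = float(state.phi.values.min())
    # the a-priori enzyme bounds are finite only for positive decay rates
    Ms = (params.bound_ms(float(state.cs.values.max()))
          if params.beta_s > 0 else np.inf)
    Mb = (params.bound_mb(float(state.b.values.max()))
          if params.beta_b > 0 else np.inf)
    ctx = FemContext(mesh, lumped=lumped)
    snap_steps = {min(N, max(0, int(round(ts / tau)))): ts
                  for ts in snapshot_times}

    def record(st: SimState) -> dict:
        rep = invariant_monitor(st, params, Ms=Ms, Mb=Mb)
        row = {"t": st.t}
        for name, (lo, hi) in rep.extrema.items():
            row[f"{name}_min"], row[f"{name}_max"] = lo, hi
        row["bounds_ok"] = rep.ok
        if observers:
            for obs in observers:
                row.update(obs(st))
        if not rep.ok:
            msg = (f"bound violation at t={st.t:g}: "
                   + "; ".join(rep.violations))
            if on_violation == "abort":
                raise RuntimeError(msg)
            if on_violation == "warn":
                import warnings
                warnings.warn(msg, RuntimeWarning, stacklevel=3)
        return row

    monitors = [record(state)]
    snapshots = [state] if 0 in snap_steps else []
    times = [0.0]
    for n in range(1, N + 1):
        state = imex_step(state, params, tau, ctx)
        monitors.append(record(state))
        times.append(state.t)
        if n in snap_steps:
            snapshots.append(state)
    return Trajectory(np.asarray(times), monitors, snapshots, state)
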