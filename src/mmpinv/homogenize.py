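"""Corrector cell problems, effective diffusion tensors and the cubic
diffusivity law.

For a periodic perforated cell ``Y_e`` (ECM pore space) the corrector ``w^j``
in direction ``e_j`` solves the pure-Neumann periodic problem

    div( Dbar (grad w^j + e_j) ) = 0   in Y_e,
    Dbar (grad w^j + e_j) . nu  = 0    on the hole boundary,
    w^j Y-periodic,  int_{Y_e} w^j = 0,

and the homogenized tensor is the pore average

    D_ij = (1 / |Y_e|) int_{Y_e} Dbar (delta_ij + d w^j / d y_i) dy.

With this normalization ``D`` has eigenvalues in ``[0, Dbar]`` and equals
``Dbar I`` for the unperforated cell.  A second convention divides by the full
cell volume ``|Y|`` instead, i.e. multiplies by the ECM fraction; it is the
superficial (Darcy-like) diffusivity and is exposed through the ``average``
switch of :func:`diffusivity_table` — the bundled 2d diffusivity study uses
the cell average, the 3d study the pore average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .fem import (PeriodicReduction, assemble_stiffness, grad_basis,
                  load_weights, solve_constrained)
from .mesh import NodalField, PeriodicMap, SimplicialMesh
from .unitcell import UnitCellSpec, build_unit_cell_mesh, ecm_fraction


class FitError(ValueError):
    """Raised when the fitted diffusivity law violates positivity."""


@dataclass
class CorrectorSet:
    """Periodic correctors ``W^1..W^d`` on one unit-cell mesh."""

    mesh: SimplicialMesh
    fields: list[NodalField]

    def __post_init__(self) -> None:
        for f in self.fields:
            if f.mesh is not self.mesh:
                raise ValueError("corrector field on a different mesh")


@dataclass
class EffectiveTensor:
    """Homogenized ``d x d`` diffusion matrix with its geometry's ECM fraction."""

    D: np.ndarray
    ecm_fraction: float
    spec: UnitCellSpec | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        nrm = np.linalg.norm(self.D)
        if nrm > 0 and np.linalg.norm(self.D - self.D.T) > 1e-8 * nrm:
            raise ValueError("effective tensor not symmetric")

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(0.5 * (self.D + self.D.T))


@dataclass
class DiffusivityLaw:
    """Cubic diffusivity law ``D_s(phi) = (a3 phi^3 + a2 phi^2 + a1 phi) Ds1``.

    Structurally ``D_s(0) = 0`` (no constant term: enzymes do not diffuse
    through cancer cells); ``Ds1`` is the reference diffusivity of the
    unobstructed matrix in the model's units.
    """

    a3: float
    a2: float
    a1: float
    Ds1: float = 1.0
    dim: int | None = None

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        return (self.a3 * phi ** 3 + self.a2 * phi ** 2
                + self.a1 * phi) * self.Ds1

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a3, self.a2, self.a1)

    def poly4(self) -> tuple[float, float, float, float]:
        """Coefficients ``(a3, a2, a1, 0) * Ds1`` for exact cell averaging."""
        return (self.a3 * self.Ds1, self.a2 * self.Ds1, self.a1 * self.Ds1, 0.0)

    def check_positive(self, npts: int = 1000) -> None:
        phi = np.linspace(0.0, 1.0, npts + 1)[1:]
        vals = self(phi) / self.Ds1
        if np.min(vals) <= 0:
            bad = phi[int(np.argmin(vals))]
            raise FitError(
                f"fitted diffusivity non-positive at phi = {bad:.4f}")

    def second_derivative(self, phi):
        phi = np.asarray(phi, dtype=float)
        return (6 * self.a3 * phi + 2 * self.a2) * self.Ds1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"a3": self.a3, "a2": self.a2, "a1": self.a1,
                       "Ds1": self.Ds1, "dim": self.dim}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DiffusivityLaw":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["a3"], d["a2"], d["a1"], d.get("Ds1", 1.0), d.get("dim"))


# --------------------------------------------------------------------------
# cell problems
# --------------------------------------------------------------------------

class CellProblemContext:
    """Shared assembly/factorization for the d corrector solves on one mesh."""

    def __init__(self, mesh: SimplicialMesh, pmap: PeriodicMap,
                 Dbar: float = 1.0):
        if Dbar <= 0:
            raise ValueError("Dbar must be positive")
        self.mesh, self.pmap, self.Dbar = mesh, pmap, Dbar
        self.grads, self.vols = grad_basis(mesh)
        self.K = assemble_stiffness(mesh, Dbar)
        self.red = PeriodicReduction(mesh.num_vertices, pmap)
        self.Kr = self.red.reduce_matrix(self.K)
        self.wr = self.red.reduce_vector(load_weights(mesh))
        # sparse direct is fast for the 2d problems; the 3d stiffness
        # factorizations fill in badly, so those use preconditioned CG
        self.method = "direct" if mesh.dim == 2 else "cg"

    def solve(self, j: int) -> NodalField:
        if not 0 <= j < self.mesh.dim:
            raise ValueError(f"direction {j} out of range")
        # rhs_i = -int Dbar e_j . grad(lambda_i)
        b = np.zeros(self.mesh.num_vertices)
        np.add.at(b, self.mesh.cells.ravel(),
                  (-self.Dbar * self.vols[:, None]
                   * self.grads[:, :, j]).ravel())
        ur = solve_constrained(self.Kr, self.red.reduce_vector(b),
                               constraint="zero-mean", weights=self.wr,
                               method=self.method)
        return NodalField(self.mesh, self.red.expand(ur))


def solve_cell_problem(mesh: SimplicialMesh, pmap: PeriodicMap,
                       Dbar: float, j: int) -> NodalField:
    """Corrector ``W^j`` (zero pore mean, periodic) for unit flux ``e_j``."""
    return CellProblemContext(mesh, pmap, Dbar).solve(j)


def solve_correctors(mesh: SimplicialMesh, pmap: PeriodicMap,
                     Dbar: float = 1.0) -> CorrectorSet:
    ctx = CellProblemContext(mesh, pmap, Dbar)
    return CorrectorSet(mesh, [ctx.solve(j) for j in range(mesh.dim)])


def effective_tensor(mesh: SimplicialMesh, Dbar: float,
                     correctors: CorrectorSet,
                     spec: UnitCellSpec | None = None) -> EffectiveTensor:
    """Pore-averaged homogenized tensor from the solved correctors.

    ``|Y_e|`` is the meshed pore volume so numerator and denominator use the
    same quadrature; the ECM fraction stored on the result is the meshed
    pore volume over the cell volume ``L^d``.
    """
    if correctors.mesh is not mesh:
        raise ValueError("correctors solved on a different mesh")
    grads, vols = grad_basis(mesh)
    d = mesh.dim
    pore = float(vols.sum())
    L = float(np.max(mesh.vertices) - np.min(mesh.vertices))
    D = np.zeros((d, d))
    for j, W in enumerate(correctors.fields):
        gw = np.einsum('ca,cad->cd', W.values[mesh.cells], grads)  # (C, d)
        D[:, j] = Dbar * (vols[:, None] * gw).sum(axis=0) / pore
        D[j, j] += Dbar
    D = 0.5 * (D + D.T)  # the continuum tensor is symmetric
    return EffectiveTensor(D, pore / L ** d, spec)


def isotropy_report(T: EffectiveTensor
                    ) -> tuple[float, float, float]:
    """(diagonal spread %, off-diagonal ratio, scalar value).

    ``diag_spread`` is the max pairwise diagonal difference relative to the
    diagonal mean in percent; ``offdiag_ratio`` the largest off-diagonal
    magnitude over the diagonal mean; ``scalar_value`` the diagonal mean —
    the scalar diffusivity used for the law fit.
    """
    diag = np.diag(T.D)
    mean = float(diag.mean())
    spread = float(np.ptp(diag)) / mean * 100.0
    off = T.D - np.diag(diag)
    ratio = float(np.max(np.abs(off))) / mean if off.size else 0.0
    return spread, ratio, mean


# --------------------------------------------------------------------------
# law fitting
# --------------------------------------------------------------------------

def fit_diffusivity(points, degree: int = 3, include_origin: bool = True,
                    include_unit: bool = False, Ds1: float = 1.0,
                    dim: int | None = None) -> DiffusivityLaw:
    """Zero-intercept cubic least-squares fit of normalized diffusivities.

    ``points`` are ``(phi, D/Dbar)`` pairs.  The origin ``(0, 0)`` is added
    by default (no diffusion through a cell-filled medium); ``include_unit``
    additionally pins ``(1, 1)``, exact for the unperforated cell.  The fit
    is rejected if the law is not strictly positive on ``(0, 1]``.
    """
    if degree != 3:
        raise ValueError("only the cubic law is supported")
    pts = [(float(p), float(v)) for p, v in points]
    if any(v < 0 for _, v in pts):
        raise FitError("negative diffusivity value supplied")
    if include_origin:
        pts.append((0.0, 0.0))
    if include_unit:
        pts.append((1.0, 1.0))
    phi = np.array([p for p, _ in pts])
    if np.unique(phi).size < degree:
        raise FitError("need at least 3 distinct phi values")
    Dv = np.array([v for _, v in pts])
    A = np.vstack([phi ** 3, phi ** 2, phi]).T
    (a3, a2, a1), *_ = np.linalg.lstsq(A, Dv, rcond=None)
    law = DiffusivityLaw(float(a3), float(a2), float(a1), Ds1, dim)
    law.check_positive()
    return law


def diffusivity_table(specs, Dbar: float = 1.0, average: str = "pore",
                      spread_tol: float = 5.0):
    """Scalar normalized diffusivity per geometry: build, solve, scalarise.

    Returns ``(table, reports)`` where ``table`` is a list of
    ``(phi_analytic, D_scalar / Dbar)`` and ``reports`` the per-geometry
    isotropy diagnostics.  Geometries whose diagonal spread exceeds
    ``spread_tol`` percent are rejected (a symptom of a bad mesh).
    ``average="pore"`` keeps the intrinsic pore average of the tensor;
    ``average="cell"`` rescales to the full-cell (superficial) average by
    the meshed ECM fraction.
    """
    if average not in ("pore", "cell"):
        raise ValueError("average must be 'pore' or 'cell'")
    table, reports = [], []
    for spec in specs:
        phi = ecm_fraction(spec)
        if spec.n == 0:
            table.append((1.0, 1.0))
            reports.append((0.0, 0.0, 1.0))
            continue
        mesh, pmap = build_unit_cell_mesh(spec)
        T = effective_tensor(mesh, Dbar, solve_correctors(mesh, pmap, Dbar),
                             spec)
        spread, ratio, scalar = isotropy_report(T)
        if spread > spread_tol:
            raise FitError(
                f"diagonal spread {spread:.2f}% exceeds {spread_tol}% for "
                f"{spec!r}; mesh too coarse or asymmetric")
        if average == "cell":
            scalar *= T.ecm_fraction
        table.append((phi, scalar / Dbar))
        reports.append((spread, ratio, scalar / Dbar))
    return table, reports
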