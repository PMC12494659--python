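"""P1 Lagrange finite elements on simplicial meshes.

Assembly is fully vectorized over cells.  Integrals of products of P1 fields
are computed *exactly* from the closed form

    int_T  lambda_1^{a_1} ... lambda_{d+1}^{a_{d+1}} dx
        = d! |T| a_1! ... a_{d+1}! / (d + a_1 + ... + a_{d+1})!

so right-hand sides containing up to triple products of nodal fields (times a
test function) need no quadrature tables, and stiffness matrices with a
polynomial coefficient of a P1 field use the exact per-cell average of the
coefficient (the P1 gradients are cellwise constant, which makes the cell
average all that enters).
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import NodalField, PeriodicMap, SimplicialMesh


class AssemblyError(ValueError):
    """Raised for invalid assembly inputs (degenerate cells, bad coefficients)."""


class SolverError(RuntimeError):
    """Raised when a linear solve fails or the rhs is incompatible."""


# --------------------------------------------------------------------------
# exact reference integrals
# --------------------------------------------------------------------------

@lru_cache(maxsize=None)
def barycentric_product_tensor(dim: int, rank: int) -> np.ndarray:
    """Tensor ``P[i1,...,ik] = (1/|T|) int_T lambda_{i1} ... lambda_{ik} dx``.

    Exact on every simplex; depends only on the multiset of indices.
    """
    n = dim + 1
    shape = (n,) * rank
    out = np.empty(shape)
    for idx in np.ndindex(*shape):
        counts = np.bincount(idx, minlength=n)
        num = factorial(dim)
        for c in counts:
            num *= factorial(int(c))
        out[idx] = num / factorial(dim + rank)
    return out


def grad_basis(mesh: SimplicialMesh) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise-constant P1 basis gradients.

    Returns ``(grads, vols)`` with ``grads`` of shape ``(C, d+1, d)`` and
    ``vols`` the (positive) cell volumes.  Raises on degenerate cells.
    """
    E = mesh.edge_matrices()          # (C, d, d), columns are edge vectors
    det = np.linalg.det(E)
    bad = np.nonzero(np.abs(det) < 1e-14)[0]
    if bad.size:
        raise AssemblyError(f"degenerate cell {bad[0]}")
    invE = np.linalg.inv(E)           # (C, d, d); row j = grad lambda_{j+1}
    grads = np.empty((mesh.num_cells, mesh.dim + 1, mesh.dim))
    grads[:, 1:, :] = invE
    grads[:, 0, :] = -invE.sum(axis=1)
    vols = mesh.cell_volumes()
    return grads, vols


# homogeneous symmetric sums h_p of the vertex values, via Newton's identities
def _hsums(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p1 = u.sum(axis=1)
    p2 = (u ** 2).sum(axis=1)
    p3 = (u ** 3).sum(axis=1)
    h1 = p1
    h2 = (p1 ** 2 + p2) / 2.0
    h3 = (p1 ** 3 + 3.0 * p1 * p2 + 2.0 * p3) / 6.0
    return h1, h2, h3


def cell_average_poly(mesh: SimplicialMesh, values: np.ndarray,
                      coeffs: tuple[float, float, float, float]) -> np.ndarray:
    """Exact per-cell average of ``a3*u^3 + a2*u^2 + a1*u + a0`` for P1 ``u``.

    ``coeffs = (a3, a2, a1, a0)``; returns an array of length C.
    """
    a3, a2, a1, a0 = coeffs
    d = mesh.dim
    u = values[mesh.cells]
    h1, h2, h3 = _hsums(u)
    c1 = factorial(d) * 1 / factorial(d + 1)
    c2 = factorial(d) * 2 / factorial(d + 2)
    c3 = factorial(d) * 6 / factorial(d + 3)
    return a3 * c3 * h3 + a2 * c2 * h2 + a1 * c1 * h1 + a0


# --------------------------------------------------------------------------
# operator assembly
# --------------------------------------------------------------------------

def _scatter(mesh: SimplicialMesh, local: np.ndarray) -> sp.csr_matrix:
    n = mesh.dim + 1
    rows = np.repeat(mesh.cells, n, axis=1).ravel()
    cols = np.tile(mesh.cells, (1, n)).ravel()
    A = sp.coo_matrix((local.ravel(), (rows, cols)),
                      shape=(mesh.num_vertices,) * 2)
    return A.tocsr()


def assemble_mass(mesh: SimplicialMesh, lumped: bool = False) -> sp.csr_matrix:
    """P1 mass matrix; ``lumped`` sums each row onto the diagonal.

    Row sums equal the vertex-patch volumes / (d+1) either way, so the total
    sum of entries is the mesh volume (partition of unity).
    """
    _, vols = grad_basis(mesh)        # also validates non-degeneracy
    d = mesh.dim
    if lumped:
        diag = np.zeros(mesh.num_vertices)
        np.add.at(diag, mesh.cells.ravel(),
                  np.repeat(vols / (d + 1), d + 1))
        return sp.diags(diag).tocsr()
    ref = (np.ones((d + 1, d + 1)) + np.eye(d + 1)) / ((d + 1) * (d + 2))
    local = vols[:, None, None] * ref[None, :, :]
    return _scatter(mesh, local)


def assemble_stiffness(mesh: SimplicialMesh, coeff=1.0) -> sp.csr_matrix:
    """Stiffness matrix ``int coeff grad u . grad v``.

    ``coeff`` may be a nonnegative scalar, a constant positive-semidefinite
    ``(d, d)`` matrix, a :class:`NodalField` (exact cellwise average is used),
    or a per-cell array of length C.
    """
    grads, vols = grad_basis(mesh)
    d = mesh.dim
    if isinstance(coeff, NodalField):
        vals = coeff.values
        if np.min(vals) < 0:
            i = int(np.argmin(vals))
            raise AssemblyError(
                f"negative diffusion coefficient {vals[i]:g} at vertex {i} "
                f"(point {mesh.vertices[i]})")
        cbar = vals[mesh.cells].mean(axis=1)
        local = np.einsum('c,cid,cjd->cij', cbar * vols, grads, grads)
    elif np.ndim(coeff) == 0:
        c = float(coeff)
        if c < 0:
            raise AssemblyError(f"negative constant coefficient {c:g}")
        local = np.einsum('c,cid,cjd->cij', c * vols, grads, grads)
    elif np.ndim(coeff) == 1:
        cells_c = np.asarray(coeff, dtype=float)
        if cells_c.shape != (mesh.num_cells,):
            raise AssemblyError("per-cell coefficient has wrong length")
        if np.min(cells_c) < 0:
            i = int(np.argmin(cells_c))
            raise AssemblyError(
                f"negative coefficient {cells_c[i]:g} on cell {i}")
        local = np.einsum('c,cid,cjd->cij', cells_c * vols, grads, grads)
    else:
        A = np.asarray(coeff, dtype=float)
        if A.shape != (d, d):
            raise AssemblyError("matrix coefficient must be (d, d)")
        ev = np.linalg.eigvalsh(0.5 * (A + A.T))
        if ev.min() < -1e-12 * max(1.0, ev.max()):
            raise AssemblyError("matrix coefficient not positive semidefinite")
        local = np.einsum('c,cid,de,cje->cij', vols, grads, A, grads)
    return _scatter(mesh, local)


def assemble_load(mesh: SimplicialMesh, *factors, scale: float = 1.0
                  ) -> np.ndarray:
    """Load vector ``b_i = scale * int (prod_k f_k) lambda_i dx``, exact.

    Each factor is a :class:`NodalField`, a value array of length V, or a
    callable ``f(points)`` (nodally interpolated first).  Up to three factors
    (quartic integrands including the test function) are supported.
    """
    vals = []
    for f in factors:
        if isinstance(f, NodalField):
            vals.append(f.values)
        elif callable(f):
            vals.append(np.asarray(f(mesh.vertices), dtype=float))
        else:
            v = np.asarray(f, dtype=float)
            if v.shape != (mesh.num_vertices,):
                raise AssemblyError("load factor has wrong length")
            vals.append(v)
    m = len(vals)
    if m == 0 or m > 3:
        raise AssemblyError("assemble_load takes 1 to 3 factors")
    vols = mesh.cell_volumes()
    U = [v[mesh.cells] for v in vals]            # (C, d+1) each
    P = barycentric_product_tensor(mesh.dim, m + 1)
    if m == 1:
        loc = np.einsum('c,ca,ai->ci', vols, U[0], P)
    elif m == 2:
        loc = np.einsum('c,ca,cb,abi->ci', vols, U[0], U[1], P)
    else:
        loc = np.einsum('c,ca,cb,ce,abei->ci', vols, U[0], U[1], U[2], P)
    b = np.zeros(mesh.num_vertices)
    np.add.at(b, mesh.cells.ravel(), loc.ravel())
    return scale * b


def load_weights(mesh: SimplicialMesh) -> np.ndarray:
    """Vector of ``int lambda_i dx`` (integration weights of nodal values)."""
    return assemble_load(mesh, np.ones(mesh.num_vertices))


# --------------------------------------------------------------------------
# periodic reduction
# --------------------------------------------------------------------------

class PeriodicReduction:
    """Eliminates slave dofs of a periodic map by identification with masters."""

    def __init__(self, num_vertices: int, pmap: PeriodicMap):
        if pmap.pairs.size and pmap.pairs.max() >= num_vertices:
            raise AssemblyError("periodic map vertex index out of range")
        parent = np.arange(num_vertices)
        parent[pmap.slaves] = pmap.masters
        # resolve chains (slave -> master that is itself a slave)
        for _ in range(3):
            nxt = parent[parent]
            if np.array_equal(nxt, parent):
                break
            parent = nxt
        keep = np.nonzero(parent == np.arange(num_vertices))[0]
        self.reduced_index = np.full(num_vertices, -1, dtype=np.int64)
        self.reduced_index[keep] = np.arange(keep.size)
        self.reduced_index = self.reduced_index[parent]
        self.num_full = num_vertices
        self.num_reduced = keep.size
        ones = np.ones(num_vertices)
        self.P = sp.csr_matrix(
            (ones, (np.arange(num_vertices), self.reduced_index)),
            shape=(num_vertices, self.num_reduced))

    def reduce_matrix(self, A: sp.spmatrix) -> sp.csr_matrix:
        return (self.P.T @ A @ self.P).tocsr()

    def reduce_vector(self, b: np.ndarray) -> np.ndarray:
        return self.P.T @ b

    def expand(self, u: np.ndarray) -> np.ndarray:
        return self.P @ u


def apply_periodic(op: sp.spmatrix, pmap: PeriodicMap,
                   num_vertices: int | None = None
                   ) -> tuple[sp.csr_matrix, PeriodicReduction]:
    """Reduced operator plus the reduction object used to expand solutions."""
    n = num_vertices if num_vertices is not None else op.shape[0]
    red = PeriodicReduction(n, pmap)
    return red.reduce_matrix(op), red


# --------------------------------------------------------------------------
# linear solves
# --------------------------------------------------------------------------

def solve_constrained(A: sp.spmatrix, b: np.ndarray, constraint: str = "none",
                      weights: np.ndarray | None = None,
                      rtol: float = 1e-10, atol: float = 1e-12,
                      method: str = "direct") -> np.ndarray:
    """Solve ``A u = b``, optionally under a zero-mean constraint.

    For ``constraint="zero-mean"`` the operator is singular with the
    constants as kernel (pure Neumann / periodic), so the rhs must be
    orthogonal to constants; the compatibility defect ``sum(b)`` is checked
    explicitly and reported before solving.  The singular system is then
    solved by grounding one degree of freedom and shifting to zero weighted
    mean afterwards (``weights`` are the basis-function integrals); the
    residual of the *unmodified* singular system is verified, which fails
    loudly if the kernel is larger than the constants.
    """
    b = np.asarray(b, dtype=float)
    nb = np.linalg.norm(b)
    if constraint == "none":
        lu = spla.splu(sp.csc_matrix(A))
        u = lu.solve(b)
        res = np.linalg.norm(A @ u - b)
        if res > max(rtol * nb, atol):
            raise SolverError(f"direct solve residual {res:g} exceeds tolerance")
        return u
    if constraint != "zero-mean":
        raise ValueError(f"unknown constraint {constraint!r}")
    if weights is None:
        raise ValueError("zero-mean constraint requires integration weights")
    defect = abs(float(np.sum(b)))
    if defect > max(rtol * max(nb, 1.0), 100 * atol):
        raise SolverError(
            f"incompatible rhs for singular operator: constant component "
            f"{defect:g}")
    w = np.asarray(weights, dtype=float)
    n = A.shape[0]
    A = sp.csc_matrix(A)
    vol = float(np.sum(w))
    if method == "cg":
        # Jacobi-preconditioned CG on the singular (consistent) SPD system;
        # much cheaper than a direct factorization for 3d stiffness matrices
        diag = A.diagonal()
        diag = np.where(diag > 0, diag, 1.0)
        M = spla.LinearOperator(A.shape, matvec=lambda r: r / diag)
        u, info = spla.cg(A, b, rtol=max(rtol, 1e-12), atol=0.0,
                          maxiter=20 * int(np.sqrt(n)) + 1000, M=M)
        if info != 0:
            raise SolverError(f"CG failed to converge (info={info})")
    else:
        keep = np.arange(1, n)
        lu = spla.splu(A[keep][:, keep])
        u = np.zeros(n)
        u[1:] = lu.solve(b[1:])
    u -= float(w @ u) / vol
    res = np.linalg.norm(A @ u - b)
    if res > max(rtol * max(nb, 1.0), 1e3 * atol):
        raise SolverError(
            f"singular solve residual {res:g} exceeds tolerance "
            f"(operator kernel larger than the constants?)")
    if abs(float(w @ u)) > 1e-8 * vol:
        raise SolverError("zero-mean constraint violated")
    return u
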