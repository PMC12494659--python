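"""Simplicial meshes, periodic identifications and nodal fields.

The containers here are deliberately minimal: a mesh is a vertex array plus a
cell connectivity array with a tag map for the non-interior facets, a periodic
map is a list of (master, slave) vertex pairs, and a nodal field is one real
per vertex.  Everything downstream (assembly, homogenization, the invasion
scheme) works on these three types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

# facet tags
HOLE_BOUNDARY = "hole"
INTERIOR = "interior"


def outer_face_tag(axis: int, side: int) -> str:
    """Tag of the outer box face with normal along ``axis`` (side 0=low, 1=high)."""
    return f"outer_{2 * axis + side + 1}"


class MeshError(ValueError):
    """Raised when a mesh violates a structural invariant."""


@dataclass
class SimplicialMesh:
    """Conforming triangulation (d=2) or tetrahedralization (d=3).

    Parameters
    ----------
    dim:
        Spatial dimension, 2 or 3.
    vertices:
        ``(V, dim)`` float array of vertex coordinates.
    cells:
        ``(C, dim+1)`` int array; every cell oriented with positive signed
        volume.
    facet_tags:
        Mapping from sorted vertex tuples of *non-interior* facets to a tag
        (``HOLE_BOUNDARY`` or ``outer_k``).  Facets absent from the map are
        interior.
    """

    dim: int
    vertices: np.ndarray
    cells: np.ndarray
    facet_tags: dict[tuple[int, ...], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.cells = np.ascontiguousarray(self.cells, dtype=np.int64)
        if self.dim not in (2, 3):
            raise MeshError(f"dim must be 2 or 3, got {self.dim}")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != self.dim:
            raise MeshError("vertices must be (V, dim)")
        if self.cells.ndim != 2 or self.cells.shape[1] != self.dim + 1:
            raise MeshError("cells must be (C, dim+1)")

    # -- basic geometry ----------------------------------------------------
    @property
    def num_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def num_cells(self) -> int:
        return self.cells.shape[0]

    def edge_matrices(self) -> np.ndarray:
        """Per-cell matrix of edge vectors from vertex 0, shape (C, d, d)."""
        v = self.vertices[self.cells]
        return (v[:, 1:, :] - v[:, :1, :]).transpose(0, 2, 1)

    def signed_volumes(self) -> np.ndarray:
        det = np.linalg.det(self.edge_matrices())
        fact = 2.0 if self.dim == 2 else 6.0
        return det / fact

    def cell_volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes())

    def total_volume(self) -> float:
        return float(self.cell_volumes().sum())

    def orient(self) -> None:
        """Flip cells in place so every signed volume is positive."""
        neg = self.signed_volumes() < 0
        if np.any(neg):
            self.cells[neg] = self.cells[neg][:, [0, 2, 1] if self.dim == 2
                                              else [0, 1, 3, 2]]

    # -- facets ------------------------------------------------------------
    def cell_facets(self) -> np.ndarray:
        """All facets of all cells (with repeats), sorted vertex tuples.

        Shape ``(C * (d+1), d)``.
        """
        idx = list(combinations(range(self.dim + 1), self.dim))
        f = np.concatenate([self.cells[:, list(c)] for c in idx], axis=0)
        return np.sort(f, axis=1)

    def boundary_facets(self) -> np.ndarray:
        """Facets appearing in exactly one cell."""
        f = self.cell_facets()
        uniq, counts = np.unique(f, axis=0, return_counts=True)
        return uniq[counts == 1]

    def validate(self, check_tags: bool = True) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure.

        Checks positive signed volumes, conformity (each interior facet shared
        by exactly two cells) and that hole facets lie strictly inside the
        bounding box.
        """
        sv = self.signed_volumes()
        bad = np.nonzero(sv <= 0)[0]
        if bad.size:
            raise MeshError(f"non-positive cell volume at cell {bad[0]}")
        f = self.cell_facets()
        _, counts = np.unique(f, axis=0, return_counts=True)
        if counts.max(initial=1) > 2:
            raise MeshError("non-conforming mesh: facet shared by >2 cells")
        if check_tags and self.facet_tags:
            lo = self.vertices.min(axis=0)
            hi = self.vertices.max(axis=0)
            tol = 1e-12 * max(np.max(hi - lo), 1.0)
            for facet, tag in self.facet_tags.items():
                if tag == HOLE_BOUNDARY:
                    pts = self.vertices[list(facet)]
                    if np.any(pts <= lo + tol) or np.any(pts >= hi - tol):
                        raise MeshError(
                            f"hole facet {facet} touches the outer bounding box")


@dataclass
class PeriodicMap:
    """Identification of opposite-face vertices of a periodic unit cell.

    ``pairs`` is an ``(S, 2)`` int array of ``(master, slave)`` vertex indices.
    Corner vertices are resolved transitively to a single master, so a corner
    slave may differ from its master in up to ``d`` coordinates (each by
    exactly the cell size ``L``).
    """

    pairs: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.ascontiguousarray(self.pairs, dtype=np.int64)
        if self.pairs.size == 0:
            self.pairs = self.pairs.reshape(0, 2)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise MeshError("pairs must be (S, 2)")

    @property
    def masters(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def slaves(self) -> np.ndarray:
        return self.pairs[:, 1]

    def validate(self, mesh: SimplicialMesh, L: float = 1.0) -> None:
        if self.pairs.size == 0:
            return
        if self.pairs.max() >= mesh.num_vertices or self.pairs.min() < 0:
            raise MeshError("periodic pair vertex index out of range")
        m = set(self.masters.tolist())
        s = self.slaves.tolist()
        if len(s) != len(set(s)):
            raise MeshError("a vertex appears more than once as a slave")
        if m & set(s):
            raise MeshError("a vertex is both master and slave")
        diff = np.abs(mesh.vertices[self.masters] - mesh.vertices[self.slaves])
        tol = 1e-9 * L
        ok = (diff < tol) | (np.abs(diff - L) < tol)
        if not np.all(ok):
            raise MeshError("paired vertices not offset by the cell size L")
        if not np.all(np.any(np.abs(diff - L) < tol, axis=1)):
            raise MeshError("paired vertices coincide")


@dataclass
class NodalField:
    """P1 nodal field: one real value per mesh vertex."""

    mesh: SimplicialMesh
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.num_vertices,):
            raise MeshError(
                f"field length {self.values.shape} != number of vertices "
                f"{self.mesh.num_vertices}")

    @classmethod
    def from_function(cls, mesh: SimplicialMesh, fn) -> "NodalField":
        """Nodal (Lagrange) interpolant of ``fn(points) -> values``."""
        return cls(mesh, np.asarray(fn(mesh.vertices), dtype=float))

    @classmethod
    def constant(cls, mesh: SimplicialMesh, value: float) -> "NodalField":
        return cls(mesh, np.full(mesh.num_vertices, float(value)))

    def integral(self) -> float:
        """Exact integral of the P1 interpolant over the mesh."""
        vols = self.mesh.cell_volumes()
        vert_vals = self.values[self.mesh.cells]
        return float(np.sum(vols * vert_vals.mean(axis=1)))

    def mean(self) -> float:
        return self.integral() / self.mesh.total_volume()
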