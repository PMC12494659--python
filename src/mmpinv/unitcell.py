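"""Perforated unit-cell and box meshes.

The reference microstructure is a unit cell ``[0, L]^d`` with an ``n x n``
(or ``n x n x n``) lattice of circular / spherical cells removed; the
remaining pore space is the extracellular matrix through which soluble
enzymes diffuse.  Meshes are produced by carving the inclusions out of a
structured background triangulation with a conforming level-set cut:

1.  vertices close to an inclusion surface (within a fraction of the local
    mesh size) are snapped exactly onto it,
2.  cells whose vertices are all strictly inside an inclusion are dropped,
3.  cells crossed by a surface are cut along the zero set of the linearly
    interpolated signed distance, which is a plane per simplex, so every
    kept fragment is the intersection of a simplex with a half-space and
    admits a valid sub-triangulation.

Quad faces produced by the cut are split with the classical minimum-vertex
rule so neighbouring cells agree on the diagonal and the mesh stays
conforming.  Opposite outer faces carry identical vertex traces (the cut
never creates boundary vertices), so the periodic identification needed by
the corrector problems is total.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

import numpy as np

from .mesh import (HOLE_BOUNDARY, MeshError, PeriodicMap, SimplicialMesh,
                   outer_face_tag)

SNAP_FRACTION = 0.25  # of local mesh size; controls worst-case cut-cell quality


class GeometryError(ValueError):
    """Invalid geometric specification (overlapping or touching inclusions)."""


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCellSpec:
    """Square/cube ``[0, L]^d`` minus an ``n^d`` lattice of balls of radius r.

    ``r`` is an absolute length (the study geometries use r = 3L/40 in 2d and
    r = 3L/25 in 3d).  Ball centres sit on the uniform lattice
    ``((2i-1) L / (2n))_{i=1..n}`` per axis.
    """

    dim: int
    n: int
    r: float
    L: float = 1.0
    mesh_size: float | None = None

    def __post_init__(self) -> None:
        if self.dim not in (2, 3):
            raise GeometryError("dim must be 2 or 3")
        if self.n < 0:
            raise GeometryError("lattice count n must be nonnegative")
        if self.n >= 1:
            if self.r <= 0:
                raise GeometryError("inclusion radius must be positive")
            if 2 * self.r >= self.L / self.n:
                raise GeometryError(
                    f"inclusions overlap or touch the boundary: "
                    f"2r = {2 * self.r:g} >= L/n = {self.L / self.n:g}")

    @property
    def centres(self) -> np.ndarray:
        if self.n == 0:
            return np.zeros((0, self.dim))
        axis = (2 * np.arange(1, self.n + 1) - 1) * self.L / (2 * self.n)
        grids = np.meshgrid(*([axis] * self.dim), indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def default_divisions(self) -> int:
        """Background-grid divisions per axis (multiple of 2n so lattice
        centres and mid-planes between inclusions fall on grid planes)."""
        target = 192 if self.dim == 2 else 36
        if self.mesh_size is not None:
            target = max(2, int(round(self.L / self.mesh_size)))
        if self.n >= 1:
            q = 2 * self.n
            target = q * max(1, int(np.ceil(target / q)))
        return target


@dataclass(frozen=True)
class BoxDomainSpec:
    """Axis-aligned simulation box with a target mesh size."""

    dim: int
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    mesh_size: float

    def __post_init__(self) -> None:
        if len(self.lower) != self.dim or len(self.upper) != self.dim:
            raise GeometryError("corner coordinates must have length dim")
        if not all(u > lo for lo, u in zip(self.lower, self.upper)):
            raise GeometryError("upper corner must exceed lower componentwise")
        if self.mesh_size <= 0:
            raise GeometryError("mesh_size must be positive")


def ecm_fraction(spec: UnitCellSpec) -> float:
    """Analytic ECM (pore) volume fraction ``1 - n^d w_d r^d / L^d``.

    ``w_2 = pi`` (disc area) and ``w_3 = 4 pi / 3`` (ball volume).
    """
    if spec.n == 0:
        return 1.0
    w = pi if spec.dim == 2 else 4 * pi / 3
    frac = 1.0 - spec.n ** spec.dim * w * spec.r ** spec.dim / spec.L ** spec.dim
    if frac <= 0:
        raise GeometryError("inclusions fill the whole cell")
    return frac


# --------------------------------------------------------------------------
# inclusions
# --------------------------------------------------------------------------

class Ball:
    """Disc (2d) or sphere (3d) inclusion."""

    def __init__(self, centre, radius: float):
        self.centre = np.asarray(centre, dtype=float)
        self.radius = float(radius)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return np.linalg.norm(pts - self.centre, axis=-1) - self.radius

    def project(self, pts: np.ndarray) -> np.ndarray:
        v = pts - self.centre
        nrm = np.linalg.norm(v, axis=-1, keepdims=True)
        nrm = np.where(nrm == 0, 1.0, nrm)
        return self.centre + v / nrm * self.radius


class Slab:
    """Layer ``a < x_axis < b`` removed across the whole cell (test geometry
    with a closed-form corrector)."""

    def __init__(self, axis: int, a: float, b: float):
        self.axis, self.a, self.b = axis, float(a), float(b)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        x = pts[..., self.axis]
        return np.maximum(self.a - x, x - self.b)

    def project(self, pts: np.ndarray) -> np.ndarray:
        x = pts[..., self.axis]
        target = np.where(np.abs(x - self.a) <= np.abs(x - self.b),
                          self.a, self.b)
        out = pts.copy()
        out[..., self.axis] = target
        return out


# --------------------------------------------------------------------------
# structured background meshes
# --------------------------------------------------------------------------

def _crossed_grid(lower, upper, divisions):
    """2d crossed (union-jack) triangulation: 4 triangles per square, mirror
    symmetric about both axes, so symmetric microstructures stay symmetric."""
    (x0, y0), (x1, y1) = lower, upper
    mx, my = divisions
    xs = np.linspace(x0, x1, mx + 1)
    ys = np.linspace(y0, y1, my + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    corners = np.stack([X.ravel(), Y.ravel()], axis=1)
    cx = 0.5 * (xs[:-1] + xs[1:])
    cy = 0.5 * (ys[:-1] + ys[1:])
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    centres = np.stack([CX.ravel(), CY.ravel()], axis=1)
    verts = np.concatenate([corners, centres], axis=0)
    nc = corners.shape[0]

    def cid(i, j):
        return i * (my + 1) + j

    I, J = np.meshgrid(np.arange(mx), np.arange(my), indexing="ij")
    I, J = I.ravel(), J.ravel()
    v00, v10 = cid(I, J), cid(I + 1, J)
    v01, v11 = cid(I, J + 1), cid(I + 1, J + 1)
    vc = nc + I * my + J
    cells = np.concatenate([
        np.stack([v00, v10, vc], axis=1),
        np.stack([v10, v11, vc], axis=1),
        np.stack([v11, v01, vc], axis=1),
        np.stack([v01, v00, vc], axis=1),
    ], axis=0)
    return verts, cells


def _kuhn_grid(lower, upper, divisions):
    """3d Kuhn triangulation: 6 tetrahedra per cube, identical in every cube
    so opposite outer faces carry matching triangulations."""
    (x0, y0, z0), (x1, y1, z1) = lower, upper
    mx, my, mz = divisions
    xs = np.linspace(x0, x1, mx + 1)
    ys = np.linspace(y0, y1, my + 1)
    zs = np.linspace(z0, z1, mz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * (my + 1) + j) * (mz + 1) + k

    I, J, K = np.meshgrid(np.arange(mx), np.arange(my), np.arange(mz),
                          indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    c = {}
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                c[(di, dj, dk)] = vid(I + di, J + dj, K + dk)
    # six tets around the main diagonal (0,0,0)-(1,1,1)
    paths = [((1, 0, 0), (1, 1, 0)), ((1, 0, 0), (1, 0, 1)),
             ((0, 1, 0), (1, 1, 0)), ((0, 1, 0), (0, 1, 1)),
             ((0, 0, 1), (1, 0, 1)), ((0, 0, 1), (0, 1, 1))]
    cells = np.concatenate([
        np.stack([c[(0, 0, 0)], c[p], c[q], c[(1, 1, 1)]], axis=1)
        for p, q in paths], axis=0)
    return verts, cells


# --------------------------------------------------------------------------
# conforming level-set cut
# --------------------------------------------------------------------------

def _quad_split(q0, q1, q2, q3):
    """Split quad (cyclic order) into 2 triangles along the diagonal through
    its minimum global vertex id (neighbour-consistent)."""
    if min(q0, q2) < min(q1, q3):
        return [(q0, q1, q2), (q0, q2, q3)]
    return [(q1, q2, q3), (q1, q3, q0)]


def _prism_split(p):
    """Split prism (p0,p1,p2 | p3,p4,p5), quads (i, i+1, i+4, i+3), into
    three tets with min-vertex-rule quad diagonals (Dompierre et al.)."""
    p = list(p)
    k = int(np.argmin(p))
    if k >= 3:           # mirror so the minimum is in the first layer
        p = p[3:] + p[:3]
        k -= 3
    p = [p[(k + i) % 3] for i in range(3)] + \
        [p[3 + (k + i) % 3] for i in range(3)]
    if min(p[1], p[5]) < min(p[2], p[4]):
        return [(p[0], p[1], p[2], p[5]), (p[0], p[1], p[5], p[4]),
                (p[0], p[4], p[5], p[3])]
    return [(p[0], p[1], p[2], p[4]), (p[0], p[4], p[2], p[5]),
            (p[0], p[4], p[5], p[3])]


def carve(vertices: np.ndarray, cells: np.ndarray, inclusions,
          frozen: np.ndarray, h: float):
    """Remove the inclusion interiors from a simplicial mesh.

    ``frozen`` marks vertices (e.g. on the outer boundary) that must not be
    snapped.  Returns ``(vertices, cells, on_surface)`` where ``on_surface``
    flags vertices lying on an inclusion surface; unused vertices are kept in
    place (callers compact afterwards).
    """
    verts = vertices.copy()
    dim = verts.shape[1]
    sd = np.stack([inc.signed_distance(verts) for inc in inclusions], axis=1)
    nearest = np.argmin(np.abs(sd), axis=1)
    d = np.min(sd, axis=1)

    snap = (np.abs(d) < SNAP_FRACTION * h) & ~frozen
    for i in np.nonzero(snap)[0]:
        verts[i] = inclusions[nearest[i]].project(verts[i])
        d[i] = 0.0

    neg = d < 0
    nneg = neg[cells].sum(axis=1)
    keep = cells[nneg == 0]
    cut = cells[(nneg > 0) & (nneg < dim + 1)]

    new_verts = [verts]
    next_id = verts.shape[0]
    edge_cut: dict[tuple[int, int], int] = {}
    extra = []

    def cut_point(a: int, b: int) -> int:
        """Vertex on the zero of the interpolated distance on edge (a, b);
        a is on the kept side.  Reuses a itself when it sits on the surface."""
        nonlocal next_id
        if d[a] == 0.0:
            return a
        key = (a, b) if a < b else (b, a)
        idx = edge_cut.get(key)
        if idx is None:
            t = d[key[0]] / (d[key[0]] - d[key[1]])
            extra.append(verts[key[0]] + t * (verts[key[1]] - verts[key[0]]))
            idx = next_id
            next_id += 1
            edge_cut[key] = idx
        return idx

    new_cells = []
    if dim == 2:
        for tri in cut:
            poly = []
            for i in range(3):
                a, b = tri[i], tri[(i + 1) % 3]
                if not neg[a]:
                    poly.append(int(a))
                if neg[a] != neg[b]:
                    poly.append(cut_point(int(b) if neg[a] else int(a),
                                          int(a) if neg[a] else int(b)))
            poly = [p for i, p in enumerate(poly) if p != poly[i - 1]]
            if len(poly) == 3:
                new_cells.append(tuple(poly))
            elif len(poly) == 4:
                new_cells.extend(_quad_split(*poly))
    else:
        for tet in cut:
            pos = [int(v) for v in tet if not neg[v]]
            ngs = [int(v) for v in tet if neg[v]]
            if len(ngs) == 3:
                A = pos[0]
                new_cells.append((A, cut_point(A, ngs[0]),
                                  cut_point(A, ngs[1]), cut_point(A, ngs[2])))
            elif len(ngs) == 1:
                D = ngs[0]
                A, B, C = pos
                new_cells.extend(_prism_split(
                    (A, B, C, cut_point(A, D), cut_point(B, D),
                     cut_point(C, D))))
            else:
                A, B = pos
                C, D = ngs
                new_cells.extend(_prism_split(
                    (A, cut_point(A, C), cut_point(A, D),
                     B, cut_point(B, C), cut_point(B, D))))

    if extra:
        new_verts.append(np.asarray(extra))
    all_verts = np.concatenate(new_verts, axis=0)
    frag = np.asarray([c for c in new_cells if len(set(c)) == dim + 1],
                      dtype=np.int64).reshape(-1, dim + 1)
    all_cells = np.concatenate([keep, frag], axis=0)

    # drop exactly degenerate fragments, orient the rest positively
    v = all_verts[all_cells]
    det = np.linalg.det((v[:, 1:, :] - v[:, :1, :]).transpose(0, 2, 1))
    scale = h ** dim
    all_cells = all_cells[np.abs(det) > 1e-12 * scale]
    on_surface = np.zeros(all_verts.shape[0], dtype=bool)
    on_surface[:verts.shape[0]] = d == 0.0
    on_surface[verts.shape[0]:] = True
    return all_verts, all_cells, on_surface


def _compact(verts, cells):
    used = np.unique(cells)
    remap = np.full(verts.shape[0], -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return verts[used], remap[cells], remap


def _tag_facets(mesh: SimplicialMesh, lower, upper) -> None:
    tol = 1e-9 * float(np.max(np.asarray(upper) - np.asarray(lower)))
    for facet in mesh.boundary_facets():
        pts = mesh.vertices[facet]
        tag = HOLE_BOUNDARY
        for axis in range(mesh.dim):
            if np.all(np.abs(pts[:, axis] - lower[axis]) < tol):
                tag = outer_face_tag(axis, 0)
                break
            if np.all(np.abs(pts[:, axis] - upper[axis]) < tol):
                tag = outer_face_tag(axis, 1)
                break
        mesh.facet_tags[tuple(int(i) for i in facet)] = tag


def _periodic_pairs(mesh: SimplicialMesh, lower, upper) -> PeriodicMap:
    """Match every outer-face vertex with >=1 maximal coordinate to the
    vertex at the componentwise-minimal position (corners resolve to one
    master)."""
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    L = hi - lo
    tol = 1e-9 * float(np.max(L))
    v = mesh.vertices
    on_lo = np.abs(v - lo) < tol
    on_hi = np.abs(v - hi) < tol
    boundary = np.nonzero(np.any(on_lo | on_hi, axis=1))[0]
    scale = np.maximum(L, 1.0)
    key = {tuple(np.round((v[i] - lo) / scale, 9)): int(i) for i in boundary}
    pairs = []
    for i in boundary:
        if not np.any(on_hi[i]):
            continue
        target = np.where(on_hi[i], lo, v[i])
        k = tuple(np.round((target - lo) / scale, 9))
        j = key.get(k)
        if j is None:
            raise MeshError(
                f"periodic master missing for vertex {i} at {v[i]}")
        pairs.append((j, int(i)))
    return PeriodicMap(np.asarray(pairs, dtype=np.int64).reshape(-1, 2))


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def build_perforated_box(lower, upper, divisions, inclusions,
                         periodic: bool = False):
    """Generic carved box mesh; returns ``(mesh, pmap-or-None)``."""
    dim = len(lower)
    divisions = tuple(divisions)
    if dim == 2:
        verts, cells = _crossed_grid(lower, upper, divisions)
    else:
        verts, cells = _kuhn_grid(lower, upper, divisions)
    h = max((u - lo) / m for lo, u, m in zip(lower, upper, divisions))
    if inclusions:
        lo = np.asarray(lower)
        hi = np.asarray(upper)
        tol = 1e-9 * float(np.max(hi - lo))
        frozen = np.any((np.abs(verts - lo) < tol) |
                        (np.abs(verts - hi) < tol), axis=1)
        verts, cells, _ = carve(verts, cells, inclusions, frozen, h)
        verts, cells, _ = _compact(verts, cells)
    mesh = SimplicialMesh(dim, verts, cells)
    mesh.orient()
    _tag_facets(mesh, lower, upper)
    pmap = _periodic_pairs(mesh, lower, upper) if periodic else None
    return mesh, pmap


def build_unit_cell_mesh(spec: UnitCellSpec
                         ) -> tuple[SimplicialMesh, PeriodicMap]:
    """Mesh the perforated unit cell with tagged hole boundaries and a total
    periodic identification of opposite outer faces."""
    ecm_fraction(spec)  # validates the geometry
    m = spec.default_divisions()
    inclusions = [Ball(c, spec.r) for c in spec.centres]
    lower = (0.0,) * spec.dim
    upper = (spec.L,) * spec.dim
    try:
        mesh, pmap = build_perforated_box(lower, upper, (m,) * spec.dim,
                                          inclusions, periodic=True)
        mesh.validate()
        pmap.validate(mesh, spec.L)
    except MeshError as exc:
        raise MeshError(
            f"meshing failed for {spec!r} (divisions={m}): {exc}") from exc
    vol = mesh.total_volume() / spec.L ** spec.dim
    target = ecm_fraction(spec)
    if abs(vol - target) > 0.02 * target:
        raise MeshError(
            f"meshed pore fraction {vol:.4f} deviates >2% from analytic "
            f"{target:.4f} for {spec!r}")
    return mesh, pmap


def build_box_mesh(spec: BoxDomainSpec) -> SimplicialMesh:
    """Uniform simplicial mesh of the simulation box."""
    divisions = tuple(
        max(1, int(round((u - lo) / spec.mesh_size)))
        for lo, u in zip(spec.lower, spec.upper))
    mesh, _ = build_perforated_box(spec.lower, spec.upper, divisions, [],
                                   periodic=False)
    return mesh
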