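"""Mesh and result file IO.

Meshes round-trip through a single-partition subset of the ASCII Gmsh 4.1
format (one node block, one element block per facet tag, physical names
carrying the tags).  Simulation snapshots are written as ASCII VTU
unstructured grids with nodal fields; VTU is export-only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import SimplicialMesh

_CELL_TYPE = {2: 2, 3: 4}        # gmsh: triangle, tetrahedron
_FACET_TYPE = {2: 1, 3: 2}       # gmsh: line, triangle
_VTK_CELL = {2: 5, 3: 10}        # vtk: triangle, tetra


def write_msh(mesh: SimplicialMesh, path) -> None:
    """Write the mesh with its facet tags as ASCII Gmsh 4.1."""
    path = Path(path)
    d = mesh.dim
    groups: dict[str, list[tuple[int, ...]]] = {}
    for facet, tag in mesh.facet_tags.items():
        groups.setdefault(tag, []).append(facet)
    names = sorted(groups)
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(names) + 1)]
    for i, name in enumerate(names, start=1):
        lines.append(f'{d - 1} {i} "{name}"')
    lines.append(f'{d} {len(names) + 1} "domain"')
    lines.append("$EndPhysicalNames")

    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    bbox = " ".join(f"{x:.16g}" for x in
                    list(lo) + [0.0] * (3 - d) + list(hi) + [0.0] * (3 - d))
    lines.append("$Entities")
    if d == 2:
        lines.append(f"0 {len(names)} 1 0")
        for i in range(1, len(names) + 1):
            lines.append(f"{i} {bbox} 1 {i} 0")
        lines.append(f"{len(names) + 1} {bbox} 1 {len(names) + 1} 0")
    else:
        lines.append(f"0 0 {len(names)} 1")
        for i in range(1, len(names) + 1):
            lines.append(f"{i} {bbox} 1 {i} 0")
        lines.append(f"{len(names) + 1} {bbox} 1 {len(names) + 1} 0")
    lines.append("$EndEntities")

    V = mesh.num_vertices
    lines += ["$Nodes", f"1 {V} 1 {V}", f"{d} {len(names) + 1} 0 {V}"]
    lines += [str(i + 1) for i in range(V)]
    for p in mesh.vertices:
        coords = list(p) + [0.0] * (3 - d)
        lines.append(" ".join(f"{x:.16g}" for x in coords))
    lines.append("$EndNodes")

    nelem = mesh.num_cells + sum(len(v) for v in groups.values())
    blocks = []
    tag = 1
    for i, name in enumerate(names, start=1):
        facets = groups[name]
        blocks.append(f"{d - 1} {i} {_FACET_TYPE[d]} {len(facets)}")
        for f in facets:
            blocks.append(f"{tag} " + " ".join(str(v + 1) for v in f))
            tag += 1
    blocks.append(f"{d} {len(names) + 1} {_CELL_TYPE[d]} {mesh.num_cells}")
    for c in mesh.cells:
        blocks.append(f"{tag} " + " ".join(str(v + 1) for v in c))
        tag += 1
    lines += ["$Elements",
              f"{len(names) + 1} {nelem} 1 {nelem}"] + blocks + ["$EndElements"]
    path.write_text("\n".join(lines) + "\n")


def read_msh(path) -> SimplicialMesh:
    """Read a mesh written by :func:`write_msh` (facet tags restored)."""
    tokens = Path(path).read_text().split("\n")
    idx = {line.strip(): i for i, line in enumerate(tokens)
           if line.startswith("$")}

    def section(name):
        return tokens[idx[f"${name}"] + 1: idx[f"$End{name}"]]

    phys = {}
    body = section("PhysicalNames")
    for line in body[1:]:
        pdim, ptag, pname = line.split(maxsplit=2)
        phys[(int(pdim), int(ptag))] = pname.strip('"')

    body = section("Nodes")
    _, num_nodes, _, _ = (int(x) for x in body[0].split())
    cursor = 1
    coords = np.empty((num_nodes, 3))
    order = np.empty(num_nodes, dtype=np.int64)
    filled = 0
    while filled < num_nodes:
        _, _, _, nblock = (int(x) for x in body[cursor].split())
        cursor += 1
        for k in range(nblock):
            order[filled + k] = int(body[cursor + k]) - 1
        for k in range(nblock):
            coords[filled + k] = [float(x)
                                  for x in body[cursor + nblock + k].split()]
        cursor += 2 * nblock
        filled += nblock

    body = section("Elements")
    nblocks = int(body[0].split()[0])
    cursor = 1
    cells = []
    facet_groups = []
    dim = 2
    for _ in range(nblocks):
        edim, etag, etype, nblock = (int(x) for x in body[cursor].split())
        cursor += 1
        conn = [[int(x) - 1 for x in body[cursor + k].split()[1:]]
                for k in range(nblock)]
        cursor += nblock
        if etype in (2, 4) and (edim, etag) in phys \
                and phys[(edim, etag)] == "domain":
            dim = edim
            cells = conn
        else:
            facet_groups.append((phys.get((edim, etag), "untagged"), conn))
    verts = np.empty((num_nodes, dim))
    verts[order] = coords[:, :dim]
    tags = {}
    for name, conn in facet_groups:
        for f in conn:
            tags[tuple(sorted(f))] = name
    mesh = SimplicialMesh(dim, verts, np.asarray(cells, dtype=np.int64),
                          tags)
    mesh.orient()
    return mesh


def write_vtu(mesh: SimplicialMesh, path, point_data: dict | None = None
              ) -> None:
    """ASCII VTU export of the mesh with optional nodal fields."""
    d = mesh.dim
    pts = np.hstack([mesh.vertices,
                     np.zeros((mesh.num_vertices, 3 - d))])
    out = ['<?xml version="1.0"?>',
           '<VTKFile type="UnstructuredGrid" version="0.1" '
           'byte_order="LittleEndian">',
           '<UnstructuredGrid>',
           f'<Piece NumberOfPoints="{mesh.num_vertices}" '
           f'NumberOfCells="{mesh.num_cells}">',
           '<Points>',
           '<DataArray type="Float64" NumberOfComponents="3" format="ascii">']
    out += [" ".join(f"{x:.16g}" for x in p) for p in pts]
    out += ['</DataArray>', '</Points>', '<Cells>',
            '<DataArray type="Int64" Name="connectivity" format="ascii">']
    out += [" ".join(str(v) for v in c) for c in mesh.cells]
    out += ['</DataArray>',
            '<DataArray type="Int64" Name="offsets" format="ascii">',
            " ".join(str((i + 1) * (d + 1))
                     for i in range(mesh.num_cells)),
            '</DataArray>',
            '<DataArray type="UInt8" Name="types" format="ascii">',
            " ".join(str(_VTK_CELL[d]) for _ in range(mesh.num_cells)),
            '</DataArray>', '</Cells>']
    out.append('<PointData>')
    for name, values in (point_data or {}).items():
        out.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
        out.append(" ".join(f"{x:.16g}" for x in np.asarray(values)))
        out.append('</DataArray>')
    out += ['</PointData>', '</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    Path(path).write_text("\n".join(out) + "\n")


def read_vtu(path) -> tuple[SimplicialMesh, dict[str, np.ndarray]]:
    """Read an ASCII VTU file written by :func:`write_vtu`."""
    from xml.etree import ElementTree
    root = ElementTree.parse(path).getroot()
    piece = root.find("UnstructuredGrid/Piece")
    pts = np.fromstring(
        piece.find("Points/DataArray").text.replace("\n", " "),
        sep=" ").reshape(-1, 3)
    arrays = {a.get("Name"): a for a in piece.find("Cells")}
    conn = np.fromstring(arrays["connectivity"].text.replace("\n", " "),
                         sep=" ").astype(np.int64)
    types = np.fromstring(arrays["types"].text.replace("\n", " "), sep=" ")
    dim = 2 if int(types[0]) == 5 else 3
    cells = conn.reshape(-1, dim + 1)
    mesh = SimplicialMesh(dim, pts[:, :dim], cells)
    mesh.orient()
    fields = {}
    pdata = piece.find("PointData")
    if pdata is not None:
        for a in pdata:
            fields[a.get("Name")] = np.fromstring(
                a.text.replace("\n", " "), sep=" ")
    return mesh, fields


MONITOR_COLUMNS = ["t", "phi_min", "phi_max", "cs_min", "cs_max",
                   "b_min", "b_max", "s_min", "s_max", "bounds_ok",
                   "invaded_area", "front_anisotropy"]


def write_outputs(trajectory, out_dir, scenario=None, level: float = 0.25
                  ) -> dict:
    """Write a run directory: VTU snapshot series, monitors.csv, manifest.

    Snapshot files are ``snapshot_####.vtu`` with fields ``phi``, ``cs``,
    ``b``, ``cb`` (reconstructed) and ``s``; ``monitors.csv`` has the fixed
    column set :data:`MONITOR_COLUMNS` (one row per time step);
    ``manifest.json`` records the full provenance.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snap_files = []
    for i, st in enumerate(trajectory.snapshots):
        fname = f"snapshot_{i:04d}.vtu"
        write_vtu(st.mesh, out / fname, {
            "phi": st.phi.values, "cs": st.cs.values, "b": st.b.values,
            "cb": st.cb_reconstructed().values, "s": st.s.values})
        snap_files.append({"file": fname, "t": st.t})
    rows = []
    for row in trajectory.monitors:
        rows.append({k: row.get(k, float("nan")) for k in MONITOR_COLUMNS})
    pd.DataFrame(rows, columns=MONITOR_COLUMNS).to_csv(
        out / "monitors.csv", index=False)
    from . import __version__
    manifest = {
        "software": {"name": "mmpinv", "version": __version__},
        "deterministic": True,
        "note": "all computations are seed-free and deterministic",
        "level": level,
        "snapshots": snap_files,
        "num_steps": len(trajectory.times) - 1,
    }
    if scenario is not None:
        manifest["scenario"] = scenario.config()
        mesh = trajectory.final.mesh
        manifest["mesh"] = {"dim": mesh.dim, "vertices": mesh.num_vertices,
                            "cells": mesh.num_cells}
        from dataclasses import asdict
        p = asdict(scenario.params)
        p["diffusivity"] = {k: p["diffusivity"][k]
                            for k in ("a3", "a2", "a1", "Ds1", "dim")}
        manifest["params"] = p
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
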