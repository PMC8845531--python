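"""File formats: legacy ASCII VTK polydata, HDF5 Vm movies, JSON/YAML.

The VTK writer emits the legacy ASCII format (POLYDATA with POINT_DATA /
CELL_DATA scalars) readable by ParaView and VTK-based toolkits; meshes
stay text-only and dependency-free.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import SurfaceMesh


def write_vtk_polydata(path, mesh: SurfaceMesh, point_data: dict | None = None,
                       cell_data: dict | None = None) -> None:
    """Write the mesh as legacy ASCII VTK polydata with optional per-vertex
    (point) and per-triangle (cell) scalar fields."""
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", "afstress surface mesh", "ASCII",
             "DATASET POLYDATA", f"POINTS {mesh.n_vertices} float"]
    lines += [" ".join(f"{x:.6f}" for x in v) for v in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]

    def scalar_block(name, arr):
        arr = np.asarray(arr, dtype=float).ravel()
        blk = [f"SCALARS {name} float 1", "LOOKUP_TABLE default"]
        blk += [f"{x:.6f}" for x in arr]
        return blk

    cell_data = dict(cell_data or {})
    cell_data.setdefault("region_label", mesh.region_label)
    lines.append(f"CELL_DATA {mesh.n_triangles}")
    for name, arr in cell_data.items():
        lines += scalar_block(name, arr)
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, arr in point_data.items():
            lines += scalar_block(name, arr)
    path.write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path):
    """Read back a mesh written by :func:`write_vtk_polydata`.

    Returns (vertices, triangles, cell_data, point_data)."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    verts = tris = None
    cell_data: dict = {}
    point_data: dict = {}
    target = None
    for line in it:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "POINTS":
            n = int(parts[1])
            verts = np.array([next(it).split() for _ in range(n)], dtype=float)
        elif parts[0] == "POLYGONS":
            m = int(parts[1])
            rows = [next(it).split() for _ in range(m)]
            tris = np.array(rows, dtype=int)[:, 1:]
        elif parts[0] == "CELL_DATA":
            target = ("cell", int(parts[1]))
        elif parts[0] == "POINT_DATA":
            target = ("point", int(parts[1]))
        elif parts[0] == "SCALARS" and target is not None:
            name = parts[1]
            next(it)  # LOOKUP_TABLE
            vals = np.array([next(it) for _ in range(target[1])], dtype=float)
            (cell_data if target[0] == "cell" else point_data)[name] = vals
    return verts, tris, cell_data, point_data


def save_movie_h5(path, movie, mesh_hash: str = "") -> None:
    """Persist a VmMovie to HDF5 (vm [time x vertex], times, stimulus log)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("vm", data=movie.vm, compression="gzip", compression_opts=4)
        f.create_dataset("times", data=movie.times)
        f.attrs["sample_interval_ms"] = movie.sample_interval
        f.attrs["mesh_hash"] = mesh_hash
        f.attrs["stimulus_log"] = json.dumps(movie.stimulus_log)


def load_movie_h5(path):
    import h5py

    from .ep import VmMovie

    with h5py.File(path, "r") as f:
        return VmMovie(vm=f["vm"][...], times=f["times"][...],
                       sample_interval=float(f.attrs["sample_interval_ms"]),
                       stimulus_log=json.loads(f.attrs["stimulus_log"]))


def save_substrate_h5(path, substrate) -> None:
    """Persist a substrate (fields + provenance) for reproducibility audits."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("vertices", data=substrate.mesh.vertices)
        f.create_dataset("triangles", data=substrate.mesh.triangles)
        f.create_dataset("region_label", data=substrate.mesh.region_label)
        f.create_dataset("fiber_directions", data=substrate.fibers.directions)
        f.create_dataset("d_long", data=substrate.conductivity.d_long)
        f.create_dataset("d_trans", data=substrate.conductivity.d_trans)
        f.create_dataset("apd_scale", data=substrate.apd_scale)
        f.create_dataset("excitability_scale", data=substrate.excitability_scale)
        f.create_dataset("decoupled_edges", data=substrate.decoupled_edges)
        f.create_dataset("ablated_triangles", data=substrate.ablated_triangles)
        if substrate.fibrosis is not None:
            f.create_dataset("iir", data=substrate.fibrosis.iir)
        f.attrs["hash"] = substrate.substrate_hash()
        f.attrs["provenance"] = json.dumps(substrate.provenance, default=str)
        f.attrs["cell"] = repr(substrate.cell)


def load_substrate_h5(path):
    """Load a substrate saved by :func:`save_substrate_h5`."""
    import h5py

    from .cohort import FiberField, FibrosisMap
    from .ep import ConductivityField, SubstrateModel
    from .geometry import find_boundary_loops

    with h5py.File(path, "r") as f:
        mesh = SurfaceMesh(f["vertices"][...], f["triangles"][...],
                           f["region_label"][...])
        mesh.boundary_loops = find_boundary_loops(mesh.triangles)
        fib = FibrosisMap(iir=f["iir"][...]) if "iir" in f else None
        sub = SubstrateModel(
            mesh=mesh,
            fibers=FiberField(directions=f["fiber_directions"][...],
                              variant="restored"),
            conductivity=ConductivityField(f["d_long"][...], f["d_trans"][...]),
            apd_scale=f["apd_scale"][...],
            excitability_scale=f["excitability_scale"][...],
            fibrosis=fib,
            decoupled_edges=f["decoupled_edges"][...],
            ablated_triangles=f["ablated_triangles"][...],
            provenance=json.loads(f.attrs["provenance"]))
    return sub


def save_initiation_map(path, imap) -> None:
    Path(path).write_text(json.dumps(
        {"variant": imap.variant, "core_radius": imap.core_radius,
         "seeds": [[int(v), int(q)] for v, q in imap.seeds]}, indent=2))


def save_lesion_vtk(path, mesh: SurfaceMesh, lesion) -> None:
    mask = np.zeros(mesh.n_triangles)
    mask[lesion.triangles] = 1.0
    write_vtk_polydata(path, mesh, cell_data={"ablated": mask})
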