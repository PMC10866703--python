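"""File input/output: mesh export, fixture containers, tables.

Meshes go out as legacy-ASCII VTK polydata (one frame per file; cell type
as an integer cell-data array) or as OFF for single cells; fixtures are
stored in a self-describing HDF5 container.  Vector fields and point
patterns travel as plain-text CSV with unit-annotated headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .morphometrics import PointPattern2D, VectorField2D
from .tissue_geometry import PeriodicBox, TissueMesh

VTK_TYPE_ARRAY = "cell_type"  # 0 membrane, 1 basal, 2 placode, 3 suprabasal


def write_vtk_polydata(mesh: TissueMesh, path) -> Path:
    """Write the mesh faces as VTK legacy polydata with per-face owner type.

    Each face is emitted once, unwrapped about its first vertex; the
    cell-data array carries the max of the two owners' type codes so
    placode faces are visible over membrane/suprabasal neighbours.
    """
    path = Path(path)
    pts, polys, types = [], [], []
    for fid, f in enumerate(mesh.faces):
        if f is None:
            continue
        Q = mesh.face_coords(fid)
        base = len(pts)
        pts.extend(map(tuple, Q))
        polys.append([base + k for k in range(len(Q))])
        o = mesh.face_owners[fid]
        types.append(int(max(mesh.cell_types[o[0]], mesh.cell_types[o[1]])))
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("placode tissue frame\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
        ntot = sum(len(p) + 1 for p in polys)
        fh.write(f"POLYGONS {len(polys)} {ntot}\n")
        for p in polys:
            fh.write(" ".join(map(str, [len(p)] + p)) + "\n")
        fh.write(f"CELL_DATA {len(polys)}\n")
        fh.write(f"SCALARS {VTK_TYPE_ARRAY} int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(map(str, types)) + "\n")
    return path


def write_cell_off(mesh: TissueMesh, cell_id: int, path) -> Path:
    """Export one cell as an OFF polyhedron (outward-oriented faces)."""
    import trimesh

    pts, polys = mesh.cell_polyhedron(cell_id)
    tris = []
    for poly in polys:
        for k in range(1, len(poly) - 1):
            tris.append([poly[0], poly[k], poly[k + 1]])
    tm = trimesh.Trimesh(vertices=pts, faces=np.asarray(tris), process=False)
    path = Path(path)
    tm.export(path, file_type="off")
    return path


def save_mesh_h5(mesh: TissueMesh, path) -> Path:
    """Self-describing HDF5 fixture: vertices, ragged faces, cell table."""
    path = Path(path)
    live = [fid for fid, f in enumerate(mesh.faces) if f is not None]
    flat = np.concatenate([mesh.faces[fid] for fid in live]) if live else np.zeros(0, int)
    lens = np.asarray([len(mesh.faces[fid]) for fid in live], dtype=np.int64)
    owners = np.asarray([mesh.face_owners[fid] for fid in live], dtype=np.int64)
    cf_flat = np.concatenate([np.asarray(c, dtype=np.int64) for c in mesh.cells]) \
        if mesh.cells else np.zeros(0, int)
    cf_lens = np.asarray([len(c) for c in mesh.cells], dtype=np.int64)
    remap = -np.ones(len(mesh.faces), dtype=np.int64)
    remap[live] = np.arange(len(live))
    with h5py.File(path, "w") as h:
        h.attrs["format"] = "placode-tissue-v1"
        h.create_dataset("box/lengths", data=np.asarray(mesh.box.L))
        h.create_dataset("box/periodic", data=np.asarray(mesh.box.periodic, dtype=np.int8))
        h.create_dataset("vertices", data=mesh.X)
        h.create_dataset("alive_vertex", data=mesh.alive_vertex.astype(np.int8))
        h.create_dataset("faces/flat", data=flat)
        h.create_dataset("faces/lengths", data=lens)
        h.create_dataset("faces/owners", data=owners)
        h.create_dataset("cells/face_flat", data=remap[cf_flat])
        h.create_dataset("cells/face_lengths", data=cf_lens)
        h.create_dataset("cells/type", data=mesh.cell_types)
        h.create_dataset("cells/V0", data=mesh.V0)
        h.create_dataset("cells/S0", data=mesh.S0)
        h.create_dataset("cells/ref", data=mesh.cell_ref)
        h.create_dataset("cells/seed", data=mesh.seed_points)
    return path


def load_mesh_h5(path) -> TissueMesh:
    with h5py.File(path, "r") as h:
        box = PeriodicBox(tuple(h["box/lengths"][...]),
                          tuple(bool(x) for x in h["box/periodic"][...]))
        X = h["vertices"][...]
        lens = h["faces/lengths"][...]
        flat = h["faces/flat"][...]
        off = np.concatenate([[0], np.cumsum(lens)])
        faces = [flat[off[i]:off[i + 1]] for i in range(len(lens))]
        owners = [tuple(o) for o in h["faces/owners"][...]]
        cf_lens = h["cells/face_lengths"][...]
        cf_flat = h["cells/face_flat"][...]
        coff = np.concatenate([[0], np.cumsum(cf_lens)])
        cells = [list(cf_flat[coff[i]:coff[i + 1]]) for i in range(len(cf_lens))]
        mesh = TissueMesh(box, X, faces, owners, cells,
                          h["cells/ref"][...], h["cells/seed"][...])
        mesh.cell_types = h["cells/type"][...]
        mesh.V0 = h["cells/V0"][...]
        mesh.S0 = h["cells/S0"][...]
        mesh.alive_vertex = h["alive_vertex"][...].astype(bool)
    return mesh


# ---------------------------------------------------------------------------
# plain-text fields / patterns / masks
# ---------------------------------------------------------------------------

def write_field_csv(fld: VectorField2D, path) -> Path:
    path = Path(path)
    X, Y = fld.node_xy()
    df = pd.DataFrame({
        "x_slu": X.ravel(), "y_slu": Y.ravel(),
        "u_slu_per_stu": fld.vec[..., 0].ravel(),
        "v_slu_per_stu": fld.vec[..., 1].ravel(),
    })
    df.to_csv(path, index=False)
    return path


def read_field_csv(path) -> VectorField2D:
    df = pd.read_csv(path)
    xs = np.unique(df.iloc[:, 0])
    ys = np.unique(df.iloc[:, 1])
    spacing = float(xs[1] - xs[0]) if len(xs) > 1 else float(ys[1] - ys[0])
    vec = np.full((len(ys), len(xs), 2), np.nan)
    ix = np.searchsorted(xs, df.iloc[:, 0])
    iy = np.searchsorted(ys, df.iloc[:, 1])
    vec[iy, ix, 0] = df.iloc[:, 2]
    vec[iy, ix, 1] = df.iloc[:, 3]
    return VectorField2D(origin=np.array([xs[0], ys[0]]), spacing=spacing, vec=vec)


def write_pattern_csv(pat: PointPattern2D, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"x_um": pat.points[:, 0], "y_um": pat.points[:, 1]})
    with path.open("w") as fh:
        fh.write(f"# center_um,{pat.center[0]},{pat.center[1]}\n")
        df.to_csv(fh, index=False)
    return path


def read_pattern_csv(path) -> PointPattern2D:
    path = Path(path)
    center = (0.0, 0.0)
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# center_um"):
            parts = first.strip().split(",")
            center = (float(parts[1]), float(parts[2]))
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return PointPattern2D(points=df[["x_um", "y_um"]].to_numpy(), center=center)


def write_mask_csv(mask: np.ndarray, path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(mask, dtype=np.int8), fmt="%d", delimiter=",")
    return path


def read_mask_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",").astype(bool)


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
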