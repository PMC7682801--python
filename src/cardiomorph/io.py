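"""File interchange: meshes (PLY / legacy VTK), contour CSV, atlas archives.

Meshes travel as ASCII PLY (via trimesh) or legacy ASCII VTK PolyData with
the node order preserved — node order is the cohort correspondence, so
readers and writers must never reorder vertices.  A JSON sidecar
(``<mesh>.grid.json``) carries the grid dimensions and the RV centroid
landmark, which the polygon formats have no standard slot for.

Contour stacks are flat CSVs with columns ``slice_z, surface, point_index,
x, y`` (surface ∈ {endo, epi}); the RV centroid and basal-plane z ride in a
sidecar JSON as well.

``load_mesh_directory`` is the adapter for externally deposited mesh sets:
it inspects each file's format, extracts vertices in stored order, checks
the cohort shares one node count, and returns either :class:`LVMesh`
objects (when grid sidecars exist) or raw shape vectors suitable for
:class:`~cardiomorph.atlas.ShapeModel`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .mesh import ContourStack, LVMesh, SliceContours

__all__ = [
    "grid_faces",
    "save_mesh",
    "load_mesh",
    "load_mesh_directory",
    "save_contours",
    "load_contours",
    "save_atlas",
    "load_atlas",
]


def grid_faces(n_circ: int, n_long: int) -> np.ndarray:
    """Triangle faces covering both lateral surfaces of the LV grid."""
    faces = []
    per = n_circ * n_long
    for s in (0, 1):
        for l in range(n_long - 1):
            for c in range(n_circ):
                a = s * per + l * n_circ + c
                b = s * per + l * n_circ + (c + 1) % n_circ
                cc = s * per + (l + 1) * n_circ + c
                d = s * per + (l + 1) * n_circ + (c + 1) % n_circ
                faces.append((a, b, cc))
                faces.append((b, d, cc))
    return np.asarray(faces, dtype=np.int64)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".grid.json")


def save_mesh(mesh: LVMesh, path: str | Path) -> Path:
    """Write a mesh as ASCII PLY (.ply) or legacy ASCII VTK PolyData (.vtk)."""
    path = Path(path)
    faces = grid_faces(mesh.n_circ, mesh.n_long)
    if path.suffix.lower() == ".ply":
        tm = trimesh.Trimesh(vertices=mesh.nodes, faces=faces, process=False)
        path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    elif path.suffix.lower() == ".vtk":
        _write_vtk_polydata(path, mesh.nodes, faces)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix!r} (use .ply/.vtk)")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "n_circ": mesh.n_circ,
                "n_long": mesh.n_long,
                "rv_centroid": list(map(float, mesh.rv_centroid)),
            }
        )
    )
    return path


def _write_vtk_polydata(path: Path, vertices: np.ndarray, faces: np.ndarray) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "cardiomorph LV surface mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} float",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in vertices]
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in faces]
    path.write_text("\n".join(lines) + "\n")


def _read_vtk_polydata(path: Path) -> np.ndarray:
    tokens = path.read_text().split()
    if "POINTS" not in tokens:
        raise ValueError(f"{path} is not a legacy VTK PolyData file")
    i = tokens.index("POINTS")
    n = int(tokens[i + 1])
    vals = [float(t) for t in tokens[i + 3 : i + 3 + 3 * n]]
    return np.asarray(vals).reshape(n, 3)


def _read_vertices(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix == ".vtk":
        return _read_vtk_polydata(path)
    loaded = trimesh.load(str(path), process=False)
    return np.asarray(loaded.vertices, dtype=float)


def load_mesh(path: str | Path) -> LVMesh:
    """Read a mesh written by :func:`save_mesh` (requires its grid sidecar)."""
    path = Path(path)
    vertices = _read_vertices(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"grid sidecar {sidecar.name} missing; use load_mesh_directory for "
            "external meshes without grid structure"
        )
    meta = json.loads(sidecar.read_text())
    return LVMesh(
        nodes=vertices,
        n_circ=int(meta["n_circ"]),
        n_long=int(meta["n_long"]),
        rv_centroid=np.asarray(meta["rv_centroid"], dtype=float),
    )


def load_mesh_directory(directory: str | Path, pattern: str = "*"):
    """Adapter for a directory of corresponded surface meshes.

    Every readable mesh file (.ply, .vtk, .obj, .stl, .off) is loaded with
    vertex order preserved.  If grid sidecars are present the result is a
    list of :class:`LVMesh`; otherwise a list of raw shape vectors (3N
    arrays) ready for :class:`~cardiomorph.atlas.ShapeModel`, plus the file
    names.  Raises if the files do not share one vertex count (no
    correspondence).

    Returns
    -------
    (shapes, names) : (list, list[str])
    """
    directory = Path(directory)
    exts = {".ply", ".vtk", ".obj", ".stl", ".off"}
    files = sorted(
        p for p in directory.glob(pattern)
        if p.suffix.lower() in exts and p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no mesh files found in {directory}")
    shapes, names = [], []
    counts = set()
    all_sidecars = all(_sidecar_path(p).exists() for p in files)
    for p in files:
        if all_sidecars:
            mesh = load_mesh(p)
            counts.add(mesh.n_nodes)
            shapes.append(mesh)
        else:
            v = _read_vertices(p)
            counts.add(len(v))
            shapes.append(v.reshape(-1))
        names.append(p.stem)
    if len(counts) != 1:
        raise ValueError(
            f"meshes in {directory} have differing vertex counts {sorted(counts)}; "
            "they are not corresponded"
        )
    return shapes, names


# ---------------------------------------------------------------------------
# contour stacks
# ---------------------------------------------------------------------------

def save_contours(stack: ContourStack, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for sl in stack.slices:
        for surface, pts in (("endo", sl.endo), ("epi", sl.epi)):
            for i, (x, y) in enumerate(pts):
                rows.append((sl.z, surface, i, x, y))
    pd.DataFrame(
        rows, columns=["slice_z", "surface", "point_index", "x", "y"]
    ).to_csv(path, index=False)
    meta = {
        "rv_centroid": list(map(float, stack.rv_centroid)),
        "basal_plane_z": float(stack.basal_plane_z),
    }
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def load_contours(path: str | Path) -> ContourStack:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar_path(path).read_text())
    slices = []
    for z in sorted(df["slice_z"].unique(), reverse=True):
        sub = df[df["slice_z"] == z]
        parts = {}
        for surface in ("endo", "epi"):
            s = sub[sub["surface"] == surface].sort_values("point_index")
            parts[surface] = s[["x", "y"]].to_numpy()
        slices.append(SliceContours(z=float(z), endo=parts["endo"], epi=parts["epi"]))
    return ContourStack(
        slices=slices,
        rv_centroid=np.asarray(meta["rv_centroid"], dtype=float),
        basal_plane_z=meta["basal_plane_z"],
    )


# ---------------------------------------------------------------------------
# atlas archives
# ---------------------------------------------------------------------------

def save_atlas(atlas, path: str | Path) -> Path:
    """Serialise a fitted atlas to one NPZ archive (documented keys)."""
    path = Path(path)
    grid = atlas.model.grid if atlas.model.grid is not None else (0, 0)
    rv = atlas.model._rv if atlas.model._rv is not None else np.zeros(3)
    np.savez(
        path,
        mean_shape=atlas.mean_shape,
        modes=atlas.modes,
        eigenvalues=atlas.eigenvalues,
        scores_sd=atlas.scores_sd,
        n_circ=grid[0],
        n_long=grid[1],
        rv_centroid=rv,
        subject_ids=np.asarray(atlas.model.subject_ids),
        degenerate=atlas.degenerate,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_atlas(path: str | Path):
    """Load an atlas archive back into a ShapeAtlasResults (scores included)."""
    from .atlas import ShapeAtlasResults, ShapeModel

    with np.load(path, allow_pickle=False) as z:
        mean = z["mean_shape"]
        modes = z["modes"]
        eig = z["eigenvalues"]
        scores = z["scores_sd"]
        grid = (int(z["n_circ"]), int(z["n_long"]))
        rv = z["rv_centroid"]
        ids = [str(s) for s in z["subject_ids"]]
        degenerate = bool(z["degenerate"])
    X = scores * np.sqrt(eig) @ modes + mean if eig.size else np.tile(mean, (len(ids), 1))
    model = ShapeModel.__new__(ShapeModel)
    model.X = X
    model.grid = grid if grid != (0, 0) else None
    model._rv = rv
    model.subject_ids = ids
    return ShapeAtlasResults(
        model=model, mean_shape=mean, modes=modes, eigenvalues=eig,
        scores_sd=scores, degenerate=degenerate,
    )
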