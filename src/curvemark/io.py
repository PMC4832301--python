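"""Shared domain types and readers/writers for meshes, curves and landmarks.

All coordinates are in millimetres throughout the package; there is no unit
autodetection.  Meshes are triangle meshes read from PLY (ASCII or binary
little-endian) or ASCII OBJ files.  Landmark configurations are stored as CSV
with a ``name,x,y,z`` header; curves are stored one CSV polyline per curve
(``x,y,z`` rows) together with a JSON index mapping curve name to file and
feature kind.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "SurfaceMesh",
    "LandmarkConfiguration",
    "NamedCurve",
    "FormatError",
    "DimensionError",
    "load_mesh",
    "save_mesh",
    "load_landmarks",
    "save_landmarks",
    "load_curves",
    "save_curves",
    "save_annotated",
]

FEATURE_KINDS = ("ridge", "rut", "edge", "continuation")


class FormatError(ValueError):
    """A file parsed but violated structural expectations (e.g. bad face index)."""


class DimensionError(ValueError):
    """Arrays whose shapes do not agree with the mesh or with each other."""


@dataclass
class SurfaceMesh:
    """Triangle surface mesh in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    normals : optional (n, 3) unit vertex normals
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DimensionError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DimensionError("faces must be an (m, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            bad = np.argwhere((self.faces < 0) | (self.faces >= n))[0, 0]
            raise FormatError(f"face {bad} references a vertex outside 0..{n - 1}")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.vertices.shape:
                raise DimensionError("normals must match vertices in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("vertex normals must be unit length")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def vertex_normals(self) -> np.ndarray:
        """Unit vertex normals, from the stored ones or from face winding."""
        if self.normals is not None:
            return self.normals
        tm = self.as_trimesh()
        nrm = np.asarray(tm.vertex_normals, dtype=float).copy()
        lens = np.linalg.norm(nrm, axis=1)
        lens[lens == 0] = 1.0
        return nrm / lens[:, None]

    def edge_lengths(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        e = np.concatenate(
            [v[f[:, 0]] - v[f[:, 1]], v[f[:, 1]] - v[f[:, 2]], v[f[:, 2]] - v[f[:, 0]]]
        )
        return np.linalg.norm(e, axis=1)

    def vertex_adjacency(self) -> list[np.ndarray]:
        """One-ring neighbour indices per vertex."""
        pairs = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        pairs = np.concatenate([pairs, pairs[:, ::-1]])
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
        uniq = pairs[np.concatenate([[True], np.any(np.diff(pairs, axis=0) != 0, axis=1)])]
        out: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * self.n_vertices
        if len(uniq):
            starts = np.searchsorted(uniq[:, 0], np.arange(self.n_vertices))
            ends = np.searchsorted(uniq[:, 0], np.arange(self.n_vertices) + 1)
            for i in range(self.n_vertices):
                out[i] = uniq[starts[i]:ends[i], 1]
        return out


@dataclass
class LandmarkConfiguration:
    """Ordered, uniquely named 3D landmark points (mm) of one annotation."""

    names: list[str]
    points: np.ndarray

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape != (len(self.names), 3):
            raise DimensionError("points must be (len(names), 3)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[self.names.index(name)]

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def subset(self, names: Sequence[str]) -> "LandmarkConfiguration":
        idx = [self.names.index(n) for n in names]
        return LandmarkConfiguration(list(names), self.points[idx])

    def transformed(self, rotation: np.ndarray | None = None,
                    scale: float = 1.0,
                    translation: np.ndarray | None = None) -> "LandmarkConfiguration":
        pts = self.points
        if translation is not None:
            pts = pts - np.asarray(translation)
        pts = pts * scale
        if rotation is not None:
            pts = pts @ np.asarray(rotation)
        return LandmarkConfiguration(list(self.names), pts)


@dataclass
class NamedCurve:
    """Ordered 3D polyline (mm) tagged with a feature kind."""

    name: str
    points: np.ndarray
    kind: str = "ridge"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise DimensionError("curve points must be (n, 3)")
        if len(self.points) < 2:
            raise ValueError("a curve needs at least 2 points")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive curve points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    def arc_lengths(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


# ---------------------------------------------------------------------------
# mesh I/O


def load_mesh(path: str | Path, fmt: str | None = None) -> SurfaceMesh:
    """Load a PLY (ASCII / binary little-endian) or ASCII OBJ triangle mesh.

    Vertex order is preserved from the file.  OBJ 1-based indices are
    converted to 0-based.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such mesh file: {path}")
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt not in ("ply", "obj"):
        raise ValueError(f"unsupported mesh format: {fmt!r}")
    try:
        tm = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # index errors surface during parsing
        raise FormatError(f"could not parse {path}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if faces.size and faces.max() >= len(vertices):
        raise FormatError(
            f"face referencing vertex {faces.max()} of a {len(vertices)}-vertex file"
        )
    return SurfaceMesh(vertices=vertices, faces=faces)


def save_mesh(mesh: SurfaceMesh, path: str | Path,
              vertex_colors: np.ndarray | None = None,
              binary: bool = False) -> Path:
    """Write a mesh as PLY, optionally with per-vertex uchar RGB colours.

    Coordinates are written as float64 (ASCII or binary little-endian) so
    that a write/read round trip preserves them to well below 1e-6 mm.
    """
    path = Path(path)
    if vertex_colors is not None:
        vertex_colors = np.asarray(vertex_colors, dtype=np.uint8)
        if len(vertex_colors) != mesh.n_vertices:
            raise DimensionError(
                f"{len(vertex_colors)} colours for {mesh.n_vertices} vertices"
            )
    n, m = mesh.n_vertices, len(mesh.faces)
    header = ["ply",
              "format binary_little_endian 1.0" if binary
              else "format ascii 1.0",
              f"element vertex {n}",
              "property double x", "property double y", "property double z"]
    if vertex_colors is not None:
        header += ["property uchar red", "property uchar green",
                   "property uchar blue"]
    header += [f"element face {m}",
               "property list uchar int vertex_indices", "end_header"]
    if binary:
        vdt = [("xyz", "<f8", 3)]
        if vertex_colors is not None:
            vdt.append(("rgb", "u1", 3))
        vrec = np.empty(n, dtype=np.dtype(vdt))
        vrec["xyz"] = mesh.vertices
        if vertex_colors is not None:
            vrec["rgb"] = vertex_colors
        frec = np.empty(m, dtype=np.dtype([("k", "u1"), ("idx", "<i4", 3)]))
        frec["k"] = 3
        frec["idx"] = mesh.faces
        path.write_bytes(("\n".join(header) + "\n").encode("ascii")
                         + vrec.tobytes() + frec.tobytes())
    else:
        lines = list(header)
        for i in range(n):
            row = " ".join(f"{c:.17g}" for c in mesh.vertices[i])
            if vertex_colors is not None:
                row += " " + " ".join(str(int(c)) for c in vertex_colors[i])
            lines.append(row)
        for f in mesh.faces:
            lines.append("3 " + " ".join(str(int(i)) for i in f))
        path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# landmark I/O


def save_landmarks(config: LandmarkConfiguration, path: str | Path,
                   qc: Mapping[str, Mapping[str, object]] | None = None) -> Path:
    """Write a landmark CSV ``name,x,y,z`` (plus QC columns when given).

    Missing landmarks are encoded by omitting the row, never by NaN.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "name": config.names,
            "x": config.points[:, 0],
            "y": config.points[:, 1],
            "z": config.points[:, 2],
        }
    )
    if qc is not None:
        for col in ("rule", "quality_metric", "flag"):
            df[col] = [qc.get(n, {}).get(col, "") for n in config.names]
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def load_landmarks(path: str | Path) -> LandmarkConfiguration:
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"landmark CSV must have columns {sorted(required)}")
    return LandmarkConfiguration(
        names=[str(n) for n in df["name"]],
        points=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# curve I/O


def _curve_filename(name: str) -> str:
    safe = "".join(c if (c.isalnum() or c in "-_") else "_" for c in name)
    return f"curve_{safe}.csv"


def save_curves(curves: Iterable[NamedCurve], out_dir: str | Path) -> Path:
    """Write one ``x,y,z`` CSV per curve plus a JSON index of name/kind/file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = {}
    for curve in curves:
        fname = _curve_filename(curve.name)
        pd.DataFrame(curve.points, columns=["x", "y", "z"]).to_csv(
            out_dir / fname, index=False, float_format="%.9g"
        )
        index[curve.name] = {"file": fname, "kind": curve.kind}
    index_path = out_dir / "curves.json"
    index_path.write_text(json.dumps(index, indent=1, sort_keys=True))
    return index_path


def load_curves(index_path: str | Path) -> list[NamedCurve]:
    index_path = Path(index_path)
    index = json.loads(index_path.read_text())
    curves = []
    for name, entry in index.items():
        df = pd.read_csv(index_path.parent / entry["file"])
        curves.append(
            NamedCurve(name=name, points=df[["x", "y", "z"]].to_numpy(dtype=float),
                       kind=entry["kind"])
        )
    return curves


def save_annotated(mesh: SurfaceMesh, shape_field, curves: Sequence[NamedCurve],
                   landmarks: LandmarkConfiguration | None,
                   out_dir: str | Path) -> dict[str, Path]:
    """Write the annotated bundle: colour-coded PLY, curve files, landmark CSV.

    ``shape_field`` is a :class:`~curvemark.curvature.ShapeIndexField` (or any
    object with an (n, 3) uint8 ``colors`` attribute aligned to the mesh).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    colors = np.asarray(shape_field.colors)
    if len(colors) != mesh.n_vertices:
        raise DimensionError(
            f"shape field has {len(colors)} entries for {mesh.n_vertices} vertices"
        )
    out: dict[str, Path] = {}
    out["mesh"] = save_mesh(mesh, out_dir / "surface_shape_index.ply",
                            vertex_colors=colors)
    if curves:
        out["curves"] = save_curves(curves, out_dir)
    if landmarks is not None:
        out["landmarks"] = save_landmarks(landmarks, out_dir / "landmarks.csv")
    return out
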