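"""Mesh and case-configuration I/O.

All geometry is in millimeters end-to-end; no unit conversion is performed.
Surface meshes are exchanged as STL (binary or ASCII); PLY and OBJ are also
accepted. The case configuration is a small JSON document describing the
user-supplied inputs of an analysis: the outlined acetabular rim, the
acetabular-region vertex subset used for sphere fitting, the three pelvic
landmarks, and the side of the hemipelvis.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import ConfigError, DegenerateGeometryError, DegenerateInputError, MeshFormatError

#: vertices closer than this (mm) are merged on read
MERGE_TOLERANCE = 1e-6
#: triangles with area (mm^2) at or below this are dropped as degenerate
ZERO_AREA_THRESHOLD = 1e-12

_KNOWN_FORMATS = ("stl", "ply", "obj")


@dataclass(frozen=True)
class TriangleMesh:
    """A triangle surface mesh in millimeter coordinates.

    Attributes
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float).reshape(-1, 3))
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=np.int64).reshape(-1, 3))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Return face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    @classmethod
    def empty(cls) -> "TriangleMesh":
        """A mesh with no geometry (used e.g. as a totally resected bone)."""
        return cls(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))

    @classmethod
    def from_arrays(cls, vertices, faces, clean: bool = True) -> "TriangleMesh":
        """Build a validated mesh, optionally merging duplicates and dropping
        degenerate (repeated-index or zero-area) faces."""
        vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(vertices)):
            raise DegenerateInputError("mesh contains non-finite vertex coordinates")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise DegenerateInputError("face index out of range")
        if clean:
            vertices, faces = _clean(vertices, faces)
        return cls(vertices, faces)


def _clean(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices within MERGE_TOLERANCE and drop degenerate faces."""
    if len(vertices) == 0:
        return vertices, faces
    keys = np.round(vertices / MERGE_TOLERANCE).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    # keep original coordinates of the first occurrence of each merged vertex
    merged = vertices[first]
    faces = inverse[faces]
    if len(faces):
        # drop faces with repeated vertices after merging
        f = faces
        distinct = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
        faces = faces[distinct]
        # drop zero-area faces
        t = merged[faces]
        areas = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        faces = faces[areas > ZERO_AREA_THRESHOLD]
    return merged, faces


def read_mesh(path, fmt: str = "auto") -> TriangleMesh:
    """Read a surface mesh from *path*.

    Parameters
    ----------
    path : str or Path
    fmt : {"auto", "stl", "ply", "obj"}
        File format; "auto" infers it from the extension.

    Returns
    -------
    TriangleMesh
        Cleaned mesh: duplicate vertices merged within 1e-6 mm, zero-area
        faces dropped. Coordinates are assumed to be millimeters.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _KNOWN_FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (expected one of {_KNOWN_FORMATS})")
    try:
        loaded = trimesh.load(path, file_type=fmt, force="mesh", process=False)
        vertices = np.asarray(loaded.vertices, dtype=float)
        faces = np.asarray(loaded.faces, dtype=np.int64)
    except Exception as exc:  # noqa: BLE001 - normalise any parser failure
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    mesh = TriangleMesh.from_arrays(vertices, faces, clean=True)
    if mesh.n_vertices < 4:
        raise DegenerateInputError(
            f"mesh {path} has only {mesh.n_vertices} vertices after cleaning (need >= 4)"
        )
    return mesh


def write_mesh(mesh: TriangleMesh, path) -> None:
    """Write a mesh as binary STL (or PLY/OBJ, by extension)."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path)


@dataclass(frozen=True)
class CaseConfig:
    """User inputs of one analysis case.

    rim_outline : (k, 3) ordered points on the reconstructed acetabular rim
    acetabular_region : (p, 3) points of the reconstructed cup surface used
        for sphere fitting
    landmarks : dict with "asis_left", "asis_right", "pubis" -> (3,) points
    side : "left" or "right"
    """

    rim_outline: np.ndarray
    acetabular_region: np.ndarray
    landmarks: dict = field(default_factory=dict)
    side: str = "right"


_LANDMARK_NAMES = ("asis_left", "asis_right", "pubis")


def _resolve_points(entry, mesh: TriangleMesh | None, what: str) -> np.ndarray:
    """An entry is either a list of [x,y,z] points or {"indices": [...]}
    resolved against the reconstructed mesh. Points take precedence."""
    if isinstance(entry, dict):
        if "indices" not in entry:
            raise ConfigError(f"{what}: expected point list or an 'indices' object")
        if mesh is None:
            raise ConfigError(f"{what} given as indices but no reconstructed mesh supplied")
        idx = np.asarray(entry["indices"], dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= mesh.n_vertices):
            raise ConfigError(f"{what}: vertex index out of range")
        return mesh.vertices[idx]
    pts = np.asarray(entry, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ConfigError(f"{what}: expected an array of 3D points")
    return pts


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def _coplanar(points: np.ndarray, tol: float = 1e-9) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[2] <= tol * max(s[0], 1.0)


def read_case_config(path, reconstructed: TriangleMesh | None = None) -> CaseConfig:
    """Read and validate a case-configuration JSON file.

    Vertex-index entries are resolved against *reconstructed* when given.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"case config not found: {path}")
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
    return parse_case_config(raw, reconstructed)


def parse_case_config(raw: dict, reconstructed: TriangleMesh | None = None) -> CaseConfig:
    """Validate an already-parsed case-configuration dictionary."""
    for key in ("rim_outline", "acetabular_region", "landmarks", "side"):
        if key not in raw:
            raise ConfigError(f"case config missing field {key!r}")
    rim = _resolve_points(raw["rim_outline"], reconstructed, "rim_outline")
    region = _resolve_points(raw["acetabular_region"], reconstructed, "acetabular_region")
    if len(rim) < 3 or _collinear(rim):
        raise ConfigError("rim_outline needs >= 3 non-collinear points")
    if len(region) < 4 or _coplanar(region):
        raise ConfigError("acetabular_region needs >= 4 non-coplanar points")
    lm = {}
    for name in _LANDMARK_NAMES:
        if name not in raw["landmarks"]:
            raise ConfigError(f"landmarks missing {name!r}")
        p = np.asarray(raw["landmarks"][name], dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise ConfigError(f"landmark {name!r} has non-finite coordinates")
        lm[name] = p
    pts = np.array([lm[n] for n in _LANDMARK_NAMES])
    if len(np.unique(np.round(pts / 1e-9), axis=0)) != 3:
        raise ConfigError("landmarks must be three distinct points")
    side = str(raw["side"]).lower()
    if side not in ("left", "right"):
        raise ConfigError(f"side must be 'left' or 'right', got {raw['side']!r}")
    return CaseConfig(rim_outline=rim, acetabular_region=region, landmarks=lm, side=side)


def write_case_config(config: CaseConfig, path) -> None:
    """Serialize a CaseConfig back to the JSON schema."""
    doc = {
        "rim_outline": config.rim_outline.tolist(),
        "acetabular_region": config.acetabular_region.tolist(),
        "landmarks": {k: np.asarray(v).tolist() for k, v in config.landmarks.items()},
        "side": config.side,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


class TrablIOError(OSError):
    """Raised when an output location cannot be written."""


def write_outputs(result, deviation, grid, planar, outdir) -> dict:
    """Write the tabular outputs of one case run.

    Writes ``ratios.csv`` (overall + six regions) and ``deviation_grid.csv``
    (one row per grid point: phi, theta, x, y, hit_rec, hit_def, distance;
    rays without a finite deviation carry ``inf``). Returns the mapping of
    logical name -> written path. Images are written by the report module.
    """
    import pandas as pd

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise TrablIOError(f"output directory not writable: {outdir}: {exc}") from exc

    rows = [{"region": "overall", "A_rec": result.A_rec, "A_def": result.A_def,
             "ratio": result.ratio}]
    for name, reg in result.per_region.items():
        rows.append({"region": name, "A_rec": reg.A_rec, "A_def": reg.A_def,
                     "ratio": reg.ratio if reg.ratio is not None else np.nan})
    ratios_path = outdir / "ratios.csv"
    pd.DataFrame(rows).to_csv(ratios_path, index=False)

    nphi, ntheta = grid.shape
    phi = np.repeat(grid.phi, ntheta)
    theta = np.tile(grid.theta, nphi)
    dev_path = outdir / "deviation_grid.csv"
    pd.DataFrame({
        "phi": phi,
        "theta": theta,
        "x": planar.x.ravel(),
        "y": planar.y.ravel(),
        "hit_rec": deviation.hit_rec.ravel().astype(int),
        "hit_def": deviation.hit_def.ravel().astype(int),
        "distance": deviation.distance.ravel(),
    }).to_csv(dev_path, index=False)
    return {"ratios": ratios_path, "deviation_grid": dev_path}
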