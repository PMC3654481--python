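"""File formats: PLY/OBJ meshes, schema-validated CSV tables, TIFF stacks.

Coordinates are interpreted as nanometers (an optional scale factor can be
applied on read); CSV outputs carry a units comment line. OBJ 1-based face
indices are converted to the internal 0-based convention by the reader.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .association import DivisionEvent
from .geometry import GeometryError, PointSet, SurfacePatch, TriangleMesh
from .kinetics import TipTrack

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_mesh",
    "write_mesh",
    "read_table",
    "write_table",
    "read_points",
    "write_points",
    "read_events",
    "write_events",
    "read_tracks",
    "write_tracks",
    "write_patches",
    "read_stack",
    "write_stack",
    "TABLE_SCHEMAS",
]


class FormatError(ValueError):
    pass


_MESH_SUFFIXES = {".ply", ".obj"}

UNITS_COMMENT = "# units: nm, s"

TABLE_SCHEMAS = {
    "foci": ["x", "y", "z", "radius"],
    "divisions": ["x", "y", "z", "t_s"],
    "ribosomes": ["x", "y", "z"],
    "nucleoids": ["x", "y", "z"],
    "tracks": ["track_id", "frame", "t_s", "ax", "ay", "az", "bx", "by", "bz", "onset"],
}


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def read_mesh(path, scale: float = 1.0, name: Optional[str] = None) -> TriangleMesh:
    """Load a PLY (ascii or binary) or OBJ mesh as a :class:`TriangleMesh`.

    Coordinates are multiplied by ``scale`` (nm per file unit). Extra
    per-vertex properties are ignored with a logged note; degenerate faces
    are dropped at load."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(f"unsupported mesh format: {path.suffix!r}")
    try:
        tm = trimesh.load(str(path), file_type=path.suffix[1:], process=False)
    except Exception as exc:  # malformed file
        raise FormatError(f"malformed mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh):
        raise FormatError(f"{path} does not contain a single triangle mesh")
    if isinstance(tm.visual, trimesh.visual.ColorVisuals) and tm.visual.defined:
        logger.info("ignoring per-vertex visual properties in %s", path)
    return TriangleMesh.create(
        np.asarray(tm.vertices, dtype=float) * scale,
        np.asarray(tm.faces, dtype=np.int64),
        name=name if name is not None else path.stem,
    )


def write_mesh(mesh: TriangleMesh, path, encoding: str = "ascii") -> None:
    """Write PLY (ascii/binary) or OBJ; round-trips coordinates to float32
    precision and face lists exactly."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(f"unsupported mesh format: {path.suffix!r}")
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".ply":
        tm.export(str(path), encoding=encoding)
    else:
        tm.export(str(path))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def read_table(path, schema: str) -> pd.DataFrame:
    """CSV with header, validated against a named schema; comment lines
    (units declarations) are skipped. Missing columns and non-numeric cells
    are reported by name / row."""
    if schema not in TABLE_SCHEMAS:
        raise FormatError(f"unknown schema {schema!r}")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    required = TABLE_SCHEMAS[schema]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    numeric = [c for c in required if c != "track_id"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(f"non-numeric cell in column {col!r}, row {row}")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """CSV with a leading units comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(UNITS_COMMENT + "\n")
        df.to_csv(fh, index=False)


# -- typed wrappers ----------------------------------------------------------


def read_points(path, schema: str, label: str = "") -> PointSet:
    df = read_table(path, schema)
    radii = df["radius"].to_numpy() if "radius" in df.columns else None
    return PointSet(
        df[["x", "y", "z"]].to_numpy(dtype=float),
        radii=radii,
        label=label or schema.rstrip("s"),
    )


def write_points(ps: PointSet, path) -> None:
    data = {"x": ps.points[:, 0], "y": ps.points[:, 1], "z": ps.points[:, 2]}
    if ps.radii is not None and np.any(ps.radii > 0):
        data["radius"] = ps.radii
    write_table(pd.DataFrame(data), path)


def read_events(path) -> list:
    df = read_table(path, "divisions")
    return [
        DivisionEvent(position=row[["x", "y", "z"]].to_numpy(dtype=float),
                      time_s=float(row["t_s"]))
        for _, row in df.iterrows()
    ]


def write_events(events: Sequence[DivisionEvent], path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "x": e.position[0],
                "y": e.position[1],
                "z": e.position[2],
                "t_s": e.time_s if e.time_s is not None else np.nan,
                "linked_focus": e.linked_focus if e.linked_focus is not None else -1,
            }
        )
    write_table(pd.DataFrame(rows), path)


def read_tracks(path) -> list:
    """Long-format track table -> TipTrack list. Columns per schema
    "tracks"; ``onset`` is 1 on the constriction-onset frame of each
    track."""
    df = read_table(path, "tracks")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        t = g["t_s"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = float(np.diff(t)[0])
            if not np.allclose(np.diff(t), dt):
                raise FormatError(f"track {tid}: frames not equally spaced")
        else:
            dt = 1.0
        onset_rows = np.flatnonzero(g["onset"].to_numpy() != 0)
        onset = int(onset_rows[0]) if onset_rows.size else 0
        tracks.append(
            TipTrack(
                track_id=str(tid),
                frame_interval_s=dt,
                constriction_onset_frame=onset,
                positions_a=g[["ax", "ay", "az"]].to_numpy(dtype=float),
                positions_b=g[["bx", "by", "bz"]].to_numpy(dtype=float),
                capture_duration_s=float(t[-1]),
            )
        )
    return tracks


def write_tracks(tracks: Sequence[TipTrack], path) -> None:
    rows = []
    for tr in tracks:
        times = tr.frame_times_s()
        for f in range(tr.n_frames):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": f,
                    "t_s": times[f],
                    "ax": tr.positions_a[f, 0],
                    "ay": tr.positions_a[f, 1],
                    "az": tr.positions_a[f, 2],
                    "bx": tr.positions_b[f, 0],
                    "by": tr.positions_b[f, 1],
                    "bz": tr.positions_b[f, 2],
                    "onset": int(f == tr.constriction_onset_frame),
                }
            )
    write_table(pd.DataFrame(rows), path)


def write_patches(patches: Sequence[SurfacePatch], path) -> None:
    rows = [
        {
            "mesh_name": p.mesh_name,
            "patch_id": i,
            "face_count": p.n_faces,
            "area_nm2": p.area,
            "centroid_x": p.centroid[0],
            "centroid_y": p.centroid[1],
            "centroid_z": p.centroid[2],
        }
        for i, p in enumerate(patches)
    ]
    write_table(pd.DataFrame(rows), path)


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, ...]
    return arr


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))
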