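"""Readers and writers for every on-disk artifact.

All tabular formats are UTF-8 comma-separated files whose metadata lives in
``#``-prefixed ``key: value`` header lines, so fixtures stay greppable and
diff-able.  Every reader/writer pair is a lossless round trip on valid
files.  Depth stacks are multi-page 16-bit grayscale TIFFs with a JSON
sidecar carrying the value-to-mm scale, the invalid-pixel sentinel, the
pixel pitch and the frame rate.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import (
    ARM_ORDER,
    ROLES,
    UNKNOWN,
    DepthMapStack,
    PhaseTable,
    TrackTable,
    TrajectorySet,
    trajectory_from_frame_table,
    trajectory_to_frame_table,
)

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_trajectories",
    "write_trajectories",
    "read_depth_stack",
    "write_depth_stack",
    "read_phase",
    "write_phase",
    "write_table",
]


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _write_csv(path: Path, df: pd.DataFrame, meta: dict[str, object]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def write_tracks(table: TrackTable, path: str | Path) -> None:
    _write_csv(
        Path(path),
        table.data,
        {
            "format": "octokin-tracks v1",
            "fps": table.fps,
            "pixel_pitch_mm": table.pixel_pitch_mm,
        },
    )


def read_tracks(path: str | Path) -> TrackTable:
    path = Path(path)
    meta = _read_metadata(path)
    if "fps" not in meta or "pixel_pitch_mm" not in meta:
        raise ValueError(f"{path}: missing 'fps' / 'pixel_pitch_mm' metadata header")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("frame", "point_id", "role", "arm", "x_px", "y_px", "valid"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["frame"] = df["frame"].astype(int)
    df["valid"] = df["valid"].astype(bool)
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"{path}: unknown role value(s) {sorted(bad)}")
    return TrackTable(df, float(meta["fps"]), float(meta["pixel_pitch_mm"]))


def write_trajectories(traj: TrajectorySet, path: str | Path) -> None:
    df = trajectory_to_frame_table(traj)
    _write_csv(Path(path), df, {"format": "octokin-traj v1", "fps": traj.fps})


def read_trajectories(path: str | Path) -> TrajectorySet:
    path = Path(path)
    meta = _read_metadata(path)
    if "fps" not in meta:
        raise ValueError(f"{path}: missing 'fps' metadata header")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return trajectory_from_frame_table(df, float(meta["fps"]))


def write_depth_stack(
    stack: DepthMapStack,
    path: str | Path,
    scale_mm: float = 0.01,
    offset_mm: float = 0.0,
) -> None:
    """Write a stack as multi-page uint16 TIFF plus a JSON sidecar.

    Raw value 0 is the invalid sentinel; valid pixels are stored as
    ``round((mm - offset_mm) / scale_mm)`` and must land in [1, 65535].
    """
    path = Path(path)
    raw = np.zeros(stack.depth_mm.shape, dtype=np.uint16)
    vals = np.round(
        (stack.depth_mm[stack.valid].astype(np.float64) - offset_mm) / scale_mm
    )
    if vals.min(initial=1) < 1 or vals.max(initial=1) > 65535:
        raise ValueError(
            "depth values do not fit the 16-bit range at this scale/offset"
        )
    raw[stack.valid] = vals.astype(np.uint16)
    tifffile.imwrite(path, raw, photometric="minisblack")
    sidecar = {
        "format": "octokin-depth v1",
        "scale_mm": scale_mm,
        "offset_mm": offset_mm,
        "invalid_value": 0,
        "pixel_pitch_mm": stack.pixel_pitch_mm,
        "fps": stack.fps,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_depth_stack(path: str | Path) -> DepthMapStack:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing depth-stack sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = raw[None]
    if raw.ndim != 3:
        raise ValueError(f"{path}: depth stack pages must share one 2D shape")
    sentinel = int(meta["invalid_value"])
    valid = raw != sentinel
    depth = np.zeros(raw.shape, dtype=np.float32)
    depth[valid] = (
        raw[valid].astype(np.float32) * np.float32(meta["scale_mm"])
        + np.float32(meta["offset_mm"])
    )
    return DepthMapStack(depth, valid, float(meta["pixel_pitch_mm"]), float(meta["fps"]))


def write_phase(phase: PhaseTable, path: str | Path) -> None:
    df = phase.to_dataframe()
    out = df.copy()
    for arm in ARM_ORDER:
        col = out[arm].astype("object")
        col[df[arm] == UNKNOWN] = "NA"
        out[arm] = col
    _write_csv(Path(path), out, {"format": "octokin-phase v1", "fps": phase.fps})


def read_phase(path: str | Path) -> PhaseTable:
    path = Path(path)
    meta = _read_metadata(path)
    if "fps" not in meta:
        raise ValueError(f"{path}: missing 'fps' metadata header")
    df = pd.read_csv(path, comment="#", dtype="object")
    missing = [c for c in ARM_ORDER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing arm column(s) {missing}")
    codes = np.empty((len(df), 8), dtype=np.int8)
    for j, arm in enumerate(ARM_ORDER):
        col = df[arm]
        for i, v in enumerate(col):
            if isinstance(v, float) and np.isnan(v) or v in ("NA", "", None):
                codes[i, j] = UNKNOWN
            elif str(v).strip() in ("0", "1"):
                codes[i, j] = int(str(v).strip())
            else:
                raise ValueError(
                    f"{path}: invalid phase value {v!r} in column {arm}, row {i}"
                )
    return PhaseTable(codes, float(meta["fps"]))


def write_table(df: pd.DataFrame, path: str | Path, kind: str = "table") -> None:
    """Write a result table (strides, stats, binned fields, ...) as CSV."""
    _write_csv(Path(path), df, {"format": f"octokin-{kind} v1"})
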