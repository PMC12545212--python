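"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* frames are 0-based integers; intervals are half-open ``[on, off)``;
* lengths are millimetres, time in seconds, curvature in mm^-1, strain in %;
* the eight arms are labelled ``L1..L4, R1..R4`` with pair 1 dorsal and
  pair 4 ventral.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

ROLES = ("key", "guide", "reference")
ARM_ORDER = ("L1", "L2", "L3", "L4", "R1", "R2", "R3", "R4")
ARM_LABELS = ARM_ORDER + ("none",)

#: phase-diagram state codes
CONTACT, AIR, UNKNOWN = 1, 0, -1

TRACK_COLUMNS = ("frame", "point_id", "role", "arm", "x_px", "y_px", "valid")


@dataclass
class TrackTable:
    """2D pixel observations of named tracked points.

    ``data`` holds one row per (frame, point) observation with columns
    ``frame, point_id, role, arm, x_px, y_px, valid``.
    """

    data: pd.DataFrame
    fps: float
    pixel_pitch_mm: float

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing required column(s): {missing}")
        bad_roles = set(self.data["role"].unique()) - set(ROLES)
        if bad_roles:
            raise ValueError(
                f"unknown role value(s) {sorted(bad_roles)}; allowed roles are {ROLES}"
            )
        bad_arms = set(self.data["arm"].unique()) - set(ARM_LABELS)
        if bad_arms:
            raise ValueError(
                f"unknown arm label(s) {sorted(bad_arms)}; allowed labels are {ARM_LABELS}"
            )
        dup = self.data.duplicated(subset=["frame", "point_id"])
        if dup.any():
            first = self.data.loc[dup.idxmax(), ["frame", "point_id"]]
            raise ValueError(
                "duplicate (frame, point_id) observation: "
                f"frame={first['frame']}, point_id={first['point_id']!r}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.data["frame"].max()) + 1 if len(self.data) else 0

    @property
    def point_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["point_id"]))


@dataclass
class TrajectorySet:
    """Per-point 3D time series in mm at a fixed frame rate.

    ``xyz`` has shape (n_frames, n_points, 3); ``valid`` is the observation
    mask.  Point metadata (``point_id, role, arm``) lives in ``point_info``
    with one row per point, in the column order of ``xyz``.
    """

    point_info: pd.DataFrame
    xyz: np.ndarray
    valid: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_points, 3)")
        if self.valid.shape != self.xyz.shape[:2]:
            raise ValueError("valid mask shape must match (n_frames, n_points)")
        if len(self.point_info) != self.xyz.shape[1]:
            raise ValueError("point_info row count must equal n_points")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.xyz[self.valid])):
            raise ValueError("positions must be finite where valid")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_points(self) -> int:
        return self.xyz.shape[1]

    @property
    def point_ids(self) -> list[str]:
        return list(self.point_info["point_id"])

    def point_index(self, point_id: str) -> int:
        idx = np.flatnonzero(self.point_info["point_id"].to_numpy() == point_id)
        if idx.size == 0:
            raise KeyError(point_id)
        return int(idx[0])

    def select_role(self, role: str) -> "TrajectorySet":
        mask = (self.point_info["role"] == role).to_numpy()
        return TrajectorySet(
            self.point_info.loc[mask].reset_index(drop=True),
            self.xyz[:, mask],
            self.valid[:, mask],
            self.fps,
        )

    def select_arm(self, arm: str) -> "TrajectorySet":
        mask = (self.point_info["arm"] == arm).to_numpy()
        return TrajectorySet(
            self.point_info.loc[mask].reset_index(drop=True),
            self.xyz[:, mask],
            self.valid[:, mask],
            self.fps,
        )

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            self.point_info.copy(), self.xyz.copy(), self.valid.copy(), self.fps
        )


def concat_trajectories(parts: Sequence[TrajectorySet]) -> TrajectorySet:
    """Stack several trajectory sets (same frame count and fps) point-wise."""
    if not parts:
        raise ValueError("nothing to concatenate")
    n = parts[0].n_frames
    fps = parts[0].fps
    for p in parts[1:]:
        if p.n_frames != n or p.fps != fps:
            raise ValueError("trajectory sets must share frame count and fps")
    info = pd.concat([p.point_info for p in parts], ignore_index=True)
    xyz = np.concatenate([p.xyz for p in parts], axis=1)
    valid = np.concatenate([p.valid for p in parts], axis=1)
    return TrajectorySet(info, xyz, valid, fps)


@dataclass
class DepthMapStack:
    """Orthographic range-image stack: per-pixel distance in mm."""

    depth_mm: np.ndarray  # (n_frames, H, W), float
    valid: np.ndarray  # (n_frames, H, W), bool
    pixel_pitch_mm: float
    fps: float

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.depth_mm.ndim != 3:
            raise ValueError("depth stack must have shape (n_frames, H, W)")
        if self.valid.shape != self.depth_mm.shape:
            raise ValueError("valid mask must match depth shape")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if not np.all(np.isfinite(self.depth_mm[self.valid])):
            raise ValueError("depth values must be finite where valid")

    @property
    def n_frames(self) -> int:
        return self.depth_mm.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth_mm.shape[1:]


@dataclass
class PhaseTable:
    """Ternary arm-contact states: frames x 8 arms.

    Codes: 1 = contact, 0 = air (no contact), -1 = unknown.
    Columns follow :data:`ARM_ORDER` (L1..L4, R1..R4).
    """

    codes: np.ndarray  # (n_frames, 8), int8
    fps: float

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[1] != 8:
            raise ValueError("phase table must have shape (n_frames, 8)")
        bad = ~np.isin(self.codes, (CONTACT, AIR, UNKNOWN))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid phase state {self.codes[r, c]} at frame {r}, arm {ARM_ORDER[c]}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    def column(self, arm: str) -> np.ndarray:
        return self.codes[:, ARM_ORDER.index(arm)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=list(ARM_ORDER))
        df.insert(0, "frame", np.arange(self.n_frames))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fps: float) -> "PhaseTable":
        cols = [c for c in ARM_ORDER if c in df.columns]
        if len(cols) != 8:
            raise ValueError(f"phase table must have all 8 arm columns {ARM_ORDER}")
        return cls(df[list(ARM_ORDER)].to_numpy(dtype=np.int8), fps)


def trajectory_to_frame_table(traj: TrajectorySet) -> pd.DataFrame:
    """Long-format view of a trajectory set (one row per frame x point)."""
    n_f, n_p = traj.xyz.shape[:2]
    frames = np.repeat(np.arange(n_f), n_p)
    pid = np.tile(traj.point_info["point_id"].to_numpy(), n_f)
    role = np.tile(traj.point_info["role"].to_numpy(), n_f)
    arm = np.tile(traj.point_info["arm"].to_numpy(), n_f)
    xyz = traj.xyz.reshape(-1, 3)
    return pd.DataFrame(
        {
            "frame": frames,
            "point_id": pid,
            "role": role,
            "arm": arm,
            "x_mm": xyz[:, 0],
            "y_mm": xyz[:, 1],
            "z_mm": xyz[:, 2],
            "valid": traj.valid.reshape(-1),
        }
    )


def trajectory_from_frame_table(df: pd.DataFrame, fps: float) -> TrajectorySet:
    """Inverse of :func:`trajectory_to_frame_table`."""
    point_ids = list(dict.fromkeys(df["point_id"]))
    n_f = int(df["frame"].max()) + 1
    n_p = len(point_ids)
    xyz = np.full((n_f, n_p, 3), np.nan)
    valid = np.zeros((n_f, n_p), dtype=bool)
    info_rows = []
    for j, pid in enumerate(point_ids):
        sub = df[df["point_id"] == pid]
        info_rows.append(
            {"point_id": pid, "role": sub["role"].iloc[0], "arm": sub["arm"].iloc[0]}
        )
        f = sub["frame"].to_numpy(int)
        xyz[f, j, 0] = sub["x_mm"].to_numpy(float)
        xyz[f, j, 1] = sub["y_mm"].to_numpy(float)
        xyz[f, j, 2] = sub["z_mm"].to_numpy(float)
        valid[f, j] = sub["valid"].to_numpy(bool)
    xyz[~valid] = np.nan
    return TrajectorySet(pd.DataFrame(info_rows), xyz, valid, fps)
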