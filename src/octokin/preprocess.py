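"""Turn 2D pixel tracks plus depth stacks into cleaned 3D trajectories.

The correction chain, applied in this fixed order:

1. depth lookup with an 11 x 11 pixel median window;
2. five-frame temporal median on the z coordinate;
3. background (vehicle/instrument) motion removal from reference points;
4. outlier rejection against a 50-frame moving-median z baseline
   (threshold: the larger of 5 mm and one standard deviation);
5. 20-frame moving-average smoothing, then piecewise-cubic filling of
   invalid gaps shorter than 100 frames.

All window filters are centred and shrink at sequence edges.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .containers import DepthMapStack, TrackTable, TrajectorySet
from .filters import median_window_2d, moving_average, moving_median

__all__ = [
    "lookup_depth",
    "filter_z_median",
    "remove_background",
    "remove_outliers",
    "smooth_and_fill",
    "PreprocessParams",
    "preprocess_tracks",
]

logger = logging.getLogger(__name__)


def lookup_depth(
    tracks: TrackTable,
    stack: DepthMapStack,
    window: int = 11,
    min_valid_fraction: float = 0.5,
) -> TrajectorySet:
    """Depth lookup: z is the median of valid pixels in a ``window``-sized
    box centred at the rounded (half-to-even) pixel position; x and y are
    the sub-pixel track positions scaled by the pixel pitch.

    An observation is invalid when the tracked point itself is invalid or
    fewer than ``min_valid_fraction`` of the window pixels carry depth.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    df = tracks.data
    point_ids = list(dict.fromkeys(df["point_id"]))
    n_frames = stack.n_frames
    n_points = len(point_ids)
    xyz = np.full((n_frames, n_points, 3), np.nan)
    valid = np.zeros((n_frames, n_points), dtype=bool)
    info_rows = []
    pitch = stack.pixel_pitch_mm
    col_index = {pid: j for j, pid in enumerate(point_ids)}
    first = df.drop_duplicates("point_id")
    for pid in point_ids:
        row = first[first["point_id"] == pid].iloc[0]
        info_rows.append(
            {"point_id": pid, "role": row["role"], "arm": row["arm"]}
        )
    for row in df.itertuples(index=False):
        f = int(row.frame)
        if f >= n_frames:
            raise ValueError(f"track frame {f} beyond depth stack length {n_frames}")
        if not row.valid:
            continue
        j = col_index[row.point_id]
        r = int(np.round(row.y_px))
        c = int(np.round(row.x_px))
        z = median_window_2d(
            stack.depth_mm[f], stack.valid[f], r, c, window, min_valid_fraction
        )
        if np.isfinite(z):
            xyz[f, j] = (row.x_px * pitch, row.y_px * pitch, z)
            valid[f, j] = True
    return TrajectorySet(pd.DataFrame(info_rows), xyz, valid, stack.fps)


def filter_z_median(traj: TrajectorySet, window: int = 5) -> TrajectorySet:
    """Temporal median filter on the z coordinate only."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    out = traj.copy()
    for j in range(traj.n_points):
        z = moving_median(traj.xyz[:, j, 2], traj.valid[:, j], window)
        ok = traj.valid[:, j]
        out.xyz[ok, j, 2] = z[ok]
    return out


def remove_background(
    traj: TrajectorySet, reference: TrajectorySet | None = None
) -> TrajectorySet:
    """Subtract per-frame camera/vehicle motion estimated from reference
    points.

    The frame offset is the component-wise median, over reference points,
    of (current position - that point's first valid position); it is
    subtracted from every trajectory.  Frames without any valid reference
    carry the last computable offset forward (zero before the first one),
    and the count of such frames is logged.
    """
    refs = reference if reference is not None else traj.select_role("reference")
    if refs.n_points == 0:
        raise ValueError("no reference points available for background removal")
    n_frames = traj.n_frames
    anchors = np.full((refs.n_points, 3), np.nan)
    for j in range(refs.n_points):
        ok = np.flatnonzero(refs.valid[:, j])
        if ok.size:
            anchors[j] = refs.xyz[ok[0], j]
    deltas = refs.xyz - anchors[None, :, :]  # (T, R, 3)

    offsets = np.zeros((n_frames, 3))
    carried = 0
    last = np.zeros(3)
    for f in range(n_frames):
        ok = refs.valid[f] & np.isfinite(anchors[:, 0])
        if ok.any():
            last = np.median(deltas[f, ok], axis=0)
        else:
            carried += 1
        offsets[f] = last
    if carried:
        logger.warning(
            "remove_background: %d frame(s) had no valid reference; "
            "offset carried forward",
            carried,
        )
    out = traj.copy()
    out.xyz = out.xyz - offsets[:, None, :]
    out.xyz[~out.valid] = np.nan
    return out


def remove_outliers(
    traj: TrajectorySet,
    baseline_window: int = 50,
    abs_thresh_mm: float = 5.0,
    all_axes: bool = False,
) -> TrajectorySet:
    """Reject samples far from a moving-median baseline.

    For each point the baseline is a ``baseline_window``-frame moving median
    of z (optionally of every axis); a sample is removed when its deviation
    exceeds ``max(abs_thresh_mm, 1 s.d.)`` where the standard deviation is
    computed from all baseline deviations of that trajectory.
    """
    if baseline_window < 3:
        raise ValueError("baseline_window must be >= 3")
    out = traj.copy()
    axes = (0, 1, 2) if all_axes else (2,)
    for j in range(traj.n_points):
        ok = traj.valid[:, j]
        if not ok.any():
            logger.warning("remove_outliers: point %d has no valid frames", j)
            continue
        drop = np.zeros(traj.n_frames, dtype=bool)
        for ax in axes:
            series = traj.xyz[:, j, ax]
            baseline = moving_median(series, ok, baseline_window)
            dev = series - baseline
            sd = float(np.std(dev[ok], ddof=1)) if ok.sum() > 1 else 0.0
            thresh = max(abs_thresh_mm, sd)
            drop |= ok & (np.abs(dev) > thresh)
        out.valid[drop, j] = False
        out.xyz[drop, j] = np.nan
    return out


def _fill_gaps_cubic(
    values: np.ndarray, valid: np.ndarray, max_gap: int, flank: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Fill interior invalid runs strictly shorter than ``max_gap`` with an
    interpolating cubic spline through up to ``flank`` valid samples on each
    side.  Runs at the sequence edges, and runs of ``max_gap`` frames or
    more, stay invalid."""
    values = values.copy()
    valid = valid.copy()
    n = values.size
    ok_idx = np.flatnonzero(valid)
    if ok_idx.size < 2:
        return values, valid
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        run = j - i
        left = ok_idx[ok_idx < i][-flank:]
        right = ok_idx[ok_idx >= j][:flank]
        interior = left.size > 0 and right.size > 0
        if interior and run < max_gap and left.size + right.size >= 2:
            knots = np.concatenate([left, right])
            spline = CubicSpline(knots, values[knots])
            fill = np.arange(i, j)
            values[fill] = spline(fill)
            valid[fill] = True
        i = j
    return values, valid


def smooth_and_fill(
    traj: TrajectorySet, ma_window: int = 20, max_gap: int = 100
) -> TrajectorySet:
    """Moving-average smoothing of every axis followed by piecewise-cubic
    filling of short invalid gaps (< ``max_gap`` frames)."""
    if ma_window < 1:
        raise ValueError("ma_window must be >= 1")
    out = traj.copy()
    for j in range(traj.n_points):
        ok = traj.valid[:, j]
        new_ok = ok.copy()
        for ax in range(3):
            sm = moving_average(traj.xyz[:, j, ax], ok, ma_window)
            sm[~ok] = np.nan
            filled, filled_ok = _fill_gaps_cubic(sm, ok, max_gap)
            out.xyz[:, j, ax] = filled
            new_ok = filled_ok  # the gap structure is shared across axes
        out.valid[:, j] = new_ok
        out.xyz[~new_ok, j] = np.nan
    return out


@dataclass
class PreprocessParams:
    depth_window_px: int = 11
    z_median_window: int = 5
    baseline_window: int = 50
    abs_thresh_mm: float = 5.0
    ma_window: int = 20
    max_gap: int = 100
    min_valid_fraction: float = 0.5


def preprocess_tracks(
    tracks: TrackTable,
    stack: DepthMapStack,
    params: PreprocessParams | None = None,
) -> TrajectorySet:
    """Full correction chain from 2D pixel tracks and a depth stack to
    cleaned 3D trajectories (in the fixed order documented above)."""
    p = params or PreprocessParams()
    traj = lookup_depth(tracks, stack, p.depth_window_px, p.min_valid_fraction)
    traj = filter_z_median(traj, p.z_median_window)
    if (traj.point_info["role"] == "reference").any():
        traj = remove_background(traj)
    else:
        logger.warning(
            "preprocess_tracks: no reference points tracked; "
            "background motion not removed"
        )
    traj = remove_outliers(traj, p.baseline_window, p.abs_thresh_mm)
    traj = smooth_and_fill(traj, p.ma_window, p.max_gap)
    return traj
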