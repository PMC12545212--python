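"""Synthetic ground truth for every pipeline stage.

The generator emulates the measurement situation of an orthographic
depth-mapping camera watching a crawling octopus arm:

* an arm is an arc-length-parameterized 3D curve whose curvature is a
  Gaussian bump centred at the "foot" joint (the medial portion placed on
  the substrate) and whose axial strain is concentrated in the third of the
  arm immediately proximal to the foot;
* both fields grow and decay over one arm cycle under a raised-cosine time
  envelope, so the stride starts (substrate release, t = 0) and ends with a
  straight, unstrained arm;
* tracked points are material markers at fixed arc-length coordinates;
  observations add i.i.d. Gaussian position noise plus a camera drift shared
  by all points, including stationary background reference points;
* 8-arm gaits are deterministic square waves (per-arm period, duty, phase)
  with optional random masking to the "unknown" state;
* depth stacks are rendered orthographically with an invalid background.

Everything stochastic is a pure function of (inputs, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .containers import (
    AIR,
    ARM_ORDER,
    CONTACT,
    UNKNOWN,
    DepthMapStack,
    PhaseTable,
    TrackTable,
    TrajectorySet,
    concat_trajectories,
)

__all__ = [
    "ArmSimConfig",
    "GaitSimConfig",
    "GroundTruth",
    "CalibrationScene",
    "simulate_arm_stride",
    "add_observation_noise",
    "smooth_drift",
    "simulate_gait",
    "render_depth_stack",
    "make_calibration_scene",
]

_OVERSAMPLE = 125  # dense material samples per tracked segment


def _check_finite(name: str, value: float) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"configuration field {name!r} must be finite, got {value}")


@dataclass
class ArmSimConfig:
    """Parameters of one simulated arm stride.

    Defaults describe a plausible adult animal: a 200 mm arm tracked at
    13 key points (spacing ~16.7 mm, at least two points per standard
    deviation of the curvature bump), bending to a 50 mm radius at the foot
    placed 45% along the arm, with 15% peak strain in the proximal third,
    over a 10 s cycle at 60 frames/s.
    """

    arm_length: float = 200.0  # mm
    n_keypoints: int = 13
    foot_fraction: float = 0.45
    kappa_peak: float = 0.02  # mm^-1
    kappa_width: float = 30.0  # mm (s.d. of the Gaussian bump in arc length)
    strain_peak: float = 15.0  # %
    cycle_duration: float = 10.0  # s
    fps: float = 60.0
    noise_sd: float = 0.0  # mm
    drift_amplitude: float = 0.0  # mm
    seed: int = 0
    # generator options (not part of the physical truth)
    time_envelope: str = "raised_cosine"  # or "constant"
    bend_tilt_deg: float = 35.0  # bending plane tilt out of the camera axis
    base_depth_mm: float = 400.0  # depth of the arm base below the camera
    arm_label: str = "L3"

    def __post_init__(self) -> None:
        for name in (
            "arm_length",
            "foot_fraction",
            "kappa_peak",
            "kappa_width",
            "strain_peak",
            "cycle_duration",
            "fps",
            "noise_sd",
            "drift_amplitude",
        ):
            _check_finite(name, getattr(self, name))
        if self.arm_length <= 0:
            raise ValueError("arm_length must be > 0")
        if self.n_keypoints < 4:
            raise ValueError("n_keypoints must be >= 4")
        if not 0 < self.foot_fraction < 1:
            raise ValueError("foot_fraction must lie in (0, 1)")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.kappa_width <= 0:
            raise ValueError("kappa_width must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.time_envelope not in ("raised_cosine", "constant"):
            raise ValueError("time_envelope must be 'raised_cosine' or 'constant'")


@dataclass
class GaitSimConfig:
    """Parameters of a synthetic 8-arm cyclic gait.

    ``period_s``, ``duty`` and ``phase`` accept a scalar (shared by all
    arms) or a sequence of 8 per-arm values in :data:`ARM_ORDER`.
    """

    period_s: float | Sequence[float] = 30.0
    duty: float | Sequence[float] = 0.6
    phase: float | Sequence[float] = 0.0  # fraction of period
    duration_s: float = 600.0
    fps: float = 60.0
    unknown_mask_prob: float = 0.0
    seed: int = 0

    def per_arm(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (8,)).copy()
        return arr

    def __post_init__(self) -> None:
        periods = self.per_arm(self.period_s)
        duties = self.per_arm(self.duty)
        if np.any(~np.isfinite(periods)) or np.any(periods <= 0):
            raise ValueError("period_s must be finite and > 0")
        if np.any(~np.isfinite(duties)) or np.any(duties <= 0) or np.any(duties > 1):
            raise ValueError("duty must lie in (0, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if not 0 <= self.unknown_mask_prob < 1:
            raise ValueError("unknown_mask_prob must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Exact kinematic truth of a simulated stride.

    ``kappa`` and ``strain_pct`` are sampled on the dense material grid
    ``sigma_mm`` (arc-length coordinate at the unstrained reference) for
    every frame; ``arc_mm`` maps material coordinate to current arc length,
    which lets the truth be expressed in the same coordinates the estimator
    uses (fractions of the current arc length).
    """

    sigma_mm: np.ndarray  # (S,)
    t_s: np.ndarray  # (T,)
    kappa: np.ndarray  # (T, S), mm^-1, >= 0
    strain_pct: np.ndarray  # (T, S)
    arc_mm: np.ndarray  # (T, S) current arc length at each material coord
    keypoint_sigma: np.ndarray  # (P,)
    keypoint_idx: np.ndarray  # indices of keypoints on the sigma grid
    positions: np.ndarray  # (T, P, 3) exact keypoint positions, mm
    release_frame: int
    fps: float
    foot_sigma: float
    config: ArmSimConfig

    def arm_length_at(self, frame: int) -> float:
        return float(self.arc_mm[frame, -1])

    def kappa_at_fracs(self, frame: int, fracs: np.ndarray) -> np.ndarray:
        """True curvature at given fractions of the frame's current arc length."""
        s_target = np.asarray(fracs) * self.arc_mm[frame, -1]
        sigma_star = np.interp(s_target, self.arc_mm[frame], self.sigma_mm)
        return np.interp(sigma_star, self.sigma_mm, self.kappa[frame])

    def segment_strain(self, frame: int) -> np.ndarray:
        """Exact strain (%) of each tracked segment relative to release."""
        arc_kp = self.arc_mm[frame, self.keypoint_idx]
        arc_ref = self.arc_mm[self.release_frame, self.keypoint_idx]
        seg = np.diff(arc_kp)
        seg_ref = np.diff(arc_ref)
        return (seg / seg_ref - 1.0) * 100.0

    def curvature_field(self, fracs: np.ndarray) -> np.ndarray:
        return np.stack(
            [self.kappa_at_fracs(i, fracs) for i in range(len(self.t_s))]
        )

    def strain_field(self, fracs: np.ndarray) -> np.ndarray:
        """Per-segment truth strain mapped piecewise-constant onto arc-fraction
        stations of the release-frame curve (the estimator's convention)."""
        ref_arc = self.arc_mm[self.release_frame, self.keypoint_idx]
        key_fracs = ref_arc / ref_arc[-1]
        seg_of_station = np.clip(
            np.searchsorted(key_fracs, np.asarray(fracs), side="right") - 1,
            0,
            len(key_fracs) - 2,
        )
        rows = [self.segment_strain(i)[seg_of_station] for i in range(len(self.t_s))]
        return np.stack(rows)


def _time_envelope(config: ArmSimConfig, n_frames: int) -> np.ndarray:
    if config.time_envelope == "constant":
        return np.ones(n_frames)
    k = np.arange(n_frames)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / n_frames))


def simulate_arm_stride(
    config: ArmSimConfig,
) -> tuple[TrajectorySet, GroundTruth]:
    """Build exact tracked-point positions for one arm cycle.

    The arm is planar (zero torsion): the geometric curvature at material
    coordinate sigma is ``kappa_peak * g(sigma) * h(t)`` with ``g`` a
    Gaussian bump centred at the foot, and the axial stretch follows a
    raised-cosine bump over the third of the arm proximal to the foot,
    scaled by the same envelope.  Frame 0 is the substrate-release frame
    (zero envelope), so the truth strain is identically 0 there.
    """
    L = config.arm_length
    n_seg = config.n_keypoints - 1
    n_dense = n_seg * _OVERSAMPLE + 1
    sigma = np.linspace(0.0, L, n_dense)
    s_foot = config.foot_fraction * L

    g_kappa = np.exp(-((sigma - s_foot) ** 2) / (2.0 * config.kappa_width**2))
    a, b = max(0.0, s_foot - L / 3.0), s_foot
    g_strain = np.zeros_like(sigma)
    inside = (sigma >= a) & (sigma <= b)
    if b > a:
        g_strain[inside] = 0.5 * (
            1.0 - np.cos(2.0 * np.pi * (sigma[inside] - a) / (b - a))
        )

    n_frames = int(round(config.cycle_duration * config.fps))
    h = _time_envelope(config, n_frames)
    kappa = config.kappa_peak * np.outer(h, g_kappa)  # (T, S)
    strain = config.strain_peak * np.outer(h, g_strain)  # (T, S), %

    lam = 1.0 + strain / 100.0
    arc = cumulative_trapezoid(lam, sigma, axis=1, initial=0.0)
    theta = cumulative_trapezoid(kappa * lam, sigma, axis=1, initial=0.0)
    du = cumulative_trapezoid(lam * np.cos(theta), sigma, axis=1, initial=0.0)
    dv = cumulative_trapezoid(lam * np.sin(theta), sigma, axis=1, initial=0.0)

    tilt = math.radians(config.bend_tilt_deg)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, math.sin(tilt), math.cos(tilt)])
    base = np.array([0.0, 0.0, config.base_depth_mm])
    dense_pos = (
        base[None, None, :]
        + du[:, :, None] * e1[None, None, :]
        + dv[:, :, None] * e2[None, None, :]
    )

    kp_idx = np.arange(0, n_dense, _OVERSAMPLE)
    positions = dense_pos[:, kp_idx, :]

    info = pd.DataFrame(
        {
            "point_id": [f"k{i:02d}" for i in range(config.n_keypoints)],
            "role": "key",
            "arm": config.arm_label,
        }
    )
    traj = TrajectorySet(
        info,
        positions,
        np.ones((n_frames, config.n_keypoints), dtype=bool),
        config.fps,
    )
    truth = GroundTruth(
        sigma_mm=sigma,
        t_s=np.arange(n_frames) / config.fps,
        kappa=kappa,
        strain_pct=strain,
        arc_mm=arc,
        keypoint_sigma=sigma[kp_idx],
        keypoint_idx=kp_idx,
        positions=positions,
        release_frame=0,
        fps=config.fps,
        foot_sigma=s_foot,
        config=config,
    )
    return traj, truth


def smooth_drift(
    n_frames: int, amplitude_mm: float, fps: float, seed: int = 0
) -> np.ndarray:
    """Slow, smooth per-frame 3-vector camera drift of given peak amplitude."""
    if amplitude_mm == 0:
        return np.zeros((n_frames, 3))
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    drift = np.zeros((n_frames, 3))
    for axis in range(3):
        for _ in range(2):
            f = rng.uniform(0.02, 0.15)  # Hz, slow vehicle/instrument sway
            phi = rng.uniform(0, 2 * np.pi)
            drift[:, axis] += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * f * t + phi)
    peak = np.abs(drift).max()
    if peak > 0:
        drift *= amplitude_mm / peak
    return drift


def _reference_positions(traj: TrajectorySet, n_reference: int) -> np.ndarray:
    xyz = traj.xyz[traj.valid]
    lo, hi = xyz.min(axis=0), xyz.max(axis=0)
    zc = float(np.median(xyz[:, 2]))
    m = 20.0  # mm margin outside the arm bounding box
    corners = np.array(
        [
            [lo[0] - m, lo[1] - m, zc],
            [hi[0] + m, lo[1] - m, zc],
            [lo[0] - m, hi[1] + m, zc],
            [hi[0] + m, hi[1] + m, zc],
            [0.5 * (lo[0] + hi[0]), lo[1] - m, zc],
            [0.5 * (lo[0] + hi[0]), hi[1] + m, zc],
            [lo[0] - m, 0.5 * (lo[1] + hi[1]), zc],
            [hi[0] + m, 0.5 * (lo[1] + hi[1]), zc],
        ]
    )
    if n_reference > len(corners):
        raise ValueError(f"at most {len(corners)} reference points supported")
    return corners[:n_reference]


def add_observation_noise(
    traj: TrajectorySet,
    noise_sd: float,
    drift: np.ndarray | None = None,
    seed: int = 0,
    n_reference: int = 3,
) -> tuple[TrajectorySet, TrajectorySet]:
    """Simulate observation: Gaussian noise per point per axis plus a drift
    shared by all points, including generated stationary reference points.

    Returns ``(observed, clean)``; both include the reference points so the
    clean set is the recovery target after background correction.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_frames = traj.n_frames
    if drift is None:
        drift = np.zeros((n_frames, 3))
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (n_frames, 3):
        raise ValueError(f"drift must have shape ({n_frames}, 3)")

    if n_reference > 0:
        ref_pos = _reference_positions(traj, n_reference)
        ref_info = pd.DataFrame(
            {
                "point_id": [f"ref{i}" for i in range(n_reference)],
                "role": "reference",
                "arm": "none",
            }
        )
        refs = TrajectorySet(
            ref_info,
            np.broadcast_to(ref_pos, (n_frames, n_reference, 3)).copy(),
            np.ones((n_frames, n_reference), dtype=bool),
            traj.fps,
        )
        clean = concat_trajectories([traj, refs])
    else:
        clean = traj.copy()

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, clean.xyz.shape) if noise_sd > 0 else 0.0
    observed = TrajectorySet(
        clean.point_info.copy(),
        clean.xyz + drift[:, None, :] + noise,
        clean.valid.copy(),
        clean.fps,
    )
    return observed, clean


def simulate_gait(config: GaitSimConfig) -> tuple[PhaseTable, pd.DataFrame]:
    """Deterministic square-wave contact pattern for 8 arms.

    Arm ``a`` is in contact while ``(t / period_a + phase_a) mod 1 < duty_a``.
    Frames are flipped to the unknown state i.i.d. with
    ``unknown_mask_prob``.  Returns the phase table and a truth table with
    per-arm period, duty and phase.
    """
    periods = config.per_arm(config.period_s)
    duties = config.per_arm(config.duty)
    phases = config.per_arm(config.phase)
    n_frames = int(round(config.duration_s * config.fps))
    t = np.arange(n_frames) / config.fps
    frac = (t[:, None] / periods[None, :] + phases[None, :]) % 1.0
    codes = np.where(frac < duties[None, :], CONTACT, AIR).astype(np.int8)
    if config.unknown_mask_prob > 0:
        rng = np.random.default_rng(config.seed)
        mask = rng.random(codes.shape) < config.unknown_mask_prob
        codes[mask] = UNKNOWN
    truth = pd.DataFrame(
        {
            "arm": list(ARM_ORDER),
            "period_s": periods,
            "duty": duties,
            "phase": phases,
            "period_frames": periods * config.fps,
            "contact_frames": duties * periods * config.fps,
        }
    )
    return PhaseTable(codes, config.fps), truth


def render_depth_stack(
    traj: TrajectorySet,
    pixel_pitch_mm: float,
    image_shape: tuple[int, int] | None = None,
    origin_mm: tuple[float, float] | None = None,
    disc_radius_px: int = 6,
    depth_noise_sd: float = 0.0,
    seed: int = 0,
    quantization_mm: float = 0.01,
) -> tuple[DepthMapStack, TrackTable]:
    """Orthographic rendering of tracked points into a depth-map stack.

    Each point paints a disc of its own depth around its projected position
    (nearest surface wins where discs overlap); all other pixels are
    invalid, emulating the sparse validity of real light-field range maps.
    Depths are optionally perturbed per pixel and quantized to
    ``quantization_mm`` so that stacks survive a 16-bit on-disk round trip
    exactly.  Points projecting outside the image are marked invalid in the
    returned 2D track table, not raised as errors.
    """
    if pixel_pitch_mm <= 0:
        raise ValueError("pixel_pitch_mm must be > 0")
    xyz = traj.xyz
    valid = traj.valid
    if origin_mm is None or image_shape is None:
        pts = xyz[valid]
        margin = (disc_radius_px + 2) * pixel_pitch_mm
        x0 = pts[:, 0].min() - margin
        y0 = pts[:, 1].min() - margin
        if image_shape is None:
            w = int(np.ceil((pts[:, 0].max() + margin - x0) / pixel_pitch_mm)) + 1
            h = int(np.ceil((pts[:, 1].max() + margin - y0) / pixel_pitch_mm)) + 1
            image_shape = (h, w)
        origin_mm = (x0, y0) if origin_mm is None else origin_mm
    h, w = image_shape
    x0, y0 = origin_mm

    dy, dx = np.mgrid[-disc_radius_px : disc_radius_px + 1, -disc_radius_px : disc_radius_px + 1]
    disc = dy**2 + dx**2 <= disc_radius_px**2
    dsel_r, dsel_c = dy[disc], dx[disc]

    rng = np.random.default_rng(seed)
    n_frames = traj.n_frames
    depth = np.full((n_frames, h, w), np.inf, dtype=np.float32)
    rows = []
    for f in range(n_frames):
        for j in range(traj.n_points):
            ok = bool(valid[f, j])
            cx = (xyz[f, j, 0] - x0) / pixel_pitch_mm if ok else np.nan
            cy = (xyz[f, j, 1] - y0) / pixel_pitch_mm if ok else np.nan
            inside = ok and 0 <= cx <= w - 1 and 0 <= cy <= h - 1
            if inside:
                rc = int(np.round(cy))
                cc = int(np.round(cx))
                rr = rc + dsel_r
                cols = cc + dsel_c
                keep = (rr >= 0) & (rr < h) & (cols >= 0) & (cols < w)
                z = np.float32(xyz[f, j, 2])
                np.minimum.at(depth[f], (rr[keep], cols[keep]), z)
            rows.append(
                {
                    "frame": f,
                    "point_id": traj.point_info["point_id"].iloc[j],
                    "role": traj.point_info["role"].iloc[j],
                    "arm": traj.point_info["arm"].iloc[j],
                    "x_px": cx,
                    "y_px": cy,
                    "valid": bool(inside),
                }
            )
    valid_px = np.isfinite(depth)
    depth[~valid_px] = 0.0
    if depth_noise_sd > 0:
        noise = rng.normal(0.0, depth_noise_sd, size=int(valid_px.sum()))
        depth[valid_px] += noise.astype(np.float32)
    if quantization_mm > 0:
        depth[valid_px] = (
            np.round(depth[valid_px] / quantization_mm) * quantization_mm
        ).astype(np.float32)

    stack = DepthMapStack(depth, valid_px, pixel_pitch_mm, traj.fps)
    tracks = TrackTable(pd.DataFrame(rows), traj.fps, pixel_pitch_mm)
    return stack, tracks


@dataclass
class CalibrationScene:
    """Rigid-transformed copies of a planar dot grid with known distances.

    ``points`` holds one (N, 3) noisy point set per pose; ``pairs`` indexes
    collinear grid points whose true separation is an exact multiple of the
    grid spacing (``known_mm``).
    """

    points: list[np.ndarray]
    pairs: np.ndarray  # (n_pairs, 2) indices into each pose's points
    known_mm: np.ndarray  # (n_pairs,)
    grid_spacing_mm: float

    def measured_mm(self) -> np.ndarray:
        """All measured pair distances, concatenated over poses."""
        out = []
        for pts in self.points:
            d = np.linalg.norm(pts[self.pairs[:, 0]] - pts[self.pairs[:, 1]], axis=1)
            out.append(d)
        return np.concatenate(out)

    def known_repeated(self) -> np.ndarray:
        return np.tile(self.known_mm, len(self.points))


def make_calibration_scene(
    grid_spacing: float = 50.0,
    n_poses: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid_shape: tuple[int, int] = (5, 5),
) -> CalibrationScene:
    """Synthetic analogue of imaging a calibration dot target at several
    poses and measuring point-to-point distances against known ones."""
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be > 0")
    rows, cols = grid_shape
    ii, jj = np.mgrid[0:rows, 0:cols]
    base = np.column_stack(
        [ii.ravel() * grid_spacing, jj.ravel() * grid_spacing, np.zeros(rows * cols)]
    )
    idx = np.arange(rows * cols).reshape(rows, cols)
    pairs = []
    known = []
    for r in range(rows):  # along-row pairs
        for c1 in range(cols):
            for c2 in range(c1 + 1, cols):
                pairs.append((idx[r, c1], idx[r, c2]))
                known.append((c2 - c1) * grid_spacing)
    for c in range(cols):  # along-column pairs
        for r1 in range(rows):
            for r2 in range(r1 + 1, rows):
                pairs.append((idx[r1, c], idx[r2, c]))
                known.append((r2 - r1) * grid_spacing)

    rng = np.random.default_rng(seed)
    points = []
    for _ in range(n_poses):
        # random rotation via QR of a Gaussian matrix (Haar-distributed)
        m = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(m)
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-100, 100, size=3) + np.array([0.0, 0.0, 500.0])
        pts = base @ q.T + t
        if noise_sd > 0:
            pts = pts + rng.normal(0.0, noise_sd, pts.shape)
        points.append(pts)
    return CalibrationScene(
        points, np.array(pairs), np.array(known, dtype=float), grid_spacing
    )
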