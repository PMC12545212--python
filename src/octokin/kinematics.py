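"""Arm-curve reconstruction and time-varying curvature/strain fields.

An arm at one frame is a simple interpolating spline through its ordered
tracked points (chord-length parameter), reparameterized to arc length by
composite Simpson quadrature on a dense grid.  Curvature comes from the
analytic spline derivatives (kappa = |r' x r''| / |r'|^3, which is
parameterization-invariant), strain from arc lengths measured along the fit
between consecutive tracked points against a reference configuration — by
convention the curve at the substrate-release frame (t = 0).

Curvature needs accurate second derivatives; a cubic interpolant through
sparse tracked points carries O(h^2) oscillatory second-derivative error
that dominates the curvature estimate near segment boundaries, so sparse
fits default to an interpolating quintic spline.  Refits from dense samples
(temporal smoothing) use a cubic, whose interpolation error is negligible
at that knot density and which amplifies residual noise less.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.interpolate import make_interp_spline

from .containers import TrajectorySet
from .filters import moving_average

__all__ = [
    "ArmCurve",
    "fit_arm_curve",
    "fit_curves",
    "smooth_temporal",
    "curvature_profile",
    "strain_profile",
    "KinematicsField",
    "build_field",
]

logger = logging.getLogger(__name__)


class ArmCurve:
    """Interpolating cubic space curve through ordered 3D points.

    Attributes
    ----------
    points : (n, 3) array — the defining points (proximal to distal).
    point_s : (n,) array — arc-length coordinate of each defining point.
    key_idx : indices of the *tracked* points among the defining points
        (all of them unless the curve was refit from dense samples).
    length : total arc length in mm.
    """

    def __init__(self, points: np.ndarray, key_idx: np.ndarray | None = None,
                 dense_per_segment: int = 32, degree: int | None = None,
                 key_labels: np.ndarray | None = None):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if points.shape[0] < 4:
            raise ValueError("at least 4 points are required to fit an arm curve")
        if not np.all(np.isfinite(points)):
            raise ValueError("points must be finite")
        chords = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(chords == 0):
            raise ValueError("consecutive points must not coincide")
        u = np.concatenate([[0.0], np.cumsum(chords)])
        if degree is None:
            degree = 5 if points.shape[0] >= 6 else 3
        self.degree = degree
        self.points = points
        self._u = u
        self._spline = make_interp_spline(u, points, k=degree, axis=0)
        # arc-length reparameterization on a dense grid (Simpson)
        m = dense_per_segment
        segs = [
            np.linspace(u[i], u[i + 1], m + 1)[: -1 if i < len(u) - 2 else None]
            for i in range(len(u) - 1)
        ]
        u_dense = np.concatenate(segs)
        speed = np.linalg.norm(self._spline(u_dense, 1), axis=1)
        s_dense = cumulative_simpson(speed, x=u_dense, initial=0.0)
        self._u_dense = u_dense
        self._s_dense = s_dense
        self.length = float(s_dense[-1])
        self.point_s = np.interp(u, u_dense, s_dense)
        self.key_idx = (
            np.arange(points.shape[0]) if key_idx is None else np.asarray(key_idx)
        )
        # material identity of the tracked points (e.g. indices into the
        # full point set when some observations were invalid at this frame)
        self.key_labels = (
            np.asarray(key_labels) if key_labels is not None else None
        )

    def _u_of_s(self, s: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self._s_dense, self._u_dense)

    def evaluate(self, s: np.ndarray) -> np.ndarray:
        """Position at arc-length coordinate(s) ``s``."""
        return self._spline(self._u_of_s(s))

    def evaluate_fracs(self, fracs: np.ndarray) -> np.ndarray:
        """Position at fraction(s) of total arc length."""
        return self.evaluate(np.asarray(fracs) * self.length)

    def curvature(self, s: np.ndarray) -> np.ndarray:
        """Curvature kappa(s) = |r' x r''| / |r'|^3 from spline derivatives."""
        u = self._u_of_s(s)
        d1 = self._spline(u, 1)
        d2 = self._spline(u, 2)
        cross = np.cross(d1, d2)
        num = np.linalg.norm(np.atleast_2d(cross), axis=1)
        den = np.linalg.norm(np.atleast_2d(d1), axis=1) ** 3
        return num / den

    def arc_between(self, s0: float, s1: float) -> float:
        return float(s1 - s0)

    def key_point_s(self) -> np.ndarray:
        """Arc-length coordinates of the tracked points along this fit."""
        return self.point_s[self.key_idx]


def fit_arm_curve(points: np.ndarray, valid: np.ndarray | None = None) -> ArmCurve:
    """Fit an arm curve through the valid ordered points of one frame."""
    points = np.asarray(points, dtype=float)
    if valid is None:
        valid = np.all(np.isfinite(points), axis=1)
    return ArmCurve(points[valid])


def fit_curves(
    traj: TrajectorySet, arm: str | None = None, min_points: int = 4
) -> dict[int, ArmCurve]:
    """Fit one curve per frame from a trajectory set (key/guide points of
    one arm, in proximal-to-distal point order).  Frames with fewer than
    ``min_points`` valid points are skipped and logged."""
    sub = traj.select_arm(arm) if arm is not None else traj
    curves: dict[int, ArmCurve] = {}
    skipped = 0
    for f in range(sub.n_frames):
        ok = sub.valid[f]
        if ok.sum() < min_points:
            skipped += 1
            continue
        curves[f] = ArmCurve(sub.xyz[f][ok], key_labels=np.flatnonzero(ok))
    if skipped:
        logger.info("fit_curves: skipped %d frame(s) with < %d valid points",
                    skipped, min_points)
    return curves


def smooth_temporal(
    curves: dict[int, ArmCurve],
    window: int = 7,
    samples_per_segment: int = 12,
) -> dict[int, ArmCurve]:
    """Temporal stabilisation of per-frame fits.

    Every curve is sampled at common per-segment arc-length fractions, each
    sampled coordinate is passed through a centred moving average across
    frames, and the curves are refit from the smoothed samples.  The tracked
    points sit at segment boundaries, so their identity survives the refit
    (``key_idx`` of the result indexes them).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not curves:
        return {}
    # frames must share the tracked point set for samples to be comparable;
    # keep the most common signature and treat the rest as missing frames
    from collections import Counter

    def signature(c: ArmCurve):
        labels = c.key_labels if c.key_labels is not None else c.key_idx
        return tuple(int(x) for x in labels)

    modal, _ = Counter(signature(c) for c in curves.values()).most_common(1)[0]
    usable = {f: c for f, c in curves.items() if signature(c) == modal}
    if len(usable) < len(curves):
        logger.info(
            "smooth_temporal: %d frame(s) dropped (tracked point set differs "
            "from the modal one)", len(curves) - len(usable),
        )
    curves = usable
    frames = np.arange(min(curves), max(curves) + 1)
    n_seg = len(modal) - 1
    m = samples_per_segment
    n_stations = n_seg * m + 1

    samples = np.full((frames.size, n_stations, 3), np.nan)
    has = np.zeros(frames.size, dtype=bool)
    for i, f in enumerate(frames):
        curve = curves.get(int(f))
        if curve is None:
            continue
        ks = curve.key_point_s()
        stations = np.concatenate(
            [
                np.linspace(ks[k], ks[k + 1], m + 1)[: -1 if k < n_seg - 1 else None]
                for k in range(n_seg)
            ]
        )
        samples[i] = curve.evaluate(stations)
        has[i] = True

    smoothed = np.empty_like(samples)
    for st in range(n_stations):
        for ax in range(3):
            smoothed[:, st, ax] = moving_average(samples[:, st, ax], has, window)

    out: dict[int, ArmCurve] = {}
    key_idx = np.arange(0, n_stations, m)
    labels = np.asarray(modal)
    for i, f in enumerate(frames):
        if has[i]:
            out[int(f)] = ArmCurve(
                smoothed[i], key_idx=key_idx, degree=3,
                dense_per_segment=6, key_labels=labels,
            )
    return out


def curvature_profile(
    curve: ArmCurve, n_samples: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Curvature at ``n_samples`` regularly spaced arc-length stations.

    Returns ``(s, kappa)`` with s from 0 (proximal) to the total arc length.
    """
    s = np.linspace(0.0, curve.length, n_samples)
    return s, curve.curvature(s)


def strain_profile(curve_t: ArmCurve, curve_ref: ArmCurve) -> np.ndarray:
    """Strain (%) of each tracked segment of ``curve_t`` relative to
    ``curve_ref``: 100 * (L_i(t) / L_i(ref) - 1), with lengths measured
    along the fits."""
    if curve_t.key_idx.size != curve_ref.key_idx.size:
        raise ValueError("curves must share the ordered tracked point set")
    if (
        curve_t.key_labels is not None
        and curve_ref.key_labels is not None
        and not np.array_equal(curve_t.key_labels, curve_ref.key_labels)
    ):
        raise ValueError("curves must share the ordered tracked point set")
    seg_t = np.diff(curve_t.key_point_s())
    seg_ref = np.diff(curve_ref.key_point_s())
    return (seg_t / seg_ref - 1.0) * 100.0


@dataclass
class KinematicsField:
    """(s, t) grids of curvature and strain for one stride.

    ``s_mm`` is measured from the chosen origin along the release-frame
    curve; ``t_s`` is time relative to substrate release.  ``kappa`` and
    ``strain_pct`` have shape (n_t, n_s); rows of frames without a curve
    are NaN.
    """

    s_mm: np.ndarray
    t_s: np.ndarray
    kappa: np.ndarray
    strain_pct: np.ndarray
    release_frame: int
    fps: float


def build_field(
    curves: dict[int, ArmCurve],
    release_frame: int,
    fps: float,
    n_stations: int = 100,
    foot_s_mm: float | None = None,
) -> KinematicsField:
    """Resample per-frame curvature and per-segment strain onto a common
    (s, t) grid.

    Stations are equally spaced fractions of each frame's arc length; the
    ``s`` axis is labelled in mm of the release-frame (reference) curve,
    shifted so that ``s = 0`` sits at ``foot_s_mm`` (the substrate
    attachment point) when given, else at the proximal end.  The strain
    reference configuration is the release-frame curve, so the t = 0 row of
    the strain field is identically zero.
    """
    if release_frame not in curves:
        raise ValueError(
            f"stride without a release event: no curve at release frame {release_frame}"
        )
    ref = curves[release_frame]
    frames = np.arange(min(curves), max(curves) + 1)
    fracs = np.linspace(0.0, 1.0, n_stations)

    ref_key_s = ref.key_point_s()
    key_fracs = ref_key_s / ref_key_s[-1]
    seg_of_station = np.clip(
        np.searchsorted(key_fracs, fracs, side="right") - 1, 0, key_fracs.size - 2
    )

    kappa = np.full((frames.size, n_stations), np.nan)
    strain = np.full((frames.size, n_stations), np.nan)
    for i, f in enumerate(frames):
        curve = curves.get(int(f))
        if curve is None:
            continue
        kappa[i] = curve.curvature(fracs * curve.length)
        strain[i] = strain_profile(curve, ref)[seg_of_station]

    s_mm = fracs * ref.length
    if foot_s_mm is not None:
        s_mm = s_mm - foot_s_mm
    t_s = (frames - release_frame) / fps
    return KinematicsField(s_mm, t_s, kappa, strain, release_frame, fps)
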