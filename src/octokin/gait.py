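"""Whole-animal gait statistics from ternary phase diagrams.

A stride (arm cycle) runs from one contact onset of an arm to its next
contact onset (half-open frame intervals); the duty cycle is the percentage
of the stride spent in contact.  Strides touching unknown frames are
excluded by default, since a grey region makes both the onset and the cycle
length uncertain.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines, GLMGam

from .containers import AIR, ARM_ORDER, CONTACT, UNKNOWN, PhaseTable

__all__ = [
    "Stride",
    "segment_strides",
    "segment_all_strides",
    "GaitStats",
    "gait_stats",
    "contact_count_series",
    "bilateral_fraction",
    "transition_matrix",
]


@dataclass(frozen=True)
class Stride:
    """One arm cycle: contact onset, lift-off, and the next contact onset
    (half-open intervals: contact spans [touch_on, touch_off))."""

    arm: str
    touch_on: int
    touch_off: int
    next_on: int

    def __post_init__(self) -> None:
        if not self.touch_on < self.touch_off <= self.next_on:
            raise ValueError("stride requires touch_on < touch_off <= next_on")

    @property
    def cycle_frames(self) -> int:
        return self.next_on - self.touch_on

    @property
    def contact_frames(self) -> int:
        return self.touch_off - self.touch_on


def _contact_runs(column: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of contact frames as half-open [on, off) intervals."""
    c = column == CONTACT
    edges = np.diff(c.astype(np.int8))
    ons = list(np.flatnonzero(edges == 1) + 1)
    offs = list(np.flatnonzero(edges == -1) + 1)
    if c[0]:
        ons = [0] + ons
    if c[-1]:
        offs = offs + [c.size]
    return list(zip(ons, offs))


def segment_strides(
    phase: PhaseTable,
    arm: str,
    exclude_unknown: bool = True,
    max_unknown_frames: int = 0,
) -> list[Stride]:
    """Segment one arm's ternary column into complete strides.

    The first contact run is dropped when it starts at frame 0 (its true
    onset is unobserved), and the trailing incomplete stride (no following
    onset) is always dropped.  With ``exclude_unknown`` a stride is kept
    only if the frames from just before its onset through its next onset
    contain at most ``max_unknown_frames`` unknowns.
    """
    col = phase.column(arm)
    runs = _contact_runs(col)
    if runs and runs[0][0] == 0:
        runs = runs[1:]
    strides = []
    for (on, off), (next_on, _) in zip(runs[:-1], runs[1:]):
        if exclude_unknown:
            lo = max(0, on - 1)
            n_unknown = int(np.sum(col[lo : next_on + 1] == UNKNOWN))
            if n_unknown > max_unknown_frames:
                continue
        strides.append(Stride(arm, on, off, next_on))
    return strides


def segment_all_strides(phase: PhaseTable, **kwargs) -> list[Stride]:
    out: list[Stride] = []
    for arm in ARM_ORDER:
        out.extend(segment_strides(phase, arm, **kwargs))
    return out


@dataclass
class GaitStats:
    """Per-stride metrics plus per-arm-pair box statistics.

    ``per_stride`` columns: arm, pair, touch_on, touch_off, next_on,
    cycle_s, duty_pct.  ``by_pair`` columns: pair, metric, n, median, q1,
    q3, iqr, whisker_lo, whisker_hi.
    """

    per_stride: pd.DataFrame
    by_pair: pd.DataFrame


def _box_stats(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    return {
        "n": values.size,
        "median": med,
        "q1": q1,
        "q3": q3,
        "iqr": iqr,
        "whisker_lo": q1 - 1.5 * iqr,
        "whisker_hi": q3 + 1.5 * iqr,
    }


def gait_stats(strides: list[Stride], fps: float) -> GaitStats:
    """Cycle duration (s) and contact duty cycle (%) per stride, with
    median/IQR/whisker summaries grouped by arm pair (1 dorsal .. 4
    ventral).  An empty stride list yields empty tables."""
    rows = [
        {
            "arm": s.arm,
            "pair": int(s.arm[1]),
            "touch_on": s.touch_on,
            "touch_off": s.touch_off,
            "next_on": s.next_on,
            "cycle_s": s.cycle_frames / fps,
            "duty_pct": 100.0 * s.contact_frames / s.cycle_frames,
        }
        for s in strides
    ]
    per_stride = pd.DataFrame(
        rows,
        columns=["arm", "pair", "touch_on", "touch_off", "next_on", "cycle_s", "duty_pct"],
    )
    summaries = []
    for metric in ("cycle_s", "duty_pct"):
        for pair, grp in per_stride.groupby("pair"):
            summaries.append(
                {"pair": pair, "metric": metric, **_box_stats(grp[metric].to_numpy())}
            )
    by_pair = pd.DataFrame(
        summaries,
        columns=["pair", "metric", "n", "median", "q1", "q3", "iqr", "whisker_lo", "whisker_hi"],
    )
    return GaitStats(per_stride, by_pair)


def contact_count_series(
    phase: PhaseTable,
    smooth: bool = True,
    spline_df: int = 20,
    alphas: tuple[float, ...] = (1e0, 1e2, 1e4, 1e6, 1e8),
) -> pd.DataFrame:
    """Per-frame count of arms in contact with a penalized-spline trend.

    Unknown states count as non-contact (their number is reported in
    ``n_unknown``); frames where every arm is unknown are excluded from the
    smoother fit.  The trend is a cubic regression B-spline with a ridge
    penalty whose weight is chosen by generalized cross-validation over
    ``alphas``; the 95% band is the normal approximation from the fitted
    coefficient covariance.
    """
    counts = np.sum(phase.codes == CONTACT, axis=1).astype(float)
    n_unknown = np.sum(phase.codes == UNKNOWN, axis=1)
    t = np.arange(phase.n_frames) / phase.fps
    df = pd.DataFrame(
        {"frame": np.arange(phase.n_frames), "t_s": t, "count": counts,
         "n_unknown": n_unknown}
    )
    usable = n_unknown < 8
    df.loc[~usable, "count"] = np.nan
    if not smooth or usable.sum() < spline_df + 2:
        return df

    x = t[usable]
    y = counts[usable]
    if np.ptp(y) == 0:  # constant series: flat trend, zero-width band
        df.loc[usable, "trend"] = y
        df.loc[usable, "trend_lo"] = y
        df.loc[usable, "trend_hi"] = y
        return df
    bs = BSplines(x[:, None], df=[spline_df], degree=[3])
    intercept = np.ones((y.size, 1))
    best = None
    n = y.size
    for alpha in alphas:
        res = GLMGam(y, exog=intercept, smoother=bs, alpha=[alpha]).fit()
        edf = n - res.df_resid
        rss = float(np.sum((y - res.fittedvalues) ** 2))
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, res)
    res = best[1]
    X = np.column_stack([intercept, bs.basis])
    mu = X @ res.params
    cov = np.asarray(res.cov_params())
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    df.loc[usable, "trend"] = mu
    df.loc[usable, "trend_lo"] = mu - 1.96 * se
    df.loc[usable, "trend_hi"] = mu + 1.96 * se
    return df


def bilateral_fraction(phase: PhaseTable) -> float:
    """Percentage of determinable frames with at least one left and one
    right arm in contact.

    A frame is determinable when the known states decide the answer: it
    counts as bilateral when both sides have a known contact, as
    non-bilateral when all arms of either side are known to be in the air,
    and is excluded otherwise (unknowns could flip it either way).
    """
    left = phase.codes[:, :4]
    right = phase.codes[:, 4:]
    l_contact = np.any(left == CONTACT, axis=1)
    r_contact = np.any(right == CONTACT, axis=1)
    l_all_air = np.all(left == AIR, axis=1)
    r_all_air = np.all(right == AIR, axis=1)
    bilateral = l_contact & r_contact
    not_bilateral = l_all_air | r_all_air
    determinable = bilateral | not_bilateral
    if not determinable.any():
        return np.nan
    return 100.0 * bilateral.sum() / determinable.sum()


def transition_matrix(phase: PhaseTable, require_known_before: bool = True) -> pd.DataFrame:
    """8 x 8 touch-down order counts.

    Entry (row b, column a) counts how often arm b's touch-down immediately
    followed arm a's.  Onsets are contact frames whose previous frame is a
    known air state (runs starting at frame 0 or after an unknown are
    skipped when ``require_known_before``); simultaneous onsets are ordered
    by the fixed arm order L1..L4, R1..R4 and every consecutive pair is
    counted.
    """
    events: list[tuple[int, int]] = []  # (frame, arm index)
    for a, arm in enumerate(ARM_ORDER):
        col = phase.column(arm)
        for on, _ in _contact_runs(col):
            if on == 0 or (require_known_before and col[on - 1] != AIR):
                continue
            events.append((on, a))
    events.sort()
    counts = np.zeros((8, 8), dtype=int)
    for (_, prev), (_, cur) in zip(events[:-1], events[1:]):
        counts[cur, prev] += 1
    return pd.DataFrame(counts, index=list(ARM_ORDER), columns=list(ARM_ORDER))
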