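"""Normalization and pooling of per-stride kinematics fields.

To compare strides across arms and individuals, the arm-distance axis is
normalized to the individual's head width and the time axis to the median
arm cycle, then curvature and strain samples are pooled into a fixed
(s', t') bin grid with per-bin means and the count of distinct sequences
contributing to each bin.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import KinematicsField

__all__ = ["NormalizedField", "normalize_field", "AggregateGrid", "bin_fields",
           "grid_to_dataframe", "plot_grid"]


@dataclass
class NormalizedField:
    """A kinematics field on unitless axes: s' = s / head width,
    t' = t / median arm cycle (0 at substrate release)."""

    s: np.ndarray
    t: np.ndarray
    kappa: np.ndarray
    strain_pct: np.ndarray


def normalize_field(
    field: KinematicsField, head_width_mm: float, median_cycle_s: float
) -> NormalizedField:
    """Rescale the axes of a field; the kappa/strain values are untouched."""
    if head_width_mm <= 0:
        raise ValueError("head_width_mm must be > 0")
    if median_cycle_s <= 0:
        raise ValueError("median_cycle_s must be > 0")
    return NormalizedField(
        s=field.s_mm / head_width_mm,
        t=field.t_s / median_cycle_s,
        kappa=field.kappa.copy(),
        strain_pct=field.strain_pct.copy(),
    )


@dataclass
class AggregateGrid:
    """Binned aggregate of pooled fields.

    ``kappa_mean``/``strain_mean`` are arithmetic means of all samples in a
    bin (NaN where no sample fell); ``count`` is the number of distinct
    sequences contributing to the bin.
    """

    s_edges: np.ndarray
    t_edges: np.ndarray
    kappa_mean: np.ndarray  # (n_t_bins, n_s_bins)
    strain_mean: np.ndarray
    count: np.ndarray  # distinct contributing sequences per bin
    n_samples: np.ndarray  # total (sequence, sample) values per bin


def _accumulate(
    values: np.ndarray, si: np.ndarray, ti: np.ndarray, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    ok = np.isfinite(values)
    sums = np.zeros(shape)
    counts = np.zeros(shape)
    np.add.at(sums, (ti[ok], si[ok]), values[ok])
    np.add.at(counts, (ti[ok], si[ok]), 1.0)
    return sums, counts


def bin_fields(
    fields: list[NormalizedField],
    s_edges: np.ndarray | None = None,
    t_edges: np.ndarray | None = None,
    n_bins: int = 20,
) -> AggregateGrid:
    """Pool normalized fields into a rectangular bin grid.

    Default edges span the observed range of the pooled fields with
    ``n_bins`` bins per axis.  Samples on the upper edge fall in the last
    bin.  Binning is a plain arithmetic mean over all in-range samples and
    is invariant to the order of the input sequences.
    """
    if not fields:
        raise ValueError("at least one field is required")
    if s_edges is None:
        lo = min(f.s.min() for f in fields)
        hi = max(f.s.max() for f in fields)
        s_edges = np.linspace(lo, hi, n_bins + 1)
    if t_edges is None:
        lo = min(f.t.min() for f in fields)
        hi = max(f.t.max() for f in fields)
        t_edges = np.linspace(lo, hi, n_bins + 1)
    s_edges = np.asarray(s_edges, dtype=float)
    t_edges = np.asarray(t_edges, dtype=float)
    if np.any(np.diff(s_edges) <= 0) or np.any(np.diff(t_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    shape = (t_edges.size - 1, s_edges.size - 1)

    k_sum = np.zeros(shape)
    k_n = np.zeros(shape)
    e_sum = np.zeros(shape)
    e_n = np.zeros(shape)
    seq_count = np.zeros(shape, dtype=int)
    for f in fields:
        ss, tt = np.meshgrid(f.s, f.t)
        si = np.digitize(ss.ravel(), s_edges) - 1
        ti = np.digitize(tt.ravel(), t_edges) - 1
        si = np.where(ss.ravel() == s_edges[-1], shape[1] - 1, si)
        ti = np.where(tt.ravel() == t_edges[-1], shape[0] - 1, ti)
        in_range = (si >= 0) & (si < shape[1]) & (ti >= 0) & (ti < shape[0])
        si, ti = si[in_range], ti[in_range]
        kv = f.kappa.ravel()[in_range]
        ev = f.strain_pct.ravel()[in_range]
        ks, kn = _accumulate(kv, si, ti, shape)
        es, en = _accumulate(ev, si, ti, shape)
        k_sum += ks
        k_n += kn
        e_sum += es
        e_n += en
        seq_count += ((kn > 0) | (en > 0)).astype(int)

    with np.errstate(invalid="ignore"):
        kappa_mean = np.where(k_n > 0, k_sum / np.where(k_n > 0, k_n, 1), np.nan)
        strain_mean = np.where(e_n > 0, e_sum / np.where(e_n > 0, e_n, 1), np.nan)
    return AggregateGrid(s_edges, t_edges, kappa_mean, strain_mean, seq_count, k_n + e_n)


def grid_to_dataframe(grid: AggregateGrid) -> pd.DataFrame:
    """Tidy long-format view of an aggregate grid (one row per bin)."""
    sc = 0.5 * (grid.s_edges[:-1] + grid.s_edges[1:])
    tc = 0.5 * (grid.t_edges[:-1] + grid.t_edges[1:])
    ss, tt = np.meshgrid(sc, tc)
    return pd.DataFrame(
        {
            "s_center": ss.ravel(),
            "t_center": tt.ravel(),
            "kappa_mean": grid.kappa_mean.ravel(),
            "strain_mean": grid.strain_mean.ravel(),
            "count": grid.count.ravel(),
        }
    )


def plot_grid(grid: AggregateGrid, path: str, which: str = "kappa") -> None:
    """Basic heat-map export of an aggregate grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = grid.kappa_mean if which == "kappa" else grid.strain_mean
    fig, ax = plt.subplots(figsize=(6, 4))
    pm = ax.pcolormesh(grid.t_edges, grid.s_edges, data.T, shading="flat")
    ax.set_xlabel("time / median arm cycle")
    ax.set_ylabel("arm distance / head width")
    fig.colorbar(pm, ax=ax, label="curvature (mm$^{-1}$)" if which == "kappa" else "strain (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
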