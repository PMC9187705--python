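"""Smoothing and normalization of the raw S/G1 ratio profile.

The smoother minimizes, over natural cubic splines f,

    p * sum_j (y_j - f(x_j))**2  +  (1 - p) * integral f''(t)**2 dt

with unit weights and x in bp (the csaps convention; the penalty scale
depends on the x units, so both are frozen here). Internally this is the
penalized-regression form with lambda = (1 - p) / p, solved after
rescaling x to unit mean spacing — an exact reparameterization
(lambda' = lambda / s**3 for x' = x / s) that keeps the linear system
well conditioned. In the extreme-lambda regimes, where direct solvers
lose accuracy, the exact limits are returned instead: the interpolant
for lambda' -> 0 and the weighted least-squares line for lambda' -> inf.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .io import GenomeDescriptor

logger = logging.getLogger(__name__)

DEFAULT_P = 1e-16
DEFAULT_MAX_GAP = 100_000

#: beyond these (after rescaling to unit mean spacing) the closed-form
#: limit is exact to well below 1e-6
_LAM_LINE_LIMIT = 1e10
_LAM_INTERP_LIMIT = 1e-10

PROFILE_COLUMNS = ["chrom", "center", "raw_ratio", "smoothed", "rt", "segment_id"]


def segment_profile(bins: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> np.ndarray:
    """Assign a segment id to each bin; a new segment starts whenever the
    chromosome changes or adjacent bin centers are more than ``max_gap``
    apart. Segments never cross chromosomes.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    centers = ((bins["start"] + bins["end"]) // 2).to_numpy()
    chroms = bins["chrom"].to_numpy()
    if len(bins) == 0:
        return np.array([], dtype=np.int64)
    new_seg = np.ones(len(bins), dtype=bool)
    same_chrom = chroms[1:] == chroms[:-1]
    close = np.abs(centers[1:] - centers[:-1]) <= max_gap
    new_seg[1:] = ~(same_chrom & close)
    return np.cumsum(new_seg).astype(np.int64) - 1


def _dense_smooth(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Direct (I + lam*K) solve for tiny segments the banded path rejects."""
    n = x.size
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for i in range(1, n - 1):
        Q[i - 1, i - 1] = 1.0 / h[i - 1]
        Q[i, i - 1] = -1.0 / h[i - 1] - 1.0 / h[i]
        Q[i + 1, i - 1] = 1.0 / h[i]
        R[i - 1, i - 1] = (h[i - 1] + h[i]) / 3.0
        if i < n - 2:
            R[i - 1, i] = R[i, i - 1] = h[i] / 6.0
    K = Q @ np.linalg.solve(R, Q.T)
    return np.linalg.solve(np.eye(n) + lam * K, y)


def smooth_segment(x: np.ndarray, y: np.ndarray, p: float = DEFAULT_P) -> np.ndarray:
    """Cubic smoothing spline fit evaluated at the data points.

    Requires at least 4 strictly increasing points (callers pass shorter
    segments through unsmoothed).
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 4:
        raise ValueError("smooth_segment requires at least 4 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    lam = (1.0 - p) / p
    scale = float(np.mean(np.diff(x)))
    xs = (x - x[0]) / scale
    lam_r = lam / scale**3
    if lam_r >= _LAM_LINE_LIMIT:
        coeffs = np.polyfit(xs, y, 1)
        return np.polyval(coeffs, xs)
    if lam_r <= _LAM_INTERP_LIMIT:
        return y.copy()
    if x.size < 5:
        return _dense_smooth(xs, y, lam_r)
    return make_smoothing_spline(xs, y, lam=lam_r)(xs)


def smooth_profile(
    bins: pd.DataFrame,
    p: float = DEFAULT_P,
    max_gap: int = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """Segment the bin table and smooth the ratio within each segment.

    Segments with fewer than 4 bins pass through unsmoothed with a
    warning. Returns the per-bin profile table (without rt values; see
    :func:`normalize`).
    """
    seg_ids = segment_profile(bins, max_gap=max_gap)
    centers = ((bins["start"] + bins["end"]) // 2).to_numpy()
    ratio = bins["ratio"].to_numpy(dtype=float)
    smoothed = np.empty(len(bins))
    for seg in np.unique(seg_ids):
        sel = seg_ids == seg
        if sel.sum() < 4:
            logger.warning(
                "segment %d has %d < 4 bins; passing through unsmoothed", seg, sel.sum()
            )
            smoothed[sel] = ratio[sel]
            continue
        smoothed[sel] = smooth_segment(centers[sel].astype(float), ratio[sel], p=p)
    return pd.DataFrame(
        {
            "chrom": bins["chrom"].to_numpy(),
            "start": bins["start"].to_numpy(),
            "end": bins["end"].to_numpy(),
            "center": centers,
            "raw_ratio": ratio,
            "smoothed": smoothed,
            "segment_id": seg_ids,
        }
    )


def normalize(profile: pd.DataFrame, genome: GenomeDescriptor | None = None) -> pd.DataFrame:
    """Z-normalize smoothed values to an autosomal mean of 0 and SD of 1.

    The mean and SD are the unweighted statistics over autosomal bins;
    chromosome X is scaled with the autosomal parameters rather than
    being forced to mean 0. Y-chromosome bins, if present, are dropped.
    """
    is_auto = np.array([GenomeDescriptor.is_autosome(c) for c in profile["chrom"]])
    is_y = np.array([GenomeDescriptor.is_y(c) for c in profile["chrom"]])
    out = profile.loc[~is_y].copy()
    auto_vals = profile.loc[is_auto, "smoothed"].to_numpy()
    if auto_vals.size < 2:
        raise ValueError("need at least 2 autosomal bins to normalize")
    mu = float(np.mean(auto_vals))
    sigma = float(np.std(auto_vals))
    if sigma == 0:
        raise ValueError("degenerate profile: autosomal SD is zero")
    out["rt"] = (out["smoothed"] - mu) / sigma
    return out.reset_index(drop=True)


def rt_profile_from_bins(
    bins: pd.DataFrame,
    p: float = DEFAULT_P,
    max_gap: int = DEFAULT_MAX_GAP,
    genome: GenomeDescriptor | None = None,
) -> pd.DataFrame:
    """smooth_profile + normalize."""
    return normalize(smooth_profile(bins, p=p, max_gap=max_gap), genome=genome)


def profile_to_bedgraph_frame(profile: pd.DataFrame) -> pd.DataFrame:
    return profile[["chrom", "start", "end", "rt"]].rename(columns={"rt": "value"})


def profile_from_bedgraph_frame(df: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> pd.DataFrame:
    """Rebuild a minimal profile table (chrom/center/rt/segment_id) from a
    bedGraph of rt values, re-deriving segment ids from bin spacing."""
    out = df.rename(columns={"value": "rt"}).copy()
    out["center"] = (out["start"] + out["end"]) // 2
    out["segment_id"] = segment_profile(out, max_gap=max_gap)
    return out
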