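"""Piecewise-constant segmentation of per-bin coverage profiles.

Copy-number style segmentation by penalized least squares: over all
segmentations of a series, minimise

    sum of squared residuals  +  penalty * (number of segments)

with each segment fitted by its mean.  The optimum is found exactly with
the PELT pruned dynamic programme (pruning is lossless for the SSE cost,
so the result equals the full O(n^2) dynamic programme).  Chromosomes are
segmented independently; masked bins (NaN) are compacted out before
fitting and re-expanded afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import BinGrid


@dataclass
class SegmentedProfile:
    """Piecewise-constant fit: per-bin fitted value plus segment structure."""

    fitted: np.ndarray                 # per-bin, NaN where masked
    segments: list[tuple[np.ndarray, float]]  # (bin indices, level) per segment

    def breakpoints(self) -> np.ndarray:
        """First bin index of every segment after the first, per output order."""
        return np.array([seg[0][0] for seg in self.segments[1:]], dtype=np.int64)

    def segment_lengths(self) -> np.ndarray:
        return np.array([seg[0].size for seg in self.segments], dtype=np.int64)

    def segment_values(self) -> np.ndarray:
        return np.array([seg[1] for seg in self.segments], dtype=float)


def pelt_breakpoints(x: np.ndarray, penalty: float) -> list[int]:
    """Exact changepoint positions minimising SSE + penalty * #segments.

    Returns the sorted interior breakpoints (split before index b); the
    empty list means a single segment.  Ties between segmentations of
    equal objective are broken toward fewer/later changepoints by the
    strict improvement test.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return []
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_cost(starts: np.ndarray, t: int) -> np.ndarray:
        # SSE of x[s:t] for each s, via sufficient statistics
        ln = t - starts
        s1 = cs[t] - cs[starts]
        s2 = cs2[t] - cs2[starts]
        return s2 - s1 * s1 / ln

    f = np.full(n + 1, np.inf)
    f[0] = 0.0
    prev = np.zeros(n + 1, dtype=np.int64)
    candidates = np.array([0], dtype=np.int64)
    for t in range(1, n + 1):
        costs = seg_cost(candidates, t)
        totals = f[candidates] + costs + penalty
        best = int(np.argmin(totals))
        f[t] = totals[best]
        prev[t] = candidates[best]
        # lossless pruning: SSE cost is superadditive under concatenation
        keep = f[candidates] + costs <= f[t]
        candidates = np.append(candidates[keep], t)
    bps = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            bps.append(s)
        t = s
    return bps[::-1]


def _fit_block(values: np.ndarray, offset: int, penalty: float,
               segments: list[tuple[np.ndarray, float]], fitted: np.ndarray) -> None:
    """Segment one chromosome block; indices reported on the full grid."""
    idx = offset + np.flatnonzero(np.isfinite(values))
    x = values[np.isfinite(values)]
    if x.size == 0:
        return
    bounds = [0] + pelt_breakpoints(x, penalty) + [x.size]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        level = float(x[lo:hi].mean())
        seg_idx = idx[lo:hi]
        segments.append((seg_idx, level))
        fitted[seg_idx] = level


def segment_profile(values: np.ndarray, bins: BinGrid,
                    penalty: float = 4.0) -> SegmentedProfile:
    """Segment a per-bin series per chromosome.

    ``values`` holds NaN at masked bins; these are excluded from fitting
    and stay NaN in the output.  An all-masked chromosome yields no
    segments.  The default penalty suits IQR-standardized, median-filtered
    profiles; pass a larger value for noisier raw-scale series.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (bins.n_bins,):
        raise ValueError("values must be one per bin")
    fitted = np.full(bins.n_bins, np.nan)
    segments: list[tuple[np.ndarray, float]] = []
    for _, lo, hi in bins.chrom_blocks():
        _fit_block(values[lo:hi], lo, penalty, segments, fitted)
    return SegmentedProfile(fitted, segments)


def mappability_filter(seg: SegmentedProfile, retain_fraction: float = 0.95) -> np.ndarray:
    """Mask bins in the lowest-value segments (low-mappability dropouts).

    Segments are ranked by fitted level (ascending, stable) and masked
    from the bottom while the running bin total stays within the
    ``1 - retain_fraction`` budget of all segmented bins, so at most that
    fraction of bins is ever dropped.  Returns a boolean per-bin mask
    (True = newly masked).  When all levels are equal nothing is masked.
    """
    n = seg.fitted.size
    mask = np.zeros(n, dtype=bool)
    if not seg.segments:
        return mask
    levels = seg.segment_values()
    lengths = seg.segment_lengths()
    if np.allclose(levels, levels[0]):
        return mask
    total = int(lengths.sum())
    budget = int(np.floor((1.0 - retain_fraction) * total))
    if budget <= 0:
        return mask
    used = 0
    for j in np.argsort(levels, kind="stable"):
        if used + lengths[j] > budget:
            break
        mask[seg.segments[j][0]] = True
        used += int(lengths[j])
    return mask
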