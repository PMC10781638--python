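"""RT peaks (initiation zones), TTRs and RT troughs (termination zones).

Bins are grouped into k = 15 clusters by RT value (1-D Gaussian mixture)
and clusters ranked by mean RT (k = earliest).  A bin is a local maximum
(minimum) when its rank equals the maximum (minimum) of the centred
21-bin window around it; maximal runs of maxima become RT peaks, runs of
minima RT troughs, and everything between them TTRs.  Feature types
alternate peak -> TTR -> trough -> TTR -> peak along each chromosome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .grid import BinGrid, RTProfile
from .synthetic import PEAK, TROUGH, TTR

log = logging.getLogger(__name__)

_TYPES = (PEAK, TTR, TROUGH)


@dataclass
class FeatureSet:
    """Typed intervals tiling the unmasked bins of each chromosome."""

    bins: BinGrid
    intervals: pd.DataFrame      # chrom, start, end, type, bin_lo, bin_hi
    cluster_rank: np.ndarray     # per-bin int, 0 where unassigned

    def per_bin_type(self) -> np.ndarray:
        """Per-bin feature type (object array, None outside any feature)."""
        out = np.full(self.bins.n_bins, None, dtype=object)
        for row in self.intervals.itertuples():
            out[row.bin_lo:row.bin_hi] = row.type
        return out


def cluster_rt_ranks(rt: RTProfile, k: int = 15, random_state: int = 0) -> np.ndarray:
    """Cluster bins by RT value and rank clusters by mean RT (k = earliest).

    Returns per-bin ranks in 1..k (0 at masked/NaN bins).  Degenerate
    profiles (fewer distinct values than k) fall back to fewer clusters
    with a warning.
    """
    values = rt.rt_interval
    ok = np.isfinite(values)
    x = values[ok]
    n_distinct = np.unique(x).size
    if n_distinct == 0:
        raise ValueError("no finite RT values to cluster")
    k_eff = min(k, n_distinct)
    if k_eff < k:
        warnings.warn(
            f"only {n_distinct} distinct RT values; clustering with k={k_eff}",
            stacklevel=2,
        )
    if k_eff == 1:
        ranks = np.zeros(values.size, dtype=np.int64)
        ranks[ok] = 1
        return ranks
    gm = GaussianMixture(n_components=k_eff, covariance_type="spherical",
                         n_init=3, random_state=random_state, reg_covar=1e-10)
    labels = gm.fit_predict(x.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel(), kind="stable")
    rank_of_label = np.empty(k_eff, dtype=np.int64)
    rank_of_label[order] = np.arange(1, k_eff + 1)
    ranks = np.zeros(values.size, dtype=np.int64)
    ranks[ok] = rank_of_label[labels]
    return ranks


def _window_flags(ranks: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred-window local-max / local-min flags; edges (half window) unflagged."""
    n = ranks.size
    half = window // 2
    is_max = np.zeros(n, dtype=bool)
    is_min = np.zeros(n, dtype=bool)
    for i in range(half, n - half):
        w = ranks[i - half:i + half + 1]
        if ranks[i] == w.max():
            is_max[i] = True
        if ranks[i] == w.min():
            is_min[i] = True
    return is_max, is_min


def _resolve_flags(ranks, is_max, is_min):
    """Tie rule: a bin flagged both ways is neither, unless it extends an
    adjacent single-flagged run of the same rank."""
    both = is_max & is_min
    is_max = is_max & ~both
    is_min = is_min & ~both
    changed = True
    while changed:
        changed = False
        for flags in (is_max, is_min):
            for i in np.flatnonzero(both):
                left = i > 0 and flags[i - 1] and ranks[i - 1] == ranks[i]
                right = i < ranks.size - 1 and flags[i + 1] and ranks[i + 1] == ranks[i]
                if left or right:
                    flags[i] = True
                    both[i] = False
                    changed = True
    return is_max, is_min


def _assemble(ranks, is_max, is_min, max_bridge: int = 2):
    """Typed runs from flags, with TTR filling and alternation repair."""
    n = ranks.size
    types = np.full(n, None, dtype=object)
    types[is_max] = PEAK
    types[is_min] = TROUGH
    # bridge tiny gaps between same-type runs
    runs = _runs(types)
    for (t1, lo1, hi1), (t2, lo2, hi2) in zip(runs[:-1], runs[1:]):
        if t1 == t2 and t1 in (PEAK, TROUGH) and 0 < lo2 - hi1 <= max_bridge:
            types[hi1:lo2] = t1
    types[np.array([t is None for t in types])] = TTR
    # alternation repair: between consecutive same-extremum features insert the
    # opposite extremum at the run of extreme ranks in the gap
    extremes = [(t, lo, hi) for t, lo, hi in _runs(types) if t in (PEAK, TROUGH)]
    for (t1, lo1, hi1), (t2, lo2, hi2) in zip(extremes[:-1], extremes[1:]):
        if t1 != t2 or lo2 <= hi1:
            continue
        gap = ranks[hi1:lo2]
        if gap.size == 0:
            continue
        target = gap.min() if t1 == PEAK else gap.max()
        pos = np.flatnonzero(gap == target)
        a, b = pos[0], pos[0]
        while b + 1 < gap.size and gap[b + 1] == target and pos[0] <= b + 1 <= pos[-1]:
            b += 1
        other = TROUGH if t1 == PEAK else PEAK
        types[hi1 + a:hi1 + b + 1] = other
    return types


def _runs(types: np.ndarray) -> list[tuple[object, int, int]]:
    out = []
    lo = 0
    for i in range(1, types.size + 1):
        if i == types.size or types[i] != types[lo]:
            if types[lo] is not None:
                out.append((types[lo], lo, i))
            lo = i
    return out


def call_features(ranks: np.ndarray, bins: BinGrid, window: int = 21,
                  max_bridge: int = 2) -> "FeatureSet":
    """Call peaks/TTRs/troughs from per-bin cluster ranks.

    Per chromosome: flag each bin whose rank is the max (min) of the
    centred ``window``-bin window; features are not called within the half
    window of chromosome ends.  Runs of maxima/minima become peaks/troughs
    (runs broken by masked gaps wider than ``max_bridge`` bins); remaining
    bins become TTRs; alternation is enforced by inserting the opposite
    extremum in any gap between two same-type features.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd number >= 3")
    ranks = np.asarray(ranks)
    rows = []
    per_bin = np.full(bins.n_bins, None, dtype=object)
    for chrom, lo, hi in bins.chrom_blocks():
        ok = ranks[lo:hi] > 0
        idx = lo + np.flatnonzero(ok)
        r = ranks[idx]
        if r.size < window:
            log.warning("%s: %d usable bins < window %d, skipped", chrom, r.size, window)
            continue
        # break runs across masked gaps wider than max_bridge by splitting
        # the compacted series at those gaps
        gaps = np.diff(idx)
        split_at = np.flatnonzero(gaps > max_bridge + 1) + 1
        for part in np.split(np.arange(r.size), split_at):
            if part.size < window:
                continue
            rr = r[part]
            is_max, is_min = _window_flags(rr, window)
            if not is_max.any() and not is_min.any():
                continue
            is_max, is_min = _resolve_flags(rr, is_max, is_min)
            types = _assemble(rr, is_max, is_min, max_bridge=max_bridge)
            for t, a, b in _runs(types):
                gi = idx[part[a]:part[b - 1] + 1]
                per_bin[gi[0]:gi[-1] + 1] = t
                rows.append((chrom, int(bins.start[gi[0]]), int(bins.end[gi[-1]]),
                             t, int(gi[0]), int(gi[-1]) + 1))
    intervals = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "type", "bin_lo", "bin_hi"]
    )
    return FeatureSet(bins, intervals, ranks)


def feature_stats(fs: FeatureSet) -> pd.DataFrame:
    """Counts and size quartiles (bp) per feature type."""
    if fs.intervals.empty:
        raise ValueError("empty feature set")
    rows = []
    for t in _TYPES:
        sub = fs.intervals[fs.intervals["type"] == t]
        sizes = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        if sizes.size:
            q25, q50, q75 = np.percentile(sizes, [25, 50, 75])
            rows.append((t, sizes.size, sizes.mean(), q25, q50, q75))
        else:
            rows.append((t, 0, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["type", "n", "mean_bp", "q25_bp",
                                       "median_bp", "q75_bp"]).set_index("type")


def trend_test(per_stage_values: np.ndarray) -> tuple[float, float]:
    """OLS of a per-stage statistic on stage rank 1..n; (slope, two-sided p)."""
    y = np.asarray(per_stage_values, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 stages for a trend test")
    x = np.arange(1, y.size + 1, dtype=float)
    res = sps.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def feature_transitions(fs_a: FeatureSet, fs_b: FeatureSet) -> pd.DataFrame:
    """Row-normalized 3x3 matrix of per-bin feature-type changes a -> b."""
    if not fs_a.bins.same_coords(fs_b.bins):
        raise ValueError("feature sets must share a bin grid")
    ta, tb = fs_a.per_bin_type(), fs_b.per_bin_type()
    ok = np.array([x is not None and y is not None for x, y in zip(ta, tb)])
    mat = pd.DataFrame(0.0, index=list(_TYPES), columns=list(_TYPES))
    for x, y in zip(ta[ok], tb[ok]):
        mat.loc[x, y] += 1
    sums = mat.sum(axis=1)
    return mat.div(sums.replace(0, np.nan), axis=0)


def composite_peak_profile(rt: RTProfile, fs: FeatureSet,
                           flank_bp: int = 1_000_000) -> pd.DataFrame:
    """Median RT around peak centres, rebased so the window minimum is 0.

    RT values are stacked in windows of +/- ``flank_bp`` around the
    mid-point bin of each RT peak; the per-offset median is taken across
    peaks and the minimum of the resulting profile subtracted.
    """
    bin_size = int(np.median(fs.bins.end - fs.bins.start))
    flank_bins = flank_bp // bin_size
    peaks = fs.intervals[fs.intervals["type"] == PEAK]
    stacks = []
    for row in peaks.itertuples():
        centre = (row.bin_lo + row.bin_hi - 1) // 2
        lo, hi = centre - flank_bins, centre + flank_bins + 1
        sl = fs.bins.chrom_slice(row.chrom)
        if lo < sl.start or hi > sl.stop:
            continue
        stacks.append(rt.rt_interval[lo:hi])
    if not stacks:
        raise ValueError("no peak with full flanks")
    stacked = np.vstack(stacks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stacked, axis=0)
    med = med - np.nanmin(med)
    offsets = (np.arange(-flank_bins, flank_bins + 1)) * bin_size
    return pd.DataFrame({"offset_bp": offsets, "relative_rt": med,
                         "n_peaks": stacked.shape[0]})


def at_content(fs: FeatureSet, fasta) -> pd.DataFrame:
    """AT fraction per feature type; N bases excluded from the denominator.

    ``fasta`` is a pyfaidx.Fasta-like mapping of contig -> sliceable
    sequence.
    """
    per_type: dict[str, list[int]] = {t: [0, 0] for t in _TYPES}  # [AT, ACGT]
    for row in fs.intervals.itertuples():
        if row.chrom not in fasta:
            raise KeyError(f"contig {row.chrom!r} missing from FASTA")
        seq = str(fasta[row.chrom][row.start:row.end]).upper()
        at = seq.count("A") + seq.count("T")
        acgt = at + seq.count("C") + seq.count("G")
        per_type[row.type][0] += at
        per_type[row.type][1] += acgt
    rows = [
        (t, v[0] / v[1] if v[1] else np.nan) for t, v in per_type.items()
    ]
    return pd.DataFrame(rows, columns=["type", "at_fraction"]).set_index("type")
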