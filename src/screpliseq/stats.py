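"""Bootstrap inference, enrichment analyses and external-track utilities.

Statistical significance for single-cell RT statistics comes from
resampling cells (not bins) with replacement and recomputing the statistic
each iteration; 95% confidence intervals are the 2.5th-97.5th percentiles
of the bootstrap distribution.  Enrichment of interval annotations in RT
features uses a shift null: elements are circularly shifted within their
chromosome and the observed/shifted overlap ratio averaged over
iterations.  Contingency enrichments are observed/expected ratios with
expected = row_sum * col_sum / total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grid import BinaryReplicationMatrix, BinGrid, RTProfile
from .rt import IntervalGrid, rt_values

log = logging.getLogger(__name__)


def _percentile_ci(samples: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Percentile CI endpoints as order statistics (Davison-Hinkley).

    Uses ranks floor((B+1)*alpha/2) and ceil((B+1)*(1-alpha/2)) rather
    than interpolated percentiles; slightly conservative for discrete
    bootstrap distributions.  NaN replicates are ignored per column.
    """
    samples = np.asarray(samples, dtype=float)
    squeeze = samples.ndim == 1
    if squeeze:
        samples = samples[:, None]
    b = samples.shape[0]
    order = np.sort(samples, axis=0)  # NaN sorts last
    n_ok = np.sum(np.isfinite(samples), axis=0)
    lo = np.full(samples.shape[1], np.nan)
    hi = np.full(samples.shape[1], np.nan)
    for j in np.flatnonzero(n_ok > 0):
        nb = int(n_ok[j])
        kl = max(int(np.floor((nb + 1) * alpha / 2)) - 1, 0)
        kh = min(int(np.ceil((nb + 1) * (1 - alpha / 2))) - 1, nb - 1)
        lo[j] = order[kl, j]
        hi[j] = order[kh, j]
    if squeeze:
        return lo[0], hi[0]
    return lo, hi


@dataclass
class BootstrapResult:
    point: float | np.ndarray
    ci_low: float | np.ndarray
    ci_high: float | np.ndarray
    b: int
    seed: int
    samples: np.ndarray | None = None

    def excludes_zero(self) -> np.ndarray:
        return (np.asarray(self.ci_low) > 0) | (np.asarray(self.ci_high) < 0)


def disjoint(a: BootstrapResult, b: BootstrapResult) -> np.ndarray:
    """True where the two confidence intervals do not overlap."""
    return (np.asarray(a.ci_high) < np.asarray(b.ci_low)) | (
        np.asarray(b.ci_high) < np.asarray(a.ci_low)
    )


def bootstrap_statistic(
    states: BinaryReplicationMatrix,
    statistic,
    b: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_retries: int = 10,
    keep_samples: bool = False,
) -> BootstrapResult:
    """Percentile bootstrap over cells resampled with replacement.

    ``statistic`` maps a BinaryReplicationMatrix (a cell resample) to a
    scalar or vector.  A statistic failure on a resample triggers a fresh
    resample, up to ``max_retries`` per iteration.
    """
    if states.n_cells < 2:
        raise ValueError("need >= 2 cells to bootstrap")
    point = np.asarray(statistic(states), dtype=float)
    rng = np.random.default_rng(seed)
    samples = np.empty((b,) + point.shape)
    n = states.n_cells
    for i in range(b):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            try:
                samples[i] = statistic(states.subset_cells(idx))
                break
            except Exception:
                if attempt == max_retries:
                    raise
    lo, hi = _percentile_ci(samples.reshape(b, -1) if point.shape else samples,
                            alpha)
    if point.shape:
        lo = lo.reshape(point.shape)
        hi = hi.reshape(point.shape)
        return BootstrapResult(point, lo, hi, b, seed,
                               samples if keep_samples else None)
    return BootstrapResult(float(point), float(lo), float(hi), b, seed,
                           samples if keep_samples else None)


EARLIER, LATER, NO_CHANGE = "earlier", "later", "no-change"


def _bootstrap_interval_rt(states: BinaryReplicationMatrix, grid: IntervalGrid,
                           b: int, rng: np.random.Generator,
                           use_interval_rt: bool) -> np.ndarray:
    """B x bins matrix of interval-RT values over cell resamples.

    Resampling cells with replacement only reweights cells (interval
    membership is a per-cell property), so each replicate reduces to
    weighted replicated/observed sums with multinomial weights.
    """
    from .rt import replication_score

    observed = states.unmasked().astype(np.float64)
    ones = ((states.states == 1) & states.unmasked()).astype(np.float64)
    n = states.n_cells
    weights = rng.multinomial(n, np.full(n, 1.0 / n), size=b).astype(np.float64)
    if not use_interval_rt:
        num = weights @ ones
        den = weights @ observed
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)
    member = grid.membership(replication_score(states))  # intervals x cells
    total = np.zeros((b, states.bins.n_bins))
    count = np.zeros((b, states.bins.n_bins))
    for i in range(grid.n_intervals):
        w = weights * member[i]
        num = w @ ones
        den = w @ observed
        ok = den > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(ok, num / den, 0.0)
        total += frac
        count += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(count > 0, total / count, np.nan)


def delta_rt(
    states_a: BinaryReplicationMatrix,
    states_b: BinaryReplicationMatrix,
    grid: IntervalGrid | None = None,
    b: int = 1000,
    seed: int = 0,
    use_interval_rt: bool = True,
) -> pd.DataFrame:
    """Per-bin RT difference b - a with bootstrap significance classes.

    Each condition is resampled independently (cells with replacement,
    RT recomputed per replicate); a bin is classed ``earlier``
    (``later``) when the 95% percentile CI of the difference lies
    entirely above (below) zero, else ``no-change``.  Positive delta =
    earlier in condition b.
    """
    if not states_a.bins.same_coords(states_b.bins):
        raise ValueError("conditions must share a bin grid")
    grid = grid or IntervalGrid()

    def rt_stat(states):
        prof = rt_values(states, grid)
        return prof.rt_interval if use_interval_rt else prof.rt_raw

    point = rt_stat(states_b) - rt_stat(states_a)
    rng = np.random.default_rng(seed)
    deltas = (_bootstrap_interval_rt(states_b, grid, b, rng, use_interval_rt)
              - _bootstrap_interval_rt(states_a, grid, b, rng, use_interval_rt))
    lo, hi = _percentile_ci(deltas, 0.05)
    classes = np.full(point.size, NO_CHANGE, dtype=object)
    classes[lo > 0] = EARLIER
    classes[hi < 0] = LATER
    classes[~np.isfinite(point)] = NO_CHANGE
    return pd.DataFrame({
        "bin": states_a.bins.keys(), "delta_rt": point,
        "ci_low": lo, "ci_high": hi, "class": classes,
    })


def enrichment_ratio_table(class_a: np.ndarray, class_b: np.ndarray) -> pd.DataFrame:
    """Observed/expected contingency ratios between two per-bin labelings.

    Expected counts are row_sum * col_sum / total; the ratio is NaN where
    the expected count is zero.  Bins labelled None/NaN in either input
    are dropped.
    """
    a = pd.Series(class_a)
    bl = pd.Series(class_b)
    ok = a.notna() & bl.notna()
    if ok.sum() == 0:
        raise ValueError("no bins labelled by both classifications")
    observed = pd.crosstab(a[ok], bl[ok])
    total = observed.to_numpy().sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed.to_numpy() / expected
    return pd.DataFrame(ratio, index=observed.index, columns=observed.columns)


def _overlap_counts(starts, ends, feat_starts, feat_ends) -> int:
    """Number of query intervals overlapping any (sorted, merged) feature."""
    if feat_starts.size == 0:
        return 0
    j = np.searchsorted(feat_starts, ends, side="left")
    prev = np.maximum(j - 1, 0)
    hit = (j > 0) & (feat_ends[prev] > starts)
    return int(hit.sum())


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts)
    s, e = starts[order], ends[order]
    ms, me = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= me[-1]:
            me[-1] = max(me[-1], b)
        else:
            ms.append(a)
            me.append(b)
    return np.array(ms), np.array(me)


def te_shift_enrichment(
    elements: pd.DataFrame,
    feature_set,
    chrom_sizes: dict[str, int],
    n_iter: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Shift-null log2 enrichment of annotated elements in RT features.

    ``elements`` has columns chrom, start, end, family.  Per iteration,
    every element is independently circularly shifted within its
    chromosome by a uniform offset; the enrichment for a (family, feature
    type) pair is the mean over iterations of
    log2((observed + pc) / (shifted + pc)).
    """
    for col in ("chrom", "start", "end", "family"):
        if col not in elements.columns:
            raise ValueError(f"elements must have a {col!r} column")
    feats: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for t in feature_set.intervals["type"].unique():
        sub = feature_set.intervals[feature_set.intervals["type"] == t]
        feats[t] = {}
        for chrom, grp in sub.groupby("chrom"):
            feats[t][chrom] = _merge(grp["start"].to_numpy(), grp["end"].to_numpy())
    rng = np.random.default_rng(seed)
    rows = []
    for family, fam in elements.groupby("family"):
        if fam.empty:
            log.warning("family %r has no elements, skipped", family)
            continue
        by_chrom = {
            chrom: (grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64))
            for chrom, grp in fam.groupby("chrom")
        }
        for chrom, (s, e) in by_chrom.items():
            size = chrom_sizes.get(chrom)
            if size is None:
                raise KeyError(f"chromosome {chrom!r} missing from chrom_sizes")
            if np.any(e > size) or np.any(s < 0):
                raise ValueError(f"element outside {chrom} bounds")
        observed = {}
        for t, per_chrom in feats.items():
            obs = 0
            for chrom, (s, e) in by_chrom.items():
                fs_, fe_ = per_chrom.get(chrom, (np.array([]), np.array([])))
                obs += _overlap_counts(s, e, fs_, fe_)
            observed[t] = obs
        log_ratios = {t: np.empty(n_iter) for t in feats}
        for it in range(n_iter):
            shifted_counts = dict.fromkeys(feats, 0)
            for chrom, (s, e) in by_chrom.items():
                size = chrom_sizes[chrom]
                offs = rng.integers(0, size, size=s.size)
                ns = (s + offs) % size
                ne = ns + (e - s)
                # wrap: an element running past the end is split in two
                for t, per_chrom in feats.items():
                    fs_, fe_ = per_chrom.get(chrom, (np.array([]), np.array([])))
                    over = ne > size
                    hit = np.zeros(s.size, dtype=bool)
                    if fs_.size:
                        j = np.searchsorted(fs_, np.minimum(ne, size), side="left")
                        prev = np.maximum(j - 1, 0)
                        hit |= (j > 0) & (fe_[prev] > ns)
                        if over.any():
                            j2 = np.searchsorted(fs_, ne[over] - size, side="left")
                            prev2 = np.maximum(j2 - 1, 0)
                            hit_over = (j2 > 0) & (fe_[prev2] > 0)
                            tmp = hit[over]
                            hit[over] = tmp | hit_over
                    shifted_counts[t] += int(hit.sum())
            for t in feats:
                log_ratios[t][it] = np.log2(
                    (observed[t] + pseudocount) / (shifted_counts[t] + pseudocount)
                )
        for t in feats:
            rows.append((family, t, observed[t], float(np.mean(log_ratios[t]))))
    return pd.DataFrame(rows, columns=["family", "type", "observed",
                                       "log2_enrichment"])


def bin_external_track(fragments: pd.DataFrame, bins: BinGrid) -> np.ndarray:
    """log2(CPM + 1) of fragment counts per bin, fragments assigned by midpoint.

    ``fragments`` has columns chrom, start, end.  Counts are normalized by
    the total fragment count, scaled to counts per million, and log2
    transformed after adding a pseudocount of 1.
    """
    total = len(fragments)
    if total == 0:
        raise ValueError("no fragments")
    counts = np.zeros(bins.n_bins)
    mids = ((fragments["start"] + fragments["end"]) // 2).to_numpy(np.int64)
    chroms = fragments["chrom"].to_numpy()
    for chrom, lo, hi in bins.chrom_blocks():
        sel = chroms == chrom
        if not sel.any():
            continue
        edges = np.append(bins.start[lo:hi], bins.end[hi - 1])
        idx = np.searchsorted(edges, mids[sel], side="right") - 1
        ok = (idx >= 0) & (idx < hi - lo)
        np.add.at(counts, lo + idx[ok], 1)
    return np.log2(counts / total * 1e6 + 1.0)


def boundary_composite(rt: RTProfile, domains: pd.DataFrame,
                       flank_bp: int = 1_000_000) -> pd.DataFrame:
    """Median and IQR of RT around domain boundaries, domain side to the right.

    ``domains`` has columns chrom, start, end (e.g. LADs).  Both edges of
    every domain contribute, each oriented so positive offsets run into
    the domain; boundaries without full flanks are skipped.
    """
    bin_size = int(np.median(rt.bins.end - rt.bins.start))
    flank = flank_bp // bin_size
    stacks = []
    for row in domains.itertuples():
        try:
            sl = rt.bins.chrom_slice(row.chrom)
        except KeyError:
            continue
        for edge, into_domain_right in ((row.start, True), (row.end, False)):
            centre = sl.start + int(np.searchsorted(rt.bins.start[sl], edge,
                                                    side="right")) - 1
            lo, hi = centre - flank, centre + flank + 1
            if lo < sl.start or hi > sl.stop:
                continue
            window = rt.rt_interval[lo:hi]
            stacks.append(window if into_domain_right else window[::-1])
    if not stacks:
        raise ValueError("no boundary with full flanks")
    stacked = np.vstack(stacks)
    med = np.nanmedian(stacked, axis=0)
    q25 = np.nanpercentile(stacked, 25, axis=0)
    q75 = np.nanpercentile(stacked, 75, axis=0)
    offsets = np.arange(-flank, flank + 1) * bin_size
    return pd.DataFrame({"offset_bp": offsets, "median_rt": med,
                         "q25": q25, "q75": q75, "n_boundaries": stacked.shape[0]})


def compartment_compare(rt: RTProfile, scores: np.ndarray) -> dict:
    """RT split by A/B compartment sign plus Spearman correlation with score.

    Positive scores are the A compartment.  Returns the two RT
    distributions and the tie-corrected Spearman rho (NaN when only one
    class is present or inputs are degenerate).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (rt.bins.n_bins,):
        raise ValueError("one compartment score per bin required")
    ok = np.isfinite(scores) & np.isfinite(rt.rt_interval)
    a = rt.rt_interval[ok & (scores > 0)]
    b_ = rt.rt_interval[ok & (scores < 0)]
    if ok.sum() >= 2 and np.unique(scores[ok]).size > 1:
        rho, p = sps.spearmanr(rt.rt_interval[ok], scores[ok])
    else:
        rho, p = np.nan, np.nan
    return {"rt_A": a, "rt_B": b_, "spearman_rho": float(rho) if np.isfinite(rho) else np.nan,
            "p_value": float(p) if np.isfinite(p) else np.nan}
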