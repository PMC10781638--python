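"""Binarization of per-cell coverage profiles into replication states.

Per cell the pipeline is: RPM + stage-mean normalization -> outlier-bin
masking -> first-pass segmentation -> low-mappability segment filter ->
centring/IQR scaling and width-15 median smoothing -> second segmentation
-> two-component Gaussian mixture on the segmented values -> threshold at
the density intersection -> state 1 (replicated) where the fitted segment
value exceeds the threshold.  No G1/G2 control normalization is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .grid import MASKED, BinaryReplicationMatrix, BinGrid, CellCountMatrix
from .qc import QCReport, normalize_counts
from .segment import mappability_filter, segment_profile

log = logging.getLogger(__name__)


class CellUnusableError(ValueError):
    """A cell whose profile cannot be binarized (degenerate spread or fit)."""


def scale_smooth(values: np.ndarray, bins: BinGrid, filter_width: int = 15) -> np.ndarray:
    """Centre by the mean, scale by the IQR, median-filter per chromosome.

    Masked (NaN) bins are skipped: the filter runs on the compacted
    unmasked series of each chromosome, so masked gaps do not leak values.
    At chromosome edges the window shrinks symmetrically (radius
    ``min(i, n-1-i, width//2)``) rather than padding.

    Raises
    ------
    CellUnusableError
        If the cell's IQR is zero (constant profile carries no signal).
    """
    if filter_width < 1 or filter_width % 2 == 0:
        raise ValueError("filter_width must be a positive odd number")
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < filter_width:
        raise CellUnusableError(
            f"only {int(finite.sum())} unmasked bins, need >= {filter_width}"
        )
    x = values[finite]
    iqr = stats.iqr(x)
    if iqr == 0:
        raise CellUnusableError("zero IQR: constant coverage profile")
    scaled = np.where(finite, (values - x.mean()) / iqr, np.nan)
    out = np.full(values.shape, np.nan)
    half = filter_width // 2
    for _, lo, hi in bins.chrom_blocks():
        idx = lo + np.flatnonzero(finite[lo:hi])
        series = scaled[idx]
        n = series.size
        sm = np.empty(n)
        for i in range(n):
            r = min(i, n - 1 - i, half)
            sm[i] = np.median(series[i - r:i + r + 1])
        out[idx] = sm
    return out


@dataclass
class MixtureFit:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    threshold: float
    used_midpoint: bool

    @property
    def separation(self) -> float:
        """Ashman's D: component separation in pooled-sigma units.

        D = |m2 - m1| / sqrt((s1^2 + s2^2) / 2).  Values above ~2 indicate
        a genuinely bimodal fit; a profile with a single copy-number
        population (a cell at the very start or end of S phase) yields a
        low D because the two components then split one continuum.
        """
        return float(abs(self.means[1] - self.means[0])
                     / np.sqrt((self.sds[0] ** 2 + self.sds[1] ** 2) / 2.0))


def _weighted_density_diff(x, fit: "MixtureFit") -> float:
    lo = fit.weights[0] * stats.norm.pdf(x, fit.means[0], fit.sds[0])
    hi = fit.weights[1] * stats.norm.pdf(x, fit.means[1], fit.sds[1])
    return lo - hi


def mixture_threshold(values: np.ndarray, n_restarts: int = 5,
                      random_state: int = 0,
                      sd_floor_fraction: float = 0.15) -> MixtureFit:
    """Two-component Gaussian mixture cut separating the two copy states.

    The mixture is fitted by EM initialised at the 25th/75th percentiles
    (plus random restarts, best log-likelihood wins).  Component variances
    are floored at ``(sd_floor_fraction * sd(values))^2`` to keep EM from
    collapsing a component onto a narrow spike of segment levels, which
    would place the cut inside one copy population.  The threshold is the
    root of w1*N(x; m1, s1) = w2*N(x; m2, s2) strictly between the means;
    when the weighted densities do not cross there, the mid-point of the
    means is used instead.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise CellUnusableError(f"need >= 20 values for the mixture fit, got {x.size}")
    if np.allclose(x, x[0]):
        raise CellUnusableError("degenerate (constant) segmented values")
    X = x.reshape(-1, 1)
    q25, q75 = np.percentile(x, [25, 75])
    best = None
    inits = [np.array([[q25], [q75]])]
    rng = np.random.default_rng(random_state)
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.choice(x, size=2, replace=False).reshape(-1, 1))
    reg = max((sd_floor_fraction * x.std()) ** 2, 1e-6)
    import warnings

    for means_init in inits:
        gm = GaussianMixture(
            n_components=2, covariance_type="spherical", means_init=means_init,
            reg_covar=reg, tol=1e-8, max_iter=500, random_state=0,
        )
        try:
            with warnings.catch_warnings():
                # non-convergence is handled explicitly via converged_
                warnings.simplefilter("ignore")
                gm.fit(X)
        except ValueError:
            continue
        if best is None or gm.lower_bound_ > best.lower_bound_:
            best = gm
    if best is None or not best.converged_:
        raise CellUnusableError("mixture EM failed to converge")
    order = np.argsort(best.means_.ravel())
    means = best.means_.ravel()[order]
    sds = np.sqrt(best.covariances_.ravel()[order])
    weights = best.weights_.ravel()[order]
    fit = MixtureFit(means, sds, weights, np.nan, False)
    m1, m2 = means
    if m2 - m1 > 1e-12:
        f1 = _weighted_density_diff(m1 + 1e-9 * (m2 - m1), fit)
        f2 = _weighted_density_diff(m2 - 1e-9 * (m2 - m1), fit)
        if np.sign(f1) != np.sign(f2) and f1 != 0 and f2 != 0:
            fit.threshold = float(
                brentq(_weighted_density_diff, m1, m2, args=(fit,), xtol=1e-12)
            )
            return fit
    fit.threshold = float((m1 + m2) / 2.0)
    fit.used_midpoint = True
    return fit


def binarize_cell(normalized: np.ndarray, bins: BinGrid,
                  first_penalty: float, second_penalty: float,
                  filter_width: int = 15,
                  retain_fraction: float = 0.95) -> tuple[np.ndarray, MixtureFit]:
    """Binarize one cell's normalized profile; returns (states, mixture fit).

    ``states`` is int8 per bin with MASKED at bins unusable for this cell.
    """
    seg1 = segment_profile(normalized, bins, penalty=first_penalty)
    low_map = mappability_filter(seg1, retain_fraction=retain_fraction)
    work = np.where(low_map, np.nan, normalized)
    smoothed = scale_smooth(work, bins, filter_width=filter_width)
    seg2 = segment_profile(smoothed, bins, penalty=second_penalty)
    fit = mixture_threshold(seg2.fitted)
    states = np.full(bins.n_bins, MASKED, dtype=np.int8)
    ok = np.isfinite(seg2.fitted)
    states[ok] = (seg2.fitted[ok] > fit.threshold).astype(np.int8)
    return states, fit


def copy_ratio_check(rpm: np.ndarray, states: np.ndarray,
                     bounds: tuple[float, float] = (1.7, 2.4),
                     min_bins_per_class: int = 10) -> float:
    """Coverage ratio between called-replicated and called-unreplicated bins.

    A correctly thresholded cell shows the copy-number contrast directly
    in its raw coverage: bins called replicated carry about twice the
    reads-per-million of bins called unreplicated.  A threshold placed
    inside a single copy population (as happens when a cell at the very
    start or end of S phase gives the mixture only one population to
    split) yields a ratio well below 2.  Returns the ratio; raises
    :class:`CellUnusableError` when it falls outside ``bounds`` or either
    class has fewer than ``min_bins_per_class`` bins.
    """
    ones = states == 1
    zeros = states == 0
    if ones.sum() < min_bins_per_class or zeros.sum() < min_bins_per_class:
        raise CellUnusableError(
            f"degenerate call set ({int(ones.sum())} replicated / "
            f"{int(zeros.sum())} unreplicated bins)"
        )
    ratio = float(rpm[ones].mean() / rpm[zeros].mean())
    if not (bounds[0] <= ratio <= bounds[1]):
        raise CellUnusableError(
            f"replicated/unreplicated coverage ratio {ratio:.2f} outside "
            f"[{bounds[0]}, {bounds[1]}]: threshold did not separate copy states"
        )
    return ratio


def binarize_matrix(
    counts: CellCountMatrix,
    qc: QCReport | None = None,
    first_penalty: float = 1.0,
    second_penalty: float = 4.0,
    filter_width: int = 15,
    retain_fraction: float = 0.95,
    low_percentile: float = 5.0,
    high_percentile: float = 1.0,
    copy_ratio_bounds: tuple[float, float] | None = (1.7, 2.4),
) -> BinaryReplicationMatrix:
    """Run the full binarization over all QC-passing cells.

    QC-failing cells are dropped; chromosomes masked by the QC rescue are
    masked in that cell's states.  Cells whose profile cannot be binarized
    are dropped with a logged reason: zero IQR, mixture failure, or a
    failed copy-ratio check — called-replicated bins must carry roughly
    twice the coverage of called-unreplicated bins (``copy_ratio_bounds``;
    None disables the check).  The first-pass penalty applies on the
    normalized-ratio scale (around 1), the second on the IQR-standardized
    smoothed scale.
    """
    if qc is not None:
        keep = [i for i, c in enumerate(counts.cell_ids) if c in set(qc.passing_cells())]
        if not keep:
            raise ValueError("no QC-passing cells to binarize")
        counts = counts.subset_cells(np.array(keep))
    normalized, _ = normalize_counts(
        counts, low_percentile=low_percentile, high_percentile=high_percentile
    )
    if qc is not None:
        for i, cell in enumerate(counts.cell_ids):
            masked_chrom = qc.masked_chrom(cell)
            if isinstance(masked_chrom, str):
                normalized[i, counts.bins.chrom_slice(masked_chrom)] = np.nan
    rpm = counts.counts / counts.counts.sum(axis=1, keepdims=True) * 1e6
    states_rows, thresholds, kept = [], [], []
    for i, cell in enumerate(counts.cell_ids):
        try:
            states, fit = binarize_cell(
                normalized[i], counts.bins, first_penalty, second_penalty,
                filter_width=filter_width, retain_fraction=retain_fraction,
            )
            if copy_ratio_bounds is not None:
                copy_ratio_check(rpm[i], states, bounds=copy_ratio_bounds)
        except CellUnusableError as exc:
            log.warning("dropping cell %s: %s", cell, exc)
            continue
        states_rows.append(states)
        thresholds.append(fit.threshold)
        kept.append(i)
    if not kept:
        raise ValueError("no cells survived binarization")
    ids = [counts.cell_ids[i] for i in kept]
    return BinaryReplicationMatrix(
        counts.bins, np.vstack(states_rows), ids,
        counts.cell_meta.iloc[kept], np.array(thresholds),
    )
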