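"""Synthetic single-cell Repli-seq data with known ground truth.

The generator emulates a population of cells sampled across S phase.  Each
bin carries a ground-truth replication-timing value ``true_rt`` in [0, 1]
(1 = earliest) organised into alternating early plateaus (RT peaks),
monotone ramps (timing transition regions, TTRs) and late plateaus (RT
troughs).  A cell at S-phase fraction ``s`` replicates a bin with
probability

    P(replicated) = 1 / (1 + exp(-g * (100 * s - M)))

where ``M`` is the bin's mid-point on the replication-score scale (the
score at which half the cells have replicated it; higher = later) and
``g`` the sigmoid slope.  ``M`` is anti-monotone in ``true_rt``.  Read
counts are Poisson with mean proportional to copy number (1 non-replicated,
2 replicated), per-bin mappability and sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AllelicCounts, BinGrid, CellCountMatrix

PEAK, TTR, TROUGH = "peak", "TTR", "trough"


@dataclass
class SyntheticTruth:
    """Ground-truth RT programme over a bin grid."""

    bins: BinGrid
    true_rt: np.ndarray        # [0, 1], 1 = earliest
    true_m: np.ndarray         # replication-score mid-point, [0, 100]
    true_g: np.ndarray         # sigmoid slope > 0
    feature_labels: np.ndarray  # per-bin {peak, TTR, trough}

    def __post_init__(self) -> None:
        self.true_rt = np.asarray(self.true_rt, dtype=float)
        self.true_m = np.asarray(self.true_m, dtype=float)
        self.true_g = np.asarray(self.true_g, dtype=float)
        self.feature_labels = np.asarray(self.feature_labels, dtype=object)
        n = self.bins.n_bins
        for name in ("true_rt", "true_m", "true_g", "feature_labels"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one value per bin")
        if np.any((self.true_rt < 0) | (self.true_rt > 1)):
            raise ValueError("true_rt must lie in [0, 1]")
        if np.any(self.true_g <= 0):
            raise ValueError("true_g must be positive")


@dataclass
class SimulatedCell:
    cell_id: str
    s_fraction: float          # true fraction of genome replicated
    states: np.ndarray = field(repr=False)  # per-bin {0, 1}


def _spawn(seed: int, *key: int) -> np.random.Generator:
    """Deterministic independent stream derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _domain_profile(n_bins: int, domain_length: int, ramp_length: int,
                    lo: float, hi: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Alternating plateau/ramp RT profile and its feature labels.

    The chromosome is tiled with cycles peak-plateau -> down-ramp ->
    trough-plateau -> up-ramp; plateaus are ``domain_length`` bins and
    ramps ``ramp_length`` bins (the last element is truncated).  Plateau
    heights are jittered a little so clustering sees distinct values.
    """
    rt = np.empty(n_bins)
    labels = np.empty(n_bins, dtype=object)
    if hi == lo:
        rt[:] = lo
        labels[:] = PEAK  # degenerate flat programme: one feature type
        return rt, labels
    span_rt = hi - lo
    # Each plateau sits at its own level: peaks spread over the upper half,
    # troughs over the lower half of the RT range, so domains fire at
    # staggered times across S phase as in real RT landscapes rather than
    # all at once.
    def peak_level():
        return rng.uniform(lo + 0.5 * span_rt, hi)

    def trough_level():
        return rng.uniform(lo, lo + 0.5 * span_rt)

    pos = 0
    phase = 0  # 0 peak plateau, 1 down ramp, 2 trough plateau, 3 up ramp
    level = peak_level()
    nxt = trough_level()
    while pos < n_bins:
        span = domain_length if phase % 2 == 0 else ramp_length
        ln = min(span, n_bins - pos)
        t = np.arange(ln) / max(span - 1, 1)
        if phase in (0, 2):
            seg = np.full(ln, level) + rng.normal(0, 0.005 * span_rt, ln)
            lab = PEAK if phase == 0 else TROUGH
        else:
            seg = level + (nxt - level) * t
            lab = TTR
        rt[pos:pos + ln] = seg
        labels[pos:pos + ln] = lab
        pos += ln
        phase = (phase + 1) % 4
        if phase in (0, 2):  # entering a plateau: adopt the ramp's target
            level = nxt
        else:  # entering a ramp: choose the next plateau's level
            nxt = trough_level() if phase == 1 else peak_level()
    return np.clip(rt, 0.0, 1.0), labels


def generate_truth(
    n_bins_per_chrom: dict[str, int],
    domain_length_bins: int = 50,
    ramp_length_bins: int | None = None,
    rt_range: tuple[float, float] = (0.1, 0.9),
    g_value: float | np.ndarray = 1.0,
    bin_size: int = 50_000,
    seed: int = 0,
) -> SyntheticTruth:
    """Build a ground-truth RT programme of alternating replication domains.

    Parameters
    ----------
    n_bins_per_chrom
        Mapping chromosome name -> bin count; each chromosome must hold at
        least three domain lengths so a full peak/TTR/trough cycle fits.
    domain_length_bins
        Length of each plateau (peak or trough), in bins.
    ramp_length_bins
        Length of each TTR ramp; defaults to a third of the plateau
        length, reflecting that timing transition regions are narrower
        than the constant-timing domains they join.
    rt_range
        (lowest, highest) true RT; equal values give a flat programme.
    g_value
        Sigmoid slope, scalar or per-bin array (per-bin heterogeneity).
    """
    if domain_length_bins <= 0:
        raise ValueError("domain_length_bins must be positive")
    if ramp_length_bins is None:
        ramp_length_bins = max(domain_length_bins // 3, 1)
    if ramp_length_bins <= 0:
        raise ValueError("ramp_length_bins must be positive")
    lo, hi = float(rt_range[0]), float(rt_range[1])
    if not (0 <= lo <= 1 and 0 <= hi <= 1):
        raise ValueError("rt_range must lie in [0, 1]")
    if hi < lo:
        raise ValueError("rt_range must be (low, high)")
    for chrom, n in n_bins_per_chrom.items():
        if n <= 0:
            raise ValueError(f"non-positive bin count for {chrom}")
        if n < 3 * domain_length_bins:
            raise ValueError(
                f"{chrom}: need >= 3 x domain_length_bins = "
                f"{3 * domain_length_bins} bins, got {n}"
            )
    rng = _spawn(seed, 0)
    sizes = {c: n * bin_size for c, n in n_bins_per_chrom.items()}
    grid = BinGrid.from_chrom_sizes(sizes, bin_size)
    rt_parts, label_parts = [], []
    for chrom, n in n_bins_per_chrom.items():
        rt, labels = _domain_profile(n, domain_length_bins, ramp_length_bins,
                                     lo, hi, rng)
        rt_parts.append(rt)
        label_parts.append(labels)
    true_rt = np.concatenate(rt_parts)
    labels = np.concatenate(label_parts)
    # Mid-point anti-monotone in RT: earliest bins have the lowest M.
    true_m = 100.0 * (1.0 - true_rt)
    true_g = np.broadcast_to(np.asarray(g_value, dtype=float), true_rt.shape).copy()
    return SyntheticTruth(grid, true_rt, true_m, true_g, labels)


def sigmoid_probability(s_fraction: float | np.ndarray, m: np.ndarray,
                        g: np.ndarray) -> np.ndarray:
    """P(bin replicated | cell at S-phase fraction s) under the sigmoid model."""
    z = np.asarray(g, dtype=float) * (100.0 * np.asarray(s_fraction, dtype=float) - m)
    # clip keeps exp() finite in the deterministic-firing limit g -> inf
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def simulate_cell_states(truth: SyntheticTruth, n_cells: int,
                         seed: int = 0,
                         s_range: tuple[float, float] = (0.02, 0.98)) -> list[SimulatedCell]:
    """Draw cells uniformly across S phase and fire bins independently.

    S-phase fractions are uniform on ``s_range`` (default (0.02, 0.98),
    leaving out the extremes that the downstream 10-90% replication-score
    filter discards).  Given a cell's s-fraction, bins are independent
    Bernoulli draws with the per-bin sigmoid probability.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    s_rng = _spawn(seed, 1)
    s_fracs = s_rng.uniform(*s_range, size=n_cells)
    cells = []
    for i, s in enumerate(s_fracs):
        p = sigmoid_probability(s, truth.true_m, truth.true_g)
        states = (_spawn(seed, 2, i).random(truth.bins.n_bins) < p).astype(np.int8)
        cells.append(SimulatedCell(f"cell{i:03d}", float(s), states))
    return cells


def simulate_read_counts(
    cells: list[SimulatedCell],
    bins: BinGrid,
    depth_per_bin: float = 50.0,
    mappability: np.ndarray | float = 1.0,
    overdispersion: float = 0.0,
    stage: str = "synthetic",
    seed: int = 0,
) -> CellCountMatrix:
    """Poisson read counts proportional to copy number (1 vs 2).

    Expected count per bin is ``depth_per_bin * mappability * (1 + state)``
    so replicated bins carry twice the coverage.  ``overdispersion`` > 0
    switches to a gamma-mixed Poisson (negative binomial) with that excess
    dispersion; the default 0 is plain Poisson.
    """
    if depth_per_bin <= 0:
        raise ValueError("depth_per_bin must be positive")
    mapp = np.broadcast_to(np.asarray(mappability, dtype=float), (bins.n_bins,))
    if np.any(mapp <= 0) or np.any(mapp > 2):
        raise ValueError("mappability must lie in (0, 2]")
    counts = np.empty((len(cells), bins.n_bins), dtype=np.int64)
    for i, cell in enumerate(cells):
        rng = _spawn(seed, 3, i)
        mu = depth_per_bin * mapp * (1.0 + cell.states)
        if overdispersion > 0:
            mu = rng.gamma(1.0 / overdispersion, overdispersion * mu)
        counts[i] = rng.poisson(mu)
    import pandas as pd

    meta = pd.DataFrame(
        {"stage": stage, "s_fraction": [c.s_fraction for c in cells]},
        index=[c.cell_id for c in cells],
    )
    return CellCountMatrix(bins, counts, [c.cell_id for c in cells], meta)


def simulate_allelic_counts(
    truth_mat: SyntheticTruth,
    truth_pat: SyntheticTruth,
    n_cells: int,
    depth_per_bin: float = 50.0,
    assignable_fraction: float = 0.2,
    stage: str = "synthetic",
    seed: int = 0,
) -> AllelicCounts:
    """Simulate maternal/paternal counts for the same cells.

    Each allele replicates independently under its own truth; each is
    sequenced at half the total depth, then binomially thinned by
    ``assignable_fraction`` — the surrogate for the fraction of reads
    overlapping a strain-distinguishing SNP.
    """
    if not truth_mat.bins.same_coords(truth_pat.bins):
        raise ValueError("maternal and paternal truths must share a bin grid")
    if not (0 < assignable_fraction <= 1):
        raise ValueError("assignable_fraction must be in (0, 1]")
    s_rng = _spawn(seed, 4)
    s_fracs = s_rng.uniform(0.02, 0.98, size=n_cells)
    n_bins = truth_mat.bins.n_bins
    mat = np.empty((n_cells, n_bins), dtype=np.int64)
    pat = np.empty((n_cells, n_bins), dtype=np.int64)
    for i, s in enumerate(s_fracs):
        rng = _spawn(seed, 5, i)
        for out, truth in ((mat, truth_mat), (pat, truth_pat)):
            p = sigmoid_probability(s, truth.true_m, truth.true_g)
            states = rng.random(n_bins) < p
            lam = 0.5 * depth_per_bin * (1.0 + states) * assignable_fraction
            out[i] = rng.poisson(lam)
    import pandas as pd

    ids = [f"cell{i:03d}" for i in range(n_cells)]
    meta = pd.DataFrame({"stage": stage, "s_fraction": s_fracs}, index=ids)
    return AllelicCounts(truth_mat.bins, mat, pat, ids, meta)


def inject_aneuploidy(counts: CellCountMatrix, cell_id: str, chrom: str,
                      factor: float) -> CellCountMatrix:
    """Scale one cell's counts on one chromosome (0 = lost, 1.5 = trisomy-like)."""
    if factor < 0:
        raise ValueError("factor must be >= 0")
    out = counts.copy()
    ci = out.cell_index(cell_id)
    sl = out.bins.chrom_slice(chrom)
    out.counts = out.counts.astype(float)
    out.counts[ci, sl] = out.counts[ci, sl] * factor
    out.counts = np.rint(out.counts).astype(np.int64)
    return out
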