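"""Per-cell quality control and count normalization.

QC filters cells on (1) total read count and (2) a coefficient of variation
(CV = sd / mean) over per-chromosome mean bin counts, which flags
aneuploidy and chromosome-scale dropouts.  A cell failing the CV cut is
rescued when excluding exactly one chromosome brings the CV under the
threshold; that chromosome is then masked for the cell downstream.

Normalization converts counts to reads per million (RPM) and divides each
bin by the mean RPM of all cells of the same developmental stage, removing
mappability bias shared within a stage.  Bins whose stage-mean RPM falls in
the lowest 5% or highest 1% are masked for every cell of that stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CellCountMatrix

log = logging.getLogger(__name__)

DEFAULT_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 20))  # mouse chr1-19

PASS = "pass"
PASS_MASKED = "pass_with_masked_chrom"
FAIL_READS = "fail_reads"
FAIL_CV = "fail_cv"


@dataclass
class QCReport:
    """Per-cell QC outcome table plus the CV detail behind it."""

    table: pd.DataFrame  # index cell_id; total_reads, cv_all, status, masked_chrom
    cv_loo: dict[str, dict[str, float]] = field(default_factory=dict)

    def passing_cells(self) -> list[str]:
        ok = self.table["status"].isin([PASS, PASS_MASKED])
        return list(self.table.index[ok])

    def masked_chrom(self, cell_id: str):
        return self.table.loc[cell_id, "masked_chrom"]


def _cv(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return float("inf")
    return float(values.std(ddof=0) / mean)


def qc_cells(
    counts: CellCountMatrix,
    min_reads: int = 750_000,
    cv_threshold: float = 0.1,
    autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES,
) -> QCReport:
    """Classify each cell as pass / pass-with-masked-chromosome / fail.

    CV is computed over the per-chromosome means of bin counts on the
    requested autosomes (present in the grid).  Leave-one-chromosome-out
    rescue applies only when the all-chromosome CV exceeds the threshold;
    a cell is rescued iff at least one single exclusion brings the CV
    under the threshold, and the best such chromosome is masked.
    """
    if counts.n_cells == 0:
        raise ValueError("empty count matrix")
    grid_chroms = set(counts.bins.chromosomes())
    use = [c for c in autosomes if c in grid_chroms]
    if not use:
        raise ValueError(
            f"none of the requested autosomes {autosomes[:3]}... are in the bin grid"
        )
    missing = [c for c in autosomes if c not in grid_chroms]
    if missing:
        log.warning("autosomes absent from grid ignored for CV: %s", missing)

    chrom_means = np.column_stack(
        [counts.counts[:, counts.bins.chrom_slice(c)].mean(axis=1) for c in use]
    )  # cells x chroms
    rows = []
    cv_loo_all: dict[str, dict[str, float]] = {}
    for i, cell in enumerate(counts.cell_ids):
        total = int(counts.counts[i].sum())
        cv_all = _cv(chrom_means[i])
        status, masked = PASS, None
        if total < min_reads:
            status = FAIL_READS
        elif cv_all > cv_threshold:
            loo = {}
            for j, c in enumerate(use):
                loo[c] = _cv(np.delete(chrom_means[i], j))
            cv_loo_all[cell] = loo
            ok = {c: v for c, v in loo.items() if v <= cv_threshold}
            if ok:
                masked = min(ok, key=ok.get)
                status = PASS_MASKED
            else:
                status = FAIL_CV
        rows.append((cell, total, cv_all, status, masked))
    table = pd.DataFrame(
        rows, columns=["cell_id", "total_reads", "cv_all", "status", "masked_chrom"]
    ).set_index("cell_id")
    n_pass = (table["status"].isin([PASS, PASS_MASKED])).sum()
    log.info("qc: %d/%d cells pass (min_reads=%d, cv<=%.3g)",
             n_pass, counts.n_cells, min_reads, cv_threshold)
    return QCReport(table, cv_loo_all)


def normalize_counts(
    counts: CellCountMatrix,
    low_percentile: float = 5.0,
    high_percentile: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """RPM-normalize then divide by the same-stage per-bin mean RPM.

    Returns ``(normalized, bin_mask)`` where ``normalized`` is cells x bins
    (NaN at masked bins for the cell's stage) and ``bin_mask`` is cells x
    bins True where the bin is masked for that cell.  Per stage, bins whose
    mean RPM lies in the lowest ``low_percentile``% or highest
    ``high_percentile``% are masked, plus any bin already masked on the
    grid.  Percentile cuts use nearest-rank counts with boundary ties all
    masked, so exactly floor(p/100 * n) bins go per tail on distinct
    values.

    Stages with a single cell skip the stage-mean division (a self-ratio
    would be identically 1) with a warning.
    """
    total = counts.counts.sum(axis=1, keepdims=True).astype(float)
    if np.any(total == 0):
        raise ValueError("cell with zero total reads; run qc first")
    rpm = counts.counts / total * 1e6
    stages = counts.cell_meta["stage"].to_numpy()
    normalized = np.full(rpm.shape, np.nan)
    bin_mask = np.zeros(rpm.shape, dtype=bool)
    for stage in pd.unique(stages):
        rows = np.flatnonzero(stages == stage)
        sub = rpm[rows]
        mean_rpm = sub.mean(axis=0)
        n = mean_rpm.size
        k_low = math.floor(low_percentile / 100.0 * n)
        k_high = math.floor(high_percentile / 100.0 * n)
        order = np.sort(mean_rpm)
        mask = counts.bins.mask.copy()
        if k_low > 0:
            mask |= mean_rpm <= order[k_low - 1]
        if k_high > 0:
            mask |= mean_rpm >= order[n - k_high]
        if rows.size == 1:
            log.warning("stage %r has a single cell; skipping stage-mean step", stage)
            out = sub
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                out = sub / mean_rpm
            mask |= ~np.isfinite(out).all(axis=0)
        normalized[rows] = np.where(mask, np.nan, out)
        bin_mask[rows] = mask
    return normalized, bin_mask
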