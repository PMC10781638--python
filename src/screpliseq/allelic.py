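"""Allele-specific analyses of maternal/paternal count matrices.

Consumes per-allele binned counts produced upstream by SNP-aware read
splitting.  Bias per bin is the log2 maternal:paternal count ratio,
defined only at bins with enough allele-assigned reads.  Per-cell median
ratios drive pronucleus label correction (physically separated pronuclei
should be strongly single-parental) and parthenote flagging (maternal-only
embryos among nominally biparental zygotes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grid import AllelicCounts, RTProfile

MATERNAL, PATERNAL = "maternal", "paternal"


def allelic_log2ratio(ac: AllelicCounts, min_reads: int = 5,
                      combined_filter: bool = False) -> np.ndarray:
    """Per-cell per-bin log2(maternal/paternal); NaN below the read filter.

    The filter keeps bins with at least ``min_reads`` reads assigned to
    either the maternal or the paternal genome (``combined_filter=True``
    switches to mat + pat >= min_reads).  Zeros on one side use a Haldane
    pseudocount of 0.5 on both sides; bins with both counts positive use
    the plain ratio.
    """
    mat = ac.mat.astype(float)
    pat = ac.pat.astype(float)
    if combined_filter:
        defined = (mat + pat) >= min_reads
    else:
        defined = (mat >= min_reads) | (pat >= min_reads)
    both_zero = (mat == 0) & (pat == 0)
    defined &= ~both_zero
    c = np.where((mat == 0) | (pat == 0), 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((mat + c) / (pat + c))
    return np.where(defined, ratio, np.nan)


@dataclass
class PronucleusAssignment:
    table: pd.DataFrame  # index cell_id: label_in, median_ratio, label_out, ambiguous


def median_ratio_per_cell(ratios: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nanmedian(ratios, axis=1)


def assign_pronucleus(cell_ids: list[str], labels: list[str],
                      ratios: np.ndarray, bound: float = 2.0) -> PronucleusAssignment:
    """Correct maternal/paternal pronucleus labels from allelic bias.

    A nominally maternal (paternal) pronucleus with median log2 ratio
    below -``bound`` (above +``bound``) is relabelled to the other parent;
    cells with |median| <= ``bound`` keep their label but are flagged
    ambiguous.
    """
    med = median_ratio_per_cell(ratios)
    out, amb = [], []
    for label, m in zip(labels, med):
        if label not in (MATERNAL, PATERNAL):
            raise ValueError(f"label must be maternal/paternal, got {label!r}")
        if not np.isfinite(m) or abs(m) <= bound:
            out.append(label)
            amb.append(True)
        elif m > bound:
            out.append(MATERNAL)
            amb.append(False)
        else:
            out.append(PATERNAL)
            amb.append(False)
    table = pd.DataFrame({
        "label_in": labels, "median_ratio": med,
        "label_out": out, "ambiguous": amb,
    }, index=cell_ids)
    return PronucleusAssignment(table)


def flag_parthenote(ratios: np.ndarray, cut: float = 1.0) -> np.ndarray:
    """Flag cells whose median log2 maternal:paternal ratio is above ``cut``.

    The inequality is strict: a median of exactly ``cut`` is not flagged.
    """
    med = median_ratio_per_cell(ratios)
    return np.isfinite(med) & (med > cut)


def allelic_pairwise_correlation(ratios: np.ndarray,
                                 min_shared_bins: int = 10) -> np.ndarray:
    """Spearman correlations of allelic bias between all cell pairs.

    Each pair is correlated over the bins where both cells have a defined
    ratio; pairs sharing fewer than ``min_shared_bins`` bins get NaN.
    """
    n = ratios.shape[0]
    if n < 2:
        raise ValueError("need >= 2 cells")
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(ratios[i]) & np.isfinite(ratios[j])
            if ok.sum() < min_shared_bins:
                continue
            rho = sps.spearmanr(ratios[i, ok], ratios[j, ok]).statistic
            out[i, j] = out[j, i] = rho
    return out


def mean_rt_over_genes(rt: RTProfile, genes: pd.DataFrame) -> pd.Series:
    """Mean RT over the unmasked bins overlapping each gene.

    ``genes`` has columns chrom, start, end and an index of gene names;
    genes overlapping no unmasked bin get NaN.
    """
    values = rt.rt_interval
    out = {}
    for name, row in genes.iterrows():
        try:
            sl = rt.bins.chrom_slice(row["chrom"])
        except KeyError:
            out[name] = np.nan
            continue
        s = rt.bins.start[sl]
        e = rt.bins.end[sl]
        hit = (s < row["end"]) & (e > row["start"]) & ~rt.bins.mask[sl]
        vals = values[sl][hit]
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.mean()) if vals.size else np.nan
    return pd.Series(out, name="mean_rt")
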