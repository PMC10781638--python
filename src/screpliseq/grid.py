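"""Genomic bin grids and the matrix containers built on them.

All coordinates are 0-based half-open internally; BED conventions apply at
I/O boundaries.  A :class:`BinGrid` is an ordered tiling of each chromosome
into fixed-width bins (50 kb by default) with a boolean mask marking bins
excluded from analysis (low mappability, outlier coverage, QC-masked
chromosomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MASKED = -1  # sentinel state in BinaryReplicationMatrix


@dataclass
class BinGrid:
    """Ordered, non-overlapping fixed-width bins tiling chromosomes.

    Parameters
    ----------
    chrom, start, end
        Per-bin arrays; bins are sorted within chromosome and chromosomes
        are contiguous blocks.  Width is constant except possibly the last
        bin of each chromosome.
    mask
        True marks a bin excluded from analysis.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.mask is None:
            self.mask = np.zeros(self.start.size, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool).copy()
        if not (self.chrom.size == self.start.size == self.end.size == self.mask.size):
            raise ValueError("BinGrid fields must have equal length")
        if np.any(self.end <= self.start):
            raise ValueError("bins must have positive width")
        for _, lo, hi in self.chrom_blocks():
            s, e = self.start[lo:hi], self.end[lo:hi]
            if np.any(s[1:] < e[:-1]):
                raise ValueError("bins overlap or are unsorted within a chromosome")

    @classmethod
    def from_chrom_sizes(cls, sizes: dict[str, int], bin_size: int = 50_000) -> "BinGrid":
        """Tile each chromosome with `bin_size` bins (last bin may be short)."""
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        chroms, starts, ends = [], [], []
        for chrom, size in sizes.items():
            if size <= 0:
                raise ValueError(f"non-positive size for {chrom}")
            s = np.arange(0, size, bin_size, dtype=np.int64)
            e = np.minimum(s + bin_size, size)
            chroms.extend([chrom] * s.size)
            starts.append(s)
            ends.append(e)
        return cls(np.array(chroms, dtype=object), np.concatenate(starts), np.concatenate(ends))

    @property
    def n_bins(self) -> int:
        return self.start.size

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.chrom:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chrom_blocks(self):
        """Yield (chrom, lo, hi) index ranges, one per chromosome block."""
        if self.chrom.size == 0:
            return
        lo = 0
        for i in range(1, self.chrom.size + 1):
            if i == self.chrom.size or self.chrom[i] != self.chrom[lo]:
                yield self.chrom[lo], lo, i
                lo = i

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def keys(self) -> np.ndarray:
        """Stable bin keys ``chrom:start-end`` used in TSV outputs."""
        return np.array(
            [f"{c}:{s}-{e}" for c, s, e in zip(self.chrom, self.start, self.end)],
            dtype=object,
        )

    def copy(self) -> "BinGrid":
        return BinGrid(self.chrom.copy(), self.start.copy(), self.end.copy(), self.mask.copy())

    def with_mask(self, mask: np.ndarray) -> "BinGrid":
        return BinGrid(self.chrom, self.start, self.end, np.asarray(mask, dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "mask": self.mask}
        )

    def same_coords(self, other: "BinGrid") -> bool:
        return (
            self.n_bins == other.n_bins
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
        )


@dataclass
class CellCountMatrix:
    """Raw (or normalized) cells x bins counts with per-cell metadata.

    ``cell_meta`` is indexed by ``cell_ids`` and carries at least a
    ``stage`` column (one label per cell); further columns (collection
    time, treatment group) pass through untouched.
    """

    bins: BinGrid
    counts: np.ndarray  # cells x bins
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x bins)")
        if self.counts.shape != (len(self.cell_ids), self.bins.n_bins):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {self.bins.n_bins} bins"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame({"stage": ["unknown"] * len(self.cell_ids)},
                                          index=self.cell_ids)
        if list(self.cell_meta.index) != list(self.cell_ids):
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_index(self, cell_id: str) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise KeyError(f"unknown cell {cell_id!r}") from None

    def subset_cells(self, keep: np.ndarray) -> "CellCountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ids = [self.cell_ids[i] for i in keep]
        return CellCountMatrix(self.bins, self.counts[keep], ids, self.cell_meta.iloc[keep])

    def copy(self) -> "CellCountMatrix":
        return CellCountMatrix(self.bins.copy(), self.counts.copy(),
                               list(self.cell_ids), self.cell_meta.copy())


@dataclass
class BinaryReplicationMatrix:
    """Cells x bins replication states: 1 replicated, 0 not, -1 masked."""

    bins: BinGrid
    states: np.ndarray  # int8, values {0, 1, MASKED}
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    thresholds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.cell_ids), self.bins.n_bins):
            raise ValueError("states shape does not match cells x bins")
        bad = ~np.isin(self.states, (0, 1, MASKED))
        if bad.any():
            raise ValueError("states must be 0, 1 or masked")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame({"stage": ["unknown"] * len(self.cell_ids)},
                                          index=self.cell_ids)
        if self.thresholds is None:
            self.thresholds = np.full(len(self.cell_ids), np.nan)
        self.thresholds = np.asarray(self.thresholds, dtype=float)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def unmasked(self) -> np.ndarray:
        """Boolean cells x bins array of observed (0/1) entries."""
        return self.states != MASKED

    def subset_cells(self, keep: np.ndarray) -> "BinaryReplicationMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ids = [self.cell_ids[i] for i in keep]
        return BinaryReplicationMatrix(self.bins, self.states[keep], ids,
                                       self.cell_meta.iloc[keep], self.thresholds[keep])


@dataclass
class RTProfile:
    """Per-stage replication-timing profile on a bin grid.

    rt_raw
        Fraction of cells that replicated each bin; in [0, 1], higher =
        earlier replication.
    rt_interval
        Sampling-corrected RT: mean replicated fraction over overlapping
        replication-score intervals.
    variability
        1 - |p - 0.5| / 0.5 with p the sampling-corrected fraction.
    """

    bins: BinGrid
    rt_raw: np.ndarray
    rt_interval: np.ndarray
    variability: np.ndarray
    stage: str = "unknown"
    n_cells: int = 0

    def __post_init__(self) -> None:
        for name in ("rt_raw", "rt_interval", "variability"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.bins.n_bins,):
                raise ValueError(f"{name} must be one value per bin")
            ok = np.isfinite(arr)
            if np.any((arr[ok] < 0) | (arr[ok] > 1)):
                raise ValueError(f"{name} values must lie in [0, 1]")
            setattr(self, name, arr)


def _as_grid_pair(a: BinGrid, b: BinGrid) -> None:
    if not a.same_coords(b):
        raise ValueError("bin grids do not share coordinates")


@dataclass
class AllelicCounts:
    """Per-allele count matrices (maternal, paternal) on a shared grid."""

    bins: BinGrid
    mat: np.ndarray
    pat: np.ndarray
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mat = np.asarray(self.mat)
        self.pat = np.asarray(self.pat)
        shape = (len(self.cell_ids), self.bins.n_bins)
        if self.mat.shape != shape or self.pat.shape != shape:
            raise ValueError("allelic count matrices must be cells x bins")
        if np.any(self.mat < 0) or np.any(self.pat < 0):
            raise ValueError("counts must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame({"stage": ["unknown"] * len(self.cell_ids)},
                                          index=self.cell_ids)
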