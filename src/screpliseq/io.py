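"""Readers and writers for the formats the pipeline touches.

Genomic output uses BED/bedGraph dialects (0-based half-open); matrices
are plain TSV with a stable ``chrom:start-end`` bin-key column and one
column per cell.  GTF input (1-based closed) is converted to internal
half-open coordinates on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import MASKED, AllelicCounts, BinaryReplicationMatrix, BinGrid, \
    CellCountMatrix, RTProfile

_KEY_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def normalize_chrom(name: str) -> str:
    """Harmonize chromosome names to the 'chr' prefixed form."""
    return name if name.startswith("chr") else f"chr{name}"


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return {normalize_chrom(str(c)): int(s) for c, s in zip(df["chrom"], df["size"])}


def write_bins_bed(bins: BinGrid, path) -> None:
    df = bins.to_frame()
    df["name"] = np.where(df.pop("mask"), "masked", "bin")
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bins_bed(path) -> BinGrid:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"],
                     usecols=[0, 1, 2, 3])
    mask = df["name"].astype(str).eq("masked").to_numpy()
    return BinGrid(df["chrom"].astype(str).to_numpy(object),
                   df["start"].to_numpy(np.int64),
                   df["end"].to_numpy(np.int64), mask)


def _parse_keys(keys: pd.Index, bins: BinGrid) -> None:
    expected = bins.keys()
    got = np.asarray(keys, dtype=object)
    if got.size != expected.size or not np.array_equal(got, expected):
        missing = set(got) - set(expected)
        if missing:
            raise ValueError(f"matrix bin keys absent from bins BED: {sorted(missing)[:5]}")
        raise ValueError("matrix bin keys do not match the bins BED (order or count)")


def write_count_matrix(counts: CellCountMatrix, path, meta_path=None) -> None:
    df = pd.DataFrame(counts.counts.T, index=pd.Index(counts.bins.keys(), name="bin"),
                      columns=counts.cell_ids)
    df.to_csv(path, sep="\t")
    if meta_path is not None:
        counts.cell_meta.rename_axis("cell_id").to_csv(meta_path, sep="\t")


def read_count_matrix(path, bins: BinGrid, meta_path=None) -> CellCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _parse_keys(df.index, bins)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
    return CellCountMatrix(bins, df.to_numpy().T, [str(c) for c in df.columns], meta)


def write_binary_matrix(states: BinaryReplicationMatrix, path,
                        thresholds_path=None) -> None:
    arr = states.states.T.astype(object)
    arr[states.states.T == MASKED] = "NA"
    df = pd.DataFrame(arr, index=pd.Index(states.bins.keys(), name="bin"),
                      columns=states.cell_ids)
    df.to_csv(path, sep="\t")
    if thresholds_path is not None:
        pd.DataFrame({"cell_id": states.cell_ids,
                      "threshold": states.thresholds}).to_csv(
            thresholds_path, sep="\t", index=False)


def read_binary_matrix(path, bins: BinGrid) -> BinaryReplicationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    _parse_keys(df.index, bins)
    arr = df.to_numpy(dtype=float).T
    states = np.where(np.isnan(arr), MASKED, arr).astype(np.int8)
    return BinaryReplicationMatrix(bins, states, [str(c) for c in df.columns])


def write_bedgraph(bins: BinGrid, values: np.ndarray, path,
                   track_name: str | None = None) -> None:
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for c, s, e, v in zip(bins.chrom[ok], bins.start[ok], bins.end[ok], values[ok]):
            fh.write(f"{c}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path, bins: BinGrid) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            c, s, e, v = line.rstrip("\n").split("\t")
            rows.append((c, int(s), int(e), float(v)))
    values = np.full(bins.n_bins, np.nan)
    lookup = {(c, s): i for i, (c, s) in enumerate(zip(bins.chrom, bins.start))}
    for c, s, e, v in rows:
        i = lookup.get((c, s))
        if i is None:
            raise ValueError(f"bedGraph interval {c}:{s}-{e} not on the bin grid")
        values[i] = v
    return values


def write_rt_profile(rt: RTProfile, prefix) -> None:
    prefix = str(prefix)
    write_bedgraph(rt.bins, rt.rt_raw, Path(prefix + ".raw.bedGraph"),
                   f"rt_raw_{rt.stage}")
    write_bedgraph(rt.bins, rt.rt_interval, Path(prefix + ".interval.bedGraph"),
                   f"rt_interval_{rt.stage}")
    write_bedgraph(rt.bins, rt.variability, Path(prefix + ".variability.bedGraph"),
                   f"variability_{rt.stage}")


def read_intervals_bed(path) -> pd.DataFrame:
    """BED3+ reader; returns chrom, start, end (+ name when present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
    df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
    return df


def read_te_gtf(path) -> pd.DataFrame:
    """Transposable-element GTF to chrom/start/end/family (half-open).

    Family is taken from the ``family_id`` attribute, falling back to
    ``gene_id``.  GTF 1-based closed coordinates become 0-based half-open.
    """
    import pyranges as pr

    gr = pr.read_gtf(path).df
    fam_col = "family_id" if "family_id" in gr.columns else "gene_id"
    out = pd.DataFrame({
        "chrom": gr["Chromosome"].astype(str).map(normalize_chrom),
        "start": gr["Start"].astype(np.int64),  # pyranges already half-open
        "end": gr["End"].astype(np.int64),
        "family": gr[fam_col].astype(str),
    })
    return out


def write_allelic(ac: AllelicCounts, mat_path, pat_path) -> None:
    for arr, path in ((ac.mat, mat_path), (ac.pat, pat_path)):
        pd.DataFrame(arr.T, index=pd.Index(ac.bins.keys(), name="bin"),
                     columns=ac.cell_ids).to_csv(path, sep="\t")


def read_allelic(mat_path, pat_path, bins: BinGrid, meta_path=None) -> AllelicCounts:
    dm = pd.read_csv(mat_path, sep="\t", index_col=0)
    dp = pd.read_csv(pat_path, sep="\t", index_col=0)
    _parse_keys(dm.index, bins)
    _parse_keys(dp.index, bins)
    if list(dm.columns) != list(dp.columns):
        raise ValueError("maternal and paternal matrices list different cells")
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return AllelicCounts(bins, dm.to_numpy().T, dp.to_numpy().T,
                         [str(c) for c in dm.columns], meta)


def write_features_bed(fs, path) -> None:
    """FeatureSet to BED6 (name = type, score = mean cluster rank)."""
    with open(path, "w") as fh:
        for row in fs.intervals.itertuples():
            ranks = fs.cluster_rank[row.bin_lo:row.bin_hi]
            ranks = ranks[ranks > 0]
            score = float(ranks.mean()) if ranks.size else 0.0
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.type}\t"
                     f"{score:.2f}\t.\n")
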