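# screpliseq

Single-cell Repli-seq analysis: from binned read counts of single S-phase
cells to binarized replication states, replication-timing (RT) profiles,
RT features and cell-to-cell heterogeneity.

During S phase a genomic region that has already replicated is present in
two copies, one that has not in a single copy. Sequencing single S-phase
cells therefore encodes each cell's replication state in its coverage
profile. `screpliseq` implements the full analysis for such data — built
for (and validated on) mouse pre-implantation embryo-style designs, where
cells sampled across S phase are pooled per developmental stage:

- **QC**: minimum aligned-read filter and a coefficient-of-variation test
  over per-chromosome mean counts (chr1–19) that flags aneuploidy, with
  leave-one-chromosome-out rescue.
- **Binarization**: RPM + stage-mean normalization (no G1/G2 control),
  outlier-bin masking, piecewise-constant segmentation (exact PELT),
  mappability filtering, IQR scaling with 15-bin median smoothing, and a
  per-cell two-component Gaussian mixture whose density intersection sets
  the replicated / not-replicated threshold.
- **RT profiles**: per-cell replication scores, the 10–90% score filter,
  raw RT (fraction of replicated cells per bin) and sampling-corrected
  interval RT averaged over 16 overlapping replication-score windows
  (35% wide, 4.33% step), plus the variability score
  `1 − |p − 0.5| / 0.5`.
- **Features**: 15-cluster RT ranking, 21-bin sliding-window calling of RT
  peaks (initiation zones), TTRs and RT troughs (termination zones), size
  and count statistics, stage trends, transitions, composite profiles and
  AT content.
- **Heterogeneity**: per-bin sigmoid fits
  `y = 100 / (1 + exp(−g (x − M)))` of percent-replicated against S-phase
  progression; `M` is the mid-point (replication score at which half the
  cells replicated the bin, higher = later), and
  `T_width = 2·ln 3 / g` the 25–75% span quantifying cell-to-cell
  heterogeneity.
- **Statistics**: cell-resampling bootstrap (percentile 95% CIs), ΔRT
  between conditions with significance classes, observed/expected
  contingency enrichment, circular shift-null enrichment of transposable
  elements in RT features, external-track binning (log2 CPM+1), LAD-boundary
  composites and compartment comparisons.
- **Allelic analyses**: maternal:paternal log2 bias per bin, pronucleus
  label correction, parthenote flagging, pairwise bias concordance and
  RT over (imprinted) genes.
- **Synthetic data**: a generator with known ground-truth RT programmes,
  sigmoid firing, Poisson copy-number counts, allelic splits and
  aneuploidy injection, used to validate every stage end to end.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from screpliseq import (
    generate_truth, simulate_cell_states, simulate_read_counts,
    qc_cells, binarize_matrix, filter_cells_by_score, rt_values,
    cluster_rt_ranks, call_features, feature_stats, fit_genome,
)

truth = generate_truth({"chr1": 600, "chr2": 600}, domain_length_bins=50, seed=1)
cells = simulate_cell_states(truth, 40, seed=1)
counts = simulate_read_counts(cells, truth.bins, depth_per_bin=50, seed=1)

report = qc_cells(counts, min_reads=10_000)   # synthetic depth, lower floor
states = filter_cells_by_score(binarize_matrix(counts, report))
print(f"cells passing QC + binarization + score filter: {states.n_cells}/40")

profile = rt_values(states)
ok = np.isfinite(profile.rt_interval)
print(f"Spearman(interval RT, true RT) = "
      f"{spearmanr(profile.rt_interval[ok], truth.true_rt[ok]).statistic:.3f}")

fs = call_features(cluster_rt_ranks(profile, k=15), truth.bins)
print(feature_stats(fs)[["n", "median_bp"]])

fits = fit_genome(states)
conv = fits["converged"]
print(f"sigmoid fits converged: {conv.sum()}/{len(fits)}; "
      f"median M = {fits.loc[conv, 'M'].median():.1f}, "
      f"median T_width = {fits.loc[conv, 't_width'].median():.1f}")
```

prints

```
cells passing QC + binarization + score filter: 18/40
Spearman(interval RT, true RT) = 0.968
         n  median_bp
type
peak    11  2550000.0
TTR     23   600000.0
trough  10  2625000.0
sigmoid fits converged: 521/1200; median M = 42.9, median T_width = 9.1
```

Roughly half of a uniform-S cell sample survives the pipeline's filters
(cells near the very start or end of S phase carry a single copy-number
population and are removed as binarization outliers); the survivors
reconstruct the generating RT programme almost perfectly (ρ = 0.97), the
caller recovers Mb-scale replication domains with narrow TTRs between them,
and the fitted mid-points spread across S phase as designed. Non-converged
sigmoid fits are bins whose replicated percentage never crosses 50% within
the sampled score range — expected for the earliest and latest bins.

The same stages are available as a CLI:

```sh
screpliseq simulate --n-cells 40 --n-bins 600 --seed 1 --outdir sim/
screpliseq qc --indir sim/ --outdir qc/ --min-reads 10000
screpliseq binarize --indir sim/ --outdir bz/ --qc-table qc/qc.tsv
screpliseq rt --indir bz/ --outdir rt/ --stage twocell
screpliseq features --rt-bedgraph rt/rt_twocell.interval.bedGraph \
    --bins-bed bz/bins.bed --outdir feats/
```

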