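# Methods

## Scope and model

`screpliseq` analyses single-cell Repli-seq data: whole-genome sequencing of
single S-phase cells, where a genomic bin that has already replicated carries
two copies and one that has not carries one. Starting from cells × 50-kb-bin
read counts, the package (i) binarizes each cell's coverage profile into
replicated / not-replicated states, (ii) aggregates cells of a developmental
stage into replication-timing (RT) profiles, (iii) segments RT profiles into
RT peaks (initiation zones), timing transition regions (TTRs) and RT troughs
(termination zones), (iv) quantifies cell-to-cell heterogeneity with a
per-bin sigmoid model, and (v) provides cell-resampling bootstrap inference,
genomic enrichment tests and allele-specific bias analyses. A synthetic-data
generator with known ground truth exercises every stage end to end.

## Binarization pipeline

Per stage, counts are normalized to reads per million (RPM) and each bin is
divided by the mean RPM of all same-stage cells at that bin, which cancels
mappability bias shared within the stage. No G1/G2 control normalization is
applied. Bins whose stage-mean RPM falls in the lowest 5% or highest 1% are
masked. Per cell the profile is then segmented (piecewise-constant penalized
least squares), bins in the lowest-level segments are masked up to a 5%
budget (low-mappability dropouts), the profile is centred by its mean, scaled
by its IQR, median-filtered with a 15-bin window (windows shrink symmetrically
at chromosome edges; masked bins are compacted out so no values leak across
gaps), re-segmented, and a two-component Gaussian mixture is fitted to the
per-bin segment levels. The replication threshold is the point where the two
weighted component densities intersect between the means, falling back to the
mid-point of the means when they do not cross there. A bin is replicated when
its fitted segment level exceeds the threshold.

Two properties of this design are worth knowing:

- **The stage must span S phase.** After the stage-mean division, a
  replicated bin's expected level is 2/(1+p) and an unreplicated bin's
  1/(1+p), with p the fraction of stage cells that replicated the bin. The
  two populations stay separated (ratio 2) only while p is strictly inside
  (0, 1); a stage composed solely of mid-S cells drives p to exactly 0/1 at
  the RT extremes and erases the contrast there.
- **Cells at the very start or end of S phase cannot be thresholded.** Such
  cells present a single copy population; the mixture then splits a
  continuum and the resulting calls track the population profile rather than
  the cell's own states, while the corrupted replication score hides the
  cell from the downstream 10–90% score filter. The pipeline therefore
  validates every binarized cell with a copy-ratio check: the mean RPM of
  called-replicated bins must be 1.7–2.4× that of called-unreplicated bins
  (2 is the theoretical copy ratio). Cells failing it are dropped as
  binarization outliers, mirroring the outlier-cell removal step of the
  original single-cell Repli-seq pipeline. On the default synthetic embryo
  roughly half of a uniform-S cell sample survives binarization plus score
  filtering; the surviving cells are binarized at ≥ 95% per-bin accuracy.

### Segmentation

Objective: sum of squared residuals + penalty × number of segments, each
segment fitted by its mean, chromosomes independent, solved exactly with the
PELT pruned dynamic programme (pruning is lossless for the SSE cost; tests
check equality with an exhaustive O(n²) DP). Penalty defaults were calibrated
on noiseless fixtures so true domain boundaries are always recovered:
splitting two adjacent 50-bin domains separated by Δ standardized units gains
25·Δ², so the defaults (1.0 on the normalized-ratio scale for the first pass,
4.0 on the IQR-standardized median-filtered scale for the second) sit well
below that gain and well above the noise floor of the smoothed data.

### Mixture details

EM is initialised at the 25th/75th percentiles with 4 random restarts (best
log-likelihood wins), tolerance 1e-8, spherical components. Component
variances are floored at (0.15 × sd of the data)² — an absolute floor lets EM
collapse onto a spike of identical segment levels and place the cut inside
one copy population. The mixture cut and the mid-point fallback follow the
intersection rule above; Ashman's D of the fit is recorded.

## RT profiles

A cell's replication score is the percentage of its unmasked bins called
replicated — a proxy for S-phase progression. Cells scoring outside [10, 90]
are excluded (bounds inclusive). Raw RT of a bin is the fraction of cells
that replicated it; to correct for uneven sampling across S phase, interval
RT averages the within-interval replicated fraction over overlapping
replication-score windows (35% wide, stepped by 4.33%: 16 windows over
0–100%; the last window is closed so every cell belongs somewhere; empty
windows are dropped from the average rather than counted as zero, which
would bias RT late). The variability score 1 − |p − 0.5|/0.5 of the
sampling-corrected fraction is 1 when half the cells replicated a bin and 0
at unanimity. RT-trajectory classes across ordered stages: constant-early /
constant-late require the side condition at every stage plus a stable
trajectory (total change < 0.1, configurable); shuffle is an early↔late
switch of ≥ 0.1 between consecutive stages; increase is monotone sharpening
away from 0.5 by ≥ 0.1 overall.

## RT features

Bins are clustered into k = 15 groups by interval RT (1-D Gaussian mixture,
i.e. model-based clustering) and clusters ranked by mean RT. A bin is a local maximum (minimum) when its rank equals the
window max (min) of the centred 21-bin window; runs of maxima become peaks,
runs of minima troughs, everything between TTRs. Features are not called
within the half-window of chromosome ends; masked gaps ≤ 2 bins are bridged,
wider gaps break runs. Flat stretches flagged both ways join an adjacent
same-rank extremum run or become TTR. Alternation
(peak–TTR–trough–TTR–peak) is enforced by inserting the opposite extremum at
the most extreme rank run between two same-type features; this repair is
rarely triggered on realistic profiles. Composite peak profiles stack
interval RT in ±1 Mb around peak mid-points, take per-offset medians and
subtract the window minimum. Trend tests regress a per-stage statistic
(feature count or 75th-percentile size) on stage rank with OLS.

## Heterogeneity

For each bin, the percentage y of cells replicating it within each
replication-score interval is regressed on the interval's mean score x via
y = 100/(1 + exp(−g(x − M))) with starts g = 0.1, M = 100 − mean(y); 16
anchor points at (0, 0) and 16 at (100, 100) pin the curve ends (the
anchored protocol is the default; anchors deliberately bias shallow noiseless
curves, so exact-recovery tests run unanchored). Optimisation is bounded
trust-region least squares (g ∈ [1e-4, 1e3], M ∈ [−50, 150]), with jittered
restarts only on failure. Bins whose y never crosses 50% are reported
non-converged rather than extrapolated. M is the replication score at which
half the cells replicated the bin (higher = later); T_width = 2·ln 3 / g is
the score span between 25% and 75% of cells replicated (higher = more
heterogeneous). Because x is observed only through 35%-wide overlapping
intervals, fitted T_width has a resolution floor of roughly the window
width's effect (~13 score units): very coordinated bins are reported wider
than truth, but the ordering across heterogeneity strata is preserved, and
for slow firing (T_width ≳ 40) the median fitted value is within a few
percent of 2·ln 3/g.

## Statistics

Significance for RT statistics comes from resampling cells (never bins) with
replacement, B = 1000, recomputing the statistic per replicate and taking
the 2.5th–97.5th percentile interval; endpoints use the Davison–Hinkley
order-statistic convention, slightly conservative for discrete bootstrap
distributions. ΔRT between conditions resamples each condition
independently; because resampling only reweights cells, the per-replicate
interval RT reduces to weighted sums with multinomial weights, which keeps
B = 1000 over 3,000 bins around a second. A bin is classed earlier/later
when its CI excludes zero. Contingency enrichments are observed/expected
with expected = row·column/total. Transposable-element enrichment uses a
shift null: each element is independently circularly shifted within its
chromosome per iteration, and the enrichment is the mean over 1,000
iterations of log2((observed + 1)/(shifted + 1)) overlap counts (the
pseudocount guards empty overlaps; with a few hundred elements its bias is
well under the Monte-Carlo noise). External tracks are binned by fragment
midpoint and normalized to log2(CPM + 1). Boundary composites stack RT
around domain edges oriented domain-side-right with per-offset median and
IQR; compartment comparisons split RT by score sign and report tie-corrected
Spearman correlation.

## Allelic analyses

From pre-split maternal/paternal count matrices: the per-bin log2
maternal:paternal ratio is defined where at least 5 reads are assigned to
either genome (configurable to a combined filter), with a Haldane 0.5
pseudocount only when one side is zero. Pronucleus labels are corrected from
the per-cell median ratio (median rather than mean, for robustness): labels
contradicting a |median| > 2 are swapped, |median| ≤ 2 is flagged ambiguous
but kept. Zygotes with median ratio > 1 (strict) are flagged as likely
parthenotes. Pairwise Spearman correlations of allelic bias use bins defined
in both cells of a pair (≥ 10 shared bins). Gene-level RT is the mean of
overlapping unmasked bins.

## Synthetic data

The generator emulates an embryo stage sampled uniformly across S phase
(s ∈ (0.02, 0.98), avoiding cells the score filter trivially discards). The
RT programme alternates peak plateaus, down-ramps, trough plateaus and
up-ramps; plateaus default to 50 bins and ramps to a third of that,
reflecting that TTRs are narrower than the constant-timing domains they
join. Each plateau draws its own level uniformly from the upper (peaks) or
lower (troughs) half of the RT range (default (0.1, 0.9)), staggering domain
firing across S phase as real RT landscapes do; the bin mid-point is
M = 100·(1 − RT). Given a cell's S-phase fraction s, bins fire independently
with probability 1/(1 + exp(−g(100s − M))); the default slope g = 1.0 keeps
per-cell states spatially coherent within domains, standing in for the
replicon-level firing correlation that real cells have but the generator
(which draws bins independently) does not model. Smaller g values are used
explicitly in heterogeneity studies. Read counts are Poisson with mean
depth × mappability × (1 + state) — replicated bins at double coverage — with
an optional gamma-mixing overdispersion knob; the Poisson default is the
simplest model the segmentation and mixture must already beat. Allelic
counts simulate each parental genome independently at half depth and thin
binomially by the assignable-read fraction (default 0.2, a typical
SNP-informative fraction for divergent mouse crosses). One global seed
drives per-cell substreams, so outputs are reproducible and individual cells
are independent.

What passing the recovery tests shows — and does not. The defaults define a
coordinated, cleanly domain-structured programme at moderate depth; they
demonstrate that the pipeline recovers states, RT order, features and
heterogeneity strata when its assumptions hold. Real embryo data add
spatially correlated firing, stage-internal substructure, mappability and
GC bias only partially shared across cells, and much larger T_width; the
recovery rates here do not transfer to those settings, and per-bin accuracy
against realized single-cell states is intrinsically limited whenever firing
is stochastic at the bin level.

## Problem sizes and determinism

The validation suite uses 60 cells × 3,000 bins at depth 50 for full-pipeline
recovery, 40-cell conditions for ΔRT detection, 200-cell fixtures for
sigmoid recovery and 500 replicates × B = 1000 for bootstrap calibration;
these sizes give stable statistics while keeping the whole suite and the
acceptance script to a few minutes on one CPU. All randomness flows from
explicit seeds (numpy Generator; SeedSequence-derived substreams per cell),
and repeated runs are byte-identical.

## Known limitations

- No within-cell spatial firing correlation in the generator (and none
  modelled in the analysis).
- The binarization discards cells near S-phase boundaries by design; stages
  whose true cell collection is strongly skewed toward one end of S phase
  will lose a large fraction of cells.
- Fitted T_width saturates below ~13 replication-score units (interval
  resolution).
- The feature caller's alternation repair assumes rank profiles with clear
  extrema; on pathological flat-with-noise profiles it may produce short
  inserted features.
- SNP splitting, read alignment, duplicate marking and G1/G2-control
  normalization are out of scope; the package consumes binned counts.
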