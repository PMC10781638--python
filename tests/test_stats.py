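"""Bootstrap inference, delta-RT, enrichment and external-track utilities."""

import numpy as np
import pandas as pd
import pytest

from screpliseq import (
    BinGrid,
    bin_external_track,
    boundary_composite,
    bootstrap_statistic,
    compartment_compare,
    delta_rt,
    disjoint,
    enrichment_ratio_table,
    te_shift_enrichment,
)
from screpliseq.grid import BinaryReplicationMatrix, RTProfile
from screpliseq.features import FeatureSet
from screpliseq.synthetic import PEAK, TROUGH, TTR


def make_states(rows):
    rows = np.asarray(rows, dtype=np.int8)
    bins = BinGrid.from_chrom_sizes({"chr1": rows.shape[1] * 50_000})
    return BinaryReplicationMatrix(bins, rows,
                                   [f"c{i}" for i in range(rows.shape[0])])


def profile_from(values):
    values = np.asarray(values, dtype=float)
    bins = BinGrid.from_chrom_sizes({"chr1": values.size * 50_000})
    return RTProfile(bins, values, values, np.full_like(values, np.nan))


class TestBootstrap:
    def test_constant_statistic_has_zero_width_ci(self):
        m = make_states(np.ones((5, 40)))
        res = bootstrap_statistic(m, lambda s: 1.0, b=50, seed=0)
        assert res.ci_low == res.ci_high == 1.0

    def test_excludes_zero_and_disjoint_predicates(self):
        from screpliseq.stats import BootstrapResult

        a = BootstrapResult(0.3, 0.2, 0.4, 100, 0)
        b = BootstrapResult(0.9, 0.8, 1.0, 100, 0)
        c = BootstrapResult(0.35, 0.25, 0.9, 100, 0)
        assert a.excludes_zero()
        assert disjoint(a, b)
        assert not disjoint(b, c)

    def test_resampling_is_seeded(self):
        rng = np.random.default_rng(0)
        m = make_states((rng.random((10, 60)) < 0.4).astype(np.int8))
        stat = lambda s: float((s.states == 1).mean())
        r1 = bootstrap_statistic(m, stat, b=100, seed=5)
        r2 = bootstrap_statistic(m, stat, b=100, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_ci_narrows_with_more_cells(self):
        rng = np.random.default_rng(1)
        small = make_states((rng.random((8, 200)) < 0.3).astype(np.int8))
        big = make_states((rng.random((64, 200)) < 0.3).astype(np.int8))
        stat = lambda s: float((s.states == 1).mean())
        ci_s = bootstrap_statistic(small, stat, b=300, seed=1)
        ci_b = bootstrap_statistic(big, stat, b=300, seed=1)
        assert (ci_b.ci_high - ci_b.ci_low) < (ci_s.ci_high - ci_s.ci_low)

    def test_coverage_of_bernoulli_fraction(self):
        """Percentile CI covers the true replicated fraction ~95% of runs."""
        p_true, n_cells, n_bins, runs = 0.3, 40, 50, 200
        covered = 0
        for r in range(runs):
            rng = np.random.default_rng(10_000 + r)
            m = make_states((rng.random((n_cells, n_bins)) < p_true)
                            .astype(np.int8))
            res = bootstrap_statistic(
                m, lambda s: float((s.states == 1).mean()), b=200, seed=r)
            covered += res.ci_low <= p_true <= res.ci_high
        assert 0.90 <= covered / runs <= 0.99


class TestDeltaRt:
    def test_identical_conditions_are_no_change(self):
        rng = np.random.default_rng(2)
        m = make_states((rng.random((20, 100)) < 0.5).astype(np.int8))
        tab = delta_rt(m, m, b=200, seed=0)
        assert (tab["class"] == "no-change").all()
        assert np.allclose(tab["delta_rt"].dropna(), 0.0)

    def test_antisymmetry_of_point_estimate(self):
        rng = np.random.default_rng(3)
        a = make_states((rng.random((15, 80)) < 0.4).astype(np.int8))
        b = make_states((rng.random((15, 80)) < 0.6).astype(np.int8))
        ab = delta_rt(a, b, b=50, seed=1)["delta_rt"]
        ba = delta_rt(b, a, b=50, seed=1)["delta_rt"]
        assert np.allclose(ab, -ba, equal_nan=True)

    def test_grid_mismatch_rejected(self):
        a = make_states(np.ones((3, 10)))
        bins = BinGrid.from_chrom_sizes({"chr2": 10 * 50_000})
        b = BinaryReplicationMatrix(bins, np.ones((3, 10), dtype=np.int8),
                                    ["x", "y", "z"])
        with pytest.raises(ValueError):
            delta_rt(a, b)


class TestEnrichmentTable:
    def test_independent_labels_have_unit_ratios(self):
        a = np.repeat(["x", "y"], 200)
        b = np.tile(np.repeat(["u", "v"], 100), 2)
        table = enrichment_ratio_table(a, b)
        assert np.allclose(table.to_numpy(), 1.0)

    def test_diagonal_construction_doubles_expectation(self):
        n = 400
        a = np.repeat(["x", "y"], n // 2)
        table = enrichment_ratio_table(a, a)
        assert np.allclose(np.diag(table.to_numpy()), 2.0)

    def test_matches_direct_count_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.choice(list("pqr"), 300)
        b = rng.choice(list("mn"), 300)
        table = enrichment_ratio_table(a, b)
        for ra in "pqr":
            for cb in "mn":
                obs = np.sum((a == ra) & (b == cb))
                exp = np.sum(a == ra) * np.sum(b == cb) / 300
                assert table.loc[ra, cb] == pytest.approx(obs / exp)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.choice(list("xy"), 200)
        b = rng.choice(list("uv"), 200)
        t1 = enrichment_ratio_table(a, b)
        swap = {"x": "y", "y": "x"}
        t2 = enrichment_ratio_table(np.array([swap[v] for v in a]), b)
        assert np.allclose(t1.loc["x"], t2.loc["y"])


def feature_set_covering(bins, fraction, feat_type=PEAK):
    """Features covering the first `fraction` of every chromosome."""
    rows = []
    for chrom, lo, hi in bins.chrom_blocks():
        k = int((hi - lo) * fraction)
        rows.append((chrom, int(bins.start[lo]), int(bins.end[lo + k - 1]),
                     feat_type, lo, lo + k))
    return FeatureSet(bins, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "type", "bin_lo", "bin_hi"]),
        np.ones(bins.n_bins, dtype=np.int64))


class TestTeShiftEnrichment:
    def test_uniform_elements_give_near_zero_enrichment(self):
        bins = BinGrid.from_chrom_sizes({"chr1": 200 * 50_000})
        fs = feature_set_covering(bins, 0.5)
        rng = np.random.default_rng(6)
        starts = rng.integers(0, 200 * 50_000 - 500, 300)
        tes = pd.DataFrame({"chrom": "chr1", "start": starts,
                            "end": starts + 300, "family": "LINE"})
        out = te_shift_enrichment(tes, fs, {"chr1": 200 * 50_000},
                                  n_iter=500, seed=0)
        assert abs(out["log2_enrichment"].iloc[0]) < 0.05

    def test_elements_inside_peaks_strongly_enriched(self):
        bins = BinGrid.from_chrom_sizes({"chr1": 200 * 50_000})
        fs = feature_set_covering(bins, 0.1)
        rng = np.random.default_rng(7)
        starts = rng.integers(0, 20 * 50_000 - 500, 100)
        tes = pd.DataFrame({"chrom": "chr1", "start": starts,
                            "end": starts + 300, "family": "ERV"})
        out = te_shift_enrichment(tes, fs, {"chr1": 200 * 50_000},
                                  n_iter=300, seed=1)
        assert out["log2_enrichment"].iloc[0] > 2.0

    def test_matches_independent_reimplementation(self):
        """Tiny fixture vs a duplicate implementation sharing the seed
        protocol (same RNG draws, independent overlap logic)."""
        bins = BinGrid.from_chrom_sizes({"chr1": 20 * 50_000})
        fs = feature_set_covering(bins, 0.25)
        tes = pd.DataFrame({
            "chrom": ["chr1"] * 5,
            "start": [10_000, 200_000, 380_000, 600_000, 910_000],
            "end": [12_000, 208_000, 390_000, 640_000, 930_000],
            "family": ["SINE"] * 5,
        })
        size = 20 * 50_000
        out = te_shift_enrichment(tes, fs, {"chr1": size}, n_iter=50, seed=9)
        # duplicate implementation
        feat_lo, feat_hi = 0, 5 * 50_000
        s = tes["start"].to_numpy()
        e = tes["end"].to_numpy()

        def overlaps(a, b):
            if b > size:  # wrapped element: two pieces
                return (a < feat_hi) or (0 < min(b - size, feat_hi))
            return (a < feat_hi) and (b > feat_lo)

        obs = sum(overlaps(a, b) for a, b in zip(s, e))
        rng = np.random.default_rng(9)
        logs = []
        for _ in range(50):
            offs = rng.integers(0, size, size=5)
            ns = (s + offs) % size
            ne = ns + (e - s)
            cnt = sum(overlaps(a, b) for a, b in zip(ns, ne))
            logs.append(np.log2((obs + 1) / (cnt + 1)))
        assert out["log2_enrichment"].iloc[0] == pytest.approx(np.mean(logs))

    def test_element_outside_bounds_rejected(self):
        bins = BinGrid.from_chrom_sizes({"chr1": 20 * 50_000})
        fs = feature_set_covering(bins, 0.25)
        tes = pd.DataFrame({"chrom": ["chr1"], "start": [999_000],
                            "end": [2_000_000], "family": ["SINE"]})
        with pytest.raises(ValueError):
            te_shift_enrichment(tes, fs, {"chr1": 20 * 50_000}, n_iter=5, seed=0)


class TestBinExternalTrack:
    def test_cpm_log2_arithmetic(self):
        bins = BinGrid.from_chrom_sizes({"chr1": 4 * 50_000})
        frags = pd.DataFrame({
            "chrom": ["chr1"] * 1_000_000,
            "start": np.r_[np.full(50, 10_000),
                           np.full(999_950, 60_000)],
        })
        frags["end"] = frags["start"] + 100
        out = bin_external_track(frags, bins)
        assert out[0] == pytest.approx(np.log2(51), abs=1e-9)
        assert out[2] == 0.0 and out[3] == 0.0

    def test_midpoint_assignment_against_oracle(self):
        rng = np.random.default_rng(8)
        bins = BinGrid.from_chrom_sizes({"chr1": 10 * 50_000,
                                         "chr2": 5 * 50_000})
        chroms = rng.choice(["chr1", "chr2"], 500, p=[2 / 3, 1 / 3])
        sizes = {"chr1": 10 * 50_000, "chr2": 5 * 50_000}
        starts = np.array([rng.integers(0, sizes[c] - 400) for c in chroms])
        frags = pd.DataFrame({"chrom": chroms, "start": starts,
                              "end": starts + 321})
        out = bin_external_track(frags, bins)
        counts = np.zeros(bins.n_bins)
        for c, s, e in zip(chroms, frags["start"], frags["end"]):
            mid = (s + e) // 2
            sl = bins.chrom_slice(c)
            idx = sl.start + mid // 50_000
            counts[idx] += 1
        assert np.allclose(out, np.log2(counts / 500 * 1e6 + 1))

    def test_zero_fragments_rejected(self):
        bins = BinGrid.from_chrom_sizes({"chr1": 50_000})
        with pytest.raises(ValueError):
            bin_external_track(pd.DataFrame(columns=["chrom", "start", "end"]),
                               bins)


class TestBoundaryComposite:
    def test_constant_rt_gives_flat_median_zero_iqr(self):
        prof = profile_from(np.full(200, 0.4))
        domains = pd.DataFrame({"chrom": ["chr1"], "start": [80 * 50_000],
                                "end": [120 * 50_000]})
        comp = boundary_composite(prof, domains, flank_bp=20 * 50_000)
        assert np.allclose(comp["median_rt"], 0.4)
        assert np.allclose(comp["q75"] - comp["q25"], 0.0)

    def test_step_at_boundary_reproduced_at_offset_zero(self):
        values = np.full(200, 0.8)
        values[80:120] = 0.2  # the domain (e.g. a LAD) is late
        prof = profile_from(values)
        domains = pd.DataFrame({"chrom": ["chr1"], "start": [80 * 50_000],
                                "end": [120 * 50_000]})
        comp = boundary_composite(prof, domains, flank_bp=10 * 50_000)
        med = comp.set_index("offset_bp")["median_rt"]
        assert med.loc[-5 * 50_000] == pytest.approx(0.8)
        assert med.loc[5 * 50_000] == pytest.approx(0.2)

    def test_medians_match_stacking_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.random(300)
        prof = profile_from(values)
        domains = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [60 * 50_000, 200 * 50_000],
            "end": [90 * 50_000, 240 * 50_000],
        })
        flank = 15
        comp = boundary_composite(prof, domains, flank_bp=flank * 50_000)
        stacks = []
        for edge_bin, into_right in ((60, True), (90, False),
                                     (200, True), (240, False)):
            w = values[edge_bin - flank:edge_bin + flank + 1]
            stacks.append(w if into_right else w[::-1])
        oracle = np.median(np.vstack(stacks), axis=0)
        assert np.allclose(comp["median_rt"], oracle)

    def test_no_usable_boundary_raises(self):
        prof = profile_from(np.full(20, 0.5))
        domains = pd.DataFrame({"chrom": ["chr1"], "start": [50_000],
                                "end": [100_000]})
        with pytest.raises(ValueError):
            boundary_composite(prof, domains, flank_bp=30 * 50_000)


class TestCompartmentCompare:
    def test_score_equal_to_rt_gives_perfect_correlation(self):
        rng = np.random.default_rng(10)
        values = rng.random(150)
        prof = profile_from(values)
        out = compartment_compare(prof, values - 0.5)
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_permuted_scores_give_near_zero_correlation(self):
        rng = np.random.default_rng(11)
        values = rng.random(400)
        prof = profile_from(values)
        out = compartment_compare(prof, rng.permutation(values) - 0.5)
        assert abs(out["spearman_rho"]) < 0.15

    def test_matches_direct_rank_oracle_and_splits_classes(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(12)
        values = rng.random(80)
        scores = rng.normal(0, 1, 80)
        prof = profile_from(values)
        out = compartment_compare(prof, scores)
        assert out["spearman_rho"] == pytest.approx(
            spearmanr(values, scores).statistic)
        assert len(out["rt_A"]) == np.sum(scores > 0)
        assert len(out["rt_B"]) == np.sum(scores < 0)

    def test_single_class_reports_undefined_correlation(self):
        prof = profile_from(np.linspace(0, 1, 30))
        out = compartment_compare(prof, np.full(30, 1.0))
        assert np.isnan(out["spearman_rho"])
        assert len(out["rt_B"]) == 0
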