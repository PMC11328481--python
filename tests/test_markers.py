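"""Marker calling, recurrence aggregation, peak binning and annotation."""

import numpy as np
import pandas as pd
import pytest

from qimbalance import markers, synth
from qimbalance.exceptions import DegenerateInputError

from conftest import make_sample_table


def brute_force_bin_counts(peak_list, bin_width):
    """Oracle: per-bin peak counts by scanning every (peak, bin) pair."""
    max_end = max(end for _, end, _ in peak_list)
    counts = {}
    for b in range(0, (max_end // bin_width) + 1):
        lo, hi = b * bin_width, (b + 1) * bin_width
        n = sum(1 for start, end, _ in peak_list if start < hi and end > lo)
        if n:
            counts[b] = n
    return counts


class TestGeneCorrelations:
    def test_self_correlated_gene(self):
        p = np.linspace(0.1, 0.9, 8)
        t = make_sample_table(p, [0] * 4 + [1] * 4)
        counts = pd.DataFrame(
            [np.round(1000 * p).astype(int), [50] * 8, [0] * 8],
            index=["tracks_quality", "flat", "silent"],
            columns=t["sample_id"],
        )
        r = markers.gene_quality_correlations(counts, t, scale="raw")
        assert r.loc["tracks_quality", "r"] == pytest.approx(1.0, abs=1e-6)
        assert bool(r.loc["flat", "excluded"]) and bool(r.loc["silent", "excluded"])
        assert np.isnan(r.loc["flat", "r"])

    def test_constant_p_low_raises(self):
        t = make_sample_table([0.5] * 6, [0, 0, 0, 1, 1, 1])
        counts = pd.DataFrame(np.arange(12).reshape(2, 6),
                              index=["a", "b"], columns=t["sample_id"])
        with pytest.raises(DegenerateInputError):
            markers.gene_quality_correlations(counts, t)

    def test_matches_per_gene_scipy_oracle(self, small_dataset):
        from scipy.stats import pearsonr
        counts, samples, _ = small_dataset
        r = markers.gene_quality_correlations(counts, samples)
        sf = markers.median_of_ratios_size_factors(counts)
        expr = np.log2(counts / sf + 1.0)
        for gene in counts.index[:25]:
            row = expr.loc[gene].to_numpy()
            if np.ptp(row) == 0:
                assert bool(r.loc[gene, "excluded"])
            else:
                expected = pearsonr(row, samples["p_low"]).statistic
                assert r.loc[gene, "r"] == pytest.approx(expected, abs=1e-10)

    def test_planted_low_markers_recovered(self, small_dataset):
        counts, samples, truth = small_dataset
        r = markers.gene_quality_correlations(counts, samples)
        low = truth.genes.index[truth.genes["role"] == "low_marker"]
        assert (r.loc[low, "r"] > 0).mean() > 0.9


class TestCallMarkers:
    def test_threshold_is_strict_and_signed(self):
        r = pd.DataFrame({"r": [0.4, 0.41, -0.41, -0.4, 0.0],
                          "excluded": [False] * 5},
                         index=["at", "low1", "high1", "at_neg", "null"])
        calls = markers.call_markers(r, threshold=0.4)
        assert calls == {"low": {"low1"}, "high": {"high1"}}

    def test_all_below_threshold_empty(self):
        r = pd.DataFrame({"r": [0.1, -0.2], "excluded": [False, False]},
                         index=["a", "b"])
        calls = markers.call_markers(r)
        assert calls["low"] == set() and calls["high"] == set()


class TestRecurrence:
    def test_counts_and_catalog_membership(self):
        calls = [{"low": {"g1", "g2"}, "high": set()} for _ in range(2)]
        calls += [{"low": {"g1"}, "high": {"g3"}} for _ in range(3)]
        catalog = markers.recurrence(calls, min_datasets=2)
        t = catalog.table.set_index(["feature", "direction"])
        assert t.loc[("g1", "low"), "n_datasets"] == 5
        assert t.loc[("g2", "low"), "n_datasets"] == 2
        assert t.loc[("g3", "high"), "n_datasets"] == 3

    def test_direction_conflict_keeps_directions_separate(self):
        calls = [{"low": {"g"}, "high": set()},
                 {"low": set(), "high": {"g"}},
                 {"low": set(), "high": set()}]
        catalog = markers.recurrence(calls, min_datasets=2)
        assert catalog.table.empty  # one call per direction: below N>=2

    def test_recurrence_table_non_increasing(self):
        rng = np.random.default_rng(4)
        calls = [{"low": set(rng.choice(50, 20).astype(str)),
                  "high": set(rng.choice(50, 10).astype(str))}
                 for _ in range(6)]
        catalog = markers.recurrence(calls)
        for col in ("low_markers", "high_markers"):
            assert (np.diff(catalog.recurrence[col]) <= 0).all()

    def test_shared_planted_markers_recur_everywhere(self):
        base = synth.SimConfig(n_control=8, n_disease=8, n_genes=300,
                               n_low_markers=20, n_high_markers=20,
                               n_disease_genes=10, qi_target=0.1, seed=2)
        shared = [f"g{j:05d}" for j in range(40)]
        coll = synth.simulate_collection(base, 3, shared)
        for _, _, truth in coll:
            assert set(truth.genes.index[truth.genes["role"] == "low_marker"]) \
                == set(shared[:20])


class TestBinPeaks:
    def test_spanning_peak_hits_both_bins(self):
        peaks = {"s1": pd.DataFrame({"chrom": ["chr1"], "start": [100],
                                     "end": [700], "enrichment": [5.0]})}
        bm = markers.bin_peaks(peaks, bin_width=500)
        assert list(bm.count.index) == ["chr1:0-500", "chr1:500-1000"]
        assert (bm.count["s1"] == 1).all()

    def test_summary_arithmetic(self):
        peaks = {"s1": pd.DataFrame({"chrom": ["chr1", "chr1"],
                                     "start": [10, 20], "end": [90, 80],
                                     "enrichment": [4.0, 8.0]})}
        bm = markers.bin_peaks(peaks, bin_width=500)
        assert bm.count.loc["chr1:0-500", "s1"] == 2
        assert bm.mean_enr.loc["chr1:0-500", "s1"] == pytest.approx(6.0)
        assert bm.min_enr.loc["chr1:0-500", "s1"] == pytest.approx(4.0)
        assert bm.max_enr.loc["chr1:0-500", "s1"] == pytest.approx(8.0)

    def test_matches_brute_force_overlap_oracle(self, rng):
        starts = rng.integers(0, 5000, size=60)
        lengths = rng.integers(1, 1200, size=60)
        peak_list = [(int(s), int(s + l), 1.0) for s, l in zip(starts, lengths)]
        peaks = {"s1": pd.DataFrame({
            "chrom": "chrX", "start": [p[0] for p in peak_list],
            "end": [p[1] for p in peak_list], "enrichment": 1.0})}
        bm = markers.bin_peaks(peaks, bin_width=500)
        oracle = brute_force_bin_counts(peak_list, 500)
        got = {int(b.split(":")[1].split("-")[0]) // 500: c
               for b, c in bm.count["s1"].items() if c > 0}
        assert got == oracle

    def test_malformed_interval_rejected(self):
        peaks = {"s1": pd.DataFrame({"chrom": ["chr1"], "start": [100],
                                     "end": [100], "enrichment": [1.0]})}
        with pytest.raises(ValueError):
            markers.bin_peaks(peaks)


class TestBinCorrelations:
    @staticmethod
    def _toy_binmatrix():
        cfg = synth.SimConfig(n_control=6, n_disease=6, n_genes=10,
                              n_low_markers=2, n_high_markers=2,
                              n_disease_genes=0, quality_effect=3.0,
                              qi_target=0.0, seed=9)
        peaks, samples, truth = synth.simulate_peaks(cfg, n_bins=40,
                                                     marker_bins=[0, 1, 2, 3])
        return markers.bin_peaks(peaks), samples, truth

    def test_eligibility_rule(self):
        samples = make_sample_table([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        peaks = {
            "s000": pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100],
                                  "enrichment": [1.0]}),
            "s001": pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100],
                                  "enrichment": [2.0]}),
            "s002": pd.DataFrame({"chrom": ["c"], "start": [600], "end": [700],
                                  "enrichment": [2.0]}),
            "s003": pd.DataFrame({"chrom": ["c"], "start": [600], "end": [700],
                                  "enrichment": [3.0]}),
        }
        bm = markers.bin_peaks(peaks)
        r_table, _ = markers.bin_quality_correlations(bm, samples,
                                                      min_samples_with_peak=3)
        assert len(r_table) == 0  # every bin has peaks in only 2 samples

    def test_planted_marker_bins_recovered(self):
        bm, samples, truth = self._toy_binmatrix()
        r_table, calls = markers.bin_quality_correlations(bm, samples)
        low_bins = set(truth.bins.loc[truth.bins["role"] == "low_marker", "bin"])
        high_bins = set(truth.bins.loc[truth.bins["role"] == "high_marker", "bin"])
        assert len(calls["low"] & low_bins) >= 1
        assert len(calls["high"] & high_bins) >= 1
        null_bins = set(truth.bins.loc[truth.bins["role"] == "null", "bin"])
        r_null = r_table.loc[r_table.index.intersection(null_bins), "r"]
        assert abs(r_null.mean()) < 0.25  # null bins center near zero


class TestAnnotateBins:
    def test_tie_breaks_to_lower_coordinate(self):
        anno = pd.DataFrame({"gene_id": ["right", "left"], "chrom": ["c", "c"],
                             "tss": [350, 150]})
        # bin midpoint 250 equidistant from 150 and 350
        out = markers.annotate_bins_to_genes(["c:0-500"], anno)
        assert out.loc[0, "gene_id"] == "left"

    def test_single_gene_chromosome(self):
        anno = pd.DataFrame({"gene_id": ["only"], "chrom": ["c"], "tss": [10]})
        out = markers.annotate_bins_to_genes(["c:0-500", "c:5000-5500"], anno)
        assert (out["gene_id"] == "only").all()

    def test_unmapped_chromosome_flagged(self):
        anno = pd.DataFrame({"gene_id": ["g"], "chrom": ["c1"], "tss": [10]})
        out = markers.annotate_bins_to_genes(["c2:0-500"], anno)
        assert not out.loc[0, "mapped"]

    def test_matches_exhaustive_nearest_scan(self, rng):
        anno = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(30)],
            "chrom": rng.choice(["c1", "c2"], 30),
            "tss": rng.integers(0, 20000, 30),
        })
        bins = [f"{c}:{s}-{s + 500}"
                for c in ("c1", "c2") for s in range(0, 20000, 4000)]
        out = markers.annotate_bins_to_genes(bins, anno).set_index("bin")
        for b in bins:
            chrom, span = b.split(":")
            mid = (int(span.split("-")[0]) + int(span.split("-")[1])) / 2
            cand = anno[anno["chrom"] == chrom].copy()
            cand["dist"] = (cand["tss"] - mid).abs()
            cand = cand.sort_values(["dist", "tss", "gene_id"])
            assert out.loc[b, "gene_id"] == cand.iloc[0]["gene_id"]
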