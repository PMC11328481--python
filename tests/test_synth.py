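"""Synthetic data generator: determinism, calibration, planted structure."""

import numpy as np
import pandas as pd
import pytest

from qimbalance import markers, qi, synth
from qimbalance.exceptions import CalibrationError


class TestConfigValidation:
    def test_planted_genes_exceed_total(self):
        cfg = synth.SimConfig(n_genes=100, n_low_markers=60, n_high_markers=60,
                              n_disease_genes=0)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_qi_target_out_of_range(self):
        with pytest.raises(ValueError):
            synth.SimConfig(qi_target=1.2).validate()

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            synth.SimConfig(n_control=1).validate()

    def test_paired_needs_equal_groups(self):
        with pytest.raises(ValueError):
            synth.SimConfig(n_control=5, n_disease=6, paired=True).validate()


class TestSimulateDataset:
    def test_size_bookkeeping(self):
        cfg = synth.SimConfig(n_control=10, n_disease=10, qi_target=0.0,
                              quality_effect=0.0, disease_effect=0.0, seed=1)
        counts, samples, truth = synth.simulate_dataset(cfg)
        assert len(samples) == 20
        assert (samples["group"] == 0).sum() == 10
        assert (samples["group"] == 1).sum() == 10
        assert counts.shape == (cfg.n_genes, 20)

    def test_determinism(self):
        cfg = synth.SimConfig(seed=42, n_genes=300, n_low_markers=20,
                               n_high_markers=20, n_disease_genes=10)
        a = synth.simulate_dataset(cfg)
        b = synth.simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2].genes, b[2].genes)
        assert a[2].realized_qi == b[2].realized_qi

    def test_counts_are_nonnegative_integers_and_sf_positive(self):
        counts, _, truth = synth.simulate_dataset(synth.SimConfig(
            seed=3, n_genes=200, n_low_markers=20, n_high_markers=20,
            n_disease_genes=10))
        values = counts.to_numpy()
        assert (values >= 0).all()
        assert np.issubdtype(values.dtype, np.integer)
        assert (truth.sample_truth["size_factor"] > 0).all()

    def test_truth_sign_convention(self):
        _, _, truth = synth.simulate_dataset(synth.SimConfig(
            seed=5, n_genes=300, n_low_markers=20, n_high_markers=20,
            n_disease_genes=10))
        g = truth.genes
        assert (g.loc[g["role"] == "low_marker", "beta_quality"] > 0).all()
        assert (g.loc[g["role"] == "high_marker", "beta_quality"] < 0).all()
        assert (g.loc[g["role"].isin(["disease", "null"]), "beta_quality"] == 0).all()
        assert (g.loc[g["role"] == "disease", "beta_disease"] != 0).all()
        assert 0.0 <= truth.realized_qi <= 1.0

    def test_null_qi_target_centers_low(self):
        vals = []
        for s in range(50):
            cfg = synth.SimConfig(n_control=10, n_disease=10, n_genes=10,
                                  n_low_markers=0, n_high_markers=0,
                                  n_disease_genes=0, qi_target=0.0, seed=s)
            _, samples, truth = synth.simulate_dataset(cfg)
            vals.append(truth.realized_qi)
        # under independence r is ~ N(0, 1/sqrt(n-1)), so the mean |r| at
        # n=20 is sqrt(2/pi)/sqrt(19) ~= 0.183; check against that null
        expected = np.sqrt(2 / np.pi) / np.sqrt(19)
        assert abs(np.mean(vals) - expected) < 0.05
        assert np.mean(vals) < 0.25

    @pytest.mark.parametrize("target", [0.2, 0.5, 0.8])
    def test_qi_calibration(self, target):
        vals = []
        for s in range(20):
            cfg = synth.SimConfig(n_control=10, n_disease=10, n_genes=10,
                                  n_low_markers=0, n_high_markers=0,
                                  n_disease_genes=0, qi_target=target, seed=100 + s)
            _, _, truth = synth.simulate_dataset(cfg)
            vals.append(truth.realized_qi)
        assert abs(np.mean(vals) - target) < 0.1

    def test_unreachable_target_reports_bound(self):
        # huge within-group quality spread makes high QI impossible
        cfg = synth.SimConfig(qi_target=1.0, quality_concentration=1.0,
                              n_genes=100, n_low_markers=0, n_high_markers=0,
                              n_disease_genes=0)
        with pytest.raises(CalibrationError) as exc_info:
            synth.simulate_dataset(cfg)
        assert exc_info.value.achievable is not None
        assert exc_info.value.achievable < 1.0

    def test_planted_low_markers_correlate_positively(self):
        cfg = synth.SimConfig(n_genes=500, n_low_markers=100, n_high_markers=0,
                              n_disease_genes=0, quality_effect=2.0,
                              qi_target=0.2, seed=7)
        counts, samples, truth = synth.simulate_dataset(cfg)
        r = markers.gene_quality_correlations(counts, samples)
        low = truth.genes.index[truth.genes["role"] == "low_marker"]
        assert (r.loc[low, "r"] > 0).mean() > 0.5

    def test_paired_layout(self):
        cfg = synth.SimConfig(n_control=6, n_disease=6, n_genes=100,
                              paired=True, seed=8, n_low_markers=10,
                              n_high_markers=10, n_disease_genes=10)
        _, samples, _ = synth.simulate_dataset(cfg)
        assert samples["pair_id"].notna().all()
        for _, grp in samples.groupby("pair_id"):
            assert set(grp["group"]) == {0, 1}

    def test_planted_outliers_detected(self):
        cfg = synth.SimConfig(n_control=10, n_disease=10, n_genes=50,
                              n_low_markers=0, n_high_markers=0,
                              n_disease_genes=0, qi_target=0.0,
                              n_outliers=2, outlier_p_low=0.97, seed=13)
        _, samples, _ = synth.simulate_dataset(cfg)
        detected = qi.detect_quality_outliers(samples)
        # the planted extreme-quality samples must be caught (the fences may
        # legitimately flag additional low-side samples)
        planted = set(samples.loc[samples["p_low"] > 0.9, "sample_id"])
        assert len(planted) == 2
        assert planted <= detected


class TestSimulateCollection:
    def test_shared_marker_identities(self):
        base = synth.SimConfig(n_genes=400, n_low_markers=30, n_high_markers=30,
                               n_disease_genes=20, qi_target=0.1, seed=2)
        shared = [f"g{j:05d}" for j in range(60)]
        coll = synth.simulate_collection(base, 4, shared)
        assert len(coll) == 4
        low_sets = [set(t.genes.index[t.genes["role"] == "low_marker"])
                    for _, _, t in coll]
        assert all(s == set(shared[:30]) for s in low_sets)
        disease_sets = [frozenset(t.genes.index[t.genes["role"] == "disease"])
                        for _, _, t in coll]
        assert len(set(disease_sets)) > 1  # disease identities differ

    def test_determinism_across_runs(self):
        base = synth.SimConfig(n_genes=200, n_low_markers=10, n_high_markers=10,
                               n_disease_genes=5, seed=6)
        shared = [f"g{j:05d}" for j in range(20)]
        a = synth.simulate_collection(base, 2, shared)
        b = synth.simulate_collection(base, 2, shared)
        for (ca, _, _), (cb, _, _) in zip(a, b):
            pd.testing.assert_frame_equal(ca, cb)

    def test_empty_shared_list_rejected(self):
        base = synth.SimConfig(n_genes=100, n_low_markers=10, n_high_markers=0,
                               n_disease_genes=0)
        with pytest.raises(ValueError):
            synth.simulate_collection(base, 2, [])

    def test_null_effects_produce_no_recurrent_markers(self):
        base = synth.SimConfig(n_control=10, n_disease=10, n_genes=600,
                               n_low_markers=0, n_high_markers=0,
                               n_disease_genes=0, qi_target=0.0, seed=21)
        coll = synth.simulate_collection(base, 2, [])
        calls = []
        for counts, samples, _ in coll:
            r = markers.gene_quality_correlations(counts, samples)
            calls.append(markers.call_markers(r))
        # null |r|>0.4 rate at n=20 is ~8%; same gene in both datasets with
        # consistent sign is ~0.2% -> expect ~1 of 600, allow a little slack
        catalog = markers.recurrence(calls, min_datasets=2)
        assert len(catalog.table) <= 6


class TestSimulatePeaks:
    def test_determinism_and_bed_layout(self):
        cfg = synth.SimConfig(n_control=5, n_disease=5, n_genes=10,
                              n_low_markers=2, n_high_markers=1,
                              n_disease_genes=0, seed=3)
        a, sa, _ = synth.simulate_peaks(cfg, n_bins=30, marker_bins=[0, 1, 2])
        b, sb, _ = synth.simulate_peaks(cfg, n_bins=30, marker_bins=[0, 1, 2])
        assert set(a) == set(b)
        for sid in a:
            pd.testing.assert_frame_equal(a[sid], b[sid])
            assert (a[sid]["start"] < a[sid]["end"]).all()
        pd.testing.assert_frame_equal(sa, sb)

    def test_null_effect_correlations_center_zero(self):
        cfg = synth.SimConfig(n_control=8, n_disease=8, n_genes=10,
                              n_low_markers=0, n_high_markers=0,
                              n_disease_genes=0, quality_effect=0.0,
                              qi_target=0.0, seed=17)
        peaks, samples, _ = synth.simulate_peaks(cfg, n_bins=60, marker_bins=[])
        bm = markers.bin_peaks(peaks)
        r_table, _ = markers.bin_quality_correlations(bm, samples)
        assert abs(r_table["r"].mean()) < 0.15

    def test_strong_marker_bin_recovered(self):
        cfg = synth.SimConfig(n_control=8, n_disease=8, n_genes=10,
                              n_low_markers=1, n_high_markers=0,
                              n_disease_genes=0, quality_effect=4.0,
                              qi_target=0.0, quality_concentration=3.0, seed=19)
        peaks, samples, truth = synth.simulate_peaks(cfg, n_bins=40, marker_bins=[5])
        bm = markers.bin_peaks(peaks)
        r_table, calls = markers.bin_quality_correlations(bm, samples)
        low_bin = truth.bins.loc[truth.bins["role"] == "low_marker", "bin"].iloc[0]
        assert r_table.loc[low_bin, "r"] > 0.3

    def test_marker_bin_bounds_checked(self):
        cfg = synth.SimConfig(n_genes=100, n_low_markers=1, n_high_markers=0,
                              n_disease_genes=0)
        with pytest.raises(ValueError):
            synth.simulate_peaks(cfg, n_bins=10, marker_bins=[10])
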