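"""Consensus peaks, normalization, and the empirical-FDR grid caller."""
import numpy as np
import pandas as pd
import pytest

from combisig import (SynthConfig, build_master_consensus,
                      call_differential_peaks, consensus_peaks, fdr_grid,
                      generate_peak_dataset, geometric_steps, merge_and_recall,
                      merge_peaks, normalize_counts)


def _summits(*positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": list(positions)})


class TestConsensusPeaks:
    def test_two_of_three_replicates_make_a_peak(self):
        out = consensus_peaks([_summits(100), _summits(105), _summits()])
        assert len(out) == 1
        row = out.iloc[0]
        assert row["support"] == 2
        assert row["summit"] == 102           # median of 100, 105
        assert (row["end"] - row["start"]) == 150

    def test_single_replicate_summit_is_dropped(self):
        out = consensus_peaks([_summits(500), _summits(), _summits()])
        assert len(out) == 0

    def test_replicate_order_invariance(self):
        reps = [_summits(100, 900), _summits(105, 910), _summits(98)]
        a = consensus_peaks(reps)
        b = consensus_peaks(reps[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_distant_summits_not_grouped(self):
        out = consensus_peaks([_summits(100, 300), _summits(105, 305)])
        assert len(out) == 2


class TestMasterConsensus:
    def test_identical_condition_sets_are_idempotent(self):
        peaks = pd.DataFrame({"chrom": "chr1", "start": [0, 500],
                              "end": [150, 650]})
        out = build_master_consensus([peaks, peaks.copy()])
        assert list(out["start"]) == [0, 500]
        assert list(out["end"]) == [150, 650]

    def test_overlapping_peaks_collapse_to_one(self):
        a = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [150]})
        b = pd.DataFrame({"chrom": "chr1", "start": [100], "end": [250]})
        out = build_master_consensus([a, b])
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (0, 250)

    def test_disjoint_peaks_conserve_count(self):
        a = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [150]})
        b = pd.DataFrame({"chrom": "chr1", "start": [150], "end": [300]})
        out = build_master_consensus([a, b])
        assert len(out) == 2  # half-open touching intervals do not overlap


class TestNormalization:
    def test_scales_follow_totals(self):
        raw = pd.DataFrame({"s1": [50.0, 50.0], "s2": [100.0, 200.0]})
        norm = normalize_counts(raw)
        # totals 100 and 300 -> scales 0.5 and 1.5
        assert norm["s1"].iloc[0] == pytest.approx(100.0)
        assert norm.sum(axis=0)["s1"] == pytest.approx(200.0)
        assert norm.sum(axis=0)["s2"] == pytest.approx(200.0)

    def test_equal_totals_identity(self):
        raw = pd.DataFrame({"s1": [10.0, 90.0], "s2": [60.0, 40.0]})
        pd.testing.assert_frame_equal(normalize_counts(raw), raw)

    def test_grand_total_conserved(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 100, size=(30, 6)),
                           columns=[f"s{i}" for i in range(6)])
        norm = normalize_counts(raw)
        assert norm.to_numpy().sum() == pytest.approx(raw.to_numpy().sum())

    def test_zero_total_sample_fatal(self):
        raw = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]})
        with pytest.raises(ValueError, match="zero reads"):
            normalize_counts(raw)


def test_geometric_grid_endpoints_exact():
    fc = geometric_steps(1.1, 10.0, 50)
    cnt = geometric_steps(10.0, 237.0, 50)
    assert fc[0] == pytest.approx(1.1) and fc[-1] == pytest.approx(10.0)
    assert cnt[0] == pytest.approx(10.0) and cnt[-1] == pytest.approx(237.0)
    assert len(fc) == len(cnt) == 50
    ratios = fc[1:] / fc[:-1]
    assert np.allclose(ratios, ratios[0])     # geometric spacing


def _toy_counts():
    """60 peaks; reference mean 20 everywhere; 20 peaks up in each of two
    experimental conditions; 3 and 1 spurious peaks in the extra controls."""
    n = 60
    idx = pd.Index([f"p{i:02d}" for i in range(n)], name="peak_id")
    base = np.full(n, 20.0)
    condA = base.copy(); condA[:20] = 80.0
    condB = base.copy(); condB[20:40] = 80.0
    extra1 = base.copy(); extra1[40:43] = 80.0
    extra2 = base.copy(); extra2[43] = 80.0
    counts = pd.DataFrame({"ref": base, "condA": condA, "condB": condB,
                           "extra1": extra1, "extra2": extra2}, index=idx)
    annotations = pd.DataFrame({
        "sample_id": ["ref", "condA", "condB", "extra1", "extra2"],
        "signal": ["control", "signalA", "signalB", "control_low_density",
                   "control_high_density"],
        "dose": ["none", "low", "low", "none", "none"],
        "replicate": [1, 1, 1, 1, 1]})
    return counts, annotations


class TestFdrGrid:
    def test_printed_formula_on_toy_counts(self):
        counts, annotations = _toy_counts()
        grid = fdr_grid(counts, annotations)
        # loosest cell: 40 experimental calls, extra controls give 3 and 1
        # -> FDR = 2 conditions * mean FP 2 / 40 = 0.1
        assert grid.n_differential[0, 0] == 40
        assert grid.fp_estimate[0, 0] == pytest.approx(2.0)
        assert grid.fdr[0, 0] == pytest.approx(0.1)

    def test_grid_corner_thresholds(self):
        counts, annotations = _toy_counts()
        grid = fdr_grid(counts, annotations)
        assert grid.fc_thresholds[0] == pytest.approx(1.1)
        assert grid.fc_thresholds[-1] == pytest.approx(10.0)
        assert grid.count_thresholds[0] == pytest.approx(10.0)
        assert grid.count_thresholds[-1] == pytest.approx(237.0)

    def test_clean_extra_controls_give_zero_fdr(self):
        counts, annotations = _toy_counts()
        counts["extra1"] = counts["ref"]
        counts["extra2"] = counts["ref"]
        grid = fdr_grid(counts, annotations)
        defined = np.isfinite(grid.fdr)
        assert defined.any()
        assert np.all(grid.fdr[defined] == 0.0)

    def test_undefined_cells_where_no_calls(self):
        counts, annotations = _toy_counts()
        grid = fdr_grid(counts, annotations)
        assert np.isnan(grid.fdr[-1, -1])  # fc >= 10 and count >= 237: nothing

    def test_suffix_counts_match_brute_force(self):
        counts, annotations = _toy_counts()
        grid = fdr_grid(counts, annotations)
        for i in (0, 10, 49):
            for j in (0, 17, 49):
                expect = int(((grid.exp_fc >= grid.fc_thresholds[i])
                              & (grid.exp_maxc >= grid.count_thresholds[j]))
                             .sum())
                assert grid.n_differential[i, j] == expect


class TestCallDifferentialPeaks:
    def test_pooled_calls_and_fdr_on_toy(self):
        counts, annotations = _toy_counts()
        grid = fdr_grid(counts, annotations)
        calls = call_differential_peaks(grid, cell_fdr_threshold=0.15)
        assert len(calls.calls) == 40
        called_peaks = set(calls.calls["peak_id"])
        assert called_peaks == {f"p{i:02d}" for i in range(40)}
        assert calls.pooled_fdr == pytest.approx(0.1)

    def test_no_qualifying_cell_returns_empty(self):
        counts, annotations = _toy_counts()
        grid = fdr_grid(counts, annotations)
        calls = call_differential_peaks(grid, cell_fdr_threshold=1e-6)
        assert len(calls.calls) == 0

    def test_threshold_monotonicity(self):
        counts, annotations = _toy_counts()
        grid = fdr_grid(counts, annotations)
        strict = call_differential_peaks(grid, 0.05)
        loose = call_differential_peaks(grid, 0.5)
        strict_set = set(map(tuple, strict.calls.to_numpy()))
        loose_set = set(map(tuple, loose.calls.to_numpy()))
        assert strict_set <= loose_set


class TestMergeAndRecall:
    def test_merge_boundary_inclusive_at_250(self):
        peaks = pd.DataFrame({"peak_id": ["a", "b"], "chrom": "chr1",
                              "start": [0, 400], "end": [150, 550]})
        assert len(merge_peaks(peaks, 250)) == 1      # gap exactly 250
        peaks2 = peaks.assign(start=[0, 401], end=[150, 551])
        assert len(merge_peaks(peaks2, 250)) == 2     # gap 251

    def test_second_round_matches_brute_force(self):
        counts, annotations = _toy_counts()
        coords = pd.DataFrame({
            "peak_id": counts.index,
            "chrom": "chr1",
            "start": np.arange(len(counts)) * 10_000,
            "end": np.arange(len(counts)) * 10_000 + 150})
        grid = fdr_grid(counts, annotations)
        round1 = call_differential_peaks(grid, 0.15)
        merged, round2 = merge_and_recall(round1, coords, counts, annotations,
                                          merge_distance=250, min_fc=1.5,
                                          min_count=30)
        # peaks are 10 kb apart: no merging; survivors = fc>=1.5 & max>=30
        assert len(merged) == 40
        expect = set()
        ref = counts["ref"]
        for sample, signal, dose in (("condA", "signalA", "low"),
                                     ("condB", "signalB", "low")):
            fc = np.maximum((counts[sample] + 1) / (ref + 1),
                            (ref + 1) / (counts[sample] + 1))
            hit = (fc >= 1.5) & (np.maximum(counts[sample], ref) >= 30)
            expect |= {(p, signal, dose) for p in counts.index[hit]}
        member_of = {m: row["peak_id"] for _, row in merged.iterrows()
                     for m in row["members"]}
        got = {(m, s, d) for pid, s, d in round2.calls.to_numpy()
               for m, mp in member_of.items() if mp == pid}
        assert got == expect

    def test_empty_round1_passes_through(self):
        counts, annotations = _toy_counts()
        grid = fdr_grid(counts, annotations)
        round1 = call_differential_peaks(grid, 1e-9)
        merged, round2 = merge_and_recall(round1, pd.DataFrame(
            columns=["peak_id", "chrom", "start", "end"]), counts, annotations)
        assert len(merged) == 0 and len(round2.calls) == 0


@pytest.fixture(scope="module")
def spike_in():
    cfg = SynthConfig(n_peaks=4000, frac_responsive_peaks=0.1, seed=21,
                      genome_length=80_000_000)
    counts, annotations, _, truth = generate_peak_dataset(cfg)
    raw = counts.set_index("peak_id").drop(columns=["chrom", "start", "end"])
    norm = normalize_counts(raw)
    return norm, annotations, truth


class TestOnSyntheticData:
    def test_realized_fdr_within_twofold_of_estimate(self, spike_in):
        """Realized and estimated FDR agree to within a factor of two, up
        to the FP estimator's resolution (its smallest nonzero value,
        n_conditions / (n_controls * n_calls))."""
        norm, annotations, truth = spike_in
        grid = fdr_grid(norm, annotations)
        calls = call_differential_peaks(grid, 0.0025)
        assert len(calls.calls) > 100
        null_peaks = set(truth.loc[~truth["truth_responsive"], "peak_id"])
        realized = calls.calls["peak_id"].isin(null_peaks).mean()
        resolution = grid.n_conditions / (grid.ctl_fc.shape[1]
                                          * len(calls.calls))
        assert realized <= max(2 * calls.pooled_fdr, resolution)
        assert calls.pooled_fdr <= max(2 * realized, resolution)

    def test_call_order_invariance(self, spike_in):
        norm, annotations, _ = spike_in
        rng = np.random.default_rng(0)
        shuffled = norm.iloc[rng.permutation(len(norm))]
        a = call_differential_peaks(fdr_grid(norm, annotations), 0.0025)
        b = call_differential_peaks(fdr_grid(shuffled, annotations), 0.0025)
        key = lambda df: set(map(tuple, df.calls.to_numpy()))
        assert key(a) == key(b)

    def test_pure_null_universe_yields_no_confident_calls(self, caplog):
        """On pure-null input the caller returns (at most) a tiny stray
        set whose zero FP estimate is flagged as unreliable; every cell
        with meaningful counts shows FDR near 1 and never qualifies."""
        cfg = SynthConfig(n_peaks=800, frac_responsive_peaks=0.0, seed=22,
                          genome_length=20_000_000)
        counts, annotations, _, _ = generate_peak_dataset(cfg)
        raw = counts.set_index("peak_id").drop(
            columns=["chrom", "start", "end"])
        grid = fdr_grid(normalize_counts(raw), annotations)
        busy = np.isfinite(grid.fdr) & (grid.n_differential >= 50)
        assert grid.fdr[busy].min() > 0.5
        assert np.median(grid.fdr[busy]) == pytest.approx(1.0, abs=0.3)
        with caplog.at_level("WARNING", logger="combisig"):
            calls = call_differential_peaks(grid, 0.0025)
        n_pairs = len(grid.peak_ids) * grid.n_conditions
        assert len(calls.calls) <= 0.002 * n_pairs
        if len(calls.calls):
            assert calls.n_false_positive_estimate == 0.0
            assert "saturated" in caplog.text

    def test_fdr_monotone_in_thresholds_on_null_data(self):
        """On null-dominated data the estimated FDR does not increase as
        either threshold tightens (checked in expectation via averages)."""
        cfg = SynthConfig(n_peaks=2000, frac_responsive_peaks=0.05, seed=23,
                          genome_length=40_000_000)
        counts, annotations, _, _ = generate_peak_dataset(cfg)
        raw = counts.set_index("peak_id").drop(
            columns=["chrom", "start", "end"])
        grid = fdr_grid(normalize_counts(raw), annotations)
        fdr = np.where(np.isfinite(grid.fdr), grid.fdr, 0.0)
        col_profile = fdr.mean(axis=1)   # increasing fc threshold
        row_profile = fdr.mean(axis=0)   # increasing count threshold
        assert col_profile[0] >= col_profile[25] >= col_profile[-1] - 1e-9
        assert row_profile[0] >= row_profile[25] >= row_profile[-1] - 1e-9
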