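"""Peak-gene linking, exclusivity, motif analyses, Welch test."""
import numpy as np
import pandas as pd
import pytest

from combisig import (collapse_to_groups, dual_dominant_gene_fraction,
                      dual_motif_shuffle_null, label_exclusive_peaks,
                      link_peaks_to_genes, load_motif_groups,
                      motif_conditional_d, motif_density,
                      motif_enrichment_score,
                      peak_class_counts_by_gene_category, welch_test)


def _peaks(mids, chrom="chr1", width=150):
    return pd.DataFrame({
        "peak_id": [f"p{i}" for i in range(len(mids))], "chrom": chrom,
        "start": [m - width // 2 for m in mids],
        "end": [m + width - width // 2 for m in mids]})


class TestLinking:
    def test_window_boundary_inclusive(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "tss": [1_000_000], "strand": ["+"]})
        links = link_peaks_to_genes(_peaks([1_099_999, 1_100_001]), genes)
        assert set(links["peak_id"]) == {"p0"}   # 99,999 in; 100,001 out
        assert links["within_window"].all()

    def test_matches_brute_force_all_pairs(self, rng):
        mids = rng.integers(0, 5_000_000, 300)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)], "chrom": "chr1",
            "tss": rng.integers(0, 5_000_000, 200), "strand": "+"})
        peaks = _peaks(sorted(int(m) for m in mids))
        links = link_peaks_to_genes(peaks, genes, window_bp=100_000)
        got = set(zip(links["gene_id"], links["peak_id"]))
        expect = set()
        for g in genes.itertuples():
            for p in peaks.itertuples():
                mid = (p.start + p.end) // 2
                if abs(mid - g.tss) <= 100_000:
                    expect.add((g.gene_id, p.peak_id))
        assert got == expect

    def test_gene_without_tss_skipped(self):
        genes = pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": ["chr1", None],
                              "tss": [1000, None], "strand": ["+", "+"]})
        links = link_peaks_to_genes(_peaks([1000]), genes)
        assert set(links["gene_id"]) == {"g1"}


class TestClassCounts:
    def test_constant_counts_have_zero_width_ci(self, rng):
        links = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)] * 2,
                              "peak_id": [f"p{i}" for i in range(20)],
                              "distance": 0, "within_window": True})
        pcat = pd.DataFrame({"peak_id": [f"p{i}" for i in range(20)],
                             "category": "additive"})
        gcat = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)],
                             "category": "multiplicative"})
        out = peak_class_counts_by_gene_category(links, pcat, gcat,
                                                 n_boot=200, rng=rng)
        row = out.iloc[0]
        assert row["mean_peaks_per_gene"] == 2.0
        assert row["ci_lo"] == row["ci_hi"] == 2.0

    def test_planted_enrichment_recovered(self, rng):
        # multiplicative genes: 3 super-additive peaks; additive genes: 1
        rows, pcat_rows = [], []
        for i in range(30):
            gene, n_peaks = (f"m{i}", 3) if i < 15 else (f"a{i}", 1)
            for j in range(n_peaks):
                pid = f"{gene}_p{j}"
                rows.append((gene, pid, 0, True))
                pcat_rows.append((pid, "super_additive"))
        links = pd.DataFrame(rows, columns=["gene_id", "peak_id", "distance",
                                            "within_window"])
        pcat = pd.DataFrame(pcat_rows, columns=["peak_id", "category"])
        gcat = pd.DataFrame({
            "gene_id": [f"m{i}" for i in range(15)] + [f"a{i}" for i in
                                                       range(15, 30)],
            "category": ["multiplicative"] * 15 + ["additive"] * 15})
        out = peak_class_counts_by_gene_category(links, pcat, gcat,
                                                 n_boot=500, rng=rng)
        m = out.set_index("gene_category")["mean_peaks_per_gene"]
        assert m["multiplicative"] / m["additive"] == pytest.approx(3.0)

    def test_bootstrap_reproducible_under_fixed_seed(self):
        links = pd.DataFrame({"gene_id": ["g1", "g2", "g2"],
                              "peak_id": ["p1", "p2", "p3"],
                              "distance": 0, "within_window": True})
        pcat = pd.DataFrame({"peak_id": ["p1", "p2", "p3"],
                             "category": "additive"})
        gcat = pd.DataFrame({"gene_id": ["g1", "g2"], "category": "additive"})
        runs = [peak_class_counts_by_gene_category(
                    links, pcat, gcat, n_boot=300,
                    rng=np.random.default_rng(7)) for _ in range(2)]
        pd.testing.assert_frame_equal(runs[0], runs[1])


class TestExclusivity:
    def _resp(self, dA, dB):
        return pd.DataFrame({"feature_id": ["p"], "dose": ["medium"],
                             "dA": [dA], "dB": [dB]})

    @pytest.mark.parametrize("dA, dB, label", [
        (9.0, 1.0, "A_dominant"),     # 0.9 boundary inclusive
        (8.0, 2.0, "shared"),
        (0.0, 5.0, "B_dominant"),
    ])
    def test_labels(self, dA, dB, label):
        out = label_exclusive_peaks(self._resp(dA, dB))
        assert out["label"].iloc[0] == label

    def test_no_response_unlabeled(self):
        out = label_exclusive_peaks(self._resp(0.0, 0.0))
        assert out["label"].iloc[0] is None
        assert np.isnan(out["major_fraction"].iloc[0])

    def test_dual_dominant_fraction_planted(self, rng):
        labels = pd.DataFrame({
            "peak_id": ["pa", "pb", "pc", "pd"],
            "label": ["A_dominant", "B_dominant", "A_dominant", "shared"]})
        links = pd.DataFrame({
            "gene_id": ["dual", "dual", "mono", "mono"],
            "peak_id": ["pa", "pb", "pc", "pd"],
            "distance": 0, "within_window": True})
        gcat = pd.DataFrame({"gene_id": ["dual", "mono"],
                             "category": ["multiplicative", "multiplicative"]})
        out = dual_dominant_gene_fraction(links, labels, gcat, n_boot=200,
                                          rng=rng)
        assert out["fraction"].iloc[0] == pytest.approx(0.5)


MOTIF_GROUPS = load_motif_groups()


class TestMotifDensity:
    def test_group_collapse_takes_member_maximum(self):
        matches = pd.DataFrame({"JUN": [3], "FOS": [2], "JDP2": [2],
                                "BACH1": [1]}, index=pd.Index(["p0"],
                                                              name="peak_id"))
        grouped = collapse_to_groups(matches, MOTIF_GROUPS)
        assert grouped.loc["p0", "AP-1"] == 3

    def test_density_per_150bp(self, rng):
        peaks = _peaks([1000], width=300).assign(category="additive")
        matches = pd.DataFrame({"CTCF": [4]},
                               index=pd.Index(["p0"], name="peak_id"))
        out = motif_density(peaks, matches, MOTIF_GROUPS, n_boot=50, rng=rng)
        ctcf = out[(out["group"] == "CTCF")]
        assert ctcf["density"].iloc[0] == pytest.approx(2.0)

    def test_identical_matrices_identical_densities(self, rng):
        peaks = pd.concat([
            _peaks([1000, 3000]).assign(category="additive"),
            _peaks([5000, 7000]).assign(category="sub_additive",
                                        peak_id=["q0", "q1"])])
        matches = pd.DataFrame(
            {"CTCF": [2, 1, 2, 1], "JUN": [0, 3, 0, 3]},
            index=pd.Index(["p0", "p1", "q0", "q1"], name="peak_id"))
        out = motif_density(peaks, matches, MOTIF_GROUPS, n_boot=50, rng=rng)
        wide = out.pivot(index="group", columns="peak_category",
                         values="density")
        assert np.allclose(wide["additive"], wide["sub_additive"])

    def test_zero_width_peak_fatal(self, rng):
        peaks = pd.DataFrame({"peak_id": ["p0"], "chrom": "chr1",
                              "start": [100], "end": [100],
                              "category": ["additive"]})
        matches = pd.DataFrame({"CTCF": [1]},
                               index=pd.Index(["p0"], name="peak_id"))
        with pytest.raises(ValueError, match="zero-width"):
            motif_density(peaks, matches, MOTIF_GROUPS, rng=rng)


class TestShuffleNull:
    def _clustered(self):
        """RA matches concentrated in some peaks, TGFB in others."""
        n = 40
        peaks = _peaks(list(range(1000, 1000 + 200 * n, 200))).assign(
            category="additive")
        matches = pd.DataFrame(0, index=pd.Index(peaks["peak_id"],
                                                 name="peak_id"),
                               columns=["RARA", "JUN"])
        matches.iloc[:5, 0] = 3     # RA-dominant clusters
        matches.iloc[5:10, 1] = 3   # TGFB-dominant clusters
        return peaks, matches

    def test_observed_dual_fraction_below_shuffled_null(self):
        peaks, matches = self._clustered()
        null = dual_motif_shuffle_null(peaks, matches, MOTIF_GROUPS,
                                       n_shuffles=200, seed=8)
        row = null.per_class.iloc[0]
        assert row["observed"] == 0.0
        assert row["null_mean"] > row["observed"]
        assert row["p"] < 0.05

    def test_single_match_peaks_can_never_be_dual(self):
        peaks = _peaks([1000, 2000, 3000]).assign(category="additive")
        matches = pd.DataFrame(
            {"RARA": [1, 0, 0], "JUN": [0, 1, 1]},
            index=pd.Index(peaks["peak_id"], name="peak_id"))
        null = dual_motif_shuffle_null(peaks, matches, MOTIF_GROUPS,
                                       n_shuffles=100, seed=9)
        row = null.per_class.iloc[0]
        assert row["observed"] == 0.0
        assert (null.null_fractions["additive"] == 0.0).all()

    def test_totals_conserved_under_shuffling(self):
        # conservation is asserted inside every shuffle; this exercises it
        # on a zero-match peak, which must stay at zero
        peaks = _peaks([1000, 2000]).assign(category="additive")
        matches = pd.DataFrame(
            {"RARA": [2, 0], "JUN": [1, 0]},
            index=pd.Index(peaks["peak_id"], name="peak_id"))
        null = dual_motif_shuffle_null(peaks, matches, MOTIF_GROUPS,
                                       n_shuffles=50, seed=10)
        assert len(null.per_class) == 1  # completed without violating totals


class TestEnrichmentScore:
    def _inputs(self, lift=1.0):
        idx = pd.Index([f"p{i}" for i in range(4)], name="peak_id")
        norm = pd.DataFrame({
            "ctrl1": [10.0, 20, 30, 40], "ctrl2": [12.0, 18, 32, 38],
            "a_low1": np.array([10.0, 20, 30, 40]) * lift,
            "a_med1": np.array([12.0, 18, 32, 38]) * lift}, index=idx)
        annotations = pd.DataFrame({
            "sample_id": ["ctrl1", "ctrl2", "a_low1", "a_med1"],
            "signal": ["control", "control", "signalA", "signalA"],
            "dose": ["none", "none", "low", "medium"],
            "replicate": [1, 2, 1, 1]})
        matches = pd.DataFrame({"RARA": [1, 1, 0, 0], "GHOST": [0, 0, 0, 0]},
                               index=idx)
        return matches, norm, annotations

    def test_identical_condition_scores_zero(self):
        matches, norm, annotations = self._inputs(lift=1.0)
        s = motif_enrichment_score(matches, norm, annotations, "signalA")
        assert s["RARA"] == pytest.approx(0.0)

    def test_uniform_lift_recovered(self):
        matches, norm, annotations = self._inputs(lift=1.19)
        s = motif_enrichment_score(matches, norm, annotations, "signalA")
        assert s["RARA"] == pytest.approx(0.19)

    def test_motif_without_peaks_undefined(self):
        matches, norm, annotations = self._inputs()
        s = motif_enrichment_score(matches, norm, annotations, "signalA")
        assert np.isnan(s["GHOST"])


class TestMotifConditionalD:
    def _d(self, values):
        return pd.DataFrame({"peak_id": [f"p{i}" for i in range(len(values))],
                             "d": values})

    def test_all_zero_d_gives_zero_median(self, rng):
        matches = pd.DataFrame({"JUN": [1, 1, 0]},
                               index=pd.Index(["p0", "p1", "p2"],
                                              name="peak_id"))
        med, lo, hi = motif_conditional_d(matches, self._d([0.0, 0.0, 5.0]),
                                          "JUN", n_boot=100, rng=rng)
        assert med == 0.0

    def test_planted_super_additive_carriers(self, rng):
        d = self._d([0.5, 0.5, 0.5, 0.0, 0.0, 0.0])
        matches = pd.DataFrame({"SMAD3": [1, 1, 1, 0, 0, 0]},
                               index=pd.Index([f"p{i}" for i in range(6)],
                                              name="peak_id"))
        med, lo, hi = motif_conditional_d(matches, d, "SMAD3", n_boot=200,
                                          rng=rng)
        assert med == pytest.approx(0.5)
        assert lo <= med <= hi

    def test_universal_motif_equals_global_median(self, rng):
        d = self._d([0.1, 0.2, 0.3, 0.4])
        matches = pd.DataFrame({"CTCF": [1, 1, 1, 1]},
                               index=pd.Index([f"p{i}" for i in range(4)],
                                              name="peak_id"))
        med, _, _ = motif_conditional_d(matches, d, "CTCF", n_boot=100,
                                        rng=rng)
        assert med == pytest.approx(float(d["d"].median()))


class TestWelch:
    def test_identical_groups_p_one(self):
        assert welch_test([1.0, 2, 3], [1.0, 2, 3]) == pytest.approx(1.0)

    def test_strong_separation_significant(self):
        assert welch_test([1.0, 2, 3], [11.0, 12, 13]) < 1e-3

    def test_matches_hand_computed_oracle(self):
        # Welch statistic by textbook formulas for (5.1,4.9,5.0,5.2) vs
        # (6.0,6.1,5.9): t = -10.9697, Satterthwaite df = 4.9592,
        # two-sided p = 1.150917e-4
        p = welch_test([5.1, 4.9, 5.0, 5.2], [6.0, 6.1, 5.9])
        assert p == pytest.approx(1.1509167363355375e-4, rel=1e-9)

    def test_undersized_group_undefined(self):
        assert np.isnan(welch_test([1.0], [1.0, 2.0]))
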