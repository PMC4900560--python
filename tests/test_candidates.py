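"""Candidate selection, enrichment and profile summaries."""

import numpy as np
import pandas as pd
import pytest

import oracles
from sweepscan.candidates import (assign_feature_classes, binned_mean_bootstrap,
                                  candidate_genes, decay_profile,
                                  feature_enrichment, group_into_sweeps,
                                  nearest_gene_distance, top_snps_near_genes)
from sweepscan.panel import GeneModel


def _genes():
    return [GeneModel("g1", "chr1", 10_000, 12_000),
            GeneModel("g2", "chr1", 50_000, 55_000),
            GeneModel("g3", "chr2", 10_000, 11_000)]


def _snp_table(positions, css, fst, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "position": positions,
                         "css": css, "fst_wc": fst})


class TestGeneLinking:
    def test_inside_gene_distance_zero(self):
        d, a = nearest_gene_distance([11_000], "chr1", _genes())
        assert d[0] == 0 and a[0] == "g1"

    def test_boundary_8000_vs_8001(self):
        genes = _genes()
        t = _snp_table([12_000 + 7_999, 12_000 + 8_000], [1.0, 2.0], [0.5, 0.5])
        # distances: pos >= stop -> pos - stop + 1, so 8000 and 8001
        with pytest.warns(UserWarning, match="eligible"):
            top = top_snps_near_genes(t, genes, n=10, max_dist=8000)
        assert top["position"].tolist() == [19_999]

    def test_brute_force_nearest_gene_agreement(self):
        rng = np.random.default_rng(0)
        genes = _genes()
        pos = rng.integers(0, 70_000, 300)
        d, a = nearest_gene_distance(pos, "chr1", genes)
        for p, dd in zip(pos, d):
            want_d, _ = oracles.nearest_gene_brute(
                p, [g for g in genes if g.chromosome == "chr1"])
            assert dd == want_d

    def test_sort_order_with_tie_breaks(self):
        t = _snp_table(
            positions=[11_000, 11_100, 11_200, 11_300],
            css=[2.0, 3.0, 3.0, 3.0],
            fst=[0.9, 0.5, 0.8, 0.8])
        top = top_snps_near_genes(t, _genes(), n=4)
        # css desc, then fst desc, then position asc
        assert top["position"].tolist() == [11_200, 11_300, 11_100, 11_000]

    def test_fewer_than_n_warns_and_returns_all(self):
        t = _snp_table([11_000], [1.0], [0.5])
        with pytest.warns(UserWarning, match="eligible"):
            top = top_snps_near_genes(t, _genes(), n=1000)
        assert len(top) == 1


class TestCandidateGenes:
    def _top(self):
        return pd.DataFrame({
            "chrom": "chr1",
            "position": [11_000, 11_100, 50_500],
            "css": [3.0, 2.5, 2.0],
            "fst_wc": [0.85, 0.6, 0.79],
            "nearest_gene": ["g1", "g1", "g2"]})

    def test_threshold_filtering(self):
        cand = candidate_genes(self._top(), fst_threshold=0.8)
        kept = cand.loc[cand["kept"], "accession"].tolist()
        assert kept == ["g1"]          # g2's best linked SNP is 0.79

    def test_zero_threshold_keeps_all_linked(self):
        cand = candidate_genes(self._top(), fst_threshold=0.0)
        assert cand["kept"].all()


class TestSweepGrouping:
    def _frame(self, positions, genes, fst=0.9, chrom="chr1"):
        return pd.DataFrame({"chrom": chrom, "position": positions,
                             "css": 3.0, "fst_wc": fst,
                             "nearest_gene": genes})

    def test_nearby_outliers_one_group(self):
        top = self._frame([100_000, 110_000], ["ga", "gb"])
        cand = candidate_genes(top, 0.8)
        g = group_into_sweeps(cand, top, merge_dist=50_000)
        assert g["sweep_group"].nunique() == 1

    def test_distant_outliers_two_groups(self):
        top = self._frame([100_000, 200_000], ["ga", "gb"])
        cand = candidate_genes(top, 0.8)
        g = group_into_sweeps(cand, top, merge_dist=50_000)
        assert g["sweep_group"].nunique() == 2
        assert sorted(g["sweep_group"]) == ["A", "B"]

    def test_chain_single_linkage(self):
        top = self._frame([100_000, 140_000, 180_000], ["ga", "gb", "gc"])
        cand = candidate_genes(top, 0.8)
        g = group_into_sweeps(cand, top, merge_dist=50_000)
        assert g["sweep_group"].nunique() == 1

    def test_groups_labelled_in_genomic_order(self):
        top = self._frame([500_000, 100_000], ["gb", "ga"])
        cand = candidate_genes(top, 0.8)
        g = group_into_sweeps(cand, top, merge_dist=50_000)
        assert g.loc[g["accession"] == "ga", "sweep_group"].iloc[0] == "A"
        assert g.loc[g["accession"] == "gb", "sweep_group"].iloc[0] == "B"


class TestFeatureEnrichment:
    def test_fold_formula(self):
        top = ["CDS"] * 20 + ["intergenic"] * 80
        allc = ["CDS"] * 1000 + ["intergenic"] * 9000
        out = feature_enrichment(top, allc).set_index("feature")
        assert out.loc["CDS", "fold"] == pytest.approx((20 / 100) / (1000 / 10000))
        assert out.loc["CDS", "fold"] == pytest.approx(2.0)

    def test_no_enrichment_fold_one(self):
        top = ["CDS"] * 10 + ["intron"] * 90
        allc = ["CDS"] * 100 + ["intron"] * 900
        out = feature_enrichment(top, allc).set_index("feature")
        assert out.loc["CDS", "fold"] == pytest.approx(1.0)
        assert out.loc["CDS", "p_value"] == pytest.approx(1.0, abs=0.05)

    def test_class_counts_partition_the_sets(self):
        rng = np.random.default_rng(1)
        allc = rng.choice(["CDS", "UTR", "intron", "intergenic"], 1000)
        top = allc[rng.choice(1000, 100, replace=False)]
        out = feature_enrichment(top, allc)
        assert out["b"].sum() == 100
        assert out["B"].sum() == 1000

    def test_random_labels_average_fold_near_one(self):
        rng = np.random.default_rng(2)
        folds = []
        for _ in range(100):
            allc = rng.choice(["CDS", "intron"], 2000, p=[0.3, 0.7])
            top = allc[rng.choice(2000, 200, replace=False)]
            out = feature_enrichment(top, allc).set_index("feature")
            folds.append(out.loc["CDS", "fold"])
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)

    def test_empty_class_nan_fold(self):
        out = feature_enrichment(["CDS"] * 10, ["CDS"] * 100).set_index("feature")
        assert np.isnan(out.loc["UTR", "fold"])

    def test_precedence_in_class_assignment(self):
        feats = pd.DataFrame({
            "chrom": "c", "start": [0, 0, 0], "stop": [100, 100, 100],
            "feature": ["intron", "UTR", "CDS"]})
        cls = assign_feature_classes([50], "c", feats)
        assert cls[0] == "CDS"
        cls2 = assign_feature_classes([500], "c", feats)
        assert cls2[0] == "intergenic"


class TestBinnedMeanBootstrap:
    def _table(self, rng, n=500):
        return pd.DataFrame({"fst_wc": rng.uniform(0, 0.3, n),
                             "pbs": rng.normal(0, 0.1, n)})

    def test_constant_values_zero_width_ci(self):
        t = pd.DataFrame({"fst_wc": np.full(50, 0.12), "pbs": np.full(50, 0.7)})
        out = binned_mean_bootstrap(t, reps=50)
        assert len(out) == 1
        assert out["ci_low"].iloc[0] == out["ci_high"].iloc[0]
        assert out["ci_low"].iloc[0] == pytest.approx(0.7)

    def test_small_bins_suppressed(self):
        t = pd.DataFrame({"fst_wc": np.r_[np.full(9, 0.02), np.full(10, 0.12)],
                          "pbs": np.ones(19)})
        out = binned_mean_bootstrap(t, min_snps=10, reps=10)
        assert out["bin_start"].tolist() == [0.1]

    def test_seed_reproducible(self):
        rng = np.random.default_rng(7)
        t = self._table(rng)
        a = binned_mean_bootstrap(t, seed=5)
        b = binned_mean_bootstrap(t, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestDecayProfile:
    def test_flat_field_gives_flat_profile(self):
        w = pd.DataFrame({"value": np.full(200, 0.3)})
        out = decay_profile([100_000, 50_000], w, "value", max_dist=20_000,
                            window_bp=1000)
        np.testing.assert_allclose(out["mean"], 0.3)

    def test_planted_peak_decays_from_anchor(self):
        vals = np.zeros(200)
        vals[95:106] = np.linspace(0, 1, 11) ** 0  # plateau at peak
        vals[95:101] = [0.2, 0.4, 0.6, 0.8, 0.9, 1.0]
        vals[101:106] = [0.9, 0.8, 0.6, 0.4, 0.2]
        w = pd.DataFrame({"value": vals})
        out = decay_profile([100_500], w, "value", max_dist=10_000,
                            window_bp=1000)
        m = out["mean"].to_numpy()
        assert m[0] == pytest.approx(1.0)
        assert np.all(np.diff(m[:6]) <= 0)

    def test_anchor_at_chromosome_start_one_sided(self):
        vals = np.arange(50, dtype=float)
        w = pd.DataFrame({"value": vals})
        out = decay_profile([500], w, "value", max_dist=5000, window_bp=1000)
        # upstream windows missing -> mean equals downstream value alone
        np.testing.assert_allclose(out["mean"], vals[:6])
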