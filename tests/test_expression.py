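"""Differential-expression engine: closed forms, symmetry, planted recovery."""

import numpy as np
import pandas as pd
import pytest

from epimr import synthetic as syn
from epimr.expression import (
    CountMatrix,
    batch_specific_clusters,
    call_degs,
    cluster_samples,
    display_matrix,
    pca_samples,
    size_factors,
)


def make_cm(counts, groups):
    return CountMatrix(pd.DataFrame(counts), pd.Series(groups))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        assert np.allclose(size_factors(df), 1.0)

    def test_scaled_sample_recovered_exactly_on_noiseless_input(self):
        base = np.array([10, 50, 100, 7, 33], dtype=float)
        df = pd.DataFrame({"a": base, "b": base * 3, "c": base})
        sf = size_factors(df)
        # geometric-mean-referenced estimator: the scaled sample's factor
        # exceeds the others by exactly c
        assert abs(sf["b"] / sf["a"] - 3.0) < 1e-12
        assert abs(sf["a"] - sf["c"]) < 1e-12

    def test_single_gene_matrix_hand_value(self):
        # counts (2, 4): geometric mean sqrt(8); factors (2, 4)/sqrt(8)
        df = pd.DataFrame([[2, 4]], columns=["a", "b"])
        sf = size_factors(df)
        assert np.allclose(sf.values, [2 / np.sqrt(8), 4 / np.sqrt(8)], atol=1e-12)

    def test_no_commonly_expressed_gene_errors(self):
        df = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError, match="pseudo"):
            size_factors(df)


class TestCallDegs:
    def test_relabeled_identical_samples_yield_no_degs(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(200, 3))
        df = pd.DataFrame(
            np.hstack([counts, counts]),
            columns=["o1", "o2", "o3", "t1", "t2", "t3"],
        )
        cm = make_cm(df, {"o1": "o", "o2": "o", "o3": "o", "t1": "t", "t2": "t", "t3": "t"})
        deg = call_degs(cm, "o", "t")
        assert (deg["direction"] == "NS").all()
        assert np.allclose(deg["log2fc"], 0.0)

    def test_direction_antisymmetry_under_group_swap(self):
        cm = syn.simulate_counts(syn.planted_design(seed=3, n_genes=300, n_deg_per_direction=40))
        fwd = call_degs(cm, "origin", "tumour")
        rev = call_degs(cm, "tumour", "origin")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert (fwd["direction"] == "UP").sum() == (rev["direction"] == "DOWN").sum()
        assert (fwd["direction"] == "DOWN").sum() == (rev["direction"] == "UP").sum()

    def test_scale_invariance_of_decisions(self):
        cm = syn.simulate_counts(syn.planted_design(seed=4, n_genes=300, n_deg_per_direction=40))
        deg = call_degs(cm, "origin", "tumour")
        scaled = cm.counts.copy()
        scaled["tumour_1"] = scaled["tumour_1"] * 4
        deg2 = call_degs(CountMatrix(scaled, cm.groups), "origin", "tumour")
        assert (deg["direction"] == deg2["direction"]).mean() > 0.99

    def test_bh_q_is_monotone_in_p_rank(self):
        cm = syn.simulate_counts(syn.planted_design(seed=5, n_genes=400, n_deg_per_direction=50))
        deg = call_degs(cm, "origin", "tumour").sort_values("p")
        assert (np.diff(deg["q"].values) >= -1e-12).all()
        assert (deg["q"] >= deg["p"] - 1e-12).all()

    def test_all_zero_gene_is_ns_with_p_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.poisson(30, size=(50, 6)), columns=list("abcdef"))
        df.iloc[0] = 0
        cm = make_cm(df, dict(zip("abcdef", ["o"] * 3 + ["t"] * 3)))
        deg = call_degs(cm, "o", "t")
        assert deg.iloc[0]["p"] == 1.0 and deg.iloc[0]["direction"] == "NS"

    def test_planted_sensitivity_and_fdr(self):
        sens, fdr = [], []
        for seed in range(5):
            design = syn.planted_design(seed=seed, n_genes=1000, n_deg_per_direction=50)
            deg = call_degs(syn.simulate_counts(design), "origin", "tumour")
            true = set(design.deg_spec)
            called = set(deg.index[deg["direction"] != "NS"])
            sens.append(len(called & true) / len(true))
            fdr.append(len(called - true) / max(len(called), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr) <= 0.1

    def test_missing_group_errors(self, small_bundle):
        with pytest.raises(ValueError):
            call_degs(small_bundle.counts, "origin", "nonexistent")


class TestSampleStructure:
    def test_display_matrix_rows_are_zscores(self, small_bundle):
        dm = display_matrix(small_bundle.counts)
        sd = dm.std(axis=1, ddof=0)
        informative = small_bundle.counts.counts.std(axis=1) > 0
        assert np.allclose(dm.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(sd[informative], 1.0, atol=1e-9)

    def test_duplicated_sample_clusters_adjacently(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.poisson(40, size=(100, 4)), columns=list("abcd"))
        df["e"] = df["a"]
        dm = np.log2(df + 1)
        order = cluster_samples(dm)["order"]
        assert abs(order.index("a") - order.index("e")) == 1

    def test_planted_groups_split_perfectly(self):
        hits = 0
        for seed in range(10):
            design = syn.planted_design(seed=100 + seed, n_genes=300, n_deg_per_direction=60)
            cm = syn.simulate_counts(design)
            order = cluster_samples(display_matrix(cm))["order"]
            labels = [cm.groups[s] for s in order]
            if labels in (
                ["origin"] * 3 + ["tumour"] * 3,
                ["tumour"] * 3 + ["origin"] * 3,
            ):
                hits += 1
        assert hits >= 9

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            pca_samples(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_pca_separates_conditions(self, small_bundle):
        res = pca_samples(display_matrix(small_bundle.counts))
        pc1 = res["coordinates"]["PC1"]
        groups = small_bundle.counts.groups
        o = pc1[groups[pc1.index] == "origin"]
        t = pc1[groups[pc1.index] == "tumour"]
        assert (o.max() < t.min()) or (t.max() < o.min())


class TestBatchClusters:
    @staticmethod
    def batch_cm(seed, planted_batch=None, n_planted=50, two_batches=False):
        rng = np.random.default_rng(seed)
        n_genes = 400
        cols = {}
        groups = {}
        for b in range(3):
            for r in range(3):
                s = f"b{b + 1}_{r + 1}"
                mean = np.full(n_genes, 50.0)
                if planted_batch is not None:
                    sel = slice(0, n_planted)
                    if b + 1 == planted_batch or (two_batches and b + 1 == planted_batch + 1):
                        mean[sel] = 50.0 * 6
                cols[s] = rng.poisson(mean)
                groups[s] = f"batch{b + 1}"
        return CountMatrix(pd.DataFrame(cols), pd.Series(groups))

    def test_identical_batches_give_empty_clusters(self):
        cm = self.batch_cm(seed=0)
        clusters = batch_specific_clusters(cm)
        assert all(len(v) == 0 for v in clusters.values())

    def test_planted_batch_cluster_recovered(self):
        cm = self.batch_cm(seed=1, planted_batch=2)
        clusters = batch_specific_clusters(cm)
        planted = {cm.counts.index[i] for i in range(50)}
        assert len(clusters["batch2"] & planted) >= 45
        assert len(clusters["batch1"]) <= 2 and len(clusters["batch3"]) <= 2

    def test_gene_up_in_two_batches_assigned_to_neither(self):
        cm = self.batch_cm(seed=2, planted_batch=1, two_batches=True)
        clusters = batch_specific_clusters(cm)
        planted = {cm.counts.index[i] for i in range(50)}
        assert len(clusters["batch1"] & planted) == 0
        assert len(clusters["batch2"] & planted) == 0

    def test_fewer_than_three_batches_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            batch_specific_clusters(small_bundle.counts)
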