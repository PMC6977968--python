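"""k-means class discovery, silhouette model selection and class summaries."""

import numpy as np
import pandas as pd
import pytest

from nascentclass import classify, nascent
from nascentclass.classify import COACTIVATOR_REDUNDANT, TFIID_DEPENDENT
from nascentclass.simulate import (
    CONTRASTS,
    FEATURES_ALT,
    FEATURES_PRIMARY,
    TAF_DEGRONS,
    GeneratorParams,
    simulate,
    baseline_samples_for,
    filter_samples_for,
)
from nascentclass.annotation import analyzed_genes


def _blobs(centers, n_per, sd, seed=0, columns=None):
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for ci, center in enumerate(centers):
        rows.append(rng.normal(center, sd, size=(n_per, len(center))))
        truth += [ci] * n_per
    X = np.vstack(rows)
    genes = [f"g{i:04d}" for i in range(len(X))]
    columns = columns or [f"f{j}" for j in range(X.shape[1])]
    return (
        pd.DataFrame(X, index=pd.Index(genes, name="gene_id"), columns=columns),
        pd.Series(truth, index=genes),
    )


@pytest.fixture(scope="module")
def midsize_pipeline():
    """1200-gene synthetic dataset run through the normalization chain."""
    params = GeneratorParams(n_genes=1200, seed=11)
    ds = simulate(params, components=("counts",))
    cm = ds.count_matrix
    nm = nascent.spike_normalize(cm).loc[analyzed_genes(ds.gene_table)]
    nonzero = nascent.filter_nonzero(nm, filter_samples_for(cm))
    lengths = ds.gene_table["end"] - ds.gene_table["start"] + 1
    ranking = nascent.rank_expression(nm.loc[nonzero], baseline_samples_for(cm), lengths)
    retained = nascent.apply_expression_cutoff(nonzero, ranking, 0.05)
    means = nascent.average_replicates(nm.loc[retained], cm.samples["group"].to_dict())
    lct = nascent.log2_change(means, CONTRASTS, on_zero="drop")
    return ds, lct, ranking


class TestClusterGenes:
    def test_separable_blobs_recover_membership(self):
        lct, truth = _blobs([[0, 0], [6, 6]], 40, 0.3)
        labels = classify.cluster_genes(lct, list(lct.columns), k=2, seed=0)
        assert classify.stability_overlap(labels, truth) == 1.0

    def test_duplicated_rows_share_a_label(self):
        lct, _ = _blobs([[0, 0], [6, 6]], 10, 0.2, seed=1)
        dup = pd.concat([lct, lct.iloc[:3].set_axis([f"d{i}" for i in range(3)])])
        labels = classify.cluster_genes(dup, list(lct.columns), k=2, seed=0)
        for i in range(3):
            assert labels[f"d{i}"] == labels[lct.index[i]]

    def test_objective_beats_random_partitions(self):
        rng = np.random.default_rng(2)
        lct, _ = _blobs([[0, 0, 0]], 50, 2.0, seed=2)
        labels = classify.cluster_genes(lct, list(lct.columns), k=2, seed=0)
        X = lct.to_numpy()

        def objective(assign):
            total = 0.0
            for c in np.unique(assign):
                pts = X[assign == c]
                total += ((pts - pts.mean(axis=0)) ** 2).sum()
            return total

        best_kmeans = objective(labels.to_numpy())
        for _ in range(1000):
            random_assign = rng.integers(0, 2, len(X))
            if len(np.unique(random_assign)) < 2:
                continue
            assert best_kmeans <= objective(random_assign) + 1e-9

    def test_deterministic_given_seed_and_permutation_equivariant(self):
        lct, _ = _blobs([[0, 0], [4, 4]], 30, 0.8, seed=3)
        a = classify.cluster_genes(lct, list(lct.columns), k=2, seed=7)
        b = classify.cluster_genes(lct, list(lct.columns), k=2, seed=7)
        pd.testing.assert_series_equal(a, b)
        perm = lct.sample(frac=1, random_state=0)
        c = classify.cluster_genes(perm, list(lct.columns), k=2, seed=7)
        assert classify.stability_overlap(a, c) == 1.0

    def test_k_beyond_distinct_rows_rejected(self):
        lct = pd.DataFrame(
            [[1.0, 1.0]] * 5, index=pd.Index(list("abcde"), name="gene_id"),
            columns=["f1", "f2"],
        )
        with pytest.raises(ValueError, match="distinct"):
            classify.cluster_genes(lct, ["f1", "f2"], k=2)


class TestSelectK:
    def test_three_separated_blobs_select_three(self):
        lct, _ = _blobs([[0, 0], [8, 0], [0, 8]], 30, 0.4, seed=4)
        k, scores = classify.select_k(lct, list(lct.columns), range(2, 6), seed=0)
        assert k == 3
        assert all(-1 <= s <= 1 for s in scores.values())

    def test_two_clusters_selected_on_study_structure_across_seeds(self, midsize_pipeline):
        _, lct, _ = midsize_pipeline
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            k, _ = classify.select_k(lct, FEATURES_PRIMARY, range(2, 7), seed=seed)
            hits += k == 2
        assert hits / n_seeds >= 0.95


class TestLabeling:
    def test_larger_cluster_is_tfiid_dependent_on_study_structure(self, midsize_pipeline):
        ds, lct, _ = midsize_pipeline
        clusters = classify.cluster_genes(lct, FEATURES_PRIMARY, 2, seed=0)
        assignment = classify.label_clusters(clusters, lct, TAF_DEGRONS)
        counts = assignment.labels.value_counts()
        assert counts[TFIID_DEPENDENT] > counts[COACTIVATOR_REDUNDANT]
        assert assignment.size_consistent

    def test_true_class_recovery_at_least_95_percent(self, midsize_pipeline):
        ds, lct, _ = midsize_pipeline
        clusters = classify.cluster_genes(lct, FEATURES_PRIMARY, 2, seed=0)
        assignment = classify.label_clusters(clusters, lct, TAF_DEGRONS)
        truth = ds.truth.loc[assignment.genes, "true_class"]
        assert (assignment.labels == truth).mean() >= 0.95

    def test_cluster_index_swap_leaves_labels_unchanged(self):
        lct, truth = _blobs(
            [[-2.0, -2.0], [0.0, 0.0]], 20, 0.2, seed=5, columns=["taf", "other"]
        )
        clusters = pd.Series(truth, index=lct.index)
        a = classify.label_clusters(clusters, lct, ["taf"])
        b = classify.label_clusters(1 - clusters, lct, ["taf"])
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_adversarial_sizes_follow_taf_sensitivity_not_size(self, caplog):
        # the *smaller* blob is the Taf-sensitive one
        rng = np.random.default_rng(6)
        big = rng.normal([0.0, 0.0], 0.1, size=(30, 2))
        small = rng.normal([-3.0, -1.0], 0.1, size=(10, 2))
        lct = pd.DataFrame(
            np.vstack([big, small]),
            index=pd.Index([f"g{i}" for i in range(40)], name="gene_id"),
            columns=["taf", "other"],
        )
        clusters = pd.Series([0] * 30 + [1] * 10, index=lct.index)
        assignment = classify.label_clusters(clusters, lct, ["taf"])
        assert (assignment.labels.iloc[30:] == TFIID_DEPENDENT).all()
        assert not assignment.size_consistent


class TestStabilityOverlap:
    def test_identity_is_one(self):
        labels = pd.Series(["x", "y", "x"], index=["a", "b", "c"])
        assert classify.stability_overlap(labels, labels) == 1.0

    def test_complementary_labels_match_after_permutation(self):
        a = pd.Series(["x", "y", "x"], index=["a", "b", "c"])
        b = pd.Series(["y", "x", "y"], index=["a", "b", "c"])
        assert classify.stability_overlap(a, b) == 1.0

    def test_alternative_feature_set_reclustering_agrees(self, midsize_pipeline):
        _, lct, _ = midsize_pipeline
        primary = classify.label_clusters(
            classify.cluster_genes(lct, FEATURES_PRIMARY, 2, seed=0), lct, TAF_DEGRONS
        )
        alt = classify.label_clusters(
            classify.cluster_genes(lct, FEATURES_ALT, 2, seed=0), lct, TAF_DEGRONS
        )
        assert classify.stability_overlap(primary.labels, alt.labels) >= 0.95


class TestClassSummaries:
    def _assignment(self, labels):
        return classify.ClassAssignment(
            labels=labels, k_selected=2, silhouette_by_k={}, cluster_means=pd.DataFrame(), seed=0
        )

    def test_quintile_bins_differ_by_at_most_one(self, midsize_pipeline):
        ds, lct, ranking = midsize_pipeline
        clusters = classify.cluster_genes(lct, FEATURES_PRIMARY, 2, seed=0)
        assignment = classify.label_clusters(clusters, lct, TAF_DEGRONS)
        table = classify.quintile_composition(ranking, assignment)
        sizes = table.loc[[1, 2, 3, 4, 5], "n"]
        assert sizes.max() - sizes.min() <= 1

    def test_cr_fraction_rises_into_the_top_quintile(self, midsize_pipeline):
        ds, lct, ranking = midsize_pipeline
        clusters = classify.cluster_genes(lct, FEATURES_PRIMARY, 2, seed=0)
        assignment = classify.label_clusters(clusters, lct, TAF_DEGRONS)
        table = classify.quintile_composition(ranking, assignment)
        assert table.loc[5, "cr_fraction"] > table.loc[4, "cr_fraction"]

    def test_sensitivity_difference_zero_and_antisymmetric(self):
        lct = pd.DataFrame(
            {"taf": [-1.0, -2.0], "saga": [-1.0, -0.5]},
            index=pd.Index(["a", "b"], name="gene_id"),
        )
        ranking = pd.DataFrame({"rank": [1, 2]}, index=lct.index)
        fwd = classify.sensitivity_difference(lct, "taf", "saga", ranking)
        assert fwd.loc["a", "delta"] == pytest.approx(0.0)
        rev = classify.sensitivity_difference(lct, "saga", "taf", ranking)
        np.testing.assert_allclose(fwd["delta"], -rev["delta"])

    def test_cr_genes_more_taf_sensitive_on_study_structure(self, midsize_pipeline):
        ds, lct, ranking = midsize_pipeline
        cr = ds.truth.index[ds.truth["true_class"] == COACTIVATOR_REDUNDANT]
        cr = cr.intersection(lct.index)
        result = classify.sensitivity_difference(
            lct, "taf13_deg", "spt3_7_deg", ranking, subset=cr
        )
        assert result.attrs["mean_delta"] < 0

    def test_additivity_zero_for_exactly_additive_gene(self):
        lct = pd.DataFrame(
            {"c1": [-1.0], "c2": [-0.5], "cd": [-1.5]},
            index=pd.Index(["a"], name="gene_id"),
        )
        out = classify.additivity_check(lct, "c1", "c2", "cd")
        assert out.loc["a", "excess"] == pytest.approx(0.0)

    def test_cr_class_shows_synergistic_double_depletion_defect(self, midsize_pipeline):
        ds, lct, _ = midsize_pipeline
        clusters = classify.cluster_genes(lct, FEATURES_PRIMARY, 2, seed=0)
        assignment = classify.label_clusters(clusters, lct, TAF_DEGRONS)
        out = classify.additivity_check(
            lct, "taf13_deg", "spt3_20_deg", "taf13_spt3_deg", assignment
        )
        means = out.attrs["class_mean_excess"]
        # generator truth: CR double effect -log2(5.7) vs sum -log2(2.0*1.6)
        assert means[COACTIVATOR_REDUNDANT] < 0
        expected_tfiid = -np.log2(4.5) - (-np.log2(4.5) + 0.0)
        assert means[TFIID_DEPENDENT] == pytest.approx(expected_tfiid, abs=0.15)
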