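"""Spike normalization, gene filtering, ranking and log2-change computation."""

import numpy as np
import pandas as pd
import pytest

from nascentclass.io import CountMatrix
from nascentclass import nascent


def _cm(counts: np.ndarray, spikes, genes=None, samples=None) -> CountMatrix:
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    sheet = pd.DataFrame(
        {"spike_total": spikes}, index=pd.Index(samples, name="sample_id")
    )
    return CountMatrix(counts=frame, samples=sheet)


class TestSpikeNormalize:
    @pytest.mark.parametrize(
        "count, spike, C, expected",
        [(100, 10000, 10000, 100.0), (0, 12345, 10000, 0.0), (250, 50000, 10000, 50.0)],
    )
    def test_arithmetic(self, count, spike, C, expected):
        nm = nascent.spike_normalize(_cm(np.array([[count]]), [spike]), C)
        assert nm.iloc[0, 0] == pytest.approx(expected)

    def test_scale_invariance_of_joint_count_and_spike_rescaling(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(30, 4))
        spikes = [10000, 20000, 5000, 40000]
        nm = nascent.spike_normalize(_cm(counts, spikes))
        for factor in (3, 100, 1000):
            nm2 = nascent.spike_normalize(
                _cm(counts * factor, [s * factor for s in spikes])
            )
            assert np.allclose(nm.to_numpy(), nm2.to_numpy(), rtol=1e-9)


class TestFilterNonzero:
    def test_single_zero_among_filter_samples_excludes_gene(self):
        nm = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [0.0, 3.0]},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        assert list(nascent.filter_nonzero(nm, ["s1", "s2"])) == ["g2"]

    def test_matches_brute_force_on_random_zero_pattern(self):
        rng = np.random.default_rng(1)
        values = rng.poisson(1.0, size=(100, 8)).astype(float)
        nm = pd.DataFrame(
            values,
            index=pd.Index([f"g{i}" for i in range(100)], name="gene_id"),
            columns=[f"s{j}" for j in range(8)],
        )
        chosen = ["s0", "s3", "s7"]
        expected = [
            g for g in nm.index if all(nm.loc[g, s] > 0 for s in chosen)
        ]
        assert list(nascent.filter_nonzero(nm, chosen)) == expected

    def test_empty_filter_set_is_an_error(self):
        nm = pd.DataFrame({"s1": [1.0]}, index=pd.Index(["g1"], name="gene_id"))
        with pytest.raises(ValueError, match="empty"):
            nascent.filter_nonzero(nm, [])


class TestRanking:
    def test_shorter_gene_ranks_higher_at_equal_counts(self):
        nm = pd.DataFrame({"s1": [10.0, 10.0]}, index=pd.Index(["a", "b"], name="gene_id"))
        lengths = pd.Series({"a": 1000, "b": 500})
        ranking = nascent.rank_expression(nm, ["s1"], lengths)
        assert ranking.loc["b", "rank"] == 1
        assert ranking.loc["a", "rank"] == 2

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:02d}" for i in range(50)]
        nm = pd.DataFrame(
            rng.poisson(40, size=(50, 3)).astype(float),
            index=pd.Index(genes, name="gene_id"),
            columns=["s1", "s2", "s3"],
        )
        lengths = pd.Series(rng.integers(500, 2500, size=50), index=genes)
        ranking = nascent.rank_expression(nm, ["s1", "s2", "s3"], lengths)
        signal = {g: nm.loc[g].mean() / lengths[g] for g in genes}
        oracle = sorted(genes, key=lambda g: (-signal[g], g))
        assert list(ranking.sort_values("rank").index) == oracle

    def test_ties_break_lexicographically(self):
        nm = pd.DataFrame({"s1": [5.0, 5.0, 5.0]}, index=pd.Index(["c", "a", "b"], name="gene_id"))
        lengths = pd.Series({"a": 100, "b": 100, "c": 100})
        ranking = nascent.rank_expression(nm, ["s1"], lengths)
        assert list(ranking.sort_values("rank").index) == ["a", "b", "c"]

    def test_missing_length_names_gene(self):
        nm = pd.DataFrame({"s1": [5.0]}, index=pd.Index(["g1"], name="gene_id"))
        with pytest.raises(KeyError, match="g1"):
            nascent.rank_expression(nm, ["s1"], pd.Series(dtype=float))


class TestExpressionCutoff:
    def _ranking(self, n):
        genes = [f"g{i:05d}" for i in range(n)]
        return pd.DataFrame(
            {"rank": np.arange(1, n + 1)}, index=pd.Index(genes, name="gene_id")
        )

    def test_five_percent_of_5158_removes_258(self):
        ranking = self._ranking(5158)
        kept = nascent.apply_expression_cutoff(ranking.index, ranking, 0.05)
        assert len(kept) == 4900

    def test_zero_fraction_is_identity(self):
        ranking = self._ranking(100)
        kept = nascent.apply_expression_cutoff(ranking.index, ranking, 0.0)
        assert len(kept) == 100

    def test_five_percent_of_100_removes_5_lowest(self):
        ranking = self._ranking(100)
        kept = nascent.apply_expression_cutoff(ranking.index, ranking, 0.05)
        assert len(kept) == 95
        assert ranking.loc[kept, "rank"].max() == 95  # the 5 worst ranks dropped

    def test_filter_monotonicity(self):
        ranking = self._ranking(200)
        strict = set(nascent.apply_expression_cutoff(ranking.index, ranking, 0.05))
        loose = set(nascent.apply_expression_cutoff(ranking.index, ranking, 0.01))
        assert strict < loose


class TestCvProfile:
    def test_constant_replicates_give_zero_cv(self):
        nm = pd.DataFrame(
            {"s1": [5.0, 7.0], "s2": [5.0, 7.0]},
            index=pd.Index(["a", "b"], name="gene_id"),
        )
        ranking = nascent.rank_expression(nm, ["s1"], pd.Series({"a": 100, "b": 100}))
        table = nascent.cv_profile(nm, {"s1": "g", "s2": "g"}, [0.0, 0.5], ranking)
        assert (table["mean_cv"] == 0).all()

    def test_largest_relative_drop_where_the_noisy_tail_ends(self):
        # bottom 5% of genes are noisy; removing exactly them gives the
        # biggest relative CV decrease
        rng = np.random.default_rng(3)
        n = 100
        genes = [f"g{i:03d}" for i in range(n)]
        base = np.linspace(1000, 105, n - 5)
        quiet = np.column_stack([base, base * 1.01, base * 0.99])
        noisy = rng.uniform(1, 100, size=(5, 3))
        nm = pd.DataFrame(
            np.vstack([quiet, noisy]),
            index=pd.Index(genes, name="gene_id"),
            columns=["s1", "s2", "s3"],
        )
        lengths = pd.Series(100, index=genes)
        ranking = nascent.rank_expression(nm, ["s1", "s2", "s3"], lengths)
        groups = {"s1": "g", "s2": "g", "s3": "g"}
        table = nascent.cv_profile(nm, groups, [0.0, 0.01, 0.05, 0.10], ranking)
        assert table.loc[table["best"], "fraction"].iloc[0] == pytest.approx(0.05)

    def test_single_candidate_reports_unfiltered_cv(self):
        nm = pd.DataFrame(
            {"s1": [10.0], "s2": [20.0]}, index=pd.Index(["a"], name="gene_id")
        )
        ranking = nascent.rank_expression(nm, ["s1"], pd.Series({"a": 100}))
        table = nascent.cv_profile(nm, {"s1": "g", "s2": "g"}, [0.0], ranking)
        expected_cv = np.std([10, 20], ddof=1) / 15.0
        assert len(table) == 1
        assert table["mean_cv"].iloc[0] == pytest.approx(expected_cv)

    def test_singleton_replicate_group_rejected(self):
        nm = pd.DataFrame({"s1": [1.0]}, index=pd.Index(["a"], name="gene_id"))
        ranking = nascent.rank_expression(nm, ["s1"], pd.Series({"a": 100}))
        with pytest.raises(ValueError, match="fewer than 2"):
            nascent.cv_profile(nm, {"s1": "g"}, [0.0], ranking)


class TestAverageAndLog2:
    def test_replicate_mean(self):
        nm = pd.DataFrame(
            {"s1": [10.0], "s2": [20.0], "s3": [30.0], "s4": [7.0]},
            index=pd.Index(["a"], name="gene_id"),
        )
        means = nascent.average_replicates(
            nm, {"s1": "t", "s2": "t", "s3": "t", "s4": "c"}
        )
        assert means.loc["a", "t"] == pytest.approx(20.0)
        assert means.loc["a", "c"] == pytest.approx(7.0)  # singleton passthrough

    def test_mean_matches_numpy_oracle_on_random_fixture(self):
        rng = np.random.default_rng(4)
        nm = pd.DataFrame(
            rng.random((20, 6)),
            index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
            columns=[f"s{j}" for j in range(6)],
        )
        groups = {f"s{j}": ("a" if j < 3 else "b") for j in range(6)}
        means = nascent.average_replicates(nm, groups)
        np.testing.assert_allclose(
            means["a"].to_numpy(), nm[["s0", "s1", "s2"]].to_numpy().mean(axis=1)
        )

    @pytest.mark.parametrize("treated, control, expected", [(50, 100, -1.0), (64, 64, 0.0)])
    def test_log2_change_values(self, treated, control, expected):
        means = pd.DataFrame(
            {"t": [float(treated)], "c": [float(control)]},
            index=pd.Index(["a"], name="gene_id"),
        )
        lct = nascent.log2_change(means, {"x": ("t", "c")})
        assert lct.loc["a", "x"] == pytest.approx(expected)

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(5)
        means = pd.DataFrame(
            {"t": rng.uniform(1, 100, 30), "c": rng.uniform(1, 100, 30)},
            index=pd.Index([f"g{i}" for i in range(30)], name="gene_id"),
        )
        fwd = nascent.log2_change(means, {"x": ("t", "c")})["x"]
        rev = nascent.log2_change(means, {"x": ("c", "t")})["x"]
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy())

    def test_zero_mean_raises_by_default_and_drops_on_request(self):
        means = pd.DataFrame(
            {"t": [0.0, 4.0], "c": [2.0, 2.0]},
            index=pd.Index(["a", "b"], name="gene_id"),
        )
        with pytest.raises(ValueError, match="filter"):
            nascent.log2_change(means, {"x": ("t", "c")})
        lct = nascent.log2_change(means, {"x": ("t", "c")}, on_zero="drop")
        assert np.isnan(lct.loc["a", "x"]) and lct.loc["b", "x"] == pytest.approx(1.0)
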