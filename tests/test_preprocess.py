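"""Quantile normalization, exact signed-rank testing and DE selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from angiocompendium.preprocess import (
    ExpressionSet,
    collapse_replicates,
    quantile_normalize,
    select_de,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(diffs):
    """Independent oracle: enumerate all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / 2**n)


class TestQuantileNormalize:
    def test_hand_computed_two_by_two(self):
        out = quantile_normalize(np.array([[1.0, 3.0], [5.0, 7.0]]))
        np.testing.assert_allclose(out, [[2.0, 2.0], [6.0, 6.0]])

    def test_identical_columns_are_fixed_point(self, rng):
        col = rng.normal(size=30)
        mat = np.column_stack([col, col, col])
        np.testing.assert_allclose(quantile_normalize(mat), mat)

    def test_preserves_dataframe_labels(self, rng):
        frame = pd.DataFrame(
            rng.normal(size=(5, 3)), index=list("abcde"), columns=list("xyz")
        )
        out = quantile_normalize(frame)
        assert list(out.index) == list("abcde")
        assert list(out.columns) == list("xyz")

    @given(st.integers(0, 2**31 - 1))
    def test_columns_share_distribution_and_idempotent(self, seed):
        gen = np.random.default_rng(seed)
        mat = gen.normal(size=(12, 4))
        out = quantile_normalize(mat)
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
        np.testing.assert_allclose(quantile_normalize(out), out, atol=1e-12)

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestWilcoxonSignedRank:
    def test_all_positive_n5(self):
        # extreme rank sum W=15 appears in exactly 1 of 32 sign patterns;
        # doubling the one-sided 1/32 gives 0.0625
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0]) == pytest.approx(
            0.0625
        )

    def test_symmetric_differences_cap_at_one(self):
        # paired +d/-d differences put W at its median: least extreme
        p = wilcoxon_signed_rank([1, -1, 2, -2], [0, 0, 0, 0])
        assert p == 1.0

    def test_n6_matches_enumeration(self):
        diffs = np.array([1, 2, 3, 4, 5, -6], dtype=float)
        p = wilcoxon_signed_rank(diffs, np.zeros(6))
        assert p == pytest.approx(brute_force_signed_rank_p(diffs), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_with_ties(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(4, 11))
        # half-integer magnitudes force tied |differences|
        diffs = gen.choice([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0, 2.5], size=n)
        p = wilcoxon_signed_rank(diffs, np.zeros(n))
        assert p == pytest.approx(brute_force_signed_rank_p(diffs), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 20))
            diffs = rng.normal(size=n)
            expected = stats.wilcoxon(diffs, method="exact").pvalue
            assert wilcoxon_signed_rank(diffs, np.zeros(n)) == pytest.approx(
                expected, abs=1e-12
            )

    def test_matches_scipy_normal_approximation_above_exact_limit(self, rng):
        diffs = rng.normal(size=40)
        expected = stats.wilcoxon(diffs, method="approx", correction=True).pvalue
        assert wilcoxon_signed_rank(diffs, np.zeros(40)) == pytest.approx(
            expected, rel=1e-10
        )

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(min_value=0.1, max_value=100.0),
    )
    def test_invariant_under_positive_scaling(self, seed, factor):
        gen = np.random.default_rng(seed)
        diffs = gen.normal(size=8)
        p1 = wilcoxon_signed_rank(diffs, np.zeros(8))
        p2 = wilcoxon_signed_rank(diffs * factor, np.zeros(8))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        assert wilcoxon_signed_rank([3.0, 3.0, 3.0, 3.0], [3.0, 3.0, 3.0, 3.0]) == 1.0


class TestSelectDE:
    def test_null_zero_noise_gives_p_one(self):
        control = np.tile(np.arange(12, dtype=float), (5, 1)) + 5.0
        expr = ExpressionSet(
            gene_ids=[f"g{i}" for i in range(5)],
            control=control,
            treated=control.copy(),
            treatment="null",
        )
        table = select_de(expr)
        assert (table["p_value"] == 1.0).all()
        assert not table["significant"].any()

    def test_significance_flag_is_strict_p_below_threshold(self, rng):
        control = rng.normal(8.0, 0.25, size=(200, 12))
        treated = control + rng.normal(0.0, 0.25, size=(200, 12))
        treated[:40] += 2.0
        expr = ExpressionSet(
            gene_ids=[f"g{i}" for i in range(200)],
            control=control,
            treated=treated,
            treatment="t",
        )
        table = select_de(expr, threshold=0.003)
        assert (table["significant"] == (table["p_value"] < 0.003)).all()
        up = table["log2_fold_change"] > 0
        assert (table.loc[up, "direction"] == "up").all()
        assert (table.loc[~up, "direction"] == "down").all()

    def test_power_planted_tenfold_effect(self, rng):
        n_genes, n_planted = 300, 100
        noise = 0.25
        control = rng.normal(8.0, noise, size=(n_genes, 12))
        treated = control + rng.normal(0.0, noise, size=(n_genes, 12))
        treated[:n_planted] += 10 * noise
        expr = ExpressionSet(
            gene_ids=[f"g{i}" for i in range(n_genes)],
            control=control,
            treated=treated,
            treatment="potent",
        )
        table = select_de(expr)
        assert table["significant"][:n_planted].sum() >= 95


class TestCollapseReplicates:
    def test_mean_p_over_probes(self):
        table = pd.DataFrame(
            {
                "p_value": [0.001, 0.002],
                "log2_fold_change": [1.5, 1.0],
                "direction": ["up", "up"],
                "significant": [True, True],
            },
            index=pd.Index(["p1", "p2"], name="gene"),
        )
        collapsed = collapse_replicates(table, {"p1": "GENE", "p2": "GENE"})
        assert collapsed.loc["GENE", "p_value"] == pytest.approx(0.0015)
        assert len(collapsed) == 1

    def test_single_probe_identity(self):
        table = pd.DataFrame(
            {
                "p_value": [0.01],
                "log2_fold_change": [-0.4],
                "direction": ["down"],
                "significant": [False],
            },
            index=pd.Index(["p1"], name="gene"),
        )
        collapsed = collapse_replicates(table, {"p1": "G1"})
        assert collapsed.loc["G1", "p_value"] == 0.01
        assert collapsed.loc["G1", "direction"] == "down"

    def test_conflicting_directions_warn_and_use_mean_fold_change(self):
        table = pd.DataFrame(
            {
                "p_value": [0.001, 0.0025],
                "log2_fold_change": [2.0, -0.5],
                "direction": ["up", "down"],
                "significant": [True, True],
            },
            index=pd.Index(["p1", "p2"], name="gene"),
        )
        with pytest.warns(UserWarning, match="conflicting"):
            collapsed = collapse_replicates(table, {"p1": "G", "p2": "G"})
        assert collapsed.loc["G", "p_value"] == pytest.approx(0.00175)
        assert collapsed.loc["G", "log2_fold_change"] == pytest.approx(0.75)
        assert collapsed.loc["G", "direction"] == "up"

    def test_resignify_threshold_is_strict(self):
        # mean of 0.002 and 0.004 lands exactly on the 0.003 boundary
        table = pd.DataFrame(
            {
                "p_value": [0.002, 0.004],
                "log2_fold_change": [1.0, 1.0],
                "direction": ["up", "up"],
                "significant": [True, False],
            },
            index=pd.Index(["p1", "p2"], name="gene"),
        )
        collapsed = collapse_replicates(
            table, {"p1": "G", "p2": "G"}, resignify=True, threshold=0.003
        )
        assert collapsed.loc["G", "p_value"] == pytest.approx(0.003)
        assert not collapsed.loc["G", "significant"]

    def test_missing_mapping_raises(self):
        table = pd.DataFrame(
            {
                "p_value": [0.01],
                "log2_fold_change": [0.4],
                "direction": ["up"],
                "significant": [False],
            },
            index=pd.Index(["p1"], name="gene"),
        )
        with pytest.raises(KeyError):
            collapse_replicates(table, {})


class TestExpressionSetIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        expr = ExpressionSet(
            gene_ids=[f"g{i}" for i in range(10)],
            control=rng.normal(size=(10, 3)),
            treated=rng.normal(size=(10, 3)),
            treatment="drugA",
        )
        path = tmp_path / "expr.tsv"
        expr.to_tsv(path)
        loaded = ExpressionSet.from_tsv(path)
        assert loaded.treatment == "drugA"
        assert loaded.gene_ids == expr.gene_ids
        np.testing.assert_allclose(loaded.control, expr.control)
        np.testing.assert_allclose(loaded.treated, expr.treated)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical shape"):
            ExpressionSet(
                gene_ids=["a"],
                control=np.zeros((1, 3)),
                treated=np.zeros((1, 4)),
                treatment="x",
            )
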