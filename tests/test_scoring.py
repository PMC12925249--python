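import warnings

import numpy as np
import pytest

from usig import (
    ExpressionMatrix,
    ParameterError,
    ScoringParams,
    UndefinedStatisticError,
    UnscorableSignatureWarning,
    aggregate_scores,
    combine_pos_neg,
    parse_signature,
    score_signatures,
    u_statistic,
    ucell_component,
)

from _oracle import naive_desc_midranks, naive_scores
from conftest import make_matrix, random_signature


class TestUStatistic:
    @pytest.mark.parametrize(
        "ranks, n, expected",
        [([1, 2], 2, 0.0), ([1, 5], 2, 3.0), ([10, 10], 2, 17.0)],
    )
    def test_direct_values(self, ranks, n, expected):
        assert u_statistic(ranks, n) == expected

    def test_empty_set_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            u_statistic([], 0)

    def test_matches_pairwise_count_oracle(self):
        """On an explicit 10-gene cell, U equals the number of (signature,
        non-signature) gene pairs in which the non-signature gene wins."""
        expr = np.array([9.0, 1.0, 7.0, 3.0, 8.0, 2.0, 6.0, 4.0, 5.0, 0.0])
        sig_idx = [1, 3, 8]
        other = [i for i in range(10) if i not in sig_idx]
        ranks = [naive_desc_midranks(expr)[i] for i in sig_idx]
        pairwise = sum(
            1.0 if expr[o] > expr[s] else (0.5 if expr[o] == expr[s] else 0.0)
            for s in sig_idx
            for o in other
        )
        assert u_statistic(ranks, 3) == pairwise


class TestUcellComponent:
    @pytest.mark.parametrize(
        "ranks, n, r_max, expected",
        [
            ([1, 2], 2, 10, 1.0),
            ([1, 5], 2, 10, 1.0 - 3.0 / 17.0),
            ([10, 10], 2, 10, 0.0),
        ],
    )
    def test_closed_form(self, ranks, n, r_max, expected):
        assert ucell_component(ranks, n, r_max) == pytest.approx(expected, abs=1e-15)

    def test_undefined_when_cap_below_set_size(self):
        assert np.isnan(ucell_component([1.0, 2.0, 2.0], 3, 2))

    def test_undefined_when_umax_nonpositive(self):
        # n=1, r_max=1: U_max = 1*1 - 1 = 0
        assert np.isnan(ucell_component([1.0], 1, 1))

    def test_legacy_normalization_never_smaller(self):
        for ranks in ([1, 5], [3.5, 7.0], [10, 10]):
            v2 = ucell_component(ranks, 2, 10, legacy_norm=False)
            v1 = ucell_component(ranks, 2, 10, legacy_norm=True)
            assert v1 >= v2


class TestCombinePosNeg:
    @pytest.mark.parametrize(
        "pos, neg, w, expected",
        [(0.3, 0.5, 1.0, 0.0), (0.8, 0.2, 1.0, 0.6), (0.8, None, 1.0, 0.8),
         (0.9, 0.2, 2.0, 0.5)],
    )
    def test_combination(self, pos, neg, w, expected):
        assert combine_pos_neg(pos, neg, w) == pytest.approx(expected, abs=1e-15)

    def test_negative_weight_rejected(self):
        with pytest.raises(ParameterError):
            combine_pos_neg(0.5, 0.5, -1.0)


class TestScoreSignatures:
    def test_top_ranked_signature_scores_one(self, small_matrix):
        table = score_signatures(
            small_matrix, [parse_signature("S", ["g1", "g2"])], ScoringParams(r_max=10)
        )
        assert table.scores[0, 0] == 1.0

    def test_pos_neg_worked_example(self, small_matrix):
        """Cell [5,3,0,0], signature g1+/g3-: zeros have midrank 3.5, so the
        combined score is max(0, 1 - (1 - 2.5/9)) = 2.5/9."""
        table = score_signatures(
            small_matrix, [parse_signature("S", ["g1+", "g3-"])], ScoringParams(r_max=10)
        )
        assert table.scores[0, 0] == pytest.approx(2.5 / 9.0, abs=1e-15)

    def test_matches_naive_oracle(self, rng):
        for policy in ("impute_zero", "skip"):
            m = make_matrix(rng, 40, 12, sparsity=0.7)
            sig = random_signature(rng, list(m.gene_ids), extra_missing=2)
            params = ScoringParams(r_max=15, policy=policy)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = score_signatures(m, [sig], params).scores[:, 0]
            dense = np.asarray(m.values.todense())
            expected = naive_scores(dense, list(m.gene_ids), sig, 15, policy=policy)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_undefined_not_zero_for_unscorable(self, small_matrix):
        sig = parse_signature("S", ["nope1", "nope2"])
        with pytest.warns(UnscorableSignatureWarning):
            table = score_signatures(small_matrix, [sig], ScoringParams(r_max=10, policy="skip"))
        assert np.isnan(table.scores[0, 0])

    def test_skip_with_missing_negative_set_falls_back_to_positive(self, small_matrix):
        sig = parse_signature("S", ["g1+", "gNOPE-"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            both = score_signatures(small_matrix, [sig], ScoringParams(r_max=10, policy="skip"))
            pos_only = score_signatures(
                small_matrix, [parse_signature("S", ["g1+"])], ScoringParams(r_max=10)
            )
        assert both.scores[0, 0] == pos_only.scores[0, 0]

    def test_chunk_size_transparency(self, rng):
        m = make_matrix(rng, 30, 23, sparsity=0.6)
        sigs = [random_signature(rng, list(m.gene_ids), name=f"s{i}") for i in range(3)]
        ref = score_signatures(m, sigs, ScoringParams(r_max=10, chunk_size=23))
        for cs in (1, 7, 64):
            t = score_signatures(m, sigs, ScoringParams(r_max=10, chunk_size=cs))
            assert ref.scores.tobytes() == t.scores.tobytes()

    def test_monotonicity_in_signal(self, rng):
        """Raising the expression of all positive-set genes in one cell never
        lowers that cell's score."""
        m = make_matrix(rng, 25, 6, sparsity=0.5)
        sig = parse_signature("S", ["g0+", "g3+", "g7+"])
        params = ScoringParams(r_max=12)
        before = score_signatures(m, [sig], params).scores[:, 0]
        dense = np.asarray(m.values.todense())
        dense[[0, 3, 7], 2] += 50.0
        m2 = ExpressionMatrix(m.gene_ids, m.cell_ids, dense)
        after = score_signatures(m2, [sig], params).scores[:, 0]
        assert after[2] >= before[2]

    def test_empty_matrix_rejected(self):
        m = ExpressionMatrix(["g1"], [], np.zeros((1, 0)))
        with pytest.raises(ParameterError):
            score_signatures(m, [parse_signature("S", ["g1"])], ScoringParams(r_max=5))

    def test_scores_within_unit_interval_fuzz(self, rng):
        for _ in range(20):
            m = make_matrix(rng, int(rng.integers(5, 40)), int(rng.integers(1, 15)),
                            sparsity=float(rng.uniform(0.3, 0.95)))
            sig = random_signature(rng, list(m.gene_ids), extra_missing=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = score_signatures(m, [sig], ScoringParams(r_max=int(rng.integers(4, 20))))
            defined = t.scores[~np.isnan(t.scores)]
            assert np.all(defined >= 0.0) and np.all(defined <= 1.0)


class TestAggregateScores:
    def _table(self):
        m = ExpressionMatrix(
            ["g1", "g2"], ["c1", "c2", "c3"],
            np.array([[5.0, 1.0, 0.0], [0.0, 2.0, 3.0]]),
        )
        return score_signatures(m, [parse_signature("S", ["g1"])], ScoringParams(r_max=2))

    def test_group_means(self):
        from usig import ScoreTable

        t = ScoreTable(["c1", "c2"], ["S"], np.array([[0.2], [0.4]]))
        agg = aggregate_scores(t, {"c1": "a", "c2": "a"})
        assert agg.loc[0, "mean_score"] == pytest.approx(0.3)
        assert agg.loc[0, "n_cells"] == 2

    def test_singleton_groups_identity(self):
        from usig import ScoreTable

        t = ScoreTable(["c1", "c2"], ["S"], np.array([[0.25], [0.75]]))
        agg = aggregate_scores(t, {"c1": "x", "c2": "y"}).set_index("group")
        assert agg.loc["x", "mean_score"] == 0.25
        assert agg.loc["y", "mean_score"] == 0.75

    def test_undefined_excluded_from_mean(self):
        from usig import ScoreTable

        t = ScoreTable(["c1", "c2"], ["S"], np.array([[np.nan], [0.6]]))
        agg = aggregate_scores(t, {"c1": "g", "c2": "g"})
        assert agg.loc[0, "mean_score"] == pytest.approx(0.6)
        assert agg.loc[0, "n_defined"] == 1
        assert agg.loc[0, "n_cells"] == 2

    def test_all_undefined_group_is_nan(self):
        from usig import ScoreTable

        t = ScoreTable(["c1"], ["S"], np.array([[np.nan]]))
        agg = aggregate_scores(t, {"c1": "g"})
        assert np.isnan(agg.loc[0, "mean_score"])

    def test_unlabeled_cell_rejected(self):
        from usig import ScoreTable

        t = ScoreTable(["c1", "c2"], ["S"], np.array([[0.1], [0.2]]))
        with pytest.raises(ParameterError):
            aggregate_scores(t, {"c1": "g"})
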