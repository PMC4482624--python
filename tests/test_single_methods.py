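import math

import numpy as np
import pytest

from mirborda.io_data import ExpressionMatrix, MatchedExpressionPair
from mirborda.single_methods import (
    ScoreMatrix,
    elastic_scores,
    lasso_scores,
    mic_scores,
    pearson_scores,
    read_rankings_tsv,
    scores_to_ranking,
    write_rankings_tsv,
    zscore_knockout_scores,
)


def _pair(mir_rows, mrna_rows, mir_ids=None, gene_ids=None):
    mir_rows = np.atleast_2d(np.asarray(mir_rows, dtype=float))
    mrna_rows = np.atleast_2d(np.asarray(mrna_rows, dtype=float))
    n = mir_rows.shape[1]
    samples = [f"s{i}" for i in range(n)]
    return MatchedExpressionPair(
        ExpressionMatrix(mir_ids or [f"mir-{i}" for i in range(len(mir_rows))], samples, mir_rows),
        ExpressionMatrix(gene_ids or [f"g{i}" for i in range(len(mrna_rows))], samples, mrna_rows),
    )


def _pearson_oracle(x, y):
    mx, my = np.mean(x), np.mean(y)
    num = float(np.sum((x - mx) * (y - my)))
    den = math.sqrt(float(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2)))
    return num / den


class TestPearson:
    def test_perfect_anticorrelation(self):
        sm = pearson_scores(_pair([[1, 2, 3, 4]], [[-1, -2, -3, -4]]))
        assert sm.scores[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_mrna_undefined(self):
        sm = pearson_scores(_pair([[1, 2, 3, 4]], [[2, 2, 2, 2]]))
        assert np.isnan(sm.scores[0, 0])

    def test_matches_product_moment_formula(self, rng):
        mir = rng.normal(size=(3, 4))
        mrna = rng.normal(size=(5, 4))
        sm = pearson_scores(_pair(mir, mrna))
        for i in range(3):
            for j in range(5):
                assert sm.scores[i, j] == pytest.approx(
                    _pearson_oracle(mir[i], mrna[j]), abs=1e-12
                )

    def test_invariant_under_positive_affine_rescaling(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = pearson_scores(_pair([x], [y])).scores[0, 0]
        b = pearson_scores(_pair([3 * x + 7], [0.5 * y - 2])).scores[0, 0]
        assert a == pytest.approx(b, abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pearson_scores(_pair([[1, 2]], [[3, 4]]))


def _orthonormal_pair(rng, n=32, p=5):
    """miRNA design with X'X = n*I, columns mean 0 and unit population sd."""
    A = rng.normal(size=(n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    X = math.sqrt(n) * Q[:, :p]
    beta = rng.normal(size=p)
    y = X @ beta + 0.1 * rng.normal(size=n)
    return X, y


class TestLasso:
    def test_lambda_above_max_zeroes_everything(self, rng):
        X, y = _orthonormal_pair(rng)
        ys = (y - y.mean()) / y.std()
        lam_max = np.max(np.abs(X.T @ ys)) / len(y)
        sm = lasso_scores(_pair(X.T, [y]), lam=lam_max * 1.01)
        assert np.all(sm.scores == 0)

    def test_soft_threshold_closed_form_on_orthonormal_design(self, rng):
        lam = 0.08
        X, y = _orthonormal_pair(rng)
        ys = (y - y.mean()) / y.std()
        b_ols = X.T @ ys / len(y)
        expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
        sm = lasso_scores(_pair(X.T, [y]), lam=lam)
        np.testing.assert_allclose(sm.scores[:, 0], expected, atol=1e-6)

    def test_near_zero_penalty_recovers_ols(self, rng):
        X, y = _orthonormal_pair(rng, n=50, p=3)
        ys = (y - y.mean()) / y.std()
        b_ols = np.linalg.lstsq(X, ys, rcond=None)[0]
        sm = lasso_scores(_pair(X.T, [y]), lam=1e-10)
        np.testing.assert_allclose(sm.scores[:, 0], b_ols, atol=1e-6)

    def test_planted_regulator_most_negative(self, rng):
        n = 200
        mir = rng.normal(size=(6, n))
        target = -2.0 * mir[2] + 0.1 * rng.normal(size=n)
        sm = lasso_scores(_pair(mir, [target]), lam=0.01)
        assert np.argmin(sm.scores[:, 0]) == 2
        assert sm.scores[2, 0] < 0

    def test_zero_variance_response_warns_and_zeroes(self, rng):
        mir = rng.normal(size=(3, 20))
        with pytest.warns(UserWarning, match="zero-variance"):
            sm = lasso_scores(_pair(mir, [np.full(20, 3.0)]), lam=0.1)
        assert np.all(sm.scores == 0)

    def test_cv_lambda_is_seed_deterministic(self, rng):
        mir = rng.normal(size=(4, 40))
        y = -mir[0] + 0.5 * rng.normal(size=40)
        a = lasso_scores(_pair(mir, [y]), lam="cv", seed=7).scores
        b = lasso_scores(_pair(mir, [y]), lam="cv", seed=7).scores
        np.testing.assert_array_equal(a, b)


class TestElasticNet:
    def test_pure_l1_mix_reduces_to_lasso(self, rng):
        mir = rng.normal(size=(5, 30))
        y = -mir[1] + mir[3] + 0.2 * rng.normal(size=30)
        a = lasso_scores(_pair(mir, [y]), lam=0.05).scores
        b = elastic_scores(_pair(mir, [y]), alpha_mix=1.0, lam=0.05).scores
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_small_l1_share_approaches_ridge(self, rng):
        lam = 0.05
        l1r = 0.01
        X, y = _orthonormal_pair(rng, n=40, p=4)
        ys = (y - y.mean()) / y.std()
        n = len(y)
        # closed-form ridge for the elastic-net objective with the l1 part dropped
        ridge = np.linalg.solve(
            X.T @ X / n + lam * (1 - l1r) * np.eye(4), X.T @ ys / n
        )
        sm = elastic_scores(_pair(X.T, [y]), alpha_mix=l1r, lam=lam)
        np.testing.assert_allclose(sm.scores[:, 0], ridge, atol=5e-3)

    def test_huge_penalty_zeroes_everything(self, rng):
        mir = rng.normal(size=(4, 30))
        y = mir.sum(axis=0)
        sm = elastic_scores(_pair(mir, [y]), alpha_mix=0.5, lam=1e6)
        assert np.all(sm.scores == 0)

    def test_mix_outside_range_rejected(self, rng):
        with pytest.raises(ValueError):
            elastic_scores(_pair(np.zeros((1, 12)), np.zeros((1, 12))), alpha_mix=0.0)


class TestKnockoutZscore:
    def test_hand_worked_example(self):
        # miRNA minimal in the first sample; mRNA (1,2,3): z = (1-2)/1 = -1
        sm = zscore_knockout_scores(_pair([[0.0, 5.0, 9.0]], [[1.0, 2.0, 3.0]]))
        assert sm.scores[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_value_at_knockout_equal_to_mean_gives_zero(self):
        sm = zscore_knockout_scores(_pair([[9.0, 0.0, 5.0]], [[1.0, 2.0, 3.0]]))
        assert sm.scores[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_mrna_scores_zero(self):
        sm = zscore_knockout_scores(_pair([[0.0, 1.0, 2.0]], [[4.0, 4.0, 4.0]]))
        assert sm.scores[0, 0] == 0.0

    def test_tied_minimum_uses_first_sample(self):
        sm = zscore_knockout_scores(_pair([[0.0, 0.0, 1.0]], [[1.0, 3.0, 2.0]]))
        # first minimum is s0 -> z = (1 - 2) / 1 = -1
        assert sm.scores[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_invariant_to_affine_rescaling_of_mrna(self, rng):
        mir = rng.normal(size=(1, 15))
        y = rng.normal(size=15)
        a = zscore_knockout_scores(_pair(mir, [y])).scores[0, 0]
        b = zscore_knockout_scores(_pair(mir, [5 * y + 3])).scores[0, 0]
        assert a == pytest.approx(b, abs=1e-12)


def _ranking_oracle(genes, values, sign_informative):
    """Brute-force composite-key comparator, independent of the library sort."""
    def bucket(v):
        if np.isnan(v):
            return 3
        if not sign_informative:
            return 0
        return 0 if v < 0 else (1 if v > 0 else 2)

    def magnitude(v):
        if np.isnan(v):
            return 0.0
        return v if not sign_informative else abs(v)

    return [
        g
        for g, v in sorted(
            zip(genes, values), key=lambda t: (bucket(t[1]), -magnitude(t[1]), t[0])
        )
    ]


class TestScoresToRanking:
    def _sm(self, genes, values, sign=True):
        return ScoreMatrix(["mir-x"], genes, [values], "test", sign)

    def test_negative_first_by_magnitude(self):
        r = scores_to_ranking(self._sm(["A", "B", "C"], [-0.9, -0.1, 0.95]), "mir-x")
        assert r.gene_ids == ["A", "B", "C"]

    def test_equal_scores_fall_back_to_lexicographic(self):
        r = scores_to_ranking(self._sm(["c", "a", "b"], [0.5, 0.5, 0.5]), "mir-x")
        assert r.gene_ids == ["a", "b", "c"]

    def test_zeros_after_positives_and_undefined_last(self):
        r = scores_to_ranking(
            self._sm(["neg", "pos", "zero", "und"], [-0.1, 0.9, 0.0, np.nan]), "mir-x"
        )
        assert r.gene_ids == ["neg", "pos", "zero", "und"]

    def test_mic_ranking_is_descending_magnitude(self):
        r = scores_to_ranking(
            self._sm(["A", "B", "C"], [0.2, 0.9, 0.5], sign=False), "mir-x"
        )
        assert r.gene_ids == ["B", "C", "A"]

    @pytest.mark.parametrize("sign", [True, False])
    def test_matches_brute_force_comparator(self, rng, sign):
        for _ in range(25):
            genes = [f"g{i}" for i in range(12)]
            vals = np.round(rng.normal(size=12), 1)  # rounding forces ties
            if not sign:
                vals = np.abs(vals)
            vals[rng.random(12) < 0.2] = np.nan
            r = scores_to_ranking(self._sm(genes, vals, sign), "mir-x")
            assert r.gene_ids == _ranking_oracle(genes, vals, sign)
            assert [e[2] for e in r.entries] == list(range(1, 13))

    def test_ranking_is_a_permutation_of_all_genes(self, small_study):
        _, pair, _ = small_study
        sm = pearson_scores(pair)
        for m in pair.mirnas.feature_ids:
            r = scores_to_ranking(sm, m)
            assert sorted(r.gene_ids) == sorted(pair.mrnas.feature_ids)

    def test_magnitude_only_ignores_sign(self):
        r = scores_to_ranking(
            self._sm(["A", "B", "C"], [-0.3, 0.9, -0.5]), "mir-x", magnitude_only=True
        )
        assert r.gene_ids == ["B", "C", "A"]

    def test_unknown_mirna_rejected(self):
        with pytest.raises(KeyError):
            scores_to_ranking(self._sm(["A"], [1.0]), "nope")


class TestMicScores:
    def test_symmetry_and_range(self, rng):
        mir = rng.normal(size=(2, 40))
        mrna = rng.normal(size=(2, 40))
        sm = mic_scores(_pair(mir, mrna))
        assert not sm.sign_informative
        assert np.all((sm.scores >= 0) & (sm.scores <= 1))

    def test_sample_floor(self, rng):
        with pytest.raises(ValueError):
            mic_scores(_pair(rng.normal(size=(1, 8)), rng.normal(size=(1, 8))))


class TestRankingTSVRoundTrip:
    def test_round_trip(self, tmp_path, small_study):
        _, pair, _ = small_study
        sm = pearson_scores(pair)
        rankings = {
            "pearson": {m: scores_to_ranking(sm, m) for m in pair.mirnas.feature_ids}
        }
        p = tmp_path / "r.tsv"
        write_rankings_tsv(rankings, p, header_lines=["seed=1"])
        back = read_rankings_tsv(p)
        assert set(back) == {"pearson"}
        for m in rankings["pearson"]:
            assert back["pearson"][m].entries == rankings["pearson"][m].entries
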