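import math

import numpy as np
import pytest

from relse import chains, delta
from relse.coefficients import odd_even_partition
from relse.delta import BoundaryError
from relse.montecarlo import coefficient_samples, sample_frequency_tables
from relse.patterns import ScoreMatrix, compress_values
from tests.conftest import calibration_gap, make_scores


def generic_se(builder, values, *args):
    table = compress_values(values)
    return delta.se_generic(builder(table, *args), table)


class TestSeMean:
    def test_ml_and_conventional_hand_values(self):
        x = np.array([0.0, 1.0, 0.0, 1.0])
        assert delta.se_mean(x).se == pytest.approx(0.25)
        assert delta.se_mean(x, variant="conventional").se == pytest.approx(
            math.sqrt((1.0 / 3.0) / 4.0)
        )

    def test_constant_variable(self):
        assert delta.se_mean(np.full(5, 2.0)).se == 0.0

    def test_agrees_with_generic_engine(self):
        x = make_scores(1, n=45, k=1, levels=3).values[:, 0]
        gen = generic_se(chains.mean_chain, x)
        est = delta.se_mean(x)
        assert est.se == pytest.approx(gen.se, rel=1e-12)
        assert est.value == pytest.approx(gen.value, rel=1e-12)


class TestSeCovariance:
    def test_constant_variable_gives_zero_se(self):
        x = np.full(10, 3.0)
        y = np.arange(10.0)
        est = delta.se_covariance(x, y)
        assert est.se == 0.0
        assert "constant-variable" in est.flags

    def test_exact_and_large_n_forms_converge(self):
        base = make_scores(4, n=30, k=2).values
        rel = []
        for m in (1, 10, 100):
            values = np.tile(base, (m, 1))
            exact = delta.se_covariance(values[:, 0], values[:, 1])
            approx = delta.se_covariance(values[:, 0], values[:, 1], large_n=True)
            rel.append(abs(exact.se - approx.se) / exact.se)
        assert rel[0] > rel[1] > rel[2]
        assert rel[2] < 1e-3

    @pytest.mark.parametrize("seed", [4, 14, 24])
    def test_agrees_with_generic_engine(self, seed):
        values = make_scores(seed, n=60, k=2, levels=3).values
        est = delta.se_covariance(values[:, 0], values[:, 1])
        gen = generic_se(chains.covariance_chain, values)
        assert est.se == pytest.approx(gen.se, rel=1e-10)

    def test_frechet_boundary_raises(self):
        # comonotone pair: the covariance attains its upper bound
        x = np.array([0.0, 0, 1, 1, 2, 2])
        with pytest.raises(BoundaryError):
            delta.se_covariance(x, 2 * x)


class TestSeVarianceAndSd:
    def test_sd_is_variance_se_over_2s(self):
        x = make_scores(6, n=50, k=1, levels=3).values[:, 0]
        var_est = delta.se_variance(x)
        sd_est = delta.se_sd(x)
        s = math.sqrt(var_est.value)
        assert sd_est.se == pytest.approx(var_est.se / (2 * s), rel=1e-15)
        assert sd_est.value == pytest.approx(s, rel=1e-15)

    def test_constant_variable_zero_se(self):
        est = delta.se_variance(np.full(8, 1.0))
        assert est.se == 0.0
        with pytest.raises(ValueError):
            delta.se_sd(np.full(8, 1.0))

    def test_dichotomous_at_half_is_boundary(self):
        x = np.array([0.0, 0, 0, 1, 1, 1])
        with pytest.raises(BoundaryError):
            delta.se_variance(x)
        with pytest.raises(BoundaryError):
            delta.se_sd(x)

    def test_dichotomous_near_half_flagged(self):
        x = np.array([0.0] * 499 + [1.0] * 501)
        est = delta.se_variance(x)
        assert "near-boundary" in est.flags
        assert est.se > 0

    def test_agrees_with_generic_engine(self):
        x = make_scores(8, n=70, k=1, levels=4).values[:, 0]
        est = delta.se_variance(x)
        gen = generic_se(chains.variance_chain, x)
        assert est.se == pytest.approx(gen.se, rel=1e-10)
        sd_gen = generic_se(chains.sd_chain, x)
        assert delta.se_sd(x).se == pytest.approx(sd_gen.se, rel=1e-10)


class TestSeCorrelation:
    def test_perfect_correlation_zero_se_with_flag(self):
        x = np.array([0.0, 1, 2, 1, 0])
        est = delta.se_correlation(x, x)
        assert est.value == 1.0
        assert est.se == 0.0
        assert "at-boundary" in est.flags

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            delta.se_correlation(np.full(5, 1.0), np.arange(5.0))

    @pytest.mark.parametrize("seed", [5, 15, 25])
    def test_agrees_with_generic_engine(self, seed):
        values = make_scores(seed, n=80, k=2).values
        est = delta.se_correlation(values[:, 0], values[:, 1])
        gen = generic_se(chains.correlation_chain, values)
        assert est.se == pytest.approx(gen.se, rel=1e-8)

    def test_se_smooth_as_r_approaches_one(self):
        # flip ever fewer entries of y = x: r climbs toward 1, SE shrinks
        n = 4096
        x = np.tile([0.0, 1.0], n // 2)
        ses = []
        for flips in (512, 64, 8, 1):
            y = x.copy()
            y[:flips] = 1.0 - y[:flips]
            est = delta.se_correlation(x, y)
            assert np.isfinite(est.se)
            ses.append(est.se)
        assert all(a > b for a, b in zip(ses, ses[1:]))

    def test_location_invariance(self):
        values = make_scores(9, n=60, k=2).values
        base = delta.se_correlation(values[:, 0], values[:, 1])
        shifted = delta.se_correlation(values[:, 0] + 7.0, values[:, 1])
        assert shifted.se == pytest.approx(base.se, rel=1e-12)


class TestSeSplitHalf:
    def test_zero_half_correlation_doubles_se(self):
        values = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]] * 5)
        scores = ScoreMatrix(values)
        est = delta.se_split_half(scores, ((0,), (1,)))
        r_est = delta.se_correlation(values[:, 0], values[:, 1])
        assert r_est.value == pytest.approx(0.0)
        assert est.se == pytest.approx(2 * r_est.se, rel=1e-12)

    def test_agrees_with_generic_engine(self, dichotomous_scores):
        part = odd_even_partition(dichotomous_scores.n_items)
        est = delta.se_split_half(dichotomous_scores, part)
        halves = np.column_stack(
            [
                dichotomous_scores.values[:, part[0]].sum(axis=1),
                dichotomous_scores.values[:, part[1]].sum(axis=1),
            ]
        )
        gen = generic_se(chains.split_half_chain, halves)
        assert est.se == pytest.approx(gen.se, rel=1e-8)

    def test_matches_multinomial_resampling_sd(self, dichotomous_scores):
        part = odd_even_partition(dichotomous_scores.n_items)
        halves = np.column_stack(
            [
                dichotomous_scores.values[:, part[0]].sum(axis=1),
                dichotomous_scores.values[:, part[1]].sum(axis=1),
            ]
        )
        analytic, mc_sd, mc_se = calibration_gap(
            "split_half", chains.split_half_chain, halves, 500, 10000, 77
        )
        assert abs(analytic - mc_sd) < 3 * mc_se


class TestCoefficientCovariance:
    def test_diagonal_matches_scalar_ses(self, dichotomous_scores):
        values = dichotomous_scores.values[:, :2]
        W = delta.coefficient_covariance(values).matrix
        d = np.sqrt(np.diag(W)).reshape(2, 2)
        assert d[0, 0] == pytest.approx(delta.se_variance(values[:, 0]).se, rel=1e-10)
        assert d[1, 1] == pytest.approx(delta.se_variance(values[:, 1]).se, rel=1e-10)
        assert d[0, 1] == pytest.approx(
            delta.se_covariance(values[:, 0], values[:, 1]).se, rel=1e-10
        )
        assert d[0, 1] == pytest.approx(d[1, 0], rel=1e-12)

    def test_duplicated_item_symmetry(self):
        x = make_scores(12, n=40, k=1, levels=3).values[:, 0]
        W = delta.coefficient_covariance(np.column_stack([x, x])).matrix
        # all four entries of vec S are the same statistic here
        np.testing.assert_allclose(W, W[0, 0] * np.ones((4, 4)), rtol=1e-10)

    def test_matches_resampling_covariance(self):
        values = make_scores(18, n=120, k=2).values
        table = compress_values(values)
        p = table.freqs / table.total
        n = int(table.total)
        rng = np.random.default_rng(99)
        draws = sample_frequency_tables(p, n, 8000, rng)
        totals = draws.sum(axis=1)
        R = table.patterns
        m1 = draws @ R / n
        prod = np.einsum("ci,cj->cij", R, R).reshape(R.shape[0], -1)
        m2 = (draws @ prod / n).reshape(-1, 2, 2)
        S = n / (n - 1.0) * (m2 - np.einsum("bi,bj->bij", m1, m1))
        emp = np.cov(S.reshape(-1, 4), rowvar=False)
        W = delta.coefficient_covariance(values).matrix
        np.testing.assert_allclose(W, emp, atol=4 * np.abs(emp).max() / math.sqrt(8000) + 2e-5)


class TestSeLambdas:
    def test_lambda3_ratio_is_exact(self, dichotomous_scores):
        k = dichotomous_scores.n_items
        e1 = delta.se_lambda1(dichotomous_scores)
        e3 = delta.se_lambda3(dichotomous_scores)
        assert e3.se / e1.se == pytest.approx(k / (k - 1.0), rel=1e-15)
        assert e3.value / e1.value == pytest.approx(k / (k - 1.0), rel=1e-12)

    @pytest.mark.parametrize(
        "builder,closed",
        [
            (chains.lambda1_chain, delta.se_lambda1),
            (chains.lambda2_chain, delta.se_lambda2),
            (chains.lambda3_chain, delta.se_lambda3),
        ],
    )
    def test_agree_with_generic_engine(self, builder, closed, polytomous_scores):
        table = compress_values(polytomous_scores.values)
        gen = delta.se_generic(builder(table), table)
        est = closed(polytomous_scores)
        assert est.se == pytest.approx(gen.se, rel=1e-8)
        assert est.value == pytest.approx(gen.value, rel=1e-10)

    def test_zero_covariances_use_epsilon_device(self):
        # a full factorial design: all inter-item covariances exactly zero
        values = np.array(
            [[a, b, c] for a in (0.0, 1) for b in (0.0, 1) for c in (0.0, 1)]
        )
        scores = ScoreMatrix(np.tile(values, (3, 1)))
        est = delta.se_lambda2(scores)
        assert "epsilon-device" in est.flags
        # in the epsilon limit the sqrt term's gradient vanishes
        assert est.se == pytest.approx(delta.se_lambda1(scores).se, rel=1e-6)

    def test_relabeling_invariance(self, dichotomous_scores):
        perm = [2, 0, 3, 1]
        permuted = ScoreMatrix(dichotomous_scores.values[:, perm])
        for f in (delta.se_lambda1, delta.se_lambda2, delta.se_lambda3):
            assert f(permuted).se == pytest.approx(
                f(dichotomous_scores).se, rel=1e-10
            )

    def test_location_invariance(self, polytomous_scores):
        shifted = ScoreMatrix(polytomous_scores.values + np.array([3.0, 0.0, 1.0]))
        for f in (delta.se_lambda1, delta.se_lambda2, delta.se_lambda3):
            assert f(shifted).se == pytest.approx(
                f(polytomous_scores).se, rel=1e-10
            )

    def test_matches_multinomial_resampling_sd(self, dichotomous_scores):
        analytic, mc_sd, mc_se = calibration_gap(
            "lambda3", chains.lambda3_chain, dichotomous_scores.values, 500, 10000, 55
        )
        assert abs(analytic - mc_sd) < 3 * mc_se


class TestSeGeneric:
    def test_full_and_homogeneous_forms_agree(self, dichotomous_scores):
        pair = compress_values(dichotomous_scores.values[:, :2])
        est = delta.se_generic(chains.correlation_chain(pair), pair)
        assert "variance_homogeneous" in est.extra
        assert est.extra["variance_homogeneous"] == pytest.approx(
            est.extra["variance_full"], rel=1e-10
        )

    def test_homogeneous_form_absent_for_unbiased_variance(self):
        x = make_scores(2, n=30, k=1, levels=3).values[:, 0]
        table = compress_values(x)
        est = delta.se_generic(chains.variance_chain(table), table)
        assert "variance_homogeneous" not in est.extra

    def test_single_pattern_zero_se(self):
        table = compress_values(np.full(6, 2.0))
        est = delta.se_generic(chains.mean_chain(table), table)
        assert est.se == pytest.approx(0.0, abs=1e-12)
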