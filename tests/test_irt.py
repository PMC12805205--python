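import numpy as np
import pytest

from relse.irt import (
    ItemParams,
    SimulationDesign,
    generate_data,
    population_values,
    response_probability,
    sample_item_params,
)


def single_item(a=1.0, b=0.0, gamma=0.0, delta=0.0, xi=1.0, w=(1.0, 0.0)):
    return ItemParams(
        a=np.array([[a, a]]),
        b=np.array([[b, b]]),
        gamma=np.array([gamma]),
        delta=np.array([delta]),
        xi=np.array([xi]),
        w=np.array([w]),
    )


class TestResponseProbability:
    def test_2pl_symmetry_point(self):
        p = response_probability(single_item(), np.array([[0.0, 0.0]]))
        assert p[0, 0] == pytest.approx(0.5)

    def test_upper_asymptote(self):
        p = response_probability(single_item(delta=0.1), np.array([[40.0, 0.0]]))
        assert p[0, 0] == pytest.approx(0.9)

    def test_lower_asymptote(self):
        p = response_probability(single_item(gamma=0.2), np.array([[-40.0, 0.0]]))
        assert p[0, 0] == pytest.approx(0.2)

    def test_acceleration_exponent_at_location(self):
        p = response_probability(single_item(xi=2.0), np.array([[0.0, 0.0]]))
        assert p[0, 0] == pytest.approx(0.25)

    def test_monotone_in_theta(self):
        thetas = np.column_stack([np.linspace(-4, 4, 30), np.zeros(30)])
        p = response_probability(single_item(xi=1.7, gamma=0.1, delta=0.05), thetas)
        assert np.all(np.diff(p[:, 0]) > 0)
        assert np.all(p >= 0.1) and np.all(p <= 0.95)

    def test_invalid_asymptotes_rejected(self):
        with pytest.raises(ValueError):
            single_item(gamma=0.6, delta=0.6)
        with pytest.raises(ValueError):
            single_item(xi=0.0)


class TestSampleItemParams:
    def test_2plm_sets_neutral_parameters(self):
        design = SimulationDesign(n_respondents=100, n_items=10, model="2PLM", seed=4)
        params = sample_item_params(design)
        assert np.all(params.gamma == 0)
        assert np.all(params.delta == 0)
        assert np.all(params.xi == 1)

    def test_deterministic_under_seed(self):
        design = SimulationDesign(n_respondents=100, n_items=5, model="5PAM", seed=9)
        a = sample_item_params(design)
        b = sample_item_params(design)
        np.testing.assert_array_equal(a.a, b.a)
        np.testing.assert_array_equal(a.xi, b.xi)

    def test_locations_evenly_spaced_with_extremes(self):
        design = SimulationDesign(n_respondents=100, n_items=10, seed=1)
        params = sample_item_params(design)
        np.testing.assert_allclose(params.b[:, 0], np.linspace(-2, 2, 10))

    def test_dimension_loadings(self):
        d2 = SimulationDesign(n_respondents=100, n_items=6, dimensionality=2, seed=0)
        params = sample_item_params(d2)
        np.testing.assert_allclose(params.w[0::2], [[1.0, 0.5]] * 3)
        np.testing.assert_allclose(params.w[1::2], [[0.0, 1.0]] * 3)
        d1 = SimulationDesign(n_respondents=100, n_items=6, dimensionality=1, seed=0)
        np.testing.assert_allclose(sample_item_params(d1).w, [[1.0, 0.0]] * 6)


class TestGenerateData:
    def test_shape_and_alphabet(self):
        design = SimulationDesign(n_respondents=100, n_items=10, seed=2)
        scores = generate_data(design, sample_item_params(design))
        assert scores.values.shape == (100, 10)
        assert set(np.unique(scores.values)) <= {0.0, 1.0}

    def test_degenerate_probability_gives_coin_flips(self):
        design = SimulationDesign(n_respondents=4000, n_items=3, seed=6)
        params = single_item(gamma=0.5, delta=0.5)
        params = ItemParams(
            a=np.ones((3, 2)),
            b=np.zeros((3, 2)),
            gamma=np.full(3, 0.5),
            delta=np.full(3, 0.5),
            xi=np.ones(3),
            w=np.tile([1.0, 0.0], (3, 1)),
        )
        scores = generate_data(design, params, seed=8)
        se = 0.5 / np.sqrt(4000)
        assert np.all(np.abs(scores.values.mean(axis=0) - 0.5) < 3 * se)

    def test_same_seed_reproduces(self):
        design = SimulationDesign(n_respondents=50, n_items=4, seed=3)
        params = sample_item_params(design)
        a = generate_data(design, params, seed=11)
        b = generate_data(design, params, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_neutral_5pam_reproduces_2plm_bit_for_bit(self):
        d5 = SimulationDesign(n_respondents=200, n_items=6, model="5PAM", seed=13)
        d2 = SimulationDesign(n_respondents=200, n_items=6, model="2PLM", seed=13)
        p5 = sample_item_params(d5)
        p2 = sample_item_params(d2)
        np.testing.assert_array_equal(p5.a, p2.a)  # drawn before the 5PAM extras
        neutral = ItemParams(
            a=p5.a, b=p5.b, gamma=np.zeros(6), delta=np.zeros(6),
            xi=np.ones(6), w=p5.w,
        )
        np.testing.assert_array_equal(
            generate_data(d5, neutral, seed=21).values,
            generate_data(d2, p2, seed=21).values,
        )


class TestPopulationValues:
    def test_monte_carlo_agreement_across_seeds(self):
        design = SimulationDesign(n_respondents=100, n_items=4, seed=5)
        params = sample_item_params(design)
        a = population_values(design, params, m=100_000, seed=1)
        b = population_values(design, params, m=100_000, seed=2)
        np.testing.assert_allclose(a.item_means, b.item_means, atol=0.01)
        assert a.lambda3 == pytest.approx(b.lambda3, abs=0.02)

    def test_m_floor_enforced(self):
        design = SimulationDesign(n_respondents=100, n_items=4, seed=5)
        with pytest.raises(ValueError):
            population_values(design, sample_item_params(design), m=10_000)

    def test_disjoint_dimensions_give_uncorrelated_items(self):
        design = SimulationDesign(
            n_respondents=100, n_items=2, dimensionality=2, seed=7, rho=0.0,
            odd_weights=(1.0, 0.0), even_weights=(0.0, 1.0),
        )
        params = sample_item_params(design)
        rep = population_values(design, params, m=200_000, seed=3)
        assert abs(rep.correlations[0, 1]) < 0.01

    def test_exchangeable_items_have_equal_covariances(self):
        design = SimulationDesign(n_respondents=100, n_items=3, seed=8)
        params = sample_item_params(design)
        equal = ItemParams(
            a=np.ones((3, 2)), b=np.zeros((3, 2)), gamma=params.gamma,
            delta=params.delta, xi=params.xi, w=params.w,
        )
        rep = population_values(design, equal, m=200_000, seed=4)
        off = [rep.covariances[0, 1], rep.covariances[0, 2], rep.covariances[1, 2]]
        assert max(off) - min(off) < 0.01
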