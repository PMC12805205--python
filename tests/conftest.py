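import numpy as np
import pytest

from relse.patterns import ScoreMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


def make_scores(seed: int, n: int = 60, k: int = 4, levels: int = 2) -> ScoreMatrix:
    """Random correlated discrete score matrix (a latent-trait mixture so
    items are positively correlated, as reliability data usually are)."""

    r = np.random.default_rng(seed)
    theta = r.normal(size=(n, 1))
    cuts = np.linspace(-1.0, 1.0, k)[None, :]
    latent = theta + r.normal(scale=1.2, size=(n, k)) - cuts
    if levels == 2:
        values = (latent > 0).astype(float)
    else:
        edges = np.quantile(latent, np.linspace(0, 1, levels + 1)[1:-1])
        values = np.digitize(latent, edges).astype(float)
    # guard against degenerate constant columns
    for j in range(k):
        if np.all(values[:, j] == values[0, j]):
            values[0, j] = 1.0 - values[0, j] if levels == 2 else values[0, j] + 1
    return ScoreMatrix(values)


def calibration_gap(kind, builder, values, n, n_draws, seed):
    """Analytic SE at expected frequencies n*p versus the Monte-Carlo SD of
    the coefficient over multinomial draws at the same p.

    Returns (analytic_se, mc_sd, mc_se_of_sd): the analytic value should sit
    within a few Monte-Carlo standard errors of the simulated SD.
    """

    from relse.explog import jacobian
    from relse.montecarlo import coefficient_samples, sample_frequency_tables
    from relse.patterns import compress_values

    table = compress_values(values)
    p = table.freqs / table.total
    expected = n * p
    G = jacobian(builder(table), expected).ravel()
    var = float(expected @ (G * G) - (expected @ G) ** 2 / n)
    analytic = np.sqrt(max(var, 0.0))
    draws = sample_frequency_tables(p, n, n_draws, np.random.default_rng(seed))
    vals = coefficient_samples(kind, table.patterns, draws)
    vals = vals[np.isfinite(vals)]
    mc_sd = float(vals.std(ddof=1))
    mc_se = mc_sd / np.sqrt(2.0 * (vals.size - 1))
    return analytic, mc_sd, mc_se


@pytest.fixture
def dichotomous_scores():
    return make_scores(11, n=80, k=4, levels=2)


@pytest.fixture
def polytomous_scores():
    return make_scores(13, n=90, k=3, levels=3)
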