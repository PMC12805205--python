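"""Vectorised coefficient evaluation over multinomial frequency draws.

Used as the Monte-Carlo oracle: for fixed pattern probabilities p, the SD of
a coefficient across many Multinomial(N, p) draws estimates the true
sampling SD that the analytic delta-method SE approximates.  Evaluation is
vectorised across draws so that 10,000 resamples cost a few matrix
products.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_frequency_tables", "coefficient_samples"]


def sample_frequency_tables(
    probs: np.ndarray, n: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws x categories matrix of Multinomial(n, probs) frequency vectors."""

    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    return rng.multinomial(n, probs, size=n_draws).astype(float)


def _moments(patterns: np.ndarray, freqs: np.ndarray):
    """First and second raw-moment blocks per draw.

    Returns (N, m1 (B x k), m2 (B x k x k)) with ML moments.
    """

    patterns = np.asarray(patterns, dtype=float)
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    totals = freqs.sum(axis=1, keepdims=True)
    k = patterns.shape[1]
    m1 = freqs @ patterns / totals
    prod = np.einsum("ci,cj->cij", patterns, patterns).reshape(patterns.shape[0], -1)
    m2 = (freqs @ prod / totals).reshape(-1, k, k)
    return totals.ravel(), m1, m2


def _cov_unbiased(patterns, freqs):
    N, m1, m2 = _moments(patterns, freqs)
    c_ml = m2 - np.einsum("bi,bj->bij", m1, m1)
    return N, m1, (N / (N - 1.0))[:, None, None] * c_ml, c_ml


def coefficient_samples(
    kind: str,
    patterns: np.ndarray,
    freqs: np.ndarray,
    partition_sizes: tuple[int, int] | None = None,
) -> np.ndarray:
    """Coefficient value for each frequency draw.

    kind in {"mean", "covariance", "variance", "sd", "correlation",
    "split_half", "lambda1", "lambda2", "lambda3"}.  For the two-variable
    kinds the pattern table must hold the two variables; for split_half the
    two half sums; for lambdas all k items.
    """

    patterns = np.asarray(patterns, dtype=float)
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    if kind == "mean":
        N, m1, _ = _moments(patterns, freqs)
        return m1[:, 0]
    N, m1, S, c_ml = _cov_unbiased(patterns, freqs)
    k = patterns.shape[1]
    if kind == "covariance":
        return S[:, 0, 1]
    if kind == "variance":
        return S[:, 0, 0]
    if kind == "sd":
        return np.sqrt(S[:, 0, 0])
    if kind in ("correlation", "split_half"):
        with np.errstate(invalid="ignore", divide="ignore"):
            r = c_ml[:, 0, 1] / np.sqrt(c_ml[:, 0, 0] * c_ml[:, 1, 1])
        if kind == "correlation":
            return r
        with np.errstate(invalid="ignore", divide="ignore"):
            return 2.0 * r / (1.0 + r)
    if kind in ("lambda1", "lambda2", "lambda3"):
        V = S.sum(axis=(1, 2))
        T1 = np.trace(S, axis1=1, axis2=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            lam1 = 1.0 - T1 / V
            if kind == "lambda1":
                return lam1
            if kind == "lambda3":
                return k / (k - 1.0) * lam1
            diag_sq = np.einsum("bii->b", S**2)
            c2 = (S**2).sum(axis=(1, 2)) - diag_sq
            return lam1 + np.sqrt(k / (k - 1.0) * c2) / V
    raise ValueError(f"unknown coefficient kind {kind!r}")
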