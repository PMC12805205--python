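"""Confidence intervals: Wald/t intervals for delta-method SEs, the
benchmark intervals they are compared against (Feldt's F-based interval for
Cronbach's alpha, the Fisher-Z interval for a correlation, normal-theory SEs
for variance/SD/covariance), and the Agresti-Coull interval for coverage
proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from relse.delta import CoefficientEstimate

__all__ = [
    "ConfInterval",
    "wald_ci",
    "feldt_ci",
    "fisher_z_ci",
    "normal_theory_se",
    "agresti_coull",
]


@dataclass(frozen=True)
class ConfInterval:
    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("interval endpoints out of order")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def wald_ci(est: CoefficientEstimate, level: float = 0.95) -> ConfInterval:
    """theta-hat +/- quantile * SE.

    The mean uses a t quantile with df = N - 1 (carried in the estimate);
    every other coefficient uses the normal deviate.  Wald intervals are not
    range-preserving and are reported unclipped.
    """

    if est.se is None or not np.isfinite(est.se):
        raise ValueError("estimate has no defined SE")
    if est.coefficient == "mean" and "df" in est.extra:
        q = float(stats.t.ppf(0.5 + level / 2.0, df=est.extra["df"]))
        method = "wald-t"
    else:
        q = float(stats.norm.ppf(0.5 + level / 2.0))
        method = "wald"
    return ConfInterval(est.value - q * est.se, est.value + q * est.se, level, method)


def feldt_ci(alpha_hat: float, n: int, k: int, level: float = 0.95) -> ConfInterval:
    """Feldt's interval for Cronbach's alpha under the ANOVA model.

    Uses F quantiles with N-1 and (N-1)(k-1) degrees of freedom applied to
    1 - alpha-hat.
    """

    if alpha_hat >= 1:
        raise ValueError("alpha must be below 1")
    if n < 3 or k < 2:
        raise ValueError("Feldt interval needs N >= 3 and k >= 2")
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    tail = (1.0 - level) / 2.0
    f_lo = float(stats.f.ppf(tail, df1, df2))
    f_hi = float(stats.f.ppf(1.0 - tail, df1, df2))
    lower = 1.0 - (1.0 - alpha_hat) * f_hi
    upper = 1.0 - (1.0 - alpha_hat) * f_lo
    return ConfInterval(lower, upper, level, "feldt")


def fisher_z_ci(r: float, n: int, level: float = 0.95) -> ConfInterval:
    """Fisher-Z interval: atanh(r) +/- z / sqrt(N - 3), back-transformed."""

    if abs(r) >= 1:
        raise ValueError("Fisher-Z interval requires |r| < 1")
    if n < 4:
        raise ValueError("Fisher-Z interval needs N >= 4")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    center = math.atanh(r)
    half = z / math.sqrt(n - 3.0)
    return ConfInterval(math.tanh(center - half), math.tanh(center + half), level, "fisher-z")


def normal_theory_se(kind: str, *, n: int, sd: float | None = None,
                     sd_x: float | None = None, sd_y: float | None = None,
                     cov: float | None = None) -> CoefficientEstimate:
    """Benchmark SEs assuming normally distributed scores.

    variance: SE(s^2) = s^2 sqrt(2/(N-1)); sd: SE(s) = s / sqrt(2(N-1));
    covariance (bivariate normal): SE(s_xy) = sqrt((s_x^2 s_y^2 + s_xy^2)/(N-1)).
    These are exact under normality and serve as the contrast with the
    multinomial delta-method SEs on discrete data.
    """

    if n < 2:
        raise ValueError("N >= 2 required")
    if kind == "variance":
        if sd is None:
            raise ValueError("variance benchmark needs sd")
        value = sd**2
        se = sd**2 * math.sqrt(2.0 / (n - 1.0))
    elif kind == "sd":
        if sd is None or sd <= 0:
            raise ValueError("sd benchmark needs a positive sd")
        value = sd
        se = sd / math.sqrt(2.0 * (n - 1.0))
    elif kind == "covariance":
        if sd_x is None or sd_y is None or cov is None:
            raise ValueError("covariance benchmark needs sd_x, sd_y, cov")
        value = cov
        se = math.sqrt((sd_x**2 * sd_y**2 + cov**2) / (n - 1.0))
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}")
    return CoefficientEstimate(
        kind, float(value), float(se), f"benchmark-normal-{kind}", (), {"n": n}
    )


def agresti_coull(successes: int, trials: int, level: float = 0.95) -> ConfInterval:
    """Adjusted binomial interval: p-tilde = (x + z^2/2)/(n + z^2),
    half-width z sqrt(p-tilde (1 - p-tilde) / (n + z^2)); lower endpoint
    clipped at 0, upper at 1."""

    if not 0 <= successes <= trials or trials < 1:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    n_tilde = trials + z**2
    p_tilde = (successes + z**2 / 2.0) / n_tilde
    half = z * math.sqrt(p_tilde * (1.0 - p_tilde) / n_tilde)
    return ConfInterval(
        max(p_tilde - half, 0.0), min(p_tilde + half, 1.0), level, "agresti-coull"
    )
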