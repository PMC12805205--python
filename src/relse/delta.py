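"""Delta-method standard errors under multinomial sampling.

The frequency vector n of observed response patterns is one draw from a
multinomial distribution with estimated covariance matrix
V(n) = diag(n) - n n'/N.  For a coefficient theta = g(n) with Jacobian G,
the estimated asymptotic variance is G V(n) G'; when g is homogeneous of
order 0 this reduces to G diag(n) G'.

Every coefficient is served by two routes:

* closed forms -- exact first-order derivatives of the estimator with
  respect to n, expressed in sample moments (this module);
* the generic engine -- :func:`se_generic` differentiates the coefficient's
  exp-log chain by the chain rule.

The two must agree to numerical precision; the test-suite enforces this on
random fixtures.

Boundary behaviour: a coefficient sitting on the edge of its parameter
space does not admit a delta-method SE.  A constant variable legitimately
yields SE 0 for covariance-type coefficients; a covariance at the Frechet
bound of its margins, or a variance whose delta variance vanishes while the
variable is non-constant (a dichotomous item at sample proportion 1/2),
raises :class:`BoundaryError`.  |r| = 1 reports SE 0 with a boundary flag.
A vanishing sum of squared inter-item covariances makes the lambda-2
gradient 0/0; a descending-epsilon limit is used there and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from relse.coefficients import half_sums
from relse.explog import ExpLogChain, evaluate as chain_evaluate, jacobian as chain_jacobian, is_homogeneous_order0
from relse.patterns import ResponsePatternTable, ScoreMatrix, compress_values

__all__ = [
    "CoefficientEstimate",
    "CoefficientCovariance",
    "BoundaryError",
    "AT_BOUNDARY_TOL",
    "NEAR_BOUNDARY_TOL",
    "se_generic",
    "se_mean",
    "se_covariance",
    "se_variance",
    "se_sd",
    "se_correlation",
    "se_split_half",
    "se_lambda1",
    "se_lambda2",
    "se_lambda3",
    "coefficient_covariance",
]

#: a coefficient is *at* its boundary within this tolerance, *near* it
#: within the second; near-boundary estimates are flagged, at-boundary ones
#: either report SE 0 (where the limit exists) or raise BoundaryError.
AT_BOUNDARY_TOL = 1e-12
NEAR_BOUNDARY_TOL = 1e-3
_EPS_LADDER = (1e-4, 1e-5, 1e-6, 1e-7, 1e-8, 1e-9, 1e-10)


class BoundaryError(ValueError):
    """The coefficient lies on the boundary of the parameter space and its
    delta-method SE does not exist."""


@dataclass(frozen=True)
class CoefficientEstimate:
    coefficient: str
    value: float
    se: float
    method: str
    flags: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se is not None and np.isfinite(self.se) and self.se < 0:
            raise ValueError("standard error cannot be negative")

    def to_dict(self) -> dict:
        return {
            "coefficient": self.coefficient,
            "value": self.value,
            "se": self.se,
            "method": self.method,
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class CoefficientCovariance:
    """Estimated covariance matrix W of vec(S), row-major (i, j) order."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    flags: tuple[str, ...] = ()

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def entry(self, i: int, j: int, k: int, l: int) -> float:
        m = self.n_items
        return float(self.matrix[i * m + j, k * m + l])


# ---------------------------------------------------------------------------
# shared moment machinery on pattern tables

def _gvar(n: np.ndarray, g: np.ndarray) -> float:
    """g V(n) g' computed stably as sum(n g^2) - (sum(n g))^2 / N."""

    total = float(n.sum())
    s = float(n @ g)
    return float(n @ (g * g)) - s * s / total


def _as_values(scores, variables) -> np.ndarray:
    if isinstance(scores, ScoreMatrix):
        cols = [scores.column(v) for v in variables]
        return scores.values[:, cols]
    arr = np.asarray(scores, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr[:, list(variables)] if arr.shape[1] > len(variables) else arr


def _column(scores, variable) -> np.ndarray:
    if isinstance(scores, ScoreMatrix):
        return scores.values[:, scores.column(0 if variable is None else variable)]
    arr = np.asarray(scores, dtype=float)
    if arr.ndim == 2:
        return arr[:, 0 if variable is None else int(variable)]
    return arr.ravel()


def _two_columns(scores, var1, var2) -> tuple[np.ndarray, np.ndarray]:
    """Resolve (x, y) from a ScoreMatrix + two names, a two-column array,
    or a pair of plain 1-D arrays."""

    if isinstance(scores, ScoreMatrix):
        x = scores.values[:, scores.column(0 if var1 is None else var1)]
        y = scores.values[:, scores.column(1 if var2 is None else var2)]
        return x, y
    arr = np.asarray(scores, dtype=float)
    if arr.ndim == 1 or (arr.ndim == 2 and arr.shape[1] == 1):
        if var1 is None:
            raise ValueError("second variable required for a two-variable SE")
        return arr.ravel(), np.asarray(var1, dtype=float).ravel()
    i = 0 if var1 is None else int(var1)
    j = 1 if var2 is None else int(var2)
    return arr[:, i], arr[:, j]


def _low_n_flags(N: float) -> tuple[str, ...]:
    return ("low-N",) if N <= 2 else ()


# ---------------------------------------------------------------------------
# generic engine route

def se_generic(chain: ExpLogChain, table: ResponsePatternTable) -> CoefficientEstimate:
    """Delta-method SE through the exp-log chain engine.

    The variance is G V(n) G'; for a chain homogeneous of order 0 the
    simplified form G diag(n) G' is also computed and the two are verified
    to agree.
    """

    n = table.freqs
    value = chain_evaluate(chain, n)
    if value.shape[0] != 1:
        raise ValueError("se_generic expects a scalar-valued chain")
    G = chain_jacobian(chain, n).ravel()
    var13 = max(_gvar(n, G), 0.0)
    extra = {"variance_full": var13, "n": table.total}
    if is_homogeneous_order0(chain, n):
        var14 = float(n @ (G * G))
        extra["variance_homogeneous"] = var14
        scale = max(var13, var14, 1e-30)
        if abs(var13 - var14) > 1e-8 * scale:
            raise AssertionError(
                "full and homogeneous variance forms disagree on a chain "
                "verified to be homogeneous of order 0"
            )
    return CoefficientEstimate(
        coefficient=chain.name or "chain",
        value=float(value[0]),
        se=math.sqrt(var13),
        method="generic-delta",
        flags=_low_n_flags(table.total),
        extra=extra,
    )


# ---------------------------------------------------------------------------
# closed forms

def se_mean(scores, variable=None, variant: str = "ml") -> CoefficientEstimate:
    """SE of the sample mean.

    variant="ml" is the delta-method result sqrt(sigma^2_ML / N) (the
    maximum-likelihood variance, no bias correction); variant="conventional"
    is s/sqrt(N) with the unbiased variance, which is the estimate to prefer
    in practice.  Both carry df = N-1 so that the Wald interval uses a t
    quantile.
    """

    x = _column(scores, variable)
    N = x.shape[0]
    mean = float(x.mean())
    if variant == "ml":
        var = float(np.mean((x - mean) ** 2)) / N
        method = "closed-form"
    elif variant == "conventional":
        var = float(np.var(x, ddof=1)) / N
        method = "benchmark-conventional"
    else:
        raise ValueError(f"unknown mean SE variant {variant!r}")
    return CoefficientEstimate(
        coefficient="mean",
        value=mean,
        se=math.sqrt(var),
        method=method,
        flags=_low_n_flags(N),
        extra={"n": N, "df": N - 1},
    )


def _frechet_bounds_ml(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Largest/smallest ML covariance attainable given the two margins
    (comonotone and antimonotone couplings of the empirical distributions)."""

    xs = np.sort(x)
    ys = np.sort(y)
    n = x.shape[0]
    exy_max = float(xs @ ys) / n
    exy_min = float(xs @ ys[::-1]) / n
    mx, my = float(x.mean()), float(y.mean())
    return exy_min - mx * my, exy_max - mx * my


def _cov_core(x: np.ndarray, y: np.ndarray, same: bool):
    N = x.shape[0]
    dx = x - x.mean()
    dy = y - y.mean()
    d = dx * dy
    c_ml = float(d.mean())
    m22 = float((d * d).mean())
    return N, c_ml, m22, dx, dy


def se_covariance(
    scores, var1=None, var2=None, large_n: bool = False
) -> CoefficientEstimate:
    """SE of the unbiased covariance.

    Exact form: Var = N (m22 - c^2) / (N-1)^2 with ML central moments
    m22 = mean[(x - xbar)^2 (y - ybar)^2] and c the ML covariance; the
    large-sample form drops the N^2/(N-1)^2 factor.  A constant variable
    gives SE 0; a covariance at the Frechet bound of its margins has no SE.
    """

    x, y = _two_columns(scores, var1, var2)
    N, c_ml, m22, dx, dy = _cov_core(x, y, same=False)
    value = N / (N - 1.0) * c_ml
    flags = list(_low_n_flags(N))
    if np.all(dx == 0) or np.all(dy == 0):
        return CoefficientEstimate(
            "covariance", value, 0.0,
            "closed-form-large-N" if large_n else "closed-form",
            tuple(flags) + ("constant-variable",), {"n": N},
        )
    lo, hi = _frechet_bounds_ml(x, y)
    span = max(hi - lo, abs(hi), abs(lo), 1e-30)
    if min(c_ml - lo, hi - c_ml) <= AT_BOUNDARY_TOL * span:
        raise BoundaryError(
            "covariance attains the Frechet bound of its margins; "
            "the delta-method SE does not exist"
        )
    if min(c_ml - lo, hi - c_ml) <= NEAR_BOUNDARY_TOL * span:
        flags.append("near-boundary")
    core = max(m22 - c_ml * c_ml, 0.0)
    if large_n:
        var = core / N
        method = "closed-form-large-N"
    else:
        var = N * core / (N - 1.0) ** 2
        method = "closed-form"
    return CoefficientEstimate(
        "covariance", value, math.sqrt(var), method, tuple(flags), {"n": N}
    )


def se_variance(scores, variable=None, large_n: bool = False) -> CoefficientEstimate:
    """SE of the unbiased variance (the covariance of a variable with itself).

    The Frechet-bound case degenerates here: at the boundary the delta
    variance itself vanishes while the variable is non-constant (for a
    dichotomous item this happens exactly at sample proportion 1/2), and the
    SE does not exist.
    """

    x = _column(scores, variable)
    N, c_ml, m22, dx, _ = _cov_core(x, x, same=True)
    value = N / (N - 1.0) * c_ml
    flags = list(_low_n_flags(N))
    if np.all(dx == 0):
        return CoefficientEstimate(
            "variance", value, 0.0,
            "closed-form-large-N" if large_n else "closed-form",
            tuple(flags) + ("constant-variable",), {"n": N},
        )
    core = m22 - c_ml * c_ml
    if core <= AT_BOUNDARY_TOL * m22:
        raise BoundaryError(
            "variance is at the boundary of its parameter space (zero delta "
            "variance for a non-constant variable); the SE does not exist"
        )
    support = np.unique(x)
    if support.shape[0] == 2:
        vmax = ((support[1] - support[0]) / 2.0) ** 2
        if abs(c_ml - vmax) <= NEAR_BOUNDARY_TOL * vmax:
            flags.append("near-boundary")
    if large_n:
        var = core / N
        method = "closed-form-large-N"
    else:
        var = N * core / (N - 1.0) ** 2
        method = "closed-form"
    return CoefficientEstimate(
        "variance", value, math.sqrt(var), method, tuple(flags), {"n": N}
    )


def se_sd(scores, variable=None, large_n: bool = False) -> CoefficientEstimate:
    """SE of the unbiased SD: SE(s) = SE(s^2) / (2 s) (delta method for sqrt)."""

    est = se_variance(scores, variable, large_n=large_n)
    if est.value <= 0:
        raise ValueError("standard deviation is zero; its SE is undefined")
    s = math.sqrt(est.value)
    return CoefficientEstimate(
        "sd", s, est.se / (2.0 * s), est.method, est.flags, dict(est.extra)
    )


def _corr_gradient(x: np.ndarray, y: np.ndarray):
    """Per-observation gradient terms of r and the value of r."""

    N = x.shape[0]
    sx = math.sqrt(float(np.mean((x - x.mean()) ** 2)))
    sy = math.sqrt(float(np.mean((y - y.mean()) ** 2)))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant variable")
    xt = (x - x.mean()) / sx
    yt = (y - y.mean()) / sy
    r = float(np.mean(xt * yt))
    g = (xt * yt - 0.5 * r * (xt * xt + yt * yt)) / N
    return r, g


def se_correlation(scores, var1=None, var2=None) -> CoefficientEstimate:
    """SE of the product-moment correlation.

    Var(r) = sum_c n_c g_c^2 with g = (xt yt - r/2 (xt^2 + yt^2)) / N in
    ML-standardised scores (the gradient sums to zero over the sample).
    |r| = 1 is the boundary: SE 0 by definition, flagged.
    """

    x, y = _two_columns(scores, var1, var2)
    N = x.shape[0]
    r, g = _corr_gradient(x, y)
    if abs(r) > 1 + 1e-9:
        raise ValueError(f"numerically invalid correlation {r}")
    flags = list(_low_n_flags(N))
    if 1.0 - abs(r) <= AT_BOUNDARY_TOL:
        return CoefficientEstimate(
            "correlation", float(np.sign(r)), 0.0, "closed-form",
            tuple(flags) + ("at-boundary",), {"n": N},
        )
    if 1.0 - abs(r) <= NEAR_BOUNDARY_TOL:
        flags.append("near-boundary")
    var = max(float(np.sum(g * g)), 0.0)
    return CoefficientEstimate(
        "correlation", r, math.sqrt(var), "closed-form", tuple(flags), {"n": N}
    )


def se_split_half(scores: ScoreMatrix, partition) -> CoefficientEstimate:
    """SE of the split-half coefficient: |d SH / d r| SE(r) = 2/(1+r)^2 SE(r)."""

    halves = half_sums(scores, partition)
    est_r = se_correlation(halves[:, 0], halves[:, 1])
    r = est_r.value
    if 1.0 + r <= AT_BOUNDARY_TOL:
        raise BoundaryError("half correlation is -1; split-half coefficient undefined")
    value = 2.0 * r / (1.0 + r)
    se = 2.0 / (1.0 + r) ** 2 * est_r.se
    return CoefficientEstimate(
        "split_half", value, se, "closed-form", est_r.flags,
        {"n": est_r.extra["n"], "half_correlation": r},
    )


# ---------------------------------------------------------------------------
# lambda coefficients via the covariance matrix of vec(S)

def _vec_s_gradient(values: np.ndarray):
    """Pattern table plus the k^2 x C matrix of gradients of the unbiased
    variances/covariances s_ij with respect to the frequency vector."""

    table = compress_values(values)
    R, n = table.patterns, table.freqs
    N = table.total
    k = R.shape[1]
    mean = (n @ R) / N
    dev = R - mean
    D = np.einsum("ci,cj->ijc", dev, dev).reshape(k * k, -1)
    c_ml = (D @ n) / N
    G = (D - c_ml[:, None]) / (N - 1.0) - (c_ml / (N - 1.0) ** 2)[:, None]
    return table, G, c_ml


def coefficient_covariance(scores) -> CoefficientCovariance:
    """Estimated covariance matrix W of the stacked inter-item variances and
    covariances vec(S) (row-major), W = Ghat V(n) Ghat'."""

    values = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    if values.shape[1] < 2:
        raise ValueError("coefficient covariance requires at least two items")
    table, G, _ = _vec_s_gradient(values)
    n = table.freqs
    Gn = G @ n
    W = (G * n) @ G.T - np.outer(Gn, Gn) / table.total
    W = (W + W.T) / 2.0
    labels = (
        scores.labels
        if isinstance(scores, ScoreMatrix)
        else tuple(f"v{i + 1}" for i in range(values.shape[1]))
    )
    flags = []
    k = values.shape[1]
    diag = np.diag(W).reshape(k, k)
    if np.any(np.diag(diag) <= AT_BOUNDARY_TOL * np.maximum(np.diag(diag).max(), 1e-30)):
        flags.append("boundary-entries")
    return CoefficientCovariance(W, labels, tuple(flags))


def _lambda_pieces(values: np.ndarray):
    k = values.shape[1]
    S = np.cov(values, rowvar=False, ddof=1)
    V = float(S.sum())
    T1 = float(np.trace(S))
    C2 = float((S**2).sum() - (np.diag(S) ** 2).sum())
    if V <= 0:
        raise ValueError("sum-score variance is zero; lambda SEs undefined")
    return k, S, V, T1, C2


def _lambda_var_from_grad(values: np.ndarray, grad_vecS: np.ndarray) -> float:
    table, G, _ = _vec_s_gradient(values)
    u = grad_vecS @ G
    return max(_gvar(table.freqs, u), 0.0), table.total


def se_lambda1(scores) -> CoefficientEstimate:
    values = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    k, S, V, T1, _ = _lambda_pieces(values)
    value = 1.0 - T1 / V
    grad = np.full((k, k), T1 / V**2)
    grad[np.diag_indices(k)] = -1.0 / V + T1 / V**2
    var, N = _lambda_var_from_grad(values, grad.ravel())
    return CoefficientEstimate(
        "lambda1", value, math.sqrt(var), "closed-form", _low_n_flags(N), {"n": N}
    )


def se_lambda3(scores) -> CoefficientEstimate:
    """SE(lambda3) = k/(k-1) SE(lambda1), exactly."""

    est = se_lambda1(scores)
    values = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    k = values.shape[1]
    f = k / (k - 1.0)
    return CoefficientEstimate(
        "lambda3", f * est.value, f * est.se, est.method, est.flags, dict(est.extra)
    )


def _lambda2_grad(k: int, S: np.ndarray, V: float, T1: float, Q: float) -> np.ndarray:
    grad = np.full((k, k), (T1 - Q) / V**2)
    grad += (k / (k - 1.0)) * S / (Q * V)
    d = np.diag_indices(k)
    grad[d] = -1.0 / V + (T1 - Q) / V**2  # no C2 contribution from diagonals
    return grad.ravel()


def se_lambda2(scores) -> CoefficientEstimate:
    """SE of Guttman's lambda-2.

    With C2 = 0 (all inter-item covariances zero) the sqrt term's gradient
    is 0/0; the SE is then obtained as the descending-epsilon limit of the
    gradient with sqrt(k/(k-1) C2) replaced by sqrt(k/(k-1)) * eps, stopping
    once consecutive values agree to 1e-6 relative.
    """

    values = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    k, S, V, T1, C2 = _lambda_pieces(values)
    fac = k / (k - 1.0)
    value = 1.0 - T1 / V + math.sqrt(fac * C2) / V
    flags = []
    scale = (T1 / k) ** 2
    if C2 > AT_BOUNDARY_TOL * scale:
        Q = math.sqrt(fac * C2)
        var, N = _lambda_var_from_grad(values, _lambda2_grad(k, S, V, T1, Q))
    else:
        flags.append("epsilon-device")
        prev = None
        var = None
        for eps in _EPS_LADDER:
            Q = math.sqrt(fac) * eps * max(T1 / k, 1.0)
            var, N = _lambda_var_from_grad(values, _lambda2_grad(k, S, V, T1, Q))
            se = math.sqrt(var)
            if prev is not None and abs(se - prev) <= 1e-6 * max(prev, 1e-30):
                break
            prev = se
    est_flags = tuple(flags) + _low_n_flags(values.shape[0])
    return CoefficientEstimate(
        "lambda2", value, math.sqrt(var), "closed-form", est_flags,
        {"n": values.shape[0]},
    )
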