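"""Exp-log chain constructions for the reliability coefficients.

Each builder takes a response-pattern table and returns an
:class:`~relse.explog.ExpLogChain` computing the coefficient from the
frequency vector n.  Construction follows two conventions that keep every
log and sqrt inside its domain:

* pattern values are shifted per variable so that the smallest value is 1
  (shifting leaves variances, covariances, correlations and the lambda
  coefficients unchanged; the mean chain undoes its shift with a final
  affine step);
* a coefficient that is a difference of ratios of positive aggregates is
  assembled by dividing each positive term separately in log space and
  taking the difference with a final linear step, so no log ever sees a
  possibly-negative quantity.

Unbiased (N-1 denominator) estimators need the sample size minus one, which
enters through a constant offset of -1 on a row computing N.
"""

from __future__ import annotations

import numpy as np

from relse.explog import ChainStep, ExpLogChain
from relse.patterns import ResponsePatternTable

__all__ = [
    "mean_chain",
    "covariance_chain",
    "variance_chain",
    "sd_chain",
    "correlation_chain",
    "split_half_chain",
    "lambda1_chain",
    "lambda2_chain",
    "lambda3_chain",
    "vec_s_chain",
]


def _shifted(table: ResponsePatternTable, var: int) -> tuple[np.ndarray, float]:
    col = table.patterns[:, var]
    shift = 1.0 - col.min()
    return col + shift, shift


def mean_chain(table: ResponsePatternTable, var: int = 0) -> ExpLogChain:
    x, shift = _shifted(table, var)
    ones = np.ones_like(x)
    steps = (
        ChainStep(np.vstack([x, ones]), "log"),
        ChainStep(np.array([[1.0, -1.0]]), "exp"),
        ChainStep(np.array([[1.0]]), "none", offset=np.array([-shift])),
    )
    return ExpLogChain(steps, name=f"mean[{var}]")


def covariance_chain(
    table: ResponsePatternTable, var1: int = 0, var2: int = 1
) -> ExpLogChain:
    """Unbiased covariance s_xy = (N sum(n x y) - sum(n x) sum(n y)) / (N(N-1))."""

    x, _ = _shifted(table, var1)
    y, _ = _shifted(table, var2)
    ones = np.ones_like(x)
    steps = (
        # (sum nxy, sum nx, sum ny, N, N-1), all positive
        ChainStep(
            np.vstack([x * y, x, y, ones, ones]),
            "log",
            offset=np.array([0.0, 0.0, 0.0, 0.0, -1.0]),
        ),
        # sum nxy/(N-1)  and  sum nx sum ny / (N (N-1))
        ChainStep(
            np.array([[1.0, 0, 0, 0, -1.0], [0, 1.0, 1.0, -1.0, -1.0]]), "exp"
        ),
        ChainStep(np.array([[1.0, -1.0]]), "none"),
    )
    return ExpLogChain(steps, name=f"cov[{var1},{var2}]")


def variance_chain(table: ResponsePatternTable, var: int = 0) -> ExpLogChain:
    x, _ = _shifted(table, var)
    ones = np.ones_like(x)
    steps = (
        ChainStep(
            np.vstack([x * x, x, x, ones, ones]),
            "log",
            offset=np.array([0.0, 0.0, 0.0, 0.0, -1.0]),
        ),
        ChainStep(
            np.array([[1.0, 0, 0, 0, -1.0], [0, 1.0, 1.0, -1.0, -1.0]]), "exp"
        ),
        ChainStep(np.array([[1.0, -1.0]]), "none"),
    )
    return ExpLogChain(steps, name=f"var[{var}]")


def sd_chain(table: ResponsePatternTable, var: int = 0) -> ExpLogChain:
    base = variance_chain(table, var)
    steps = base.steps + (ChainStep(np.array([[1.0]]), "sqrt"),)
    return ExpLogChain(steps, name=f"sd[{var}]")


def _correlation_core(x: np.ndarray, y: np.ndarray) -> tuple[ChainStep, ...]:
    """Steps computing (P1/V, P2/V) with r = P1/V - P2/V.

    P1 = N sum(nxy), P2 = sum(nx) sum(ny), V = sqrt(Dx Dy) with
    Dx = N sum(nx^2) - sum(nx)^2 (and likewise Dy); all four positive.
    """

    ones = np.ones_like(x)
    return (
        ChainStep(np.vstack([x * y, x * x, y * y, x, y, ones]), "log"),
        ChainStep(
            np.array(
                [
                    [1.0, 0, 0, 0, 0, 1.0],  # N sum nxy
                    [0, 0, 0, 1.0, 1.0, 0],  # sum nx sum ny
                    [0, 1.0, 0, 0, 0, 1.0],  # N sum nx^2
                    [0, 0, 0, 2.0, 0, 0],  # (sum nx)^2
                    [0, 0, 1.0, 0, 0, 1.0],  # N sum ny^2
                    [0, 0, 0, 0, 2.0, 0],  # (sum ny)^2
                ]
            ),
            "exp",
        ),
        # (Dx, Dy, P1, P2); Dx or Dy <= 0 (constant variable) trips the log
        ChainStep(
            np.array(
                [
                    [0, 0, 1.0, -1.0, 0, 0],
                    [0, 0, 0, 0, 1.0, -1.0],
                    [1.0, 0, 0, 0, 0, 0],
                    [0, 1.0, 0, 0, 0, 0],
                ]
            ),
            "log",
        ),
        ChainStep(
            np.array([[-0.5, -0.5, 1.0, 0], [-0.5, -0.5, 0, 1.0]]), "exp"
        ),
    )


def correlation_chain(
    table: ResponsePatternTable, var1: int = 0, var2: int = 1
) -> ExpLogChain:
    x, _ = _shifted(table, var1)
    y, _ = _shifted(table, var2)
    steps = _correlation_core(x, y) + (ChainStep(np.array([[1.0, -1.0]]), "none"),)
    return ExpLogChain(steps, name=f"corr[{var1},{var2}]")


def split_half_chain(table: ResponsePatternTable) -> ExpLogChain:
    """Spearman-Brown stepped-up correlation 2r/(1+r) of two half sums.

    The table must hold the two half-sum variables.  r = -1 makes 1 + r
    non-positive and raises a boundary error from the log step.
    """

    if table.n_variables != 2:
        raise ValueError("split-half chain expects a two-variable (half sums) table")
    x, _ = _shifted(table, 0)
    y, _ = _shifted(table, 1)
    steps = _correlation_core(x, y) + (
        # (1 + r, P1/V, P2/V)
        ChainStep(
            np.array([[1.0, -1.0], [1.0, 0.0], [0.0, 1.0]]),
            "log",
            offset=np.array([1.0, 0.0, 0.0]),
        ),
        ChainStep(np.array([[-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]]), "exp"),
        ChainStep(np.array([[2.0, -2.0]]), "none"),
    )
    return ExpLogChain(steps, name="split_half")


def _lambda_base(table: ResponsePatternTable, pairs: bool):
    """Base aggregates for the lambda chains.

    Returns the first (log) step plus index bookkeeping.  Aggregate order:
    [pair products u_ij (i<j) if requested] + [squares u_jj] + [sums u_j]
    + [uXX, uX, N].
    """

    k = table.n_variables
    cols = [(_shifted(table, j))[0] for j in range(k)]
    total = np.sum(cols, axis=0)  # shifted sum score per pattern
    rows = []
    if pairs:
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(cols[i] * cols[j])
    rows += [c * c for c in cols]
    rows += cols
    rows += [total * total, total, np.ones_like(total)]
    return np.vstack(rows), k


def lambda1_chain(table: ResponsePatternTable) -> ExpLogChain:
    A1, k = _lambda_base(table, pairs=False)
    # log-aggregate indices: squares 0..k-1, sums k..2k-1, uXX 2k, uX 2k+1, N 2k+2
    m = 2 * k + 3
    A2 = np.zeros((2 * k + 2, m))
    for j in range(k):
        A2[j, j] = 1.0  # N u_jj ...
        A2[j, m - 1] = 1.0
        A2[k + j, k + j] = 2.0  # u_j^2
    A2[2 * k, 2 * k] = 1.0  # N uXX
    A2[2 * k, m - 1] = 1.0
    A2[2 * k + 1, 2 * k + 1] = 2.0  # uX^2
    # T1* = sum_j (P_j - Q_j) = N(N-1) sum_j s_j^2 ;  D* = N(N-1) s_X^2
    A3 = np.zeros((2, 2 * k + 2))
    A3[0, :k] = 1.0
    A3[0, k : 2 * k] = -1.0
    A3[1, 2 * k] = 1.0
    A3[1, 2 * k + 1] = -1.0
    steps = (
        ChainStep(A1, "log"),
        ChainStep(A2, "exp"),
        ChainStep(A3, "log"),
        ChainStep(np.array([[1.0, -1.0]]), "exp"),
        ChainStep(np.array([[-1.0]]), "none", offset=np.array([1.0])),
    )
    return ExpLogChain(steps, name="lambda1")


def lambda3_chain(table: ResponsePatternTable) -> ExpLogChain:
    k = table.n_variables
    base = lambda1_chain(table)
    factor = k / (k - 1.0)
    steps = base.steps[:-1] + (
        ChainStep(np.array([[-factor]]), "none", offset=np.array([factor])),
    )
    return ExpLogChain(steps, name="lambda3")


def lambda2_chain(table: ResponsePatternTable) -> ExpLogChain:
    A1, k = _lambda_base(table, pairs=True)
    npairs = k * (k - 1) // 2
    m = npairs + 2 * k + 3
    off = {"sq": npairs, "sum": npairs + k, "XX": npairs + 2 * k,
           "X": npairs + 2 * k + 1, "N": npairs + 2 * k + 2}
    # products: pair P/Q, diagonal P/Q, sum-score P/Q
    A2 = np.zeros((2 * npairs + 2 * k + 2, m))
    p = 0
    for i in range(k):
        for j in range(i + 1, k):
            A2[p, p] = 1.0  # N u_ij
            A2[p, off["N"]] = 1.0
            A2[npairs + p, off["sum"] + i] = 1.0  # u_i u_j
            A2[npairs + p, off["sum"] + j] = 1.0
            p += 1
    for j in range(k):
        A2[2 * npairs + j, off["sq"] + j] = 1.0
        A2[2 * npairs + j, off["N"]] = 1.0
        A2[2 * npairs + k + j, off["sum"] + j] = 2.0
    A2[-2, off["XX"]] = 1.0
    A2[-2, off["N"]] = 1.0
    A2[-1, off["X"]] = 2.0
    # squared: pair differences N(N-1) s_ij, then T1*, D*
    A3 = np.zeros((npairs + 2, 2 * npairs + 2 * k + 2))
    for p in range(npairs):
        A3[p, p] = 1.0
        A3[p, npairs + p] = -1.0
    A3[npairs, 2 * npairs : 2 * npairs + k] = 1.0
    A3[npairs, 2 * npairs + k : 2 * npairs + 2 * k] = -1.0
    A3[npairs + 1, -2] = 1.0
    A3[npairs + 1, -1] = -1.0
    # sqrt: (sqrt(k/(k-1) C2*), T1*, D*); C2* counts each unordered pair twice
    factor = k / (k - 1.0)
    A4 = np.zeros((3, npairs + 2))
    A4[0, :npairs] = 2.0 * factor
    A4[1, npairs] = 1.0
    A4[2, npairs + 1] = 1.0
    steps = (
        ChainStep(A1, "log"),
        ChainStep(A2, "exp"),
        ChainStep(A3, "square"),
        ChainStep(A4, "sqrt"),
        ChainStep(np.eye(3), "log"),
        ChainStep(np.array([[1.0, 0, -1.0], [0, 1.0, -1.0]]), "exp"),
        ChainStep(np.array([[1.0, -1.0]]), "none", offset=np.array([1.0])),
    )
    return ExpLogChain(steps, name="lambda2")


def vec_s_chain(table: ResponsePatternTable) -> ExpLogChain:
    """All k^2 unbiased variances/covariances s_ij, row-major order."""

    k = table.n_variables
    cols = [(_shifted(table, j))[0] for j in range(k)]
    ones = np.ones_like(cols[0])
    rows = []
    upper = {}
    for i in range(k):
        for j in range(i, k):
            upper[(i, j)] = len(rows)
            rows.append(cols[i] * cols[j])
    sums_off = len(rows)
    rows += cols
    n_off = len(rows)
    rows += [ones, ones]
    offset1 = np.zeros(len(rows))
    offset1[-1] = -1.0  # last aggregate is N - 1
    m = len(rows)
    A2 = np.zeros((2 * k * k, m))
    for i in range(k):
        for j in range(k):
            q = i * k + j
            u = upper[(min(i, j), max(i, j))]
            A2[q, u] = 1.0  # u_ij / (N-1)
            A2[q, n_off + 1] = -1.0
            A2[k * k + q, sums_off + i] = 1.0  # u_i u_j / (N (N-1))
            A2[k * k + q, sums_off + j] += 1.0
            A2[k * k + q, n_off] = -1.0
            A2[k * k + q, n_off + 1] = -1.0
    A3 = np.hstack([np.eye(k * k), -np.eye(k * k)])
    steps = (
        ChainStep(np.vstack(rows), "log", offset=offset1),
        ChainStep(A2, "exp"),
        ChainStep(A3, "none"),
    )
    return ExpLogChain(steps, name="vec_s")
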