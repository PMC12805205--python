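"""Classical-test-theory reliability coefficients.

Point estimates for the statistics of a standard reliability analysis:
item means/variances/SDs, scale (sum-score) statistics, inter-item
covariance and correlation matrices, item-rest and item-total correlations,
Guttman's lambda-1/lambda-2/lambda-3 (= Cronbach's alpha), the split-half
coefficient, and item-deleted variants.

Variances and covariances use the unbiased N-1 denominator throughout; the
maximum-likelihood (1/N) variants are exposed separately because the
delta-method standard error of the mean is based on the ML variance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from relse.patterns import ScoreMatrix

__all__ = [
    "ReliabilityReport",
    "descriptives",
    "ml_variance",
    "lambda1",
    "lambda2",
    "lambda3",
    "split_half",
    "item_deleted",
    "first_second_partition",
    "odd_even_partition",
]


def ml_variance(x: np.ndarray) -> float:
    """Maximum-likelihood (1/N) variance."""

    x = np.asarray(x, dtype=float)
    return float(np.mean((x - x.mean()) ** 2))


def _cov_matrix(values: np.ndarray) -> np.ndarray:
    return np.cov(values, rowvar=False, ddof=1).reshape(
        values.shape[1], values.shape[1]
    )


def _corr_from_cov(S: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(S))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = S / np.outer(sd, sd)
    return R


def lambda1(scores: ScoreMatrix) -> float:
    """Guttman's lambda-1: 1 - (sum of item variances) / (sum-score variance)."""

    S = _require_scale(scores)
    s_x2 = float(S.sum())
    return 1.0 - float(np.trace(S)) / s_x2


def lambda2(scores: ScoreMatrix) -> float:
    """Guttman's lambda-2: lambda-1 + sqrt(k/(k-1) * C2) / s_X^2.

    C2 sums the squared inter-item covariances over ordered pairs i != j
    (each unordered pair counted twice).
    """

    S = _require_scale(scores)
    k = S.shape[0]
    s_x2 = float(S.sum())
    c2 = float((S**2).sum() - (np.diag(S) ** 2).sum())
    return 1.0 - float(np.trace(S)) / s_x2 + math.sqrt(k / (k - 1.0) * c2) / s_x2


def lambda3(scores: ScoreMatrix) -> float:
    """Guttman's lambda-3 = Cronbach's alpha = k/(k-1) * lambda-1."""

    k = scores.n_items
    return k / (k - 1.0) * lambda1(scores)


def _require_scale(scores: ScoreMatrix) -> np.ndarray:
    if scores.n_items < 2:
        raise ValueError("lambda coefficients require at least two items")
    S = _cov_matrix(scores.values)
    if not S.sum() > 0:
        raise ValueError("sum-score variance is zero; lambda coefficients undefined")
    return S


def first_second_partition(k: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """First half versus second half (first half gets the extra item if k is odd)."""

    half = (k + 1) // 2
    return tuple(range(half)), tuple(range(half, k))


def odd_even_partition(k: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Odd-position items (1st, 3rd, ...) versus even-position items."""

    return tuple(range(0, k, 2)), tuple(range(1, k, 2))


def half_sums(
    scores: ScoreMatrix, partition: tuple[tuple[int, ...], tuple[int, ...]]
) -> np.ndarray:
    a, b = partition
    cols_a = [scores.column(i) for i in a]
    cols_b = [scores.column(i) for i in b]
    if set(cols_a) & set(cols_b) or sorted(cols_a + cols_b) != list(
        range(scores.n_items)
    ):
        raise ValueError("partition must split the item set into two disjoint halves")
    if not cols_a or not cols_b:
        raise ValueError("both halves must be nonempty")
    return np.column_stack(
        [scores.values[:, cols_a].sum(axis=1), scores.values[:, cols_b].sum(axis=1)]
    )


def split_half(
    scores: ScoreMatrix, partition: tuple[tuple[int, ...], tuple[int, ...]]
) -> float:
    """Spearman-Brown stepped split-half coefficient 2 r_AB / (1 + r_AB)."""

    halves = half_sums(scores, partition)
    va, vb = np.var(halves[:, 0], ddof=1), np.var(halves[:, 1], ddof=1)
    if va <= 0 or vb <= 0:
        raise ValueError("half-sum variance is zero; split-half undefined")
    r = float(np.corrcoef(halves[:, 0], halves[:, 1])[0, 1])
    if r == -1.0:
        raise ValueError("half correlation is -1; split-half undefined")
    return 2.0 * r / (1.0 + r)


@dataclass
class ReliabilityReport:
    """Point estimates of a full reliability analysis."""

    labels: tuple[str, ...]
    item_means: np.ndarray
    item_variances: np.ndarray
    item_sds: np.ndarray
    item_variances_ml: np.ndarray
    scale_mean: float
    scale_variance: float
    scale_sd: float
    covariances: np.ndarray  # inter-item covariance matrix S (unbiased)
    correlations: np.ndarray
    item_rest: np.ndarray  # corrected item-total correlations
    item_total: np.ndarray  # uncorrected item-total correlations
    lambda1: float | None = None
    lambda2: float | None = None
    lambda3: float | None = None
    split_half: float | None = None
    partition: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    alpha_if_deleted: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        return {
            k: conv(v)
            for k, v in self.__dict__.items()
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def item_table(self) -> pd.DataFrame:
        data = {
            "mean": self.item_means,
            "variance": self.item_variances,
            "sd": self.item_sds,
            "item_rest_r": self.item_rest,
            "item_total_r": self.item_total,
        }
        if self.alpha_if_deleted is not None:
            data["alpha_if_deleted"] = self.alpha_if_deleted
        return pd.DataFrame(data, index=list(self.labels))


def descriptives(
    scores: ScoreMatrix,
    partition: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
) -> ReliabilityReport:
    """Full set of point estimates; lambdas/split-half only when defined."""

    values = scores.values
    k = scores.n_items
    means = values.mean(axis=0)
    variances = values.var(axis=0, ddof=1)
    variances_ml = values.var(axis=0, ddof=0)
    sds = np.sqrt(variances)
    S = _cov_matrix(values)
    R = _corr_from_cov(S)
    total = values.sum(axis=1)
    notes: list[str] = []
    if np.any(variances == 0):
        flat = [scores.labels[j] for j in np.flatnonzero(variances == 0)]
        notes.append(f"zero-variance item(s) {flat}: correlations undefined")

    item_rest = np.full(k, np.nan)
    item_total = np.full(k, np.nan)
    for j in range(k):
        rest = total - values[:, j]
        if variances[j] > 0 and np.var(rest, ddof=1) > 0:
            item_rest[j] = np.corrcoef(values[:, j], rest)[0, 1]
        if variances[j] > 0 and np.var(total, ddof=1) > 0:
            item_total[j] = np.corrcoef(values[:, j], total)[0, 1]

    report = ReliabilityReport(
        labels=scores.labels,
        item_means=means,
        item_variances=variances,
        item_sds=sds,
        item_variances_ml=variances_ml,
        scale_mean=float(total.mean()),
        scale_variance=float(np.var(total, ddof=1)),
        scale_sd=float(np.std(total, ddof=1)),
        covariances=S,
        correlations=R,
        item_rest=item_rest,
        item_total=item_total,
        notes=notes,
    )
    if k >= 2 and S.sum() > 0:
        report.lambda1 = lambda1(scores)
        report.lambda2 = lambda2(scores)
        report.lambda3 = lambda3(scores)
        part = partition or first_second_partition(k)
        report.partition = part
        try:
            report.split_half = split_half(scores, part)
        except ValueError as exc:
            notes.append(f"split-half undefined: {exc}")
        if k >= 3:
            report.alpha_if_deleted = np.array(
                [lambda3(_drop_item(scores, j)) for j in range(k)]
            )
    elif k >= 2:
        notes.append("sum-score variance is zero; lambdas undefined")
    return report


def _drop_item(scores: ScoreMatrix, item: int | str) -> ScoreMatrix:
    j = scores.column(item)
    keep = [c for c in range(scores.n_items) if c != j]
    return scores.select(keep)


def item_deleted(
    scores: ScoreMatrix,
    item: int | str,
    partition: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
) -> ReliabilityReport:
    """Reliability analysis on the remaining k-1 items."""

    if scores.n_items < 3:
        raise ValueError(
            "item deletion requires at least three items so that the reduced "
            "scale still supports the lambda coefficients"
        )
    return descriptives(_drop_item(scores, item), partition=partition)
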