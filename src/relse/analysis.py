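"""End-to-end reliability analysis: every statistic of a standard
reliability-analysis output with its delta-method SE and Wald CI.

Rows that are undefined for the data at hand (correlations with a constant
item, boundary coefficients) are reported with a status note instead of a
number, never silently as NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from relse import delta
from relse.coefficients import descriptives, first_second_partition
from relse.delta import BoundaryError
from relse.intervals import wald_ci
from relse.patterns import ScoreMatrix

__all__ = ["analyze"]


def _row(kind, target, maker, level):
    try:
        est = maker()
        ci = wald_ci(est, level)
        return {
            "type": kind,
            "target": target,
            "estimate": est.value,
            "se": est.se,
            "ci_lower": ci.lower,
            "ci_upper": ci.upper,
            "method": est.method,
            "status": ";".join(est.flags) if est.flags else "ok",
        }
    except (BoundaryError, ValueError) as exc:
        return {
            "type": kind,
            "target": target,
            "estimate": np.nan,
            "se": np.nan,
            "ci_lower": np.nan,
            "ci_upper": np.nan,
            "method": "",
            "status": f"undefined: {exc}",
        }


def analyze(
    scores: ScoreMatrix,
    level: float = 0.95,
    partition=None,
    large_n: bool = False,
    mean_variant: str = "conventional",
) -> pd.DataFrame:
    """Full reliability analysis as a tidy table.

    One row per coefficient: item statistics (mean, variance, SD), scale
    statistics (sum-score mean/variance/SD, lambdas, split-half), rest
    statistics (alpha if item deleted), inter-item covariances and
    correlations, and item-rest (plus uncorrected item-total) correlations.
    """

    k = scores.n_items
    labels = scores.labels
    total = scores.sum_score()
    rows = []
    for j in range(k):
        rows.append(_row("item", f"mean[{labels[j]}]",
                         lambda j=j: delta.se_mean(scores, j, variant=mean_variant), level))
        rows.append(_row("item", f"variance[{labels[j]}]",
                         lambda j=j: delta.se_variance(scores, j, large_n=large_n), level))
        rows.append(_row("item", f"sd[{labels[j]}]",
                         lambda j=j: delta.se_sd(scores, j, large_n=large_n), level))
    rows.append(_row("scale", "mean[sum]",
                     lambda: delta.se_mean(total, variant=mean_variant), level))
    rows.append(_row("scale", "variance[sum]",
                     lambda: delta.se_variance(total, large_n=large_n), level))
    rows.append(_row("scale", "sd[sum]",
                     lambda: delta.se_sd(total, large_n=large_n), level))
    if k >= 2:
        part = partition or first_second_partition(k)
        rows.append(_row("scale", "lambda1", lambda: delta.se_lambda1(scores), level))
        rows.append(_row("scale", "lambda2", lambda: delta.se_lambda2(scores), level))
        rows.append(_row("scale", "lambda3_alpha", lambda: delta.se_lambda3(scores), level))
        rows.append(_row("scale", f"split_half{part}",
                         lambda: delta.se_split_half(scores, part), level))
        for i in range(k):
            for j in range(i + 1, k):
                pair = f"{labels[i]},{labels[j]}"
                rows.append(_row("inter-item", f"covariance[{pair}]",
                                 lambda i=i, j=j: delta.se_covariance(scores, i, j, large_n=large_n),
                                 level))
                rows.append(_row("inter-item", f"correlation[{pair}]",
                                 lambda i=i, j=j: delta.se_correlation(scores, i, j), level))
        for j in range(k):
            rest = total - scores.values[:, j]
            rows.append(_row("item-rest", f"correlation[{labels[j]},rest]",
                             lambda j=j, rest=rest: delta.se_correlation(
                                 scores.values[:, j], rest), level))
            rows.append(_row("item-total", f"correlation[{labels[j]},total]",
                             lambda j=j: delta.se_correlation(
                                 scores.values[:, j], total), level))
    if k >= 3:
        for j in range(k):
            reduced = scores.select([c for c in range(k) if c != j])
            rows.append(_row("rest", f"alpha_if_deleted[{labels[j]}]",
                             lambda r=reduced: delta.se_lambda3(r), level))
    frame = pd.DataFrame(rows)
    frame.attrs["level"] = level
    frame.attrs["n_respondents"] = scores.n_respondents
    frame.attrs["descriptives"] = descriptives(scores, partition=partition)
    return frame
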