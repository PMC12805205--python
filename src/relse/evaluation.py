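"""Simulation harness: scaled bias of SEs and coverage of Wald CIs.

For a design cell, data generation is replicated; each replication yields a
coefficient estimate, its SE and a Wald CI.  The SD of the estimates across
replications is the *true* SE; scaled bias is
100 * (mean estimated SE - true SE) / true SE, and coverage is the
percentage of CIs containing the population value (computed once per cell
from a large generated sample).  Replications where the coefficient sits on
the boundary of the parameter space (no SE) are omitted and counted.
Coverage is judged against the Agresti-Coull interval for the nominal level
at the post-omission replication count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from relse import delta
from relse.coefficients import ReliabilityReport, odd_even_partition
from relse.delta import BoundaryError, CoefficientEstimate
from relse.intervals import agresti_coull, normal_theory_se, wald_ci
from relse.irt import SimulationDesign, generate_data, population_values, sample_item_params
from relse.patterns import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoefficientTask",
    "standard_tasks",
    "benchmark_tasks",
    "EvaluationResult",
    "cell_seeds",
    "cell_params",
    "cell_population",
    "run_study",
    "report",
]


def cell_population(design: "SimulationDesign", m: int = 1_000_000, partition=None):
    """Population reliability report of a design cell, reusable across
    run_study calls with the same design."""

    param_seed, pop_seed, _ = cell_seeds(design)
    params = sample_item_params(design, seed=param_seed)
    if partition is None:
        partition = odd_even_partition(design.n_items)
    return population_values(design, params, m=m, seed=pop_seed, partition=partition)


@dataclass(frozen=True)
class CoefficientTask:
    """A coefficient followed through the study: how to estimate it on a
    sample and where its population value lives in a reliability report."""

    name: str
    estimate: Callable[[ScoreMatrix], CoefficientEstimate]
    population: Callable[[ReliabilityReport], float]


def _sum_score(scores: ScoreMatrix) -> np.ndarray:
    return scores.sum_score()


def standard_tasks(
    item_a: int = 0,
    item_b: int | None = None,
    partition=None,
) -> list[CoefficientTask]:
    """The delta-method tasks of the study: sum-score mean and SD, item-B
    variance and SD (the near-boundary cell), the item-A/item-B covariance
    and correlation, the split-half coefficient and the three lambdas."""

    def b_of(scores):
        return item_b if item_b is not None else scores.n_items // 2

    def part_of(scores):
        return partition or odd_even_partition(scores.n_items)

    return [
        CoefficientTask(
            "mean_sum",
            lambda s: delta.se_mean(_sum_score(s)),
            lambda rep: rep.scale_mean,
        ),
        CoefficientTask(
            "sd_sum",
            lambda s: delta.se_sd(_sum_score(s)),
            lambda rep: rep.scale_sd,
        ),
        CoefficientTask(
            "mean_itemA",
            lambda s: delta.se_mean(s, item_a),
            lambda rep: float(rep.item_means[item_a]),
        ),
        CoefficientTask(
            "variance_itemB",
            lambda s: delta.se_variance(s, b_of(s)),
            lambda rep: float(rep.item_variances[rep.n_items // 2 if item_b is None else item_b]),
        ),
        CoefficientTask(
            "sd_itemB",
            lambda s: delta.se_sd(s, b_of(s)),
            lambda rep: float(rep.item_sds[rep.n_items // 2 if item_b is None else item_b]),
        ),
        CoefficientTask(
            "covariance_AB",
            lambda s: delta.se_covariance(s, item_a, b_of(s)),
            lambda rep: float(rep.covariances[item_a, rep.n_items // 2 if item_b is None else item_b]),
        ),
        CoefficientTask(
            "correlation_AB",
            lambda s: delta.se_correlation(s, item_a, b_of(s)),
            lambda rep: float(rep.correlations[item_a, rep.n_items // 2 if item_b is None else item_b]),
        ),
        CoefficientTask(
            "split_half",
            lambda s: delta.se_split_half(s, part_of(s)),
            lambda rep: rep.split_half,
        ),
        CoefficientTask(
            "lambda1", delta.se_lambda1, lambda rep: rep.lambda1
        ),
        CoefficientTask(
            "lambda2", delta.se_lambda2, lambda rep: rep.lambda2
        ),
        CoefficientTask(
            "lambda3", delta.se_lambda3, lambda rep: rep.lambda3
        ),
    ]


def benchmark_tasks(item_a: int = 0, item_b: int | None = None) -> list[CoefficientTask]:
    """Normal-theory benchmark SEs for the covariance and SD cells, the
    contrast against the multinomial delta-method SEs."""

    def b_of(scores):
        return item_b if item_b is not None else scores.n_items // 2

    def cov_bench(s: ScoreMatrix) -> CoefficientEstimate:
        x = s.values[:, s.column(item_a)]
        y = s.values[:, s.column(b_of(s))]
        return normal_theory_se(
            "covariance",
            n=s.n_respondents,
            sd_x=float(np.std(x, ddof=1)),
            sd_y=float(np.std(y, ddof=1)),
            cov=float(np.cov(x, y, ddof=1)[0, 1]),
        )

    def sd_sum_bench(s: ScoreMatrix) -> CoefficientEstimate:
        total = _sum_score(s)
        return normal_theory_se("sd", n=s.n_respondents, sd=float(np.std(total, ddof=1)))

    def sd_b_bench(s: ScoreMatrix) -> CoefficientEstimate:
        col = s.values[:, s.column(b_of(s))]
        return normal_theory_se("sd", n=s.n_respondents, sd=float(np.std(col, ddof=1)))

    return [
        CoefficientTask(
            "covariance_AB_normal",
            cov_bench,
            lambda rep: float(rep.covariances[item_a, rep.n_items // 2 if item_b is None else item_b]),
        ),
        CoefficientTask("sd_sum_normal", sd_sum_bench, lambda rep: rep.scale_sd),
        CoefficientTask(
            "sd_itemB_normal",
            sd_b_bench,
            lambda rep: float(rep.item_sds[rep.n_items // 2 if item_b is None else item_b]),
        ),
    ]


@dataclass
class EvaluationResult:
    design: SimulationDesign
    level: float
    rows: pd.DataFrame  # per-task summary
    population: ReliabilityReport
    seeds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def cell_seeds(design: SimulationDesign):
    """Deterministic child seeds for one design cell: (item parameters,
    population sample, one per replication)."""

    master = np.random.SeedSequence(design.seed)
    param_seed, pop_seed, *rep_seeds = master.spawn(design.n_replications + 2)
    return param_seed, pop_seed, rep_seeds


def cell_params(design: SimulationDesign):
    """The item parameters of a design cell (fixed across replications)."""

    param_seed, _, _ = cell_seeds(design)
    return sample_item_params(design, seed=param_seed)


def run_study(
    design: SimulationDesign,
    tasks: Sequence[CoefficientTask] | None = None,
    level: float = 0.95,
    population_m: int = 1_000_000,
    population: ReliabilityReport | None = None,
) -> EvaluationResult:
    """Run the replication study for one design cell.

    Child seeds for item parameters, the population sample and every
    replication are spawned deterministically from the design's master
    seed, so results do not depend on execution order.  A precomputed
    ``population`` report must come from :func:`cell_params` of the same
    design (see :func:`cell_population`).
    """

    if design.n_replications < 2:
        raise ValueError("at least two replications are needed for a true SE")
    partition = odd_even_partition(design.n_items)
    tasks = list(tasks) if tasks is not None else standard_tasks(partition=partition)
    param_seed, pop_seed, rep_seeds = cell_seeds(design)
    params = sample_item_params(design, seed=param_seed)
    if population is None:
        population = population_values(
            design, params, m=population_m, seed=pop_seed, partition=partition
        )
    pop_values = {t.name: float(t.population(population)) for t in tasks}

    records: dict[str, dict[str, list]] = {
        t.name: {"value": [], "se": [], "covered": []} for t in tasks
    }
    omitted = {t.name: 0 for t in tasks}
    for r, rep_seed in enumerate(rep_seeds):
        scores = generate_data(design, params, seed=rep_seed)
        for task in tasks:
            try:
                est = task.estimate(scores)
                ci = wald_ci(est, level)
            except (BoundaryError, ValueError):
                omitted[task.name] += 1
                continue
            rec = records[task.name]
            rec["value"].append(est.value)
            rec["se"].append(est.se)
            rec["covered"].append(ci.contains(pop_values[task.name]))

    rows = []
    for task in tasks:
        rec = records[task.name]
        used = len(rec["value"])
        if used < 2:
            raise RuntimeError(
                f"all replications degenerate for {task.name}; cannot form a true SE"
            )
        values = np.asarray(rec["value"])
        ses = np.asarray(rec["se"])
        true_se = float(np.std(values, ddof=1))
        mean_se = float(ses.mean())
        scaled_bias = 100.0 * (mean_se - true_se) / true_se
        coverage = 100.0 * float(np.mean(rec["covered"]))
        band = agresti_coull(int(round(level * used)), used, level)
        rows.append(
            {
                "coefficient": task.name,
                "population": pop_values[task.name],
                "true_se": true_se,
                "mean_se": mean_se,
                "scaled_bias_pct": scaled_bias,
                "coverage_pct": coverage,
                "band_lower_pct": 100.0 * band.lower,
                "band_upper_pct": 100.0 * band.upper,
                "used": used,
                "omitted": omitted[task.name],
            }
        )
        logger.info(
            "%s: bias %.2f%%, coverage %.2f%% (omitted %d)",
            task.name, scaled_bias, coverage, omitted[task.name],
        )
    if rows:
        frame = pd.DataFrame(rows).set_index("coefficient")
    else:
        frame = pd.DataFrame(
            columns=[
                "population", "true_se", "mean_se", "scaled_bias_pct",
                "coverage_pct", "band_lower_pct", "band_upper_pct",
                "used", "omitted",
            ]
        )
    return EvaluationResult(
        design=design,
        level=level,
        rows=frame,
        population=population,
        seeds={"master": design.seed},
    )


def report(result: EvaluationResult, decimals: int = 3) -> pd.DataFrame:
    """Human-readable table with the boldface rules as flag columns:
    coverage outside the Agresti-Coull band, |scaled bias| > 10%."""

    frame = result.rows.copy()
    if frame.empty:
        return frame
    frame["coverage_flag"] = ~frame.apply(
        lambda r: r["band_lower_pct"] <= r["coverage_pct"] <= r["band_upper_pct"],
        axis=1,
    )
    frame["bias_flag"] = frame["scaled_bias_pct"].abs() > 10.0
    num = frame.select_dtypes(include=[float]).columns
    frame[num] = frame[num].round(decimals)
    return frame
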