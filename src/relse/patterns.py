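"""Response-pattern representation of a score matrix.

A reliability analysis operates on one or more *derived variables* (an item
score, a sum score, a rest score, or the sums of two test halves) obtained
from an N x d matrix of discrete item scores.  The sufficient statistic for
multinomial inference is the table of unique response patterns of those
derived variables together with their observed frequencies.  This module
builds that table and provides the estimated multinomial covariance matrix
of the frequency vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreMatrix",
    "ScoreSpec",
    "Item",
    "Pair",
    "ItemRest",
    "Halves",
    "AllItems",
    "ResponsePatternTable",
    "compress",
    "expand",
    "multinomial_cov",
    "read_scores_csv",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Complete N x d matrix of item scores (integer or real valued)."""

    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("score matrix must be two-dimensional")
        if values.shape[0] < 2:
            raise ValueError("at least two respondents are required")
        if values.shape[1] < 1:
            raise ValueError("score matrix has no variables")
        if not np.all(np.isfinite(values)):
            raise ValueError(
                "score matrix contains missing or non-finite entries; "
                "complete data are required"
            )
        object.__setattr__(self, "values", values)
        labels = self.labels or tuple(f"item{i + 1}" for i in range(values.shape[1]))
        if len(labels) != values.shape[1]:
            raise ValueError("number of labels does not match number of columns")
        object.__setattr__(self, "labels", tuple(str(l) for l in labels))

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def column(self, item: int | str) -> int:
        if isinstance(item, str):
            try:
                return self.labels.index(item)
            except ValueError:
                raise KeyError(f"unknown item label {item!r}") from None
        item = int(item)
        if not 0 <= item < self.n_items:
            raise KeyError(f"item index {item} out of range")
        return item

    def sum_score(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def rest_score(self, item: int | str) -> np.ndarray:
        j = self.column(item)
        return self.sum_score() - self.values[:, j]

    def select(self, items: Sequence[int | str]) -> "ScoreMatrix":
        cols = [self.column(i) for i in items]
        return ScoreMatrix(self.values[:, cols], tuple(self.labels[c] for c in cols))


class ScoreSpec:
    """Selection of derived variables for one analysis."""

    def derive(self, scores: ScoreMatrix) -> tuple[np.ndarray, tuple[str, ...]]:
        raise NotImplementedError


@dataclass(frozen=True)
class Item(ScoreSpec):
    item: int | str

    def derive(self, scores):
        j = scores.column(self.item)
        return scores.values[:, [j]], (scores.labels[j],)


@dataclass(frozen=True)
class Pair(ScoreSpec):
    first: int | str
    second: int | str

    def derive(self, scores):
        i = scores.column(self.first)
        j = scores.column(self.second)
        if i == j:
            raise ValueError("pair must reference two distinct items")
        return scores.values[:, [i, j]], (scores.labels[i], scores.labels[j])


@dataclass(frozen=True)
class ItemRest(ScoreSpec):
    """An item score paired with its rest score (sum minus item)."""

    item: int | str

    def derive(self, scores):
        j = scores.column(self.item)
        cols = np.column_stack([scores.values[:, j], scores.rest_score(j)])
        return cols, (scores.labels[j], f"rest({scores.labels[j]})")


@dataclass(frozen=True)
class Halves(ScoreSpec):
    """Sum scores of two halves partitioning the item set."""

    half_a: tuple[int, ...]
    half_b: tuple[int, ...]

    def derive(self, scores):
        a = [scores.column(i) for i in self.half_a]
        b = [scores.column(i) for i in self.half_b]
        if set(a) & set(b):
            raise ValueError("halves must be disjoint")
        if sorted(a + b) != list(range(scores.n_items)):
            raise ValueError("halves must partition the full item set")
        if not a or not b:
            raise ValueError("both halves must be nonempty")
        cols = np.column_stack(
            [scores.values[:, a].sum(axis=1), scores.values[:, b].sum(axis=1)]
        )
        return cols, ("halfA", "halfB")


@dataclass(frozen=True)
class AllItems(ScoreSpec):
    def derive(self, scores):
        return scores.values, scores.labels


@dataclass(frozen=True)
class ResponsePatternTable:
    """Unique observed response patterns R with frequency vector n.

    Rows of ``patterns`` are sorted lexicographically with the last column
    changing fastest; ``freqs`` holds the positive observed frequencies and
    sums to the sample size N.  Only observed patterns are carried: under
    multinomial sampling every pattern has positive probability, but
    unobserved patterns contribute nothing to the estimated covariance
    matrix of the frequency vector.
    """

    patterns: np.ndarray  # (C, d)
    freqs: np.ndarray  # (C,)
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        freqs = np.asarray(self.freqs)
        if patterns.shape[0] != freqs.shape[0]:
            raise ValueError("patterns and frequencies differ in length")
        if np.any(freqs < 1) or np.any(freqs != np.round(freqs)):
            raise ValueError("frequencies must be positive integers")
        object.__setattr__(self, "patterns", patterns)
        object.__setattr__(self, "freqs", freqs.astype(float))

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_variables(self) -> int:
        return self.patterns.shape[1]

    @property
    def total(self) -> float:
        return float(self.freqs.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = self.labels or tuple(f"v{i + 1}" for i in range(self.n_variables))
        frame = pd.DataFrame(self.patterns, columns=list(labels))
        frame["freq"] = self.freqs.astype(int)
        return frame


def compress(scores: ScoreMatrix, spec: ScoreSpec | None = None) -> ResponsePatternTable:
    """Collapse derived score rows into the unique-pattern frequency table."""

    if spec is None:
        spec = AllItems()
    derived, labels = spec.derive(scores)
    derived = np.atleast_2d(np.asarray(derived, dtype=float))
    # np.unique on rows sorts lexicographically, first column slowest --
    # i.e. the last column changes fastest.
    patterns, counts = np.unique(derived, axis=0, return_counts=True)
    return ResponsePatternTable(patterns, counts, labels)


def compress_values(values: np.ndarray, labels: tuple[str, ...] = ()) -> ResponsePatternTable:
    """Pattern table straight from an array of derived scores (no spec)."""

    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    patterns, counts = np.unique(values, axis=0, return_counts=True)
    return ResponsePatternTable(patterns, counts, labels)


def expand(table: ResponsePatternTable) -> np.ndarray:
    """Inverse of :func:`compress` up to row order."""

    return np.repeat(table.patterns, table.freqs.astype(int), axis=0)


def multinomial_cov(table: ResponsePatternTable) -> np.ndarray:
    """Estimated covariance matrix of the frequency vector, diag(n) - n n'/N."""

    n = table.freqs
    return np.diag(n) - np.outer(n, n) / table.total


def read_scores_csv(path) -> ScoreMatrix:
    """Strictly parse a CSV of scores: header row, one respondent per row.

    Any missing or non-numeric cell is an error; the multinomial framework
    assumes complete data and no imputation is attempted.
    """

    frame = pd.read_csv(path, header=0)
    if frame.shape[0] == 0:
        raise ValueError("empty score file")
    if frame.isna().any().any():
        bad = [c for c in frame.columns if frame[c].isna().any()]
        raise ValueError(f"missing values in column(s) {bad}; complete data required")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in score file: {exc}") from exc
    return ScoreMatrix(values, tuple(str(c) for c in frame.columns))
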