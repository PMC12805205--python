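"""Dichotomous item-score simulation from a two-dimensional acceleration
model.

The population model is a two-dimensional extension of the five-parameter
acceleration model (5PAM).  The probability of a score 1 on item j given
the latent pair theta = (theta_1, theta_2) is

    P_j(theta) = gamma_j + (1 - gamma_j - delta_j) * F(z_j)^xi_j,
    z_j = sum_d w_jd * a_jd * (theta_d - b_jd),

with F the logistic function, gamma_j the lower asymptote, 1 - delta_j the
upper asymptote, xi_j > 0 the acceleration parameter, a/b discrimination
and location parameters per dimension and w_jd fixed design weights
controlling how strongly the item loads on each dimension.  Setting
gamma = delta = 0 and xi = 1 recovers the two-dimensional two-parameter
logistic model (2PLM).

Latent traits are bivariate standard normal with correlation rho.  A score
of 1 is assigned when an independent uniform draw falls below P_j(theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from relse.coefficients import ReliabilityReport, descriptives
from relse.patterns import ScoreMatrix

__all__ = [
    "ItemParams",
    "SimulationDesign",
    "response_probability",
    "sample_item_params",
    "generate_data",
    "population_values",
]


@dataclass(frozen=True)
class ItemParams:
    """Per-item 5PAM parameters; arrays have shape (k,) or (k, 2)."""

    a: np.ndarray  # discrimination per dimension
    b: np.ndarray  # location per dimension
    gamma: np.ndarray  # lower asymptote
    delta: np.ndarray  # 1 - upper asymptote
    xi: np.ndarray  # acceleration
    w: np.ndarray  # design weights per dimension

    def __post_init__(self):
        a = np.atleast_2d(np.asarray(self.a, dtype=float))
        b = np.atleast_2d(np.asarray(self.b, dtype=float))
        w = np.atleast_2d(np.asarray(self.w, dtype=float))
        gamma = np.asarray(self.gamma, dtype=float).ravel()
        delta = np.asarray(self.delta, dtype=float).ravel()
        xi = np.asarray(self.xi, dtype=float).ravel()
        # gamma + delta = 1 is allowed: the response curve degenerates to the
        # constant gamma (useful as a coin-flip check), anything above is invalid
        if np.any(gamma < 0) or np.any(delta < 0) or np.any(gamma + delta > 1):
            raise ValueError("asymptotes must satisfy gamma >= 0, delta >= 0, gamma + delta <= 1")
        if np.any(xi <= 0):
            raise ValueError("acceleration parameters must be positive")
        for name, arr in (("a", a), ("b", b), ("w", w)):
            if arr.shape != (gamma.shape[0], 2):
                raise ValueError(f"{name} must have shape (k, 2)")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "xi", xi)

    @property
    def n_items(self) -> int:
        return self.gamma.shape[0]


@dataclass(frozen=True)
class SimulationDesign:
    """Design cell of the simulation study.

    Defaults mirror the study conditions: dichotomous items, latent
    correlation 0.5, item locations evenly spaced on [-2, 2], lower and
    upper asymptote deficits uniform on [0, 0.2] and acceleration uniform
    on [0.5, 2] for the 5PAM (all zero / one for the 2PLM).
    """

    n_respondents: int
    n_items: int = 10
    dimensionality: int = 1
    model: str = "2PLM"  # or "5PAM"
    rho: float = 0.5
    n_replications: int = 1
    seed: int = 0
    location_range: tuple[float, float] = (-2.0, 2.0)
    gamma_range: tuple[float, float] = (0.0, 0.2)
    delta_range: tuple[float, float] = (0.0, 0.2)
    xi_range: tuple[float, float] = (0.5, 2.0)
    # dimension loadings: odd items (1st, 3rd, ...) load on theta_1 and more
    # weakly on theta_2; even items load only on theta_2
    odd_weights: tuple[float, float] = (1.0, 0.5)
    even_weights: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.n_respondents < 2:
            raise ValueError("at least two respondents required")
        if self.n_replications < 1:
            raise ValueError("at least one replication required")
        if self.dimensionality not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")
        if self.model not in ("2PLM", "5PAM"):
            raise ValueError("model must be '2PLM' or '5PAM'")

    def to_dict(self) -> dict:
        return asdict(self)


def response_probability(params: ItemParams, theta: np.ndarray) -> np.ndarray:
    """P(score 1) for each respondent x item; theta has shape (n, 2)."""

    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    z = np.einsum("nd,jd->nj", theta, params.w * params.a) - np.sum(
        params.w * params.a * params.b, axis=1
    )
    logistic = 1.0 / (1.0 + np.exp(-z))
    p = params.gamma + (1.0 - params.gamma - params.delta) * logistic**params.xi
    return p


def sample_item_params(design: SimulationDesign, seed: int | None = None) -> ItemParams:
    """Draw item parameters for a design cell.

    Discriminations are lognormal with log-mean 0 and log-SD 0.1; locations
    are evenly spaced over the design's range (both dimensions share the
    location); 5PAM asymptote/acceleration parameters are uniform over the
    design's supports, the 2PLM fixes gamma = delta = 0 and xi = 1.
    """

    rng = np.random.default_rng(design.seed if seed is None else seed)
    k = design.n_items
    a = rng.lognormal(mean=0.0, sigma=0.1, size=(k, 2))
    locations = np.linspace(*design.location_range, k)
    b = np.column_stack([locations, locations])
    if design.model == "5PAM":
        gamma = rng.uniform(*design.gamma_range, size=k)
        delta = rng.uniform(*design.delta_range, size=k)
        xi = rng.uniform(*design.xi_range, size=k)
    else:
        gamma = np.zeros(k)
        delta = np.zeros(k)
        xi = np.ones(k)
    if design.dimensionality == 1:
        w = np.tile([1.0, 0.0], (k, 1))
    else:
        w = np.empty((k, 2))
        w[0::2] = design.odd_weights
        w[1::2] = design.even_weights
    return ItemParams(a=a, b=b, gamma=gamma, delta=delta, xi=xi, w=w)


def _draw_theta(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")


def generate_data(
    design: SimulationDesign, params: ItemParams, seed: int | None = None
) -> ScoreMatrix:
    """One N x k matrix of dichotomous scores from the design cell."""

    rng = np.random.default_rng(design.seed if seed is None else seed)
    theta = _draw_theta(design.n_respondents, design.rho, rng)
    p = response_probability(params, theta)
    u = rng.uniform(size=p.shape)
    scores = (u < p).astype(float)
    return ScoreMatrix(scores, tuple(f"item{j + 1}" for j in range(params.n_items)))


def population_values(
    design: SimulationDesign,
    params: ItemParams,
    m: int = 1_000_000,
    seed: int | None = None,
    partition=None,
) -> ReliabilityReport:
    """Population coefficient values by large-sample evaluation.

    Generates an m-respondent sample from the cell and computes every
    coefficient on it; m = 1e6 by default (Monte-Carlo error ~ 1/sqrt(m)).
    Generation is chunked to bound memory.
    """

    if m < 100_000:
        raise ValueError("population evaluation needs m >= 1e5")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    chunks = []
    remaining = int(m)
    while remaining > 0:
        size = min(remaining, 500_000)
        theta = _draw_theta(size, design.rho, rng)
        p = response_probability(params, theta)
        chunks.append((rng.uniform(size=p.shape) < p).astype(np.int8))
        remaining -= size
    scores = ScoreMatrix(
        np.concatenate(chunks).astype(float),
        tuple(f"item{j + 1}" for j in range(params.n_items)),
    )
    return descriptives(scores, partition=partition)
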