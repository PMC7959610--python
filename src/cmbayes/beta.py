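"""Conjugate beta inference for proportions: updating, HPD intervals,
metric uncertainty, sampling, and a split-half convergence diagnostic.

Everything downstream (confusion-matrix posteriors, sample-size planning,
probabilistic leaderboards) reduces to beta distributions of proportions,
so this module is the numerical foundation of the package.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betainc, betaincinv
from scipy.stats import beta as _beta_dist

__all__ = [
    "BetaParams",
    "PointMass",
    "Interval",
    "LAPLACE",
    "JEFFREYS",
    "HALDANE",
    "get_prior",
    "beta_update",
    "hpd_interval",
    "hpd_from_samples",
    "metric_uncertainty",
    "sample_beta",
    "split_rhat",
    "RHAT_THRESHOLD",
]

#: convergence flag threshold for the split-half potential scale reduction
RHAT_THRESHOLD = 1.01

#: epsilon used to represent the (improper) Haldane prior as a proper beta
HALDANE_EPS = 1e-4


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters (alpha, beta) of a beta distribution of a proportion.

    Stands for either a prior or a posterior; both shapes must be strictly
    positive so the distribution is proper.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite real, got {v!r}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    def pdf(self, x):
        return _beta_dist.pdf(x, self.alpha, self.beta)

    def ppf(self, q):
        return betaincinv(self.alpha, self.beta, q)

    def cdf(self, x):
        return betainc(self.alpha, self.beta, x)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=n)


@dataclass(frozen=True)
class PointMass:
    """Degenerate distribution concentrated at a single value in [0, 1].

    Used for a prevalence that is known exactly by design of the test set.
    """

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"point mass must lie in [0, 1], got {self.value!r}")

    @property
    def mean(self) -> float:
        return self.value

    @property
    def variance(self) -> float:
        return 0.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, self.value)


@dataclass(frozen=True)
class Interval:
    """Credible interval [lower, upper] holding `mass` posterior probability."""

    lower: float
    upper: float
    mass: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mass < 1.0:
            raise ValueError(f"mass must lie in (0, 1), got {self.mass!r}")
        if self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower


LAPLACE = BetaParams(1.0, 1.0)
JEFFREYS = BetaParams(0.5, 0.5)
HALDANE = BetaParams(HALDANE_EPS, HALDANE_EPS)

_NAMED_PRIORS = {"laplace": LAPLACE, "jeffreys": JEFFREYS, "haldane": HALDANE}


def get_prior(spec) -> BetaParams:
    """Resolve a prior specification to :class:`BetaParams`.

    Accepts a name ('laplace', 'jeffreys', 'haldane'), an (alpha, beta)
    pair, or an existing :class:`BetaParams`.
    """
    if isinstance(spec, BetaParams):
        return spec
    if isinstance(spec, str):
        try:
            return _NAMED_PRIORS[spec.lower()]
        except KeyError:
            raise ValueError(
                f"unknown prior {spec!r}; expected one of {sorted(_NAMED_PRIORS)}"
            ) from None
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        return BetaParams(float(spec[0]), float(spec[1]))
    raise TypeError(f"cannot interpret prior specification {spec!r}")


def _check_count(value, name: str) -> int:
    if isinstance(value, bool) or not isinstance(value, numbers.Integral):
        raise TypeError(f"{name} must be an integer count, got {value!r}")
    value = int(value)
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return value


def beta_update(prior: BetaParams, successes, failures) -> BetaParams:
    """Conjugate update of a beta prior with binomial count data.

    The beta distribution is the conjugate prior of the binomial
    likelihood, so the posterior is again a beta with the observed
    successes and failures added to the shapes.
    """
    successes = _check_count(successes, "successes")
    failures = _check_count(failures, "failures")
    return BetaParams(prior.alpha + successes, prior.beta + failures)


def _hpd_beta(alpha: float, beta: float, mass: float) -> tuple[float, float]:
    # Monotone densities pin one endpoint to the support boundary.
    if alpha == 1.0 and beta == 1.0:
        # Uniform: every interval of length `mass` ties; adopt the central one.
        return (1.0 - mass) / 2.0, (1.0 + mass) / 2.0
    if alpha >= 1.0 and beta <= 1.0:  # monotone increasing
        return float(betaincinv(alpha, beta, 1.0 - mass)), 1.0
    if alpha <= 1.0 and beta >= 1.0:  # monotone decreasing
        return 0.0, float(betaincinv(alpha, beta, mass))

    # Interior mode (or U-shape): minimise the width of [Q(t), Q(t+mass)]
    # over the lower-tail offset t.  For unimodal densities the minimiser is
    # the exact HPD; for U-shaped densities (alpha, beta < 1) this returns
    # the shortest *contiguous* interval of the requested mass.
    def width(t: float) -> float:
        return betaincinv(alpha, beta, t + mass) - betaincinv(alpha, beta, t)

    res = minimize_scalar(
        width, bounds=(0.0, 1.0 - mass), method="bounded", options={"xatol": 1e-12}
    )
    candidates = [0.0, 1.0 - mass, float(res.x)]
    t = min(candidates, key=width)
    return float(betaincinv(alpha, beta, t)), float(betaincinv(alpha, beta, t + mass))


def hpd_interval(dist, mass: float = 0.95) -> Interval:
    """Highest-posterior-density interval of a beta (or point-mass) distribution.

    The HPD interval is the shortest interval containing `mass` posterior
    probability.  Monotone densities are handled in closed form; the
    interior-mode case is solved by bounded scalar minimisation of the
    interval width over the lower-tail offset.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass!r}")
    if isinstance(dist, PointMass):
        return Interval(dist.value, dist.value, mass)
    if not isinstance(dist, BetaParams):
        raise TypeError(f"expected BetaParams or PointMass, got {type(dist).__name__}")
    lower, upper = _hpd_beta(dist.alpha, dist.beta, mass)
    return Interval(lower, upper, mass)


def _shortest_window(draws: np.ndarray, mass: float) -> tuple[float, float]:
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def hpd_from_samples(draws, mass: float = 0.95) -> Interval:
    """Empirical HPD interval: the shortest contiguous window over the sorted
    draws containing ``ceil(mass * n)`` points.

    Requires at least 100 draws; with fewer the window estimate is too noisy
    to be meaningful.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass!r}")
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 1 or draws.size < 100:
        raise ValueError(f"need at least 100 one-dimensional draws, got shape {draws.shape}")
    lower, upper = _shortest_window(draws, mass)
    return Interval(lower, upper, mass)


def metric_uncertainty(dist_or_draws, mass: float = 0.95) -> float:
    """Metric uncertainty (MU): the length of the 95% HPD interval.

    MU is the headline uncertainty measure of this package: 0 means the
    quantity is known exactly, while 0.95 (the width of the uniform's
    central 95% interval) means nothing is known beyond the prior.
    Accepts analytic beta parameters or a set of posterior draws.
    """
    if isinstance(dist_or_draws, (BetaParams, PointMass)):
        return hpd_interval(dist_or_draws, mass).width
    draws = np.asarray(dist_or_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draw set")
    if draws.size == 1:
        return 0.0
    lower, upper = _shortest_window(draws, mass)
    return upper - lower


def sample_beta(dist: BetaParams, n: int, random_state=None) -> np.ndarray:
    """Draw ``n`` independent samples; reproducible under a fixed seed."""
    n = _check_count(n, "n")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(random_state)
    return dist.sample(n, rng)


def split_rhat(draws) -> float:
    """Split-half Gelman–Rubin potential scale reduction.

    The draw vector is split into two equal halves treated as chains and the
    classic (non rank-normalised) R-hat is computed.  Values near 1 indicate
    the two halves agree; >= 1.01 is flagged as a sampling problem.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 1 or draws.size < 4 or draws.size % 2 != 0:
        raise ValueError("need an even number of at least 4 one-dimensional draws")
    chains = draws.reshape(2, -1)
    n = chains.shape[1]
    within = chains.var(axis=1, ddof=1).mean()
    between = n * chains.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else float("inf")
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))
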