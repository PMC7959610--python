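"""Sample-size determination for a precision (metric-uncertainty) goal.

Follows the simulation protocol of Kruschke-style Bayesian power analysis
for a proportion: hypothesise a data-generating beta distribution given by
its mode omega and concentration kappa, repeatedly (i) draw a true rate,
(ii) draw binomial data of size N, (iii) update the analysis prior and
record the width of the 95% HPD interval (the metric uncertainty, MU).
The statistical power for a precision goal is the fraction of simulated
studies whose MU falls below the target width.

An analytic screen complements the simulation: from the beta standard
deviation and the central limit theorem, MU is bounded by roughly
2/sqrt(N) (valid for N > 20), which gives the right order of magnitude
before any simulation is run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .beta import BetaParams, LAPLACE, get_prior, hpd_interval

__all__ = [
    "GeneratingSpec",
    "PowerResult",
    "mu_power",
    "mu_at_power",
    "min_sample_size",
    "mu_bound",
]

DEFAULT_REPS = 5000


@dataclass(frozen=True)
class GeneratingSpec:
    """Hypothesised data-generating beta, parameterised by mode and
    concentration: alpha = omega*(kappa-2)+1, beta = (1-omega)*(kappa-2)+1.

    ``kappa > 2`` keeps the distribution proper and unimodal with mode
    ``omega``.
    """

    omega: float
    kappa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega!r}")
        if self.kappa <= 2.0:
            raise ValueError(f"kappa must exceed 2, got {self.kappa!r}")

    @property
    def beta(self) -> BetaParams:
        k = self.kappa - 2.0
        return BetaParams(self.omega * k + 1.0, (1.0 - self.omega) * k + 1.0)


@dataclass(frozen=True)
class PowerResult:
    """Fraction of simulated studies meeting the MU target at size n."""

    n: int
    target_mu: float
    power: float
    reps: int
    mc_error: float


def _simulate_mu_widths(
    n: int, gen: GeneratingSpec, prior: BetaParams, reps: int,
    rng: np.random.Generator, mass: float = 0.95,
) -> np.ndarray:
    """MU widths of `reps` simulated studies of size n.

    The posterior, hence the width, depends only on the success count, so
    widths are computed once per distinct count and broadcast back.
    """
    gb = gen.beta
    theta = rng.beta(gb.alpha, gb.beta, size=reps)
    s = rng.binomial(n, theta)
    uniq, inv = np.unique(s, return_inverse=True)
    widths_u = np.array([
        hpd_interval(BetaParams(prior.alpha + si, prior.beta + n - si), mass).width
        for si in uniq
    ])
    return widths_u[inv]


def mu_power(
    n: int,
    gen: GeneratingSpec,
    target_mu: float,
    prior=LAPLACE,
    reps: int = DEFAULT_REPS,
    random_state=None,
) -> PowerResult:
    """Probability that a study of size ``n`` achieves MU <= ``target_mu``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 < target_mu < 0.95:
        raise ValueError("target_mu must lie in (0, 0.95)")
    prior = get_prior(prior)
    rng = np.random.default_rng(random_state)
    widths = _simulate_mu_widths(n, gen, prior, reps, rng)
    power = float(np.mean(widths <= target_mu))
    return PowerResult(
        n=n, target_mu=target_mu, power=power, reps=reps,
        mc_error=float(np.sqrt(power * (1.0 - power) / reps)),
    )


def mu_at_power(
    n: int,
    gen: GeneratingSpec,
    power: float = 0.95,
    prior=LAPLACE,
    reps: int = DEFAULT_REPS,
    random_state=None,
) -> float:
    """The ``power``-quantile of simulated MU widths at sample size ``n`` —
    the tightest MU target that the requested power still achieves."""
    if not 0.0 < power < 1.0:
        raise ValueError("power must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be at least 1")
    prior = get_prior(prior)
    rng = np.random.default_rng(random_state)
    widths = _simulate_mu_widths(n, gen, prior, reps, rng)
    return float(np.quantile(widths, power))


def mu_bound(n: int) -> float:
    """Analytic order-of-magnitude bound MU <~ 2/sqrt(n), valid for n > 20."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return 2.0 / np.sqrt(n)


def min_sample_size(
    target_mu: float,
    power: float = 0.95,
    gen: GeneratingSpec = GeneratingSpec(0.8, 10.0),
    prior=LAPLACE,
    reps: int = DEFAULT_REPS,
    random_state=None,
    max_simulated_n: int = 200_000,
) -> int:
    """Smallest sample size whose MU power meets the requested level.

    The analytic bound brackets the search: around n0 = (2/target)^2 a
    doubling scan finds a bracket, refined by integer bisection; each
    candidate n uses an independent sub-stream of the seed.  Targets so
    tight that n0 exceeds ``max_simulated_n`` are answered with the
    analytic screen value itself rather than simulated.
    """
    if not 0.0 < target_mu < 0.95:
        raise ValueError("target_mu must lie in (0, 0.95)")
    if not 0.0 < power < 1.0:
        raise ValueError("power must lie in (0, 1)")
    if reps * (1.0 - power) < 5.0:
        raise ValueError(
            f"reps={reps} cannot resolve power={power}; increase the budget"
        )
    prior = get_prior(prior)
    n0 = int(np.ceil((2.0 / target_mu) ** 2))
    if n0 > max_simulated_n:
        return n0

    ss = np.random.SeedSequence(random_state if random_state is not None else 0)

    def achieves(n: int) -> bool:
        # per-n sub-stream: re-evaluating the same n reuses the same draws
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(n,))
        )
        widths = _simulate_mu_widths(n, gen, prior, reps, rng)
        return float(np.mean(widths <= target_mu)) >= power

    if achieves(1):
        return 1
    # doubling scan for a bracket [lo fails, hi achieves]
    lo, hi = 1, max(2, n0 // 8)
    while not achieves(hi):
        lo = hi
        hi *= 2
        if hi > max(16 * n0, 1024):
            raise RuntimeError(
                f"target MU {target_mu} at power {power} not reached by "
                f"n={hi // 2} under the simulation budget"
            )
    # integer bisection on [lo, hi]
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if achieves(mid):
            hi = mid
        else:
            lo = mid
    return hi
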