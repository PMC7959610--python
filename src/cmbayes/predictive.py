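"""Posterior-predictive confusion matrices and reproducibility analysis.

A posterior-predictive confusion matrix is a multinomial draw
CM ~ Mult(theta, N) using one posterior draw of theta per replicate.  The
plug-in metric values computed on such synthetic matrices form the
*empirical* distribution — what independent repetitions of the experiment
at sample size N would report.  That spread exceeds the *posterior*
spread of the metric itself, because it adds fresh multinomial noise on
top of parameter uncertainty; computing metric distributions this way
therefore systematically overstates the metric's uncertainty, while it is
exactly the right object for asking whether a result would replicate.

Also hosts the synthetic confusion-matrix generator used as the
study-condition fixture throughout the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .confusion import ConfusionMatrix
from .metrics import get_metric
from .model import ThetaSamples

__all__ = [
    "PredictiveCMSet",
    "sample_predictive_cm",
    "empirical_metric_distribution",
    "variance_inflation_check",
    "VarianceComparison",
    "synthetic_cm",
]


@dataclass(frozen=True)
class PredictiveCMSet:
    """Replicated synthetic confusion matrices, each summing to ``n_per_cm``."""

    cms: tuple
    n_per_cm: int
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.cms)

    def as_array(self) -> np.ndarray:
        """(reps, 4) array of cells in (TP, FN, FP, TN) order."""
        return np.array([cm.as_tuple() for cm in self.cms], dtype=int)


def _theta_rows(theta, reps: int, rng: np.random.Generator) -> np.ndarray:
    """One theta row per replicate, columns (TP, FN, TN, FP)."""
    if isinstance(theta, ThetaSamples):
        idx = rng.integers(0, theta.n, size=reps)
        return theta.draws[idx]
    row = np.asarray(theta, dtype=float)
    if row.shape != (4,):
        raise ValueError("point theta must be a length-4 probability vector "
                         "(TP, FN, TN, FP)")
    if np.any(row < 0) or not np.isclose(row.sum(), 1.0):
        raise ValueError("point theta must be non-negative and sum to 1")
    return np.tile(row / row.sum(), (reps, 1))


def sample_predictive_cm(
    theta: Union[ThetaSamples, Sequence[float]],
    n_per_cm: int,
    reps: int,
    random_state=None,
) -> PredictiveCMSet:
    """Draw ``reps`` synthetic confusion matrices of size ``n_per_cm``.

    Each replicate pairs one fresh theta draw (or the supplied point theta)
    with one multinomial count vector — the full posterior predictive.
    """
    if reps < 1 or n_per_cm < 1:
        raise ValueError("reps and n_per_cm must be at least 1")
    rng = np.random.default_rng(random_state)
    rows = _theta_rows(theta, reps, rng)
    counts = rng.multinomial(n_per_cm, rows)  # columns (TP, FN, TN, FP)
    cms = tuple(
        ConfusionMatrix(tp=int(c[0]), fn=int(c[1]), tn=int(c[2]), fp=int(c[3]))
        for c in counts
    )
    seed = random_state if isinstance(random_state, int) else None
    return PredictiveCMSet(cms=cms, n_per_cm=n_per_cm, seed=seed)


def empirical_metric_distribution(
    cms: PredictiveCMSet, metric
) -> tuple[np.ndarray, int]:
    """Plug-in metric value on every synthetic confusion matrix.

    Returns the defined values and the count of matrices on which the
    metric was undefined (zero denominator at small N); undefined values
    are excluded, not imputed.
    """
    m = get_metric(metric)
    cells = cms.as_array().astype(float)  # (TP, FN, FP, TN)
    values = m.on_cells(cells[:, 0], cells[:, 1], cells[:, 3], cells[:, 2])
    bad = np.isnan(values)
    return values[~bad], int(bad.sum())


@dataclass(frozen=True)
class VarianceComparison:
    """Posterior vs empirical (posterior-predictive) metric variance."""

    posterior_var: float
    empirical_var: float
    ratio: float  # empirical / posterior
    violation: bool  # empirical smaller than posterior beyond MC error

    @property
    def inflated(self) -> bool:
        return self.empirical_var >= self.posterior_var


def _var_se(x: np.ndarray) -> float:
    # standard error of the sample variance from the fourth central moment
    n = x.size
    m2 = np.var(x)
    m4 = np.mean((x - x.mean()) ** 4)
    return float(np.sqrt(max(m4 - m2 * m2, 0.0) / n))


def variance_inflation_check(
    posterior_draws, empirical_draws
) -> VarianceComparison:
    """Contrast the true posterior spread of a metric with the spread of
    plug-in values on posterior-predictive confusion matrices.

    The empirical variance equals the posterior variance plus the mean
    multinomial sampling variance, so it can fall below the posterior
    variance only by Monte Carlo fluctuation; such a case is flagged.
    """
    p = np.asarray(posterior_draws, dtype=float)
    e = np.asarray(empirical_draws, dtype=float)
    if p.size == 0 or e.size == 0:
        raise ValueError("both draw sets must be non-empty")
    pv = float(np.var(p))
    ev = float(np.var(e))
    ratio = ev / pv if pv > 0 else (1.0 if ev == 0 else float("inf"))
    tol = 2.0 * (_var_se(p) + _var_se(e))
    return VarianceComparison(
        posterior_var=pv, empirical_var=ev, ratio=ratio,
        violation=ev < pv - tol,
    )


def synthetic_cm(
    phi: float, tpr: float, tnr: float, n: int, random_state=None
) -> ConfusionMatrix:
    """Simulate a confusion matrix from known generating rates.

    Factorises exactly like the inference model: the positive count is
    binomial(n, phi), then TP is binomial over the positives with rate
    ``tpr`` and TN binomial over the negatives with rate ``tnr``.
    """
    for name, v in (("phi", phi), ("tpr", tpr), ("tnr", tnr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(random_state)
    positives = int(rng.binomial(n, phi))
    negatives = n - positives
    tp = int(rng.binomial(positives, tpr)) if positives else 0
    tn = int(rng.binomial(negatives, tnr)) if negatives else 0
    return ConfusionMatrix(tp=tp, fn=positives - tp, fp=negatives - tn, tn=tn)
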