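"""The three-rate Bayesian model of a binary classifier.

A tested classifier is described by three proportions: the prevalence phi
of the positive class in the data, the true positive rate (sensitivity)
and the true negative rate (specificity).  Each gets an independent beta
prior updated conjugately with the corresponding binomial counts of the
confusion matrix.  From joint posterior draws of (phi, TPR, TNR) the
confusion probability matrix

    theta_TP = TPR * phi          theta_FN = (1 - TPR) * phi
    theta_TN = TNR * (1 - phi)    theta_FP = (1 - TNR) * (1 - phi)

is assembled row-wise, and any confusion-matrix metric's posterior follows
by evaluating its formula on the theta draws.

Because phi is data-intrinsic while TPR/TNR are classifier-intrinsic, the
prevalence can be exchanged after fitting to evaluate the classifier on a
deployment population whose base rate differs from the test set's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from sklearn.base import BaseEstimator

from .beta import (
    BetaParams,
    Interval,
    PointMass,
    beta_update,
    get_prior,
    hpd_from_samples,
    hpd_interval,
    split_rhat,
    RHAT_THRESHOLD,
)
from .confusion import ConfusionMatrix
from .metrics import Metric, get_metric, point_estimate

__all__ = [
    "PrevalenceSpec",
    "ClassifierPosterior",
    "ThetaSamples",
    "MetricPosterior",
    "UndefinedMetricError",
    "ConfusionMatrixModel",
    "fit_confusion_model",
    "theta_samples",
    "metric_posterior",
    "acc_direct",
    "deceptive_probability",
    "exchange_prevalence",
    "individual_posterior",
]

#: default number of posterior draws used for metric posteriors
DEFAULT_N_DRAWS = 20_000

#: maximum tolerated fraction of draws on which a metric is undefined
MAX_UNDEFINED_FRACTION = 0.01


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined on more than 1% of posterior draws."""


@dataclass(frozen=True)
class PrevalenceSpec:
    """How the prevalence phi is treated.

    * ``inferred`` — phi gets a beta prior updated with the class counts
      (TP+FN positives vs TN+FP negatives);
    * ``fixed`` — phi is known exactly (test set designed with a specified
      class fraction) and enters as a point mass;
    * ``custom`` — phi follows a user-supplied beta, detached from the
      counts (e.g. an external estimate of the deployment base rate).
    """

    kind: str = "inferred"
    value: Optional[float] = None
    params: Optional[BetaParams] = None

    def __post_init__(self) -> None:
        if self.kind not in ("inferred", "fixed", "custom"):
            raise ValueError(f"unknown prevalence kind {self.kind!r}")
        if self.kind == "fixed":
            if self.value is None or not 0.0 <= self.value <= 1.0:
                raise ValueError("fixed prevalence requires a value in [0, 1]")
        if self.kind == "custom" and not isinstance(self.params, BetaParams):
            raise ValueError("custom prevalence requires BetaParams")

    @classmethod
    def inferred(cls) -> "PrevalenceSpec":
        return cls("inferred")

    @classmethod
    def fixed(cls, value: float) -> "PrevalenceSpec":
        return cls("fixed", value=float(value))

    @classmethod
    def from_beta(cls, alpha: float, beta: float) -> "PrevalenceSpec":
        return cls("custom", params=BetaParams(alpha, beta))

    @classmethod
    def parse(cls, spec) -> "PrevalenceSpec":
        """Coerce user input (None/'inferred', a float, a beta) to a spec."""
        if spec is None or (isinstance(spec, str) and spec.lower() == "inferred"):
            return cls.inferred()
        if isinstance(spec, PrevalenceSpec):
            return spec
        if isinstance(spec, BetaParams):
            return cls("custom", params=spec)
        if isinstance(spec, (int, float)) and not isinstance(spec, bool):
            return cls.fixed(float(spec))
        if isinstance(spec, (tuple, list)) and len(spec) == 2:
            return cls.from_beta(*spec)
        raise TypeError(f"cannot interpret prevalence specification {spec!r}")


@dataclass(frozen=True)
class ClassifierPosterior:
    """Joint (independent-margin) posterior of phi, TPR and TNR."""

    phi: Union[BetaParams, PointMass]
    tpr: BetaParams
    tnr: BetaParams
    priors: dict = field(default_factory=dict)
    source_cm: Optional[ConfusionMatrix] = None


@dataclass(frozen=True)
class ThetaSamples:
    """Posterior draws of the confusion probability matrix.

    ``draws`` has one row per draw with columns (theta_TP, theta_FN,
    theta_TN, theta_FP); each row sums to 1 up to float round-off.  The
    generating rate draws are kept alongside so rate-form metrics can be
    evaluated without round-trip through theta.
    """

    draws: np.ndarray
    phi: np.ndarray
    tpr: np.ndarray
    tnr: np.ndarray
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return self.draws.shape[0]


@dataclass(frozen=True)
class MetricPosterior:
    """Posterior draws of one metric with its plug-in point estimate,
    95% HPD interval and metric uncertainty (MU = interval length)."""

    name: str
    draws: np.ndarray
    point: float
    hpd: Interval
    mu: float
    n_dropped: int = 0

    def summary(self, digits: int = 0) -> str:
        fmt = f"{{:.{digits}%}}"
        pt = "undefined" if np.isnan(self.point) else fmt.format(self.point)
        return (
            f"{self.name.upper()}: point {pt}, "
            f"{self.hpd.mass:.0%} HPD [{fmt.format(self.hpd.lower)}, "
            f"{fmt.format(self.hpd.upper)}], MU {fmt.format(self.mu)}"
        )


def fit_confusion_model(
    cm: ConfusionMatrix,
    priors=None,
    prevalence="inferred",
) -> ClassifierPosterior:
    """Conjugate posterior of (phi, TPR, TNR) given a confusion matrix.

    ``priors`` may be a single prior specification applied to all three
    rates or a mapping with keys 'phi', 'tpr', 'tnr'; the default is the
    uniform Laplace prior Beta(1, 1) for each.
    """
    if priors is None:
        priors = "laplace"
    if isinstance(priors, dict):
        prior_map = {k: get_prior(priors.get(k, "laplace")) for k in ("phi", "tpr", "tnr")}
    else:
        p = get_prior(priors)
        prior_map = {"phi": p, "tpr": p, "tnr": p}

    spec = PrevalenceSpec.parse(prevalence)
    tpr = beta_update(prior_map["tpr"], cm.tp, cm.fn)
    tnr = beta_update(prior_map["tnr"], cm.tn, cm.fp)
    if spec.kind == "inferred":
        phi: Union[BetaParams, PointMass] = beta_update(
            prior_map["phi"], cm.positives, cm.negatives
        )
    elif spec.kind == "fixed":
        phi = PointMass(spec.value)
    else:
        phi = spec.params
    return ClassifierPosterior(
        phi=phi, tpr=tpr, tnr=tnr, priors=prior_map, source_cm=cm
    )


def theta_samples(
    post: ClassifierPosterior, n: int = DEFAULT_N_DRAWS, random_state=None
) -> ThetaSamples:
    """Sample the confusion probability matrix row-wise from independent
    draws of phi, TPR and TNR."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(random_state)
    phi = post.phi.sample(n, rng)
    tpr = post.tpr.sample(n, rng)
    tnr = post.tnr.sample(n, rng)
    draws = np.column_stack([
        tpr * phi,
        (1.0 - tpr) * phi,
        tnr * (1.0 - phi),
        (1.0 - tnr) * (1.0 - phi),
    ])
    seed = random_state if isinstance(random_state, int) else None
    return ThetaSamples(draws=draws, phi=phi, tpr=tpr, tnr=tnr, seed=seed)


def _finish_metric(
    name: str, values: np.ndarray, point: float, mass: float, analytic=None
) -> MetricPosterior:
    bad = np.isnan(values)
    n_dropped = int(bad.sum())
    if n_dropped:
        frac = n_dropped / values.size
        if frac > MAX_UNDEFINED_FRACTION:
            raise UndefinedMetricError(
                f"metric {name!r} undefined on {frac:.1%} of draws "
                f"({n_dropped}/{values.size}); exceeds the {MAX_UNDEFINED_FRACTION:.0%} limit"
            )
        warnings.warn(
            f"metric {name!r}: dropped {n_dropped} undefined draws "
            f"({frac:.3%})", RuntimeWarning, stacklevel=3
        )
        values = values[~bad]
    if analytic is not None:
        # single-beta margins have an exact HPD; prefer it to the sample window
        hpd = hpd_interval(analytic, mass)
    elif values.size >= 100:
        hpd = hpd_from_samples(values, mass)
    else:
        hpd = Interval(float(values.min()), float(values.max()), mass)
    return MetricPosterior(
        name=name, draws=values, point=point, hpd=hpd,
        mu=hpd.width, n_dropped=n_dropped,
    )


def metric_posterior(
    theta: ThetaSamples, metric, cm: Optional[ConfusionMatrix] = None,
    mass: float = 0.95, analytic=None,
) -> MetricPosterior:
    """Posterior of a registered metric evaluated on theta draws.

    Rate-form metrics (ACC, TPR, TNR, prevalence, informedness, balanced
    accuracy) are evaluated directly on the rate draws; the rest on theta
    cells.  Draws where the metric is undefined (zero denominator, possible
    only for degenerate point-mass inputs) are dropped with a warning, and
    an error is raised if more than 1% drop.  The plug-in point estimate
    comes from the source confusion matrix when one is given.  For metrics
    that are single-beta margins, ``analytic`` may carry the exact marginal
    posterior, whose HPD then replaces the sample-window estimate.
    """
    m: Metric = get_metric(metric)
    if m.rate_func is not None:
        values = m.on_rates(theta.phi, theta.tpr, theta.tnr)
    else:
        d = theta.draws
        values = m.on_cells(d[:, 0], d[:, 1], d[:, 2], d[:, 3])
    point = point_estimate(cm, m) if cm is not None else float("nan")
    return _finish_metric(m.name, values, point, mass, analytic=analytic)


def acc_direct(cm: ConfusionMatrix) -> BetaParams:
    """Direct beta posterior of accuracy: Beta(TP+TN+1, FP+FN+1).

    Models the number of correct predictions as a single binomial under a
    uniform prior; also applies to micro-averaged multiclass accuracy.
    """
    return BetaParams(cm.tp + cm.tn + 1.0, cm.fp + cm.fn + 1.0)


def deceptive_probability(bm: MetricPosterior) -> tuple[float, float]:
    """Posterior probabilities that a classifier is informative (BM > 0)
    or deceptive (BM < 0).

    A deceptive classifier is worse than random guessing: following its
    predictions is actively misleading.
    """
    if bm.name != "bm":
        raise ValueError(
            f"deceptive_probability requires the bookmaker-informedness posterior, "
            f"got metric {bm.name!r}"
        )
    r_informative = float(np.mean(bm.draws > 0.0))
    r_deceptive = float(np.mean(bm.draws < 0.0))
    return r_informative, r_deceptive


def exchange_prevalence(
    post: ClassifierPosterior, new_phi
) -> ClassifierPosterior:
    """Replace the prevalence margin, keeping TPR and TNR posteriors.

    Downstream theta draws and metrics then describe the classifier on a
    population with the new base rate — e.g. a screening population whose
    prevalence is far below the enriched test set's.
    """
    spec = PrevalenceSpec.parse(new_phi)
    if spec.kind == "fixed":
        phi: Union[BetaParams, PointMass] = PointMass(spec.value)
    elif spec.kind == "custom":
        phi = spec.params
    else:
        if post.source_cm is None:
            raise ValueError("cannot re-infer prevalence without the source confusion matrix")
        phi = beta_update(post.priors["phi"], post.source_cm.positives,
                          post.source_cm.negatives)
    return replace(post, phi=phi)


def individual_posterior(
    prior_prob: float,
    post: ClassifierPosterior,
    result: str = "positive",
    n: int = DEFAULT_N_DRAWS,
    random_state=None,
    mass: float = 0.95,
) -> MetricPosterior:
    """Posterior probability that an individual has the condition given
    their test result.

    ``prior_prob`` is the individual's pre-test probability (the population
    prevalence, or sharper if previous tests exist).  Each (TPR, TNR)
    posterior draw acts as a likelihood in Bayes' rule, so the returned
    draws propagate classifier uncertainty into the individual's posterior.
    """
    if not 0.0 <= prior_prob <= 1.0:
        raise ValueError("prior_prob must lie in [0, 1]")
    if result not in ("positive", "negative"):
        raise ValueError(f"result must be 'positive' or 'negative', got {result!r}")
    rng = np.random.default_rng(random_state)
    tpr = post.tpr.sample(n, rng)
    tnr = post.tnr.sample(n, rng)
    pi = prior_prob
    with np.errstate(divide="ignore", invalid="ignore"):
        if result == "positive":
            values = pi * tpr / (pi * tpr + (1.0 - pi) * (1.0 - tnr))
        else:
            values = pi * (1.0 - tpr) / (pi * (1.0 - tpr) + (1.0 - pi) * tnr)
    values = np.asarray(values)
    values[~np.isfinite(values)] = np.nan

    point = float("nan")
    if post.source_cm is not None:
        tpr_pt = point_estimate(post.source_cm, "tpr")
        tnr_pt = point_estimate(post.source_cm, "tnr")
        if not (np.isnan(tpr_pt) or np.isnan(tnr_pt)):
            if result == "positive":
                den = pi * tpr_pt + (1.0 - pi) * (1.0 - tnr_pt)
            else:
                den = pi * (1.0 - tpr_pt) + (1.0 - pi) * tnr_pt
            if den > 0:
                num = pi * tpr_pt if result == "positive" else pi * (1.0 - tpr_pt)
                point = num / den
    return _finish_metric(f"p(condition|{result})", values, point, mass)


class ConfusionMatrixModel(BaseEstimator):
    """Bayesian evaluation of a binary classifier from its confusion matrix.

    Fit on a confusion matrix (a :class:`ConfusionMatrix`, a 2x2 array in
    the ``[[TP, FN], [FP, TN]]`` layout, or a length-4 sequence in
    (TP, FN, FP, TN) order); the fitted posterior of (phi, TPR, TNR) then
    yields any metric's posterior, posterior-predictive confusion matrices,
    prevalence exchange and individual-level test interpretation.

    Parameters
    ----------
    prior : str, tuple, BetaParams or dict, default 'laplace'
        Beta prior for the three rates, or a per-rate mapping with keys
        'phi', 'tpr', 'tnr'.  Named options: 'laplace' (uniform),
        'jeffreys', 'haldane' (proper epsilon approximation).
    prevalence : 'inferred', float, (alpha, beta) or PrevalenceSpec
        Treatment of the prevalence margin.
    n_draws : int, default 20000
        Posterior draws used for metric posteriors.
    mass : float, default 0.95
        Credible mass of HPD intervals; metric uncertainty is their length.
    random_state : int or None
        Seed for all sampling performed by this estimator.

    Attributes
    ----------
    cm_ : ConfusionMatrix
        The fitted confusion matrix.
    posterior_ : ClassifierPosterior
        Conjugate posterior of the three rates.
    phi_, tpr_, tnr_ : BetaParams or PointMass
        Marginal posteriors.
    rhat_ : dict
        Split-half Gelman–Rubin diagnostic per rate on the cached draws.

    Examples
    --------
    >>> m = ConfusionMatrixModel(random_state=0).fit([26, 0, 2, 6])
    >>> round(m.metric_posterior("tnr").point, 2)
    0.75
    """

    def __init__(self, prior="laplace", prevalence="inferred",
                 n_draws=DEFAULT_N_DRAWS, mass=0.95, random_state=None):
        self.prior = prior
        self.prevalence = prevalence
        self.n_draws = n_draws
        self.mass = mass
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------
    @staticmethod
    def _coerce_cm(X) -> ConfusionMatrix:
        if isinstance(X, ConfusionMatrix):
            return X
        if isinstance(X, dict):
            return ConfusionMatrix.from_dict(X)
        arr = np.asarray(X)
        if arr.shape == (2, 2):
            return ConfusionMatrix.from_array(arr)
        if arr.shape == (4,):
            return ConfusionMatrix(*[int(v) for v in arr])
        raise ValueError(
            "expected a ConfusionMatrix, a 2x2 array [[TP, FN], [FP, TN]] "
            f"or a length-4 sequence (TP, FN, FP, TN); got shape {arr.shape}"
        )

    def fit(self, X, y=None):
        """Fit the three-rate posterior to a confusion matrix ``X``."""
        self.cm_ = self._coerce_cm(X)
        self.posterior_ = fit_confusion_model(self.cm_, self.prior, self.prevalence)
        self.phi_ = self.posterior_.phi
        self.tpr_ = self.posterior_.tpr
        self.tnr_ = self.posterior_.tnr
        self._theta = None
        return self

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=1, **params):
        """Fit directly from paired label vectors."""
        return cls(**params).fit(ConfusionMatrix.from_predictions(y_true, y_pred, positive))

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("this ConfusionMatrixModel instance is not fitted yet")

    # -- posterior surfaces ------------------------------------------------
    def sample_theta(self, n: Optional[int] = None, random_state=None) -> ThetaSamples:
        """Fresh draws of the confusion probability matrix."""
        self._check_fitted()
        n = self.n_draws if n is None else n
        rs = self.random_state if random_state is None else random_state
        return theta_samples(self.posterior_, n, rs)

    @property
    def theta_(self) -> ThetaSamples:
        """Cached theta draws at the estimator's settings."""
        self._check_fitted()
        if self._theta is None:
            self._theta = self.sample_theta()
        return self._theta

    def metric_posterior(self, metric) -> MetricPosterior:
        """Posterior of one registered metric (see :mod:`cmbayes.metrics`).

        TPR, TNR and prevalence are exact single-beta margins of the model,
        so their HPD intervals come from the analytic posterior; every other
        metric's interval is estimated from the draws.
        """
        self._check_fitted()
        name = get_metric(metric).name
        analytic = {"tpr": self.tpr_, "tnr": self.tnr_, "prev": self.phi_}.get(name)
        return metric_posterior(self.theta_, metric, cm=self.cm_, mass=self.mass,
                                analytic=analytic)

    def acc_direct(self) -> BetaParams:
        """Single-binomial accuracy posterior Beta(TP+TN+1, FP+FN+1)."""
        self._check_fitted()
        return acc_direct(self.cm_)

    def deceptive_probability(self) -> tuple[float, float]:
        """(r_informative, r_deceptive) from the informedness posterior."""
        return deceptive_probability(self.metric_posterior("bm"))

    def exchange_prevalence(self, new_phi) -> "ConfusionMatrixModel":
        """Fitted copy of this model with the prevalence margin replaced."""
        self._check_fitted()
        out = ConfusionMatrixModel(**self.get_params())
        out.prevalence = new_phi
        return out.fit(self.cm_)

    def individual_posterior(self, prior_prob: float, result: str = "positive"
                             ) -> MetricPosterior:
        """Individual's post-test condition probability given a result."""
        self._check_fitted()
        return individual_posterior(prior_prob, self.posterior_, result,
                                    self.n_draws, self.random_state, self.mass)

    def predict(self, n_per_cm: Optional[int] = None, reps: int = 1000):
        """Posterior-predictive confusion matrices (see :mod:`cmbayes.predictive`)."""
        from .predictive import sample_predictive_cm

        self._check_fitted()
        n_per_cm = self.cm_.n if n_per_cm is None else n_per_cm
        return sample_predictive_cm(self.theta_, n_per_cm, reps,
                                    random_state=self.random_state)

    # -- diagnostics -------------------------------------------------------
    @property
    def rhat_(self) -> dict:
        """Split-half R-hat per rate on the cached draws (< 1.01 expected)."""
        t = self.theta_
        def _r(x):
            x = x[: 2 * (len(x) // 2)]
            return split_rhat(x) if np.ptp(x) > 0 else 1.0
        return {"phi": _r(t.phi), "tpr": _r(t.tpr), "tnr": _r(t.tnr)}

    @property
    def converged_(self) -> bool:
        return all(r < RHAT_THRESHOLD for r in self.rhat_.values())
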