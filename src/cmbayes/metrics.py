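"""Registry of confusion-matrix performance metrics.

Every metric is a pure function of the four cell values, applicable both to
raw counts (plug-in point estimates) and to rows of the confusion
probability matrix theta (posterior draws).  Metrics that are functions of
the three underlying rates — prevalence phi, TPR and TNR — additionally
declare a rate form, which is evaluated directly on the rate draws; this
keeps identities such as informedness = TPR + TNR − 1 exact in floating
point instead of holding only up to round-off through theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = ["Metric", "REGISTRY", "register_metric", "get_metric", "point_estimate"]


@dataclass(frozen=True)
class Metric:
    """A named performance metric with its mathematical range.

    ``cell_func(tp, fn, tn, fp)`` evaluates the metric on cell values
    (counts or theta probabilities); ``rate_func(phi, tpr, tnr)``, when
    given, evaluates it directly on the generating rates.
    """

    name: str
    label: str
    cell_func: Callable
    lower: float = 0.0
    upper: float = 1.0
    rate_func: Optional[Callable] = None

    def on_cells(self, tp, fn, tn, fp) -> np.ndarray:
        """Evaluate on cell arrays; undefined entries (0/0 etc.) become NaN."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.asarray(self.cell_func(
                np.asarray(tp, dtype=float),
                np.asarray(fn, dtype=float),
                np.asarray(tn, dtype=float),
                np.asarray(fp, dtype=float),
            ), dtype=float)
        out[~np.isfinite(out)] = np.nan
        return out

    def on_rates(self, phi, tpr, tnr) -> np.ndarray:
        if self.rate_func is None:
            raise ValueError(f"metric {self.name!r} has no rate form")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.asarray(self.rate_func(
                np.asarray(phi, dtype=float),
                np.asarray(tpr, dtype=float),
                np.asarray(tnr, dtype=float),
            ), dtype=float)
        out[~np.isfinite(out)] = np.nan
        return out


REGISTRY: dict[str, Metric] = {}
_ALIASES: dict[str, str] = {}


def register_metric(metric: Metric, aliases: tuple[str, ...] = ()) -> Metric:
    """Add a metric to the registry; new metrics register by formula."""
    key = metric.name.lower()
    if key in REGISTRY:
        raise ValueError(f"metric {metric.name!r} already registered")
    REGISTRY[key] = metric
    for a in aliases:
        _ALIASES[a.lower()] = key
    return metric


def get_metric(name) -> Metric:
    if isinstance(name, Metric):
        return name
    key = str(name).lower()
    key = _ALIASES.get(key, key)
    try:
        return REGISTRY[key]
    except KeyError:
        known = sorted(set(REGISTRY) | set(_ALIASES))
        raise KeyError(f"unknown metric {name!r}; known metrics: {known}") from None


def point_estimate(cm, metric) -> float:
    """Plug-in value of a metric on observed counts; NaN when undefined."""
    m = get_metric(metric)
    return float(m.on_cells(cm.tp, cm.fn, cm.tn, cm.fp))


def _acc(tp, fn, tn, fp):
    return (tp + tn) / (tp + fn + tn + fp)


def _tpr(tp, fn, tn, fp):
    return tp / (tp + fn)


def _tnr(tp, fn, tn, fp):
    return tn / (tn + fp)


def _prev(tp, fn, tn, fp):
    return (tp + fn) / (tp + fn + tn + fp)


def _bm(tp, fn, tn, fp):
    return _tpr(tp, fn, tn, fp) + _tnr(tp, fn, tn, fp) - 1.0


def _ba(tp, fn, tn, fp):
    return 0.5 * (_tpr(tp, fn, tn, fp) + _tnr(tp, fn, tn, fp))


def _ppv(tp, fn, tn, fp):
    return tp / (tp + fp)


def _npv(tp, fn, tn, fp):
    return tn / (tn + fn)


def _f1(tp, fn, tn, fp):
    return 2.0 * tp / (2.0 * tp + fp + fn)


def _mcc(tp, fn, tn, fp):
    num = tp * tn - fp * fn
    den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return num / den


def _mk(tp, fn, tn, fp):
    return _ppv(tp, fn, tn, fp) + _npv(tp, fn, tn, fp) - 1.0


register_metric(Metric("acc", "accuracy", _acc,
                       rate_func=lambda phi, tpr, tnr: tpr * phi + tnr * (1.0 - phi)),
                aliases=("accuracy",))
register_metric(Metric("tpr", "true positive rate", _tpr,
                       rate_func=lambda phi, tpr, tnr: tpr),
                aliases=("sensitivity", "recall"))
register_metric(Metric("tnr", "true negative rate", _tnr,
                       rate_func=lambda phi, tpr, tnr: tnr),
                aliases=("specificity",))
register_metric(Metric("prev", "prevalence", _prev,
                       rate_func=lambda phi, tpr, tnr: phi),
                aliases=("prevalence", "phi"))
register_metric(Metric("bm", "bookmaker informedness", _bm, lower=-1.0,
                       rate_func=lambda phi, tpr, tnr: tpr + tnr - 1.0),
                aliases=("informedness", "youden"))
register_metric(Metric("ba", "balanced accuracy", _ba,
                       rate_func=lambda phi, tpr, tnr: 0.5 * (tpr + tnr)),
                aliases=("balanced_accuracy",))
register_metric(Metric("ppv", "positive predictive value", _ppv),
                aliases=("precision",))
register_metric(Metric("npv", "negative predictive value", _npv))
register_metric(Metric("f1", "F1 score", _f1))
register_metric(Metric("mcc", "Matthews correlation", _mcc, lower=-1.0))
register_metric(Metric("mk", "markedness", _mk, lower=-1.0),
                aliases=("markedness",))
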