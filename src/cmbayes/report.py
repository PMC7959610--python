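"""Human- and machine-readable uncertainty reports for a confusion matrix."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .beta import RHAT_THRESHOLD
from .confusion import ConfusionMatrix
from .design import mu_bound
from .model import ConfusionMatrixModel, UndefinedMetricError

__all__ = ["ReportConfig", "Report", "report"]

DEFAULT_METRICS = ("acc", "prev", "tpr", "tnr", "ba", "bm", "ppv", "npv", "f1", "mcc")


@dataclass(frozen=True)
class ReportConfig:
    """Run-level settings; defaults are uniform priors, 95% intervals and
    20,000 posterior draws."""

    metrics: tuple = DEFAULT_METRICS
    mass: float = 0.95
    n_draws: int = 20_000
    seed: int = 0
    prior: object = "laplace"
    prevalence: object = "inferred"
    digits: int = 0  # display digits after the percent point


@dataclass
class Report:
    """Structured per-metric uncertainty report."""

    cm: ConfusionMatrix
    config: ReportConfig
    rows: list = field(default_factory=list)
    r_informative: float = float("nan")
    r_deceptive: float = float("nan")
    rhat: dict = field(default_factory=dict)
    converged: bool = True
    advice: str = ""

    def to_dict(self) -> dict:
        """Full-precision machine-readable form."""
        return {
            "confusion_matrix": self.cm.to_dict(),
            "settings": {
                "prior": str(self.config.prior),
                "prevalence": str(self.config.prevalence),
                "mass": self.config.mass,
                "n_draws": self.config.n_draws,
                "seed": self.config.seed,
            },
            "metrics": self.rows,
            "bm_split": {
                "r_informative": self.r_informative,
                "r_deceptive": self.r_deceptive,
            },
            "diagnostics": {"split_rhat": self.rhat, "converged": self.converged},
            "advice": self.advice,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        d = self.config.digits
        fmt = f"{{:.{d}%}}"

        def pct(x):
            return "   n/a" if x is None or (isinstance(x, float) and np.isnan(x)) \
                else fmt.format(x)

        lines = [
            f"Confusion matrix: TP={self.cm.tp} FN={self.cm.fn} "
            f"FP={self.cm.fp} TN={self.cm.tn} (N={self.cm.n})",
            f"Prior: {self.config.prior}; prevalence: {self.config.prevalence}; "
            f"{self.config.n_draws} draws; seed {self.config.seed}",
            "",
            f"{'metric':<8}{'point':>10}{'HPD low':>10}{'HPD high':>10}{'MU':>10}",
        ]
        for row in self.rows:
            if row.get("undefined"):
                lines.append(f"{row['metric']:<8}{'undefined (' + row['reason'] + ')':>40}")
                continue
            lines.append(
                f"{row['metric']:<8}{pct(row['point']):>10}"
                f"{pct(row['hpd_lower']):>10}{pct(row['hpd_upper']):>10}"
                f"{pct(row['mu']):>10}"
            )
        if not np.isnan(self.r_deceptive):
            lines += [
                "",
                f"P(informative, BM > 0) = {self.r_informative:.1%}; "
                f"P(deceptive, BM < 0) = {self.r_deceptive:.1%}",
            ]
        flag = "ok" if self.converged else "FLAG: split R-hat >= 1.01"
        lines += ["", f"Split R-hat: " + ", ".join(
            f"{k}={v:.4f}" for k, v in self.rhat.items()) + f" ({flag})"]
        if self.advice:
            lines += [self.advice]
        return "\n".join(lines) + "\n"


def plot_posteriors(cm: ConfusionMatrix, config: ReportConfig, path,
                    metrics=("tpr", "tnr", "bm")) -> None:
    """Histogram the posterior draws of a few metrics into a PNG/PDF file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    model = ConfusionMatrixModel(
        prior=config.prior, prevalence=config.prevalence,
        n_draws=config.n_draws, mass=config.mass, random_state=config.seed,
    ).fit(cm)
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3))
    axes = [axes] if len(metrics) == 1 else list(axes)
    for ax, name in zip(axes, metrics):
        mp = model.metric_posterior(name)
        ax.hist(mp.draws, bins=80, density=True, color="#4878a8")
        ax.axvspan(mp.hpd.lower, mp.hpd.upper, color="orange", alpha=0.2,
                   label=f"{config.mass:.0%} HPD (MU {mp.mu:.0%})")
        if not np.isnan(mp.point):
            ax.axvline(mp.point, color="k", ls="--", lw=1, label="point estimate")
        ax.set_title(mp.name.upper())
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(cm: ConfusionMatrix, config: ReportConfig = ReportConfig()) -> Report:
    """Per-metric point estimate, HPD interval, MU, and for informedness the
    informative/deceptive split; plus sampling diagnostics and significant-
    digit advice derived from the 2/sqrt(N) uncertainty bound."""
    model = ConfusionMatrixModel(
        prior=config.prior, prevalence=config.prevalence,
        n_draws=config.n_draws, mass=config.mass, random_state=config.seed,
    ).fit(cm)

    rows = []
    r_inf, r_dec = float("nan"), float("nan")
    for name in config.metrics:
        try:
            mp = model.metric_posterior(name)
        except UndefinedMetricError as err:
            rows.append({"metric": name, "undefined": True, "reason": str(err)})
            continue
        rows.append({
            "metric": mp.name,
            "point": None if np.isnan(mp.point) else mp.point,
            "hpd_lower": mp.hpd.lower,
            "hpd_upper": mp.hpd.upper,
            "mu": mp.mu,
            "n_dropped": mp.n_dropped,
        })
        if mp.name == "bm":
            r_inf = float(np.mean(mp.draws > 0))
            r_dec = float(np.mean(mp.draws < 0))

    rhat = model.rhat_
    converged = all(v < RHAT_THRESHOLD for v in rhat.values())

    if cm.n > 0:
        bound = mu_bound(cm.n)
        if bound >= 0.005:
            advice = (f"At N={cm.n}, metric uncertainty is of order "
                      f"2/sqrt(N) = {bound:.0%}: report whole percentages at most.")
        else:
            advice = (f"At N={cm.n}, the 2/sqrt(N) bound is {bound:.2%}; "
                      f"decimals beyond this are not significant.")
    else:
        advice = "N=0: prior-only analysis; every metric is maximally uncertain."

    return Report(cm=cm, config=config, rows=rows, r_informative=r_inf,
                  r_deceptive=r_dec, rhat=rhat, converged=converged, advice=advice)
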