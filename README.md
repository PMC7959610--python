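# cmbayes

Bayesian uncertainty quantification for binary-classifier performance
metrics, from nothing but the 2×2 confusion matrix.

Classifiers in biology, chemistry and medicine are routinely evaluated on
small test sets, yet their accuracy, sensitivity and specificity are
reported as if exact.  `cmbayes` replaces those point estimates with
posterior distributions and reports each metric's **metric uncertainty
(MU)** — the length of its 95% highest-posterior-density (HPD) credible
interval — so that a "TPR = 100%" measured on 26 positives is correctly
read as "TPR somewhere between 89% and 100%".

## The model

A test of N instances is three binomial experiments: prevalence
ϕ (how often the positive class occurs), the true positive rate TPR and
the true negative rate TNR.  Each rate gets a beta prior (uniform
Beta(1,1) by default) updated conjugately with the confusion-matrix
counts, so every posterior is an exact beta — no MCMC.  Draws of
(ϕ, TPR, TNR) are mapped to the confusion probability matrix

    θ_TP = TPR·ϕ        θ_FN = (1−TPR)·ϕ
    θ_TN = TNR·(1−ϕ)    θ_FP = (1−TNR)·(1−ϕ)

and any metric of a confusion matrix — accuracy, balanced accuracy, PPV,
NPV, F1, MCC, bookmaker informedness BM = TPR + TNR − 1, … — becomes a
posterior by evaluating its formula on the θ draws.  On top of this the
package provides:

* **deceptiveness**: r_deceptive = P(BM < 0), the probability the
  classifier is worse than random guessing;
* **prevalence exchange**: re-evaluate the classifier on a population
  with a different base rate, and Bayes-invert test results for an
  individual patient;
* **reproducibility analysis**: posterior-predictive confusion matrices
  CM ~ Mult(θ, N), whose plug-in metric spread shows what independent
  replications would report (always wider than the metric's own
  posterior);
* **sample-size planning**: simulation-based power for a precision goal
  ("what N keeps MU below 19 points with 95% power?") plus the analytic
  screen MU ⪅ 2/√N;
* **probabilistic leaderboards**: rank-probability matrices,
  probability-that-the-winner-is-best, and expected prize payouts for
  competition tables of (label, accuracy) on a shared test set.

## Worked example

The running example is a published forensic classifier of cocaine purity
with TP=26, FN=0, FP=2, TN=6:

```sh
cmbayes report --cm 26,0,2,6 --seed 0
```

```
Confusion matrix: TP=26 FN=0 FP=2 TN=6 (N=34)
Prior: laplace; prevalence: inferred; 20000 draws; seed 0

metric       point   HPD low  HPD high        MU
acc            94%       80%       98%       18%
prev           76%       61%       88%       27%
tpr           100%       89%      100%       11%
tnr            75%       43%       95%       51%
ba             88%       70%       96%       26%
bm             75%       39%       92%       52%
ppv            93%       81%       99%       18%
npv           100%       63%      100%       37%
f1             96%       87%       99%       12%
mcc            83%       47%       94%       46%

P(informative, BM > 0) = 100.0%; P(deceptive, BM < 0) = 0.0%

Split R-hat: phi=1.0000, tpr=1.0000, tnr=1.0000 (ok)
At N=34, metric uncertainty is of order 2/sqrt(N) = 34%: report whole percentages at most.
```

The point estimates (TPR 100%, TNR 75%) look decisive; the intervals do
not.  With only 8 negative samples the specificity is anywhere between
43% and 95% — the classifier might produce more false accusations than
correct acquittals, and no one could tell from this test set.

The same analysis in Python, sklearn-style:

```python
from cmbayes import ConfusionMatrixModel

m = ConfusionMatrixModel(prior="laplace", random_state=0).fit([26, 0, 2, 6])
tnr = m.metric_posterior("tnr")
print(tnr.summary())        # TNR: point 75%, 95% HPD [43%, 95%], MU 51%
r_inf, r_dec = m.deceptive_probability()
rare = m.exchange_prevalence(0.01)   # deploy at 1% prevalence
print(rare.metric_posterior("ppv").summary())
```

Planning a better test set:

```sh
cmbayes sample-size --target-mu 0.19 --power 0.95 --omega 0.8 --kappa 10 --seed 1
# Smallest N with P(MU <= 19%) >= 95%: 103  (analytic bound at that N: 19.7%)
```

Other subcommands: `cmbayes leaderboard --file lb.csv --n 15123 --prizes
10000,2000,1000 --seed 1` (probabilistic competition ranking),
`cmbayes predictive` (reproducibility spread), `cmbayes simulate`
(synthetic confusion matrices from known rates).  Every subcommand takes
`--format json` for machine-readable output and a `--seed` making results
exactly reproducible.

See `docs/methods.md` for the model's assumptions, numerical choices and
limitations.

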