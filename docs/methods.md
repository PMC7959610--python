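# Methods

## The model

A binary classifier tested on N instances yields a confusion matrix
CM = [[TP, FN], [FP, TN]]. `cmbayes` treats the test as three independent
binomial experiments governed by three proportions:

* prevalence **ϕ** — P(instance is positive); a property of the data,
  informed by (TP+FN) positives out of N;
* true positive rate **TPR** (sensitivity) — informed by TP out of TP+FN;
* true negative rate **TNR** (specificity) — informed by TN out of TN+FP.

Each rate gets a beta prior, updated conjugately (beta is conjugate to the
binomial, so no MCMC is involved; posteriors are exact betas).  Joint
posterior draws of (ϕ, TPR, TNR) are mapped to the confusion probability
matrix

    θ_TP = TPR·ϕ        θ_FN = (1−TPR)·ϕ
    θ_TN = TNR·(1−ϕ)    θ_FP = (1−TNR)·(1−ϕ)

and any confusion-matrix metric's posterior follows by evaluating its
formula row-wise on the θ draws.  The three rates are sampled
independently — that is the model's factorisation, not an approximation —
and correlations between metrics arise only through the θ arithmetic.

Separating data-intrinsic ϕ from classifier-intrinsic TPR/TNR is what
enables *prevalence exchange*: after fitting, ϕ can be replaced by a
point mass or another beta to evaluate the classifier on a deployment
population (e.g. a screening population far less enriched than the test
set), and by Bayes' rule the same machinery converts an individual's
pre-test probability into a post-test posterior that carries the
classifier's own uncertainty.

### Metric uncertainty

Metric uncertainty (MU) is the length of the 95% highest-posterior-density
interval.  For single-beta margins (TPR, TNR, ϕ) the HPD is computed on
the analytic posterior; for compound metrics (informedness, MCC, PPV, …)
it is the shortest contiguous window over the sorted draws.  MU = 0 means
the metric is known exactly; MU = 0.95 (a uniform posterior) means the
data said nothing.

### Informedness and deceptiveness

Bookmaker informedness BM = TPR + TNR − 1 measures how much better than
random guessing the classifier is (0 = guessing, negative = misleading).
`r_informative` and `r_deceptive` are the posterior masses of BM above
and below 0.  In the registry BM is evaluated directly on the rate draws,
so the identity BM = TPR + TNR − 1 holds exactly in floating point.

### Two accuracy routes

Accuracy can also be modelled as a single binomial:
ACC ~ Beta(TP+TN+1, FP+FN+1).  This direct route is the default for
leaderboard analysis (it is the natural model for published point
accuracies, including micro-averaged multiclass accuracy); the θ route is
the default for confusion-matrix reports.  The two differ by O(1/N)
because their priors differ — a 3-parameter uniform prior does not induce
a uniform prior on ACC.  The discrepancy (~0.5/N in the mean) is real and
documented, not reconciled.

## Posterior-predictive matrices and reproducibility

CM ~ Multinomial(θ, N) with a fresh θ draw per replicate produces
synthetic confusion matrices — what repetitions of the experiment would
report.  Plug-in metric values on those matrices form the *empirical*
distribution, whose variance equals the posterior variance plus the mean
multinomial noise; it therefore always exceeds the true posterior spread
(the package flags any sub-posterior empirical variance beyond twice the
Monte Carlo standard error of a variance estimate, computed from fourth
moments).  At N = 1 the empirical accuracy distribution is supported on
{0, 1} while the posterior after one observed success puts zero mass at
0 — the clearest illustration of why metric posteriors must come from θ,
not from sampled matrices.  Undefined plug-in values (zero denominators
at small N) are excluded and counted, never imputed.

## Sample-size planning

Planning follows a Bayesian power simulation for a precision goal:
hypothesise a generating beta in mode/concentration form
(α = ω(κ−2)+1, β = (1−ω)(κ−2)+1, κ > 2), then repeatedly draw a true
rate, draw Binomial(N) data, update the analysis prior (Laplace by
default) and record the posterior's MU.  Power is the fraction of
simulated studies with MU at or below target.  Because the posterior
depends only on the success count, widths are computed once per distinct
count, which makes 10⁴ replicates take about a second at N = 100.  The MU
distribution is discrete in the success count, so power jumps between
attainable widths; at N = 100 under (ω = 0.8, κ = 10) the 95% quantile of
MU is 19.2 percentage points.

The analytic screen MU ⪅ 2/√N (from the beta standard deviation and the
central limit theorem, usable for N > 20) brackets the search in
`min_sample_size`; targets so tight that the bracket exceeds
`max_simulated_n` (default 2·10⁵) are answered with the screen value
(2/target)² directly — asking for MU ≤ 0.1 percentage point honestly
requires millions of instances and is not worth simulating.

## Probabilistic leaderboards

Each submission's published accuracy on a shared test set of size N is
converted back to counts by round-half-even (|correct/N − acc| ≤ 0.5/N by
construction; a warning is emitted when acc·N is not integral, i.e. when
the published precision cannot pin the counts down).  Sampling one
accuracy per submission per iteration and ranking descending — exact ties
broken uniformly at random — yields a rank-probability matrix whose rows
and columns each sum to 1 exactly.  From it: the probability that the
nominal winner is truly best, and expected prize payouts
payout_i = Σ_r P(rank r)·prize_r, which conserve the prize pool exactly.
All entries must share one N; heterogeneous test sets are rejected.

## Numerical choices

* **HPD algorithm.**  Monotone densities (α ≥ 1 ≥ β or vice versa) are
  closed-form ([q, 1] or [0, q]).  Interior-mode densities minimise the
  width of [Q(t), Q(t+mass)] over the lower-tail offset t by bounded
  scalar optimisation (xatol 10⁻¹²) through `scipy.special.betaincinv`,
  with the bracket endpoints also evaluated so boundary-anchored optima
  (shapes nearly monotone) are returned exactly.  The uniform Beta(1,1)
  is degenerate (all 95% intervals tie); the central [0.025, 0.975] is
  returned by convention.
* **U-shaped densities.**  For α, β < 1 the true 95% HPD region is
  two-sided; the package returns the shortest *contiguous* interval,
  which can exceed 0.95 in width.  The 0.95 "maximal MU" benchmark
  therefore applies to unimodal and monotone posteriors only.
* **Sample-window HPD** uses ⌈mass·n⌉ points and requires ≥ 100 draws;
  it agrees with `arviz.hdi` to the one-draw difference of their window
  conventions.
* **Haldane prior** is represented as Beta(ε, ε), ε = 10⁻⁴, keeping
  posteriors proper when cells are empty.
* **Counts are strict integers**; real-valued cells are rejected, never
  floored.
* **Undefined metric draws** (possible only for degenerate point-mass
  prevalence, e.g. MCC at ϕ = 1) are dropped with a logged count; more
  than 1% dropped raises an error rather than silently distorting the
  HPD.
* **Convergence diagnostic.**  The default 20,000 draws are split into
  two halves and the classic (non rank-normalised) Gelman–Rubin statistic
  is computed; ≥ 1.01 is flagged.  For i.i.d. conjugate draws this is a
  sanity check on the sampling plumbing, not an MCMC necessity.
* **Seeding.**  Every stochastic entry point takes a seed / Generator;
  `min_sample_size` derives a per-candidate-N sub-stream so bisection
  re-evaluates an N on identical draws.

## The synthetic generator and what tests can show

`synthetic_cm(ϕ, tpr, tnr, n)` factorises exactly like the inference
model (positives ~ Binomial(n, ϕ), then two conditional binomials), so
parameter-recovery and coverage tests run under a correctly specified
model.  Real classifier evaluations can violate the model's assumptions —
instances may not be i.i.d., the classifier may drift between test and
deployment, and the reported confusion matrix may mix train/test data.
Passing recovery tests therefore demonstrate the inference machinery is
correct, not that any published confusion matrix satisfies the binomial
sampling picture.

Default test-suite problem sizes (20,000 posterior draws; 10,000 planning
replicates; 200 recovery replicates at N = 10⁵; 50 variance-inflation
fixtures) were chosen so each check's Monte Carlo error is comfortably
below the tolerance it asserts.

## Known limitations

* Binary classification only; no multiclass θ, ROC/AUC uncertainty, or
  score-based models.
* Only uncertainty from finite N is captured — overfitting, dataset shift
  and publication bias are outside the model, so the posteriors are
  best-case.
* The objective-prior family is Laplace/Jeffreys/Haldane; informative
  priors can be passed as explicit (α, β) but no elicitation tooling is
  provided.
* The leaderboard model treats submissions as independent; correlated
  errors between submissions (shared architectures, shared data quirks)
  would tighten or distort rank probabilities in ways the model ignores.
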