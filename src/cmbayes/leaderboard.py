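"""Probabilistic meta-analysis of competing classifiers.

Competition leaderboards publish point accuracies on a shared private test
set of size N.  Reconstructing the correct/incorrect counts from each
point accuracy gives every submission a Beta(correct+1, incorrect+1)
accuracy posterior (the single-binomial model, which also covers
micro-averaged multiclass accuracy).  Monte Carlo draws from these
posteriors yield synthetic leaderboards; tallying how often each
submission lands at each position produces a rank-probability matrix,
from which the probability that the nominal winner is truly best and
probability-weighted prize payouts follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .beta import BetaParams

__all__ = [
    "LeaderboardEntry",
    "RankMatrix",
    "reconstruct_counts",
    "make_entries",
    "rank_distribution",
    "best_probability",
    "expected_prizes",
    "LeaderboardModel",
]

DEFAULT_N_DRAWS = 20_000


def reconstruct_counts(acc_point: float, n: int) -> tuple[int, int]:
    """Recover (correct, incorrect) counts from a published point accuracy.

    Uses round-half-even on ``acc_point * n``; by construction the
    reconstructed accuracy differs from the published one by at most
    0.5/n.  A warning is emitted when the product is not integral, i.e.
    when the published precision does not pin down the counts exactly.
    """
    if not 0.0 <= acc_point <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1], got {acc_point!r}")
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n!r}")
    product = acc_point * n
    correct = int(np.rint(product))
    if abs(product - correct) > 1e-9 * max(1.0, product):
        warnings.warn(
            f"accuracy {acc_point!r} at n={n} does not correspond to an "
            f"integer count; using nearest count {correct} "
            f"(reconstructed accuracy {correct / n:.6g})",
            UserWarning, stacklevel=2,
        )
    return correct, n - correct


@dataclass(frozen=True)
class LeaderboardEntry:
    """One submission: label, published accuracy, reconstructed counts and
    the implied Beta(correct+1, incorrect+1) accuracy posterior."""

    label: str
    acc_point: float
    n: int
    correct: int
    incorrect: int
    posterior: BetaParams

    @classmethod
    def build(cls, label: str, acc_point: float, n: int) -> "LeaderboardEntry":
        correct, incorrect = reconstruct_counts(acc_point, n)
        return cls(
            label=str(label), acc_point=float(acc_point), n=int(n),
            correct=correct, incorrect=incorrect,
            posterior=BetaParams(correct + 1.0, incorrect + 1.0),
        )


def make_entries(table, n: int) -> list[LeaderboardEntry]:
    """Build entries from a (label, accuracy) table sharing one test size.

    ``table`` may be a DataFrame with columns ``label`` and ``accuracy``
    or a sequence of (label, accuracy) pairs.  All submissions must share
    the same n (a single private test set).
    """
    if isinstance(table, pd.DataFrame):
        missing = {"label", "accuracy"} - set(table.columns)
        if missing:
            raise ValueError(f"leaderboard table lacks columns: {sorted(missing)}")
        pairs = list(zip(table["label"], table["accuracy"]))
    else:
        pairs = [(lbl, acc) for lbl, acc in table]
    if not pairs:
        raise ValueError("leaderboard is empty")
    return [LeaderboardEntry.build(lbl, acc, n) for lbl, acc in pairs]


@dataclass(frozen=True)
class RankMatrix:
    """probs[i, r]: probability that submission i occupies rank r (0-based).

    Rows and columns each sum to 1 exactly, because every synthetic
    leaderboard assigns every rank exactly once.
    """

    probs: pd.DataFrame  # index: labels; columns: ranks 1..s
    n_draws: int
    seed: Optional[int] = None

    @property
    def labels(self) -> list:
        return list(self.probs.index)


def _check_entries(entries: Sequence[LeaderboardEntry]) -> None:
    if len(entries) == 0:
        raise ValueError("need at least one leaderboard entry")
    ns = {e.n for e in entries}
    if len(ns) > 1:
        raise ValueError(
            f"all submissions must share one test-set size; got n values {sorted(ns)}"
        )


def rank_distribution(
    entries: Sequence[LeaderboardEntry],
    n_draws: int = DEFAULT_N_DRAWS,
    random_state=None,
) -> RankMatrix:
    """Monte Carlo rank-probability matrix over synthetic leaderboards.

    Per draw, one accuracy is sampled from each submission's posterior and
    submissions are ranked in descending order; exact ties are broken
    uniformly at random.
    """
    _check_entries(entries)
    labels = [e.label for e in entries]
    s = len(entries)
    if s == 1:
        probs = pd.DataFrame([[1.0]], index=labels, columns=[1])
        return RankMatrix(probs=probs, n_draws=n_draws, seed=None)

    rng = np.random.default_rng(random_state)
    alphas = np.array([e.posterior.alpha for e in entries])
    betas = np.array([e.posterior.beta for e in entries])
    samples = rng.beta(alphas, betas, size=(n_draws, s))
    tiebreak = rng.random(size=(n_draws, s))
    # order[d, r] = entry index at rank r in draw d (primary key: -accuracy)
    order = np.lexsort((tiebreak, -samples), axis=1)

    counts = np.zeros((s, s), dtype=np.int64)
    np.add.at(counts, (order.ravel(), np.tile(np.arange(s), n_draws)), 1)
    probs = pd.DataFrame(counts / n_draws, index=labels,
                         columns=np.arange(1, s + 1))
    seed = random_state if isinstance(random_state, int) else None
    return RankMatrix(probs=probs, n_draws=n_draws, seed=seed)


def best_probability(
    entries: Sequence[LeaderboardEntry],
    n_draws: int = DEFAULT_N_DRAWS,
    random_state=None,
) -> float:
    """Probability that the submission with the highest point accuracy is
    truly the best (occupies rank 1)."""
    _check_entries(entries)
    if len(entries) == 1:
        return 1.0
    ranks = rank_distribution(entries, n_draws, random_state)
    top = max(entries, key=lambda e: e.acc_point)
    return float(ranks.probs.loc[top.label, 1])


def expected_prizes(ranks: RankMatrix, prizes: Sequence[float]) -> pd.Series:
    """Probability-weighted payouts: payout_i = sum_r P(rank r) * prize_r.

    The prize vector is padded with zeros to the number of ranks; the
    payouts sum to the total prize pool exactly (up to float round-off),
    because the rank matrix columns each sum to 1.
    """
    s = ranks.probs.shape[1]
    prizes = np.asarray(prizes, dtype=float)
    if prizes.size > s:
        raise ValueError(
            f"prize vector of length {prizes.size} exceeds the {s} available ranks"
        )
    full = np.zeros(s)
    full[: prizes.size] = prizes
    payouts = ranks.probs.to_numpy() @ full
    return pd.Series(payouts, index=ranks.probs.index, name="expected_prize")


class LeaderboardModel(BaseEstimator):
    """Probabilistic leaderboard from point accuracies and a test-set size.

    Parameters
    ----------
    n : int
        Size of the (shared) private test set the accuracies were computed on.
    n_draws : int, default 20000
        Monte Carlo synthetic leaderboards.
    random_state : int or None
        Seed for sampling.

    Attributes
    ----------
    entries_ : list of LeaderboardEntry
    rank_matrix_ : RankMatrix
    best_probability_ : float
        Rank-1 probability of the submission with the highest point accuracy.
    """

    def __init__(self, n=None, n_draws=DEFAULT_N_DRAWS, random_state=None):
        self.n = n
        self.n_draws = n_draws
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit from a (label, accuracy) table (DataFrame or pair sequence)."""
        if self.n is None:
            raise ValueError("the test-set size n must be set before fitting")
        self.entries_ = make_entries(X, self.n)
        self.rank_matrix_ = rank_distribution(
            self.entries_, self.n_draws, self.random_state
        )
        top = max(self.entries_, key=lambda e: e.acc_point)
        self.best_probability_ = float(self.rank_matrix_.probs.loc[top.label, 1]) \
            if len(self.entries_) > 1 else 1.0
        return self

    def expected_prizes(self, prizes: Sequence[float]) -> pd.Series:
        if not hasattr(self, "rank_matrix_"):
            raise RuntimeError("this LeaderboardModel instance is not fitted yet")
        return expected_prizes(self.rank_matrix_, prizes)
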