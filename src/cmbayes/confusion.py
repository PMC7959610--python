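"""The 2x2 confusion matrix: the sole required input of every analysis."""

from __future__ import annotations

import numbers
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix"]


def _check_cell(value, name: str) -> int:
    # Real-valued "counts" are rejected rather than silently floored.
    if isinstance(value, bool) or not isinstance(value, numbers.Integral):
        raise TypeError(f"confusion-matrix cell {name} must be an integer, got {value!r}")
    value = int(value)
    if value < 0:
        raise ValueError(f"confusion-matrix cell {name} must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true positives, false negatives, false positives and true
    negatives from testing a binary classifier.

    The canonical cell order throughout the package is (TP, FN, FP, TN),
    i.e. the row-major layout ``[[TP, FN], [FP, TN]]`` with rows indexed by
    the reference (true) class and columns by the model's prediction.
    ``N = 0`` is allowed and describes a prior-only analysis.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "tp", _check_cell(self.tp, "TP"))
        object.__setattr__(self, "fn", _check_cell(self.fn, "FN"))
        object.__setattr__(self, "fp", _check_cell(self.fp, "FP"))
        object.__setattr__(self, "tn", _check_cell(self.tn, "TN"))

    @property
    def n(self) -> int:
        """Total test-set size."""
        return self.tp + self.fn + self.fp + self.tn

    @property
    def positives(self) -> int:
        """Number of instances whose reference label is positive."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Number of instances whose reference label is negative."""
        return self.tn + self.fp

    @classmethod
    def from_array(cls, arr) -> "ConfusionMatrix":
        """Build from a 2x2 array in the ``[[TP, FN], [FP, TN]]`` layout."""
        arr = np.asarray(arr)
        if arr.shape != (2, 2):
            raise ValueError(f"expected a 2x2 array, got shape {arr.shape}")
        cells = [arr[0, 0], arr[0, 1], arr[1, 0], arr[1, 1]]
        cells = [c.item() if isinstance(c, np.generic) else c for c in cells]
        return cls(*cells)

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=1) -> "ConfusionMatrix":
        """Tally a confusion matrix from paired label vectors."""
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same shape")
        t = y_true == positive
        p = y_pred == positive
        return cls(
            tp=int(np.sum(t & p)),
            fn=int(np.sum(t & ~p)),
            fp=int(np.sum(~t & p)),
            tn=int(np.sum(~t & ~p)),
        )

    def as_array(self) -> np.ndarray:
        """Return the ``[[TP, FN], [FP, TN]]`` layout as an int array."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=int)

    def as_tuple(self) -> tuple[int, int, int, int]:
        """Cells in the canonical (TP, FN, FP, TN) order."""
        return (self.tp, self.fn, self.fp, self.tn)

    def to_dict(self) -> dict:
        return {"TP": self.tp, "FN": self.fn, "FP": self.fp, "TN": self.tn}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionMatrix":
        keys = {k.upper(): v for k, v in d.items()}
        unknown = set(keys) - {"TP", "FN", "FP", "TN"}
        if unknown:
            raise ValueError(f"unknown confusion-matrix keys: {sorted(unknown)}")
        missing = {"TP", "FN", "FP", "TN"} - set(keys)
        if missing:
            raise ValueError(f"missing confusion-matrix keys: {sorted(missing)}")
        return cls(tp=keys["TP"], fn=keys["FN"], fp=keys["FP"], tn=keys["TN"])

    def __str__(self) -> str:
        return f"ConfusionMatrix(TP={self.tp}, FN={self.fn}, FP={self.fp}, TN={self.tn})"
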