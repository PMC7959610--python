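"""Readers and writers for confusion matrices and leaderboard tables.

Three confusion-matrix dialects are supported:

* ``inline`` — a comma-separated string in the canonical TP,FN,FP,TN order;
* ``csv2x2`` — a headerless 2x2 CSV grid with rows = model prediction
  (positive, negative) and columns = reference class (positive, negative),
  i.e. ``[[TP, FP], [FN, TN]]`` — the layout diagnostic papers print;
* ``json-named`` — a JSON object with keys TP, FN, FP, TN.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .confusion import ConfusionMatrix

__all__ = [
    "read_cm",
    "parse_inline_cm",
    "write_cm_json",
    "read_leaderboard",
    "rank_matrix_frame",
]

_DIALECTS = ("inline", "csv2x2", "json-named")


def parse_inline_cm(text: str) -> ConfusionMatrix:
    """Parse 'TP,FN,FP,TN' (the canonical cell order)."""
    parts = [p.strip() for p in str(text).split(",")]
    if len(parts) != 4:
        raise ValueError(
            f"inline confusion matrix must have 4 cells in TP,FN,FP,TN order, "
            f"got {len(parts)}: {text!r}"
        )
    cells = []
    for name, p in zip(("TP", "FN", "FP", "TN"), parts):
        try:
            cells.append(int(p))
        except ValueError:
            raise ValueError(f"cell {name} is not an integer: {p!r}") from None
    return ConfusionMatrix(*cells)


def _read_csv2x2(path) -> ConfusionMatrix:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    if len(rows) != 2 or any(len(r) != 2 for r in rows):
        raise ValueError(
            f"{path}: expected a headerless 2x2 grid "
            "(rows = model positive/negative, columns = reference positive/negative)"
        )
    cells = {}
    names = [["TP", "FP"], ["FN", "TN"]]  # row = model, column = reference
    for i in range(2):
        for j in range(2):
            raw = rows[i][j].strip()
            try:
                v = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: cell ({i + 1}, {j + 1}) [{names[i][j]}] is not an "
                    f"integer: {raw!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"{path}: cell ({i + 1}, {j + 1}) [{names[i][j]}] is negative: {v}"
                )
            cells[names[i][j]] = v
    return ConfusionMatrix.from_dict(cells)


def _read_json(path) -> ConfusionMatrix:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a JSON object with keys TP, FN, FP, TN")
    return ConfusionMatrix.from_dict(data)


def read_cm(source, dialect: str = "infer") -> ConfusionMatrix:
    """Read a confusion matrix from an inline string or a CSV/JSON file.

    With ``dialect='infer'`` a path ending in .json is read as
    ``json-named``, a path ending in .csv as ``csv2x2``, and anything else
    as an inline TP,FN,FP,TN string.
    """
    if dialect not in _DIALECTS + ("infer",):
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "infer":
        p = Path(str(source))
        if p.suffix.lower() == ".json" and p.exists():
            dialect = "json-named"
        elif p.suffix.lower() == ".csv" and p.exists():
            dialect = "csv2x2"
        else:
            dialect = "inline"
    if dialect == "inline":
        return parse_inline_cm(source)
    if dialect == "csv2x2":
        return _read_csv2x2(source)
    return _read_json(source)


def write_cm_json(cm: ConfusionMatrix, path) -> None:
    with open(path, "w") as fh:
        json.dump(cm.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_leaderboard(path) -> pd.DataFrame:
    """Read a leaderboard CSV with header ``label,accuracy``."""
    df = pd.read_csv(path)
    missing = {"label", "accuracy"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: leaderboard CSV must have header 'label,accuracy'; "
            f"missing columns: {sorted(missing)}"
        )
    if df.empty:
        raise ValueError(f"{path}: leaderboard is empty")
    bad = df[(df["accuracy"] < 0) | (df["accuracy"] > 1)]
    if not bad.empty:
        raise ValueError(
            f"{path}: accuracies outside [0, 1] for labels "
            f"{bad['label'].tolist()}"
        )
    return df[["label", "accuracy"]]


def rank_matrix_frame(rank_matrix) -> pd.DataFrame:
    """Rank matrix as a DataFrame with a 'label' column, ready for CSV."""
    df = rank_matrix.probs.copy()
    df.columns = [f"rank_{c}" for c in df.columns]
    df.insert(0, "label", df.index)
    return df.reset_index(drop=True)
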