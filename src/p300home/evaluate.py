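"""Evaluation: selection accuracies, display contrast, classifier
comparison tables, and information-transfer rate.

Accuracies are percentages of correct selections.  The study protocol
gives each subject 20 test selections per display, so per-subject
accuracies are multiples of 5%.  The display contrast is the mean
secondary-display (numbers) accuracy minus the mean primary-display
(symbols) accuracy in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decode import SelectionResult

__all__ = [
    "AccuracyTable",
    "selection_accuracy",
    "build_accuracy_table",
    "display_contrast",
    "compare_classifiers",
    "information_transfer_rate",
]


def _round2(x: float) -> float:
    """Half-up rounding to two decimals (table precision)."""
    return float(np.floor(x * 100 + 0.5) / 100)


@dataclass
class AccuracyTable:
    """Per-subject primary/secondary/average accuracies plus a mean row."""

    rows: pd.DataFrame  # columns: subject, primary, secondary, average
    mean_row: pd.Series  # columns means over subjects

    def validate(self) -> None:
        r = self.rows
        # entries are rounded to table precision (2 decimals), hence the atol
        if not np.allclose(r["average"], (r["primary"] + r["secondary"]) / 2, atol=0.0051):
            raise ValueError("average column must equal (primary+secondary)/2")
        for col in ("primary", "secondary", "average"):
            if not ((r[col] >= 0) & (r[col] <= 100)).all():
                raise ValueError("accuracies must lie in [0, 100]")
            if not np.isclose(self.mean_row[col], r[col].mean(), atol=0.0051):
                raise ValueError("mean_row must hold the column means")

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat(
            [self.rows, self.mean_row.to_frame().T.assign(subject="Mean")],
            ignore_index=True,
        )
        out.to_csv(path, sep="\t", index=False)


def selection_accuracy(results: Sequence[SelectionResult] | Sequence[float]) -> float:
    """Percent of selections whose chosen symbol equals the true symbol.

    Accepts SelectionResults (each must carry a known true symbol) or an
    already-computed 0/1 correctness sequence.
    """
    if len(results) == 0:
        raise ValueError("cannot compute accuracy of zero selections")
    flags = []
    for r in results:
        if isinstance(r, SelectionResult):
            if r.true_symbol is None:
                raise ValueError("every result needs a known true_symbol")
            flags.append(r.correct)
        else:
            flags.append(bool(r))
    return 100.0 * float(np.mean(flags))


def build_accuracy_table(
    per_subject: Mapping[str, tuple[Sequence, Sequence]] | Mapping[str, tuple[float, float]],
) -> AccuracyTable:
    """Build the per-display accuracy table from per-subject results.

    ``per_subject`` maps a subject id to ``(primary, secondary)`` where
    each element is either a list of SelectionResults or an accuracy
    percentage already computed from one.
    """
    rows = []
    for subject, (prim, sec) in per_subject.items():
        p = prim if np.isscalar(prim) else selection_accuracy(prim)
        s = sec if np.isscalar(sec) else selection_accuracy(sec)
        rows.append(
            {"subject": subject, "primary": float(p), "secondary": float(s),
             "average": _round2((float(p) + float(s)) / 2)}
        )
    df = pd.DataFrame(rows)
    mean_row = pd.Series(
        {col: _round2(df[col].mean()) for col in ("primary", "secondary", "average")}
    )
    table = AccuracyTable(rows=df, mean_row=mean_row)
    table.validate()
    return table


def display_contrast(table: AccuracyTable) -> float:
    """Mean secondary accuracy minus mean primary accuracy (points)."""
    return _round2(table.mean_row["secondary"] - table.mean_row["primary"])


def compare_classifiers(
    per_subject_results: Mapping[tuple[str, str], Sequence],
    methods: Sequence[str] = ("random_forest", "svm", "lda", "knn"),
) -> pd.DataFrame:
    """Per-subject accuracy per classifier, with a Mean row appended.

    ``per_subject_results`` maps ``(subject, method)`` to a list of
    SelectionResults or to a precomputed accuracy percentage.
    """
    subjects = sorted({s for s, _ in per_subject_results})
    for s in subjects:
        for m in methods:
            if (s, m) not in per_subject_results:
                raise ValueError(f"missing results for subject {s!r}, method {m!r}")
    rows = []
    for s in subjects:
        row = {"subject": s}
        for m in methods:
            res = per_subject_results[(s, m)]
            row[m] = float(res) if np.isscalar(res) else selection_accuracy(res)
        rows.append(row)
    df = pd.DataFrame(rows)
    mean = {"subject": "Mean", **{m: _round2(df[m].mean()) for m in methods}}
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)


def information_transfer_rate(
    n_classes: int, accuracy: float, selection_time: float
) -> float:
    """Wolpaw information-transfer rate in bits per minute.

    bits/selection = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)),
    times 60/selection_time.  P=1 degenerates to log2 N; accuracy at or
    below chance carries zero (or negative, clipped meaningless) bits —
    returned as computed except P=0 with N>1, where the limit is used.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not 0 <= accuracy <= 1:
        raise ValueError("accuracy must be a probability")
    if selection_time <= 0:
        raise ValueError("selection_time must be positive")
    n, p = n_classes, accuracy
    bits = np.log2(n)
    if 0 < p < 1:
        bits += p * np.log2(p) + (1 - p) * np.log2((1 - p) / (n - 1))
    elif p == 0:
        bits += np.log2(1.0 / (n - 1))
    return float(bits * 60.0 / selection_time)
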