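"""Multiclass evaluation metrics derived from a confusion matrix.

Per-class sensitivity, specificity, accuracy and Matthews correlation
coefficient (MCC) come from one-vs-rest marginal counts; the overall
accuracy is the trace fraction; macro averages weight every class
equally; and the overall multiclass MCC is Gorodkin's R_K statistic
computed directly from the K x K matrix, which reduces exactly to the
binary MCC when K = 2.

Undefined ratios (zero denominators) are returned as NaN with a warning,
never silently as zero, so degenerate matrices cannot masquerade as
informative ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix: entry (k, l) = actual class k predicted as l."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(
                f"counts shape {counts.shape} does not match {k} classes"
            )
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if counts.sum() < 1:
            raise ValueError("confusion matrix is empty")
        if len(set(self.classes)) != k:
            raise ValueError("duplicate class labels")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        classes: Sequence[str],
    ) -> "ConfusionMatrix":
        if len(y_true) != len(y_pred):
            raise ValueError("y_true and y_pred differ in length")
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(classes=tuple(classes), counts=counts)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot add confusion matrices over different classes")
        return ConfusionMatrix(self.classes, self.counts + other.counts)


class BinaryCounts(NamedTuple):
    """One-vs-rest marginal counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class BinaryMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


def one_vs_rest(cm: ConfusionMatrix, k: str) -> BinaryCounts:
    """Collapse a confusion matrix to TP/TN/FP/FN for class ``k`` vs rest."""
    try:
        i = cm.classes.index(k)
    except ValueError:
        raise KeyError(f"unknown class {k!r}; have {list(cm.classes)}") from None
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i, :].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.n - tp - fn - fp
    return BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning NaN", stacklevel=3)
        return math.nan
    return num / den


def binary_metrics(b: BinaryCounts) -> BinaryMetrics:
    """Sensitivity, specificity, accuracy and MCC from one-vs-rest counts.

    Values are fractions in [0, 1] (MCC in [-1, 1]); undefined cases are
    NaN with a warning.
    """
    sens = _ratio(b.tp, b.tp + b.fn, "sensitivity")
    spec = _ratio(b.tn, b.tn + b.fp, "specificity")
    acc = _ratio(b.tp + b.tn, b.n, "accuracy")
    denom = (
        (b.tp + b.fp) * (b.tp + b.fn) * (b.tn + b.fp) * (b.tn + b.fn)
    )
    if denom == 0:
        warnings.warn("MCC undefined (zero denominator); returning NaN", stacklevel=2)
        mcc = math.nan
    else:
        mcc = (b.tp * b.tn - b.fp * b.fn) / math.sqrt(denom)
    return BinaryMetrics(sensitivity=sens, specificity=spec, accuracy=acc, mcc=mcc)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace / N."""
    return float(np.trace(cm.counts)) / cm.n


def macro_metrics(cm: ConfusionMatrix) -> tuple[float, float]:
    """Unweighted per-class means of one-vs-rest accuracy and MCC."""
    accs, mccs = [], []
    for k in cm.classes:
        m = binary_metrics(one_vs_rest(cm, k))
        accs.append(m.accuracy)
        mccs.append(m.mcc)
    return float(np.mean(accs)), float(np.mean(mccs))


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """Gorodkin's R_K multiclass correlation from the confusion matrix.

    ``(N tr(C) - sum_k r_k c_k) / sqrt((N^2 - sum c_k^2)(N^2 - sum r_k^2))``
    with row sums ``r_k`` and column sums ``c_k``; identical to the binary
    MCC when K = 2.  Undefined denominators yield NaN with a warning.
    """
    c = cm.counts.astype(float)
    n = c.sum()
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    num = n * np.trace(c) - rows @ cols
    den_sq = (n**2 - (cols**2).sum()) * (n**2 - (rows**2).sum())
    if den_sq <= 0:
        warnings.warn(
            "multiclass MCC undefined (zero denominator); returning NaN",
            stacklevel=2,
        )
        return math.nan
    return float(num / math.sqrt(den_sq))


def metrics_report(cm: ConfusionMatrix) -> dict[str, object]:
    """All per-class and aggregate metrics in one structure.

    Per-class sensitivity/specificity/accuracy are percentages (0-100);
    MCC values stay on [-1, 1].
    """
    per_class = {}
    for k in cm.classes:
        m = binary_metrics(one_vs_rest(cm, k))
        per_class[k] = {
            "sensitivity": 100.0 * m.sensitivity,
            "specificity": 100.0 * m.specificity,
            "accuracy": 100.0 * m.accuracy,
            "mcc": m.mcc,
        }
    macro_acc, macro_mcc = macro_metrics(cm)
    return {
        "per_class": per_class,
        "overall_accuracy": 100.0 * overall_accuracy(cm),
        "overall_mcc": multiclass_mcc(cm),
        "macro_accuracy": 100.0 * macro_acc,
        "macro_mcc": macro_mcc,
        "n": cm.n,
    }


def format_report(cm: ConfusionMatrix) -> str:
    """Human-readable metrics table (percentages with two decimals)."""
    rep = metrics_report(cm)
    lines = [f"{'class':<14}{'sens%':>8}{'spec%':>8}{'acc%':>8}{'mcc':>8}"]
    for k, m in rep["per_class"].items():
        lines.append(
            f"{k:<14}{m['sensitivity']:>8.2f}{m['specificity']:>8.2f}"
            f"{m['accuracy']:>8.2f}{m['mcc']:>8.2f}"
        )
    lines.append(
        f"{'overall':<14}{'':>8}{'':>8}"
        f"{rep['overall_accuracy']:>8.2f}{rep['overall_mcc']:>8.2f}"
    )
    lines.append(
        f"{'macro':<14}{'':>8}{'':>8}"
        f"{rep['macro_accuracy']:>8.2f}{rep['macro_mcc']:>8.2f}"
    )
    return "\n".join(lines)


def read_confusion(path: str | Path) -> ConfusionMatrix:
    """Read a tab-delimited confusion matrix with class-label header row/column."""
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    classes = tuple(header[1:])
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    seen: set[str] = set()
    for ln in lines[1:]:
        parts = ln.split("\t")
        label = parts[0]
        if label not in classes:
            raise ValueError(f"{path}: row label {label!r} not in header")
        if label in seen:
            raise ValueError(f"{path}: duplicate row label {label!r}")
        seen.add(label)
        counts[classes.index(label)] = [int(x) for x in parts[1:]]
    if seen != set(classes):
        raise ValueError(f"{path}: missing rows for {sorted(set(classes) - seen)}")
    return ConfusionMatrix(classes=classes, counts=counts)


def write_confusion(cm: ConfusionMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("actual\\predicted\t" + "\t".join(cm.classes) + "\n")
        for k, row in zip(cm.classes, cm.counts):
            fh.write(k + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
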