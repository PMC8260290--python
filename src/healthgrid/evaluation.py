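"""Classifier evaluation metrics and measurement-verification arithmetic.

Three-class results are scored one-vs-rest: for each class the remaining two
classes are pooled as negatives, giving binary TP/FP/TN/FN counts from which

    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)

are computed per class. The macro summary is the unweighted mean and
population standard deviation of the three per-class accuracies. Micro
accuracy (trace / total) is a distinct quantity and is reported separately,
never conflated with the macro average.

The module also carries the device-verification arithmetic: relative error
of a test-node measurement against a reference device, rounded half-up to
one decimal percent, plus the published cuff and pedometer verification
tables used as fixed reference inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

__all__ = [
    "N_CLASSES",
    "CLASS_NAMES",
    "ClassMetrics",
    "MacroSummary",
    "confusion",
    "class_metrics",
    "macro_summary",
    "micro_accuracy",
    "relative_error",
    "BP_VERIFICATION_TABLE",
    "STEP_VERIFICATION_TABLE",
    "verify_tables",
]

N_CLASSES = 3
CLASS_NAMES = ("health", "sub-health", "illness")


# ---------------------------------------------------------------------------
# Confusion accounting
# ---------------------------------------------------------------------------

def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> np.ndarray:
    """3x3 confusion matrix; rows are true classes, columns predicted."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    if t.size and (t.min() < 0 or t.max() >= N_CLASSES or p.min() < 0 or p.max() >= N_CLASSES):
        raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def _check_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.shape != (N_CLASSES, N_CLASSES):
        raise ValueError(f"confusion matrix must be {N_CLASSES}x{N_CLASSES}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix counts must be nonnegative")
    return cm.astype(int)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest counts and rates for a single class.

    ``degenerate_precision`` / ``degenerate_recall`` flag divisions by zero
    (no predicted positives / no true positives); the affected rate is
    reported as 0 rather than NaN so small test sets summarize stably.
    """

    class_index: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    recall: float
    precision: float
    f1: float
    degenerate_precision: bool = False
    degenerate_recall: bool = False


def class_metrics(cm: np.ndarray, class_index: int) -> ClassMetrics:
    """One-vs-rest TP/FP/TN/FN and the four binary rates for one class."""
    cm = _check_cm(cm)
    if not 0 <= class_index < N_CLASSES:
        raise ValueError(f"class index out of range: {class_index}")
    k = class_index
    tp = int(cm[k, k])
    fn = int(cm[k].sum() - tp)
    fp = int(cm[:, k].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)

    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else 0.0
    degenerate_recall = (tp + fn) == 0
    degenerate_precision = (tp + fp) == 0
    recall = 0.0 if degenerate_recall else tp / (tp + fn)
    precision = 0.0 if degenerate_precision else tp / (tp + fp)
    f1 = 0.0 if tp == 0 else 2.0 * precision * recall / (precision + recall)
    return ClassMetrics(
        class_index=k, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, recall=recall, precision=precision, f1=f1,
        degenerate_precision=degenerate_precision,
        degenerate_recall=degenerate_recall,
    )


@dataclass(frozen=True)
class MacroSummary:
    mean_accuracy: float
    sd_accuracy: float          # population sd over the 3 per-class accuracies
    per_class: tuple[ClassMetrics, ...]


def macro_summary(cm: np.ndarray) -> MacroSummary:
    """Unweighted mean +/- population sd of the per-class one-vs-rest accuracies."""
    per_class = tuple(class_metrics(cm, k) for k in range(N_CLASSES))
    accs = np.array([m.accuracy for m in per_class])
    return MacroSummary(
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std()),  # ddof=0
        per_class=per_class,
    )


def micro_accuracy(cm: np.ndarray) -> float:
    """Fraction of samples on the diagonal (overall hit rate)."""
    cm = _check_cm(cm)
    total = cm.sum()
    return float(np.trace(cm) / total) if total else 0.0


# ---------------------------------------------------------------------------
# Device-verification arithmetic
# ---------------------------------------------------------------------------

def relative_error(reference: float, measured: float) -> float:
    """Relative error in percent, rounded half-up to one decimal.

    100 * |measured - reference| / reference, against a nonzero reference.
    """
    if reference == 0:
        raise ValueError("reference measurement must be nonzero")
    pct = 100.0 * abs(measured - reference) / abs(reference)
    return float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# Cuff verification: (reference SP, node SP, printed error %, reference DP,
# node DP, printed error %) per subject, reference device a clinical monitor.
BP_VERIFICATION_TABLE: tuple[tuple[float, float, float, float, float, float], ...] = (
    (120, 123, 2.5, 83, 86, 3.6),
    (107, 112, 4.7, 78, 82, 5.1),
    (124, 130, 4.8, 89, 86, 3.4),
    (109, 105, 3.7, 78, 81, 3.8),
    (140, 145, 3.6, 95, 99, 4.2),
)

# Pedometer verification: (reference steps, node steps, printed error %,
# reference sleep h, node sleep h, printed error %) per subject, reference
# device a commercial sports bracelet.
STEP_VERIFICATION_TABLE: tuple[tuple[float, float, float, float, float, float], ...] = (
    (5600, 5743, 2.6, 6.5, 6.3, 3.1),
    (8212, 7920, 3.6, 7.4, 7.0, 5.4),
    (15401, 16280, 5.7, 8.2, 7.7, 6.1),
    (7231, 7102, 1.8, 7.1, 6.6, 7.0),
    (11005, 10098, 8.2, 9.4, 9.0, 4.3),
)


@dataclass(frozen=True)
class TableVerification:
    n_cells: int
    n_matching: int
    max_bp_error: float     # largest recomputed cuff error, percent
    max_step_error: float   # largest recomputed pedometer error, percent
    mismatches: tuple[tuple[str, int, float, float], ...]  # (table, row, printed, recomputed)

    @property
    def all_match(self) -> bool:
        return self.n_matching == self.n_cells


def verify_tables() -> TableVerification:
    """Recompute every printed error cell of the two verification tables.

    Each (reference, node) pair is run through :func:`relative_error` and
    compared with the printed percent at one-decimal precision.
    """
    mismatches: list[tuple[str, int, float, float]] = []
    n_cells = 0
    n_matching = 0
    max_bp = 0.0
    max_step = 0.0
    for name, table in (("bp", BP_VERIFICATION_TABLE), ("step", STEP_VERIFICATION_TABLE)):
        for row_idx, (ref_a, test_a, err_a, ref_b, test_b, err_b) in enumerate(table, start=1):
            for printed, recomputed in (
                (err_a, relative_error(ref_a, test_a)),
                (err_b, relative_error(ref_b, test_b)),
            ):
                n_cells += 1
                if abs(recomputed - printed) < 0.05:
                    n_matching += 1
                else:
                    mismatches.append((name, row_idx, printed, recomputed))
                if name == "bp":
                    max_bp = max(max_bp, recomputed)
                else:
                    max_step = max(max_step, recomputed)
    return TableVerification(
        n_cells=n_cells,
        n_matching=n_matching,
        max_bp_error=max_bp,
        max_step_error=max_step,
        mismatches=tuple(mismatches),
    )
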