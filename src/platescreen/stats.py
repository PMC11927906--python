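"""Evaluation metrics and paired-classifier statistics.

Covers accuracy, the macro-averaged F1 score computed from a confusion
matrix (unweighted mean over classes of 2*TP / (2*TP + FN + FP); a class
with no truth and no predictions contributes 0 by convention), image-wise
and well-wise confusion matrices, McNemar's chi-squared test on the
discordant cells of a paired 2x2 agreement table, and the Pearson
correlation used to compare combined-channel with single-channel
predictions.

McNemar's statistic is (a - b)^2 / (a + b) on 1 df, where a counts items
only the first classifier got right and b items only the second got right.
The continuity-corrected variant uses (|a - b| - 1)^2 / (a + b); both are
first-class and every report states which was used.  For a = 32, b = 1 the
two give 29.12 and 27.27 respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ConfusionMatrix",
    "McNemarResult",
    "AgreementTable",
    "accuracy",
    "confusion",
    "macro_f1",
    "mcnemar",
    "build_agreement_table",
    "channel_correlation",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple
    level: str = "image"  # "image" or "well"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("negative counts")

    @property
    def n(self) -> int:
        return int(np.asarray(self.counts).sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))

    # numpy interop so ConfusionMatrix can be treated as its count array
    def __array__(self, dtype=None):
        return np.asarray(self.counts, dtype=dtype)


def accuracy(true, predicted) -> float:
    """Fraction of correct predictions."""
    t = np.asarray(true)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("true and predicted must have equal length")
    if t.size == 0:
        raise ValueError("empty input")
    return float((t == p).mean())


def confusion(true, predicted, labels=None, level: str = "image") -> ConfusionMatrix:
    """Count matrix of true (rows) vs predicted (columns) labels."""
    t = np.asarray(true)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("true and predicted must have equal length")
    if labels is None:
        labels = np.unique(np.concatenate([t, p]))
    labels = np.asarray(labels)
    pos = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for ti, pi in zip(t, p):
        counts[pos[ti], pos[pi]] += 1
    return ConfusionMatrix(counts=counts, labels=tuple(labels), level=level)


def macro_f1(cm: ConfusionMatrix | np.ndarray) -> float:
    """Unweighted mean over classes of 2*TP / (2*TP + FN + FP).

    A class with TP = FN = FP = 0 (no truth, no predictions) contributes 0.
    """
    counts = np.asarray(cm.counts if isinstance(cm, ConfusionMatrix) else cm, dtype=float)
    if counts.sum() == 0:
        raise ValueError("all-zero confusion matrix")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    denom = 2 * tp + fn + fp
    f1 = np.divide(2 * tp, denom, out=np.zeros_like(tp), where=denom > 0)
    return float(f1.mean())


@dataclass(frozen=True)
class McNemarResult:
    a: int          # correct only by the first (e.g. ensemble) classifier
    b: int          # correct only by the second (e.g. best single) classifier
    statistic: float
    p_value: float
    continuity: bool


def mcnemar(a: int, b: int, continuity: bool = False) -> McNemarResult:
    """Chi-squared test on the discordant counts of a paired comparison.

    Without continuity correction: (a - b)^2 / (a + b).  With it:
    (|a - b| - 1)^2 / (a + b), the numerator clamped at 0.  The p-value is
    the upper tail of chi-squared with 1 df.
    """
    if a < 0 or b < 0:
        raise ValueError("counts must be >= 0")
    if a + b == 0:
        raise ValueError("undefined test: no discordant pairs (a + b = 0)")
    if continuity:
        num = max(abs(a - b) - 1.0, 0.0) ** 2
    else:
        num = float(a - b) ** 2
    stat = num / (a + b)
    p = float(sps.chi2.sf(stat, df=1))
    return McNemarResult(a=int(a), b=int(b), statistic=stat, p_value=p,
                         continuity=continuity)


@dataclass(frozen=True)
class AgreementTable:
    """2x2 paired-classifier agreement cells; cells sum to n."""

    both_correct: int
    a_only: int   # first classifier correct, second wrong
    b_only: int   # second classifier correct, first wrong
    both_wrong: int

    @property
    def n(self) -> int:
        return self.both_correct + self.a_only + self.b_only + self.both_wrong

    @property
    def discordant(self) -> tuple[int, int]:
        return self.a_only, self.b_only


def build_agreement_table(true, pred_a, pred_b) -> AgreementTable:
    """Cross-classify two models' correctness on the same items.

    Pass the ensemble as ``pred_a`` to follow the screening convention in
    which ``a`` counts items only the ensemble classified correctly.
    """
    t = np.asarray(true)
    pa = np.asarray(pred_a)
    pb = np.asarray(pred_b)
    if not (t.shape == pa.shape == pb.shape):
        raise ValueError("sequences must have equal length")
    ca = pa == t
    cb = pb == t
    return AgreementTable(
        both_correct=int((ca & cb).sum()),
        a_only=int((ca & ~cb).sum()),
        b_only=int((~ca & cb).sum()),
        both_wrong=int((~ca & ~cb).sum()),
    )


def channel_correlation(pred_combined, pred_single) -> float:
    """Pearson r between paired per-well control proportions."""
    x = np.asarray(pred_combined, dtype=float)
    y = np.asarray(pred_single, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired wells")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for a constant vector")
    r, _ = sps.pearsonr(x, y)
    return float(r)
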