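"""Segmentation-quality and inter-rater agreement statistics.

Covers the evaluation battery used to validate automated pterygium staging
against clinician visual inspection: Dice, mean IoU and pixel accuracy for
masks; Pearson chi-square with the contingency coefficient
``C = sqrt(chi2 / (n + chi2))`` (bounded by ``sqrt((k-1)/k)``); Cohen's
kappa; binary diagnostic metrics; ROC/AUC with the Youden-optimal cutoff;
and Bland-Altman limits of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "CrossTab", "ChiSquareResult", "KappaResult", "BinaryConfusion",
    "BinaryMetrics", "RocResult", "BlandAltmanResult",
    "dice_coefficient", "miou", "pixel_accuracy",
    "chi_square_with_C", "cohen_kappa", "binary_metrics",
    "roc_auc_youden", "bland_altman",
]


# ---------------------------------------------------------------- mask scores

def _check_pair(pred, truth):
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return p > 0 if p.dtype != bool else p, t > 0 if t.dtype != bool else t


def dice_coefficient(pred, truth) -> float:
    """2|X∩Y| / (|X|+|Y|); 1.0 when both masks are empty."""
    p, t = _check_pair(pred, truth)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(p, t).sum() / denom


def miou(pred, truth) -> float:
    """Mean IoU over the two classes (background, foreground)."""
    p, t = _check_pair(pred, truth)
    ious = []
    for cls in (False, True):
        pi, ti = p == cls, t == cls
        union = np.logical_or(pi, ti).sum()
        if union == 0:
            ious.append(1.0)
        else:
            ious.append(np.logical_and(pi, ti).sum() / union)
    return float(np.mean(ious))


def pixel_accuracy(pred, truth) -> float:
    p, t = _check_pair(pred, truth)
    return float((p == t).mean())


# ---------------------------------------------------------------- crosstab

@dataclass
class CrossTab:
    """k x k contingency table; rows = reference rating, cols = prediction."""

    counts: np.ndarray
    labels: list | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("crosstab must be square")
        if self.counts.shape[0] < 2:
            raise ValueError("crosstab needs k >= 2 categories")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or (self.counts < 0).any():
                raise ValueError("counts must be non-negative integers")
            self.counts = np.round(self.counts).astype(np.int64)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(cls, reference, prediction, labels=None) -> "CrossTab":
        ref = pd.Series(reference)
        pred = pd.Series(prediction)
        if labels is None:
            labels = sorted(set(ref) | set(pred))
        tab = pd.crosstab(ref, pred).reindex(index=labels, columns=labels,
                                             fill_value=0)
        return cls(tab.to_numpy(), labels=list(labels))

    @classmethod
    def from_csv(cls, path) -> "CrossTab":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), labels=list(df.columns))

    def to_csv(self, path):
        labels = self.labels or list(range(self.k))
        pd.DataFrame(self.counts, index=labels, columns=labels).to_csv(path)


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    C: float
    C_max: float


def chi_square_with_C(tab: CrossTab) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) plus contingency coefficient.

    ``C = sqrt(chi2 / (n + chi2))``; its supremum for a k x k table is
    ``C_max = sqrt((k-1)/k)`` (0.8165 for k = 3).
    """
    counts = tab.counts.astype(float)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    for i, r in enumerate(rows):
        if r == 0:
            raise ValueError(f"degenerate crosstab: row {i} has zero total")
    for j, c in enumerate(cols):
        if c == 0:
            raise ValueError(f"degenerate crosstab: column {j} has zero total")
    n = counts.sum()
    expected = np.outer(rows, cols) / n
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = (tab.k - 1) ** 2
    p = float(chi2_dist.sf(chi2, df))
    c = math.sqrt(chi2 / (n + chi2))
    c_max = math.sqrt((tab.k - 1) / tab.k)
    return ChiSquareResult(chi2=chi2, df=df, p_value=p, C=c, C_max=c_max)


@dataclass
class KappaResult:
    po: float
    pe: float
    kappa: float
    weighted: bool = False


def cohen_kappa(tab: CrossTab, weighted: bool = False) -> KappaResult:
    """Cohen's kappa, ``(Po - Pe) / (1 - Pe)``; unweighted by default.

    ``weighted=True`` selects linear disagreement weights over the ordinal
    categories (quadratic-style weighted kappa with weight |i-j|/(k-1)).
    """
    counts = tab.counts.astype(float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty crosstab")
    p = counts / n
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    if weighted:
        k = tab.k
        i, j = np.mgrid[0:k, 0:k]
        w = 1.0 - np.abs(i - j) / (k - 1)
        po = float((w * p).sum())
        pe = float((w * np.outer(rows, cols)).sum())
    else:
        po = float(np.trace(p))
        pe = float(rows @ cols)
    if pe >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: expected agreement is 1 "
                         "(all mass in one category)")
    return KappaResult(po=po, pe=pe, kappa=(po - pe) / (1.0 - pe),
                       weighted=weighted)


# ---------------------------------------------------------------- binary task

@dataclass
class BinaryConfusion:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion matrix is empty")

    @classmethod
    def from_crosstab_surgery(cls, tab: CrossTab) -> "BinaryConfusion":
        """Collapse a 3-class staging crosstab to the surgery-vs-observe task.

        Restricted to the pterygium patients (reference classes 1 and 2);
        positive = surgery-indicated (class 2).
        """
        if tab.k != 3:
            raise ValueError("expected a 3x3 staging crosstab")
        c = tab.counts
        return cls(tp=int(c[2, 2]), fn=int(c[2, 1] + c[2, 0]),
                   fp=int(c[1, 2]), tn=int(c[1, 1] + c[1, 0]))


@dataclass
class BinaryMetrics:
    accuracy: float | None
    specificity: float | None
    sensitivity: float | None
    precision: float | None
    f1: float | None


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def binary_metrics(c: BinaryConfusion) -> BinaryMetrics:
    """Accuracy, specificity, sensitivity, precision, F1; ``None`` when the
    denominator is zero (undefined, not 0)."""
    acc = _ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    sens = _ratio(c.tp, c.tp + c.fn)
    prec = _ratio(c.tp, c.tp + c.fp)
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    return BinaryMetrics(accuracy=acc, specificity=spec, sensitivity=sens,
                         precision=prec, f1=f1)


# ---------------------------------------------------------------- ROC / Youden

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    youden_threshold: float
    youden_index: float


def roc_auc_youden(scores, labels) -> RocResult:
    """ROC over all score thresholds (higher score => positive), trapezoid AUC,
    and the Youden-optimal cutoff (ties broken toward the larger threshold)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.unique(s)[::-1]  # descending
    tpr = np.empty(thresholds.size + 1)
    fpr = np.empty(thresholds.size + 1)
    tpr[0] = fpr[0] = 0.0  # threshold above all scores
    for i, t in enumerate(thresholds, start=1):
        pred = s >= t
        tpr[i] = np.logical_and(pred, y).sum() / n_pos
        fpr[i] = np.logical_and(pred, ~y).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr[1:] - fpr[1:]  # Youden index at each attainable threshold
    best = int(np.argmax(j))  # thresholds are descending: first max = largest t
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                     youden_threshold=float(thresholds[best]),
                     youden_index=float(j[best]))


# ---------------------------------------------------------------- Bland-Altman

@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_outside: int


def bland_altman(a, b) -> BlandAltmanResult:
    """Limits of agreement for paired measurements (d = a - b, mean ± 1.96 SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 paired measurements")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    outside = int(((d < lo) | (d > hi)).sum())
    return BlandAltmanResult(mean_diff=mean, sd_diff=sd, loa_low=lo,
                             loa_high=hi, n_outside=outside)


def bland_altman_plot(a, b, path):  # pragma: no cover - optional plotting
    """Scatter of (mean, difference) with the limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    fig, ax = plt.subplots()
    ax.scatter((a + b) / 2, a - b, s=12)
    for yv, style in ((res.mean_diff, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of paired measurements")
    ax.set_ylabel("difference")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res
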