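"""Reference-set benchmarking: ROC analysis, t-tests and box summaries.

Positive (PRS) and random (RRS) reference pairs provide ground truth for
comparing scoring schemes. Higher scores are interaction-like; the AUC is
the probability that a random positive pair outscores a random negative
one (ties count half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "RocSummary",
    "BoxStats",
    "TTestResult",
    "roc_auc",
    "sensitivity_at_specificity",
    "specificity_at_sensitivity",
    "two_sample_t",
    "box_stats",
]

POSITIVE_LABEL = "PRS"


@dataclass(frozen=True)
class RocSummary:
    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc out of [0, 1]")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("fpr/tpr must be non-decreasing")


@dataclass(frozen=True)
class BoxStats:
    median: float
    q25: float
    q75: float
    minimum: float
    maximum: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> RocSummary:
    """ROC curve and trapezoidal AUC with PRS as the positive class."""
    y = np.asarray([1 if lab == POSITIVE_LABEL else 0 for lab in labels])
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both PRS and RRS labels are required for ROC analysis")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocSummary(
        thresholds=tuple(float(t) for t in thr),
        fpr=tuple(float(v) for v in fpr),
        tpr=tuple(float(v) for v in tpr),
        auc=auc,
    )


def sensitivity_at_specificity(roc: RocSummary, spec: float) -> float:
    """Best sensitivity over thresholds holding specificity ≥ ``spec``."""
    fpr = np.asarray(roc.fpr)
    tpr = np.asarray(roc.tpr)
    ok = fpr <= (1.0 - spec) + 1e-12
    return float(tpr[ok].max()) if ok.any() else 0.0


def specificity_at_sensitivity(roc: RocSummary, sens: float) -> float:
    """Best specificity over thresholds holding sensitivity ≥ ``sens``."""
    fpr = np.asarray(roc.fpr)
    tpr = np.asarray(roc.tpr)
    ok = tpr >= sens - 1e-12
    return float(1.0 - fpr[ok].min()) if ok.any() else 0.0


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Pooled-variance (Student) two-sample t-test, two-tailed."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = x.size + y.size - 2
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled == 0.0:
        # all readings identical within groups: difference either exact zero
        # (t=0, p=1) or infinitely significant; flag instead of guessing
        same = x.mean() == y.mean()
        return TTestResult(
            t=0.0 if same else np.inf, df=df, p=1.0 if same else np.nextafter(0, 1),
            degenerate=True,
        )
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def box_stats(x: Sequence[float]) -> BoxStats:
    """Box-whisker summary with whiskers at the extremes (no trimming).

    Quartiles use linear interpolation (numpy's default, type 7).
    """
    v = np.asarray(x, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one observation")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return BoxStats(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        minimum=float(v.min()),
        maximum=float(v.max()),
        n=int(v.size),
    )
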