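"""Diagnostic-accuracy metrics and the accompanying statistical toolbox.

AUC (Mann-Whitney with midrank ties), threshold confusion metrics,
Clopper-Pearson exact binomial CIs, stratified-bootstrap AUC CIs, the
DeLong test for correlated AUCs, Fisher's exact test, the Wilcoxon
signed-rank test with continuity correction, and the one-sample proportion
score test with continuity correction.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DimensionError

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "roc_auc",
    "confusion_metrics",
    "clopper_pearson_ci",
    "bootstrap_auc_ci",
    "delong_test",
    "fisher_exact",
    "wilcoxon_signed_rank",
    "one_sample_proportion_test",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    """AUC/accuracy/sensitivity/specificity/F1, each optionally with a CI."""

    auc: float = np.nan
    accuracy: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    f1: float = np.nan
    ci: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {k: getattr(self, k)
               for k in ("auc", "accuracy", "sensitivity", "specificity", "f1")}
        out.update({f"{k}_ci": v for k, v in self.ci.items()})
        return out


def _check_binary(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.size == 0:
        raise DimensionError("empty label vector")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return labels


def roc_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney statistic with midrank tie handling."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def confusion_metrics(scores, labels, threshold: float = 0.5
                      ) -> tuple[ConfusionCounts, MetricSet]:
    """Threshold the scores at `threshold` and compute the standard metrics."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != labels.shape:
        raise DimensionError("scores and labels lengths differ")
    pred = (scores >= threshold).astype(int)
    cm = ConfusionCounts(
        tp=int(((pred == 1) & (labels == 1)).sum()),
        fp=int(((pred == 1) & (labels == 0)).sum()),
        tn=int(((pred == 0) & (labels == 0)).sum()),
        fn=int(((pred == 0) & (labels == 1)).sum()),
    )
    return cm, metrics_from_confusion(cm, scores=scores, labels=labels)


def metrics_from_confusion(cm: ConfusionCounts, scores=None, labels=None) -> MetricSet:
    acc = (cm.tp + cm.tn) / cm.n if cm.n else np.nan
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else np.nan
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else np.nan
    f1 = 2 * cm.tp / (2 * cm.tp + cm.fp + cm.fn) if 2 * cm.tp + cm.fp + cm.fn else np.nan
    auc = np.nan
    if scores is not None and labels is not None:
        lab = np.asarray(labels)
        if 0 < lab.sum() < len(lab):
            auc = roc_auc(scores, labels)
    return MetricSet(auc=auc, accuracy=acc, sensitivity=sens,
                     specificity=spec, f1=f1)


def clopper_pearson_ci(successes: int, n: int, conf: float = 0.95
                       ) -> tuple[float, float]:
    """Exact binomial CI from beta quantiles; (0, .) at 0 and (., 1) at n."""
    if not (0 <= successes <= n) or n < 1:
        raise ValueError(f"invalid counts: {successes}/{n}")
    alpha = 1.0 - conf
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, conf: float = 0.95,
                     seed: int = 0) -> tuple[float, float]:
    """Percentile CI for the AUC from stratified bootstrap replicates."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateInputError("need at least 2 subjects per class")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, len(pos), replace=True)
        ineg = rng.choice(neg, len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        aucs[b] = roc_auc(scores[idx], labels[idx])
    alpha = 1.0 - conf
    return (float(np.quantile(aucs, alpha / 2)),
            float(np.quantile(aucs, 1 - alpha / 2)))


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_structural(scores: np.ndarray, labels: np.ndarray):
    """Placement values (structural components) V10, V01 and the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return v10, v01, auc


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong z-test comparing two correlated AUCs."""
    labels = _check_binary(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise DimensionError("paired scores and labels must share one length")
    if labels.sum() in (0, len(labels)):
        raise DegenerateInputError("both classes must be present")
    v10a, v01a, auc_a = _delong_structural(scores_a, labels)
    v10b, v01b, auc_b = _delong_structural(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        return 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric masses <= observed."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def wilcoxon_signed_rank(x, y, continuity: bool = True) -> float:
    """Two-sided Wilcoxon signed-rank p, normal approximation with
    continuity correction; zero differences dropped, ties midranked."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError("paired samples must share one length")
    if np.all(x == y):
        raise DegenerateInputError("all paired differences are zero")
    res = stats.wilcoxon(x, y, zero_method="wilcox",
                         correction=continuity, method="approx")
    return float(res.pvalue)


def one_sample_proportion_test(successes: int, n: int, p0: float) -> float:
    """Two-sided one-sample proportion score test with continuity correction
    (the chi-squared form used by R's prop.test)."""
    if not (0 <= successes <= n) or n < 1:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly in (0, 1)")
    phat = successes / n
    cc = min(0.5 / n, abs(phat - p0))
    z = (abs(phat - p0) - cc) / np.sqrt(p0 * (1 - p0) / n)
    return float(2 * stats.norm.sf(z))
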