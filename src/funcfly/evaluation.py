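"""Benchmark metrics and method comparisons.

The two headline metrics are the Matthews Correlation Coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the zero-denominator convention MCC = 0, and the rank-based AUROC
(Mann-Whitney with midrank tie handling). Paired method comparisons across
GO terms use the two-tailed Wilcoxon signed-rank test; confidence-score
calibration is summarised by the Pearson correlation between confidence
thresholds and the precision of the predictions above each threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .containers import NAMESPACES
from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

ALGORITHMS = ("RF", "AdaBoost", "KNN", "LDA")
OPT_LABEL = "Opt"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts at a fixed decision threshold."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative confusion count {name}")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def mcc(c: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient of a confusion table.

    Any zero marginal (no predicted positives, no actual negatives, ...)
    yields 0.0; an entirely empty table is a parameter error.
    """
    if c.total == 0:
        raise ParameterError("confusion table is empty")
    tp, fp, tn, fn = (float(c.TP), float(c.FP), float(c.TN), float(c.FN))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    """Count the confusion table with 'positive' meaning score strictly
    greater than `threshold`."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank-based, midrank ties)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ParameterError("AUROC requires both classes to be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded. With n <= 25 remaining pairs and no tied
    absolute differences the exact null distribution is used; otherwise the
    normal approximation with tie and continuity correction. If every
    difference is zero the test is vacuous and p = 1 is returned with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        logger.warning("wilcoxon_signed_rank: all differences are zero; p = 1")
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        alternative="two-sided",
        correction=True,
        method=method,
    )
    return float(res.pvalue)


@dataclass
class PrecisionConfidenceCurve:
    """Precision as a function of the confidence threshold, plus Pearson r."""

    r: float                  # NaN when degenerate (constant precision or < 3 points)
    thresholds: np.ndarray    # thresholds retaining >= 1 prediction
    precisions: np.ndarray

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.r)


def precision_confidence_correlation(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Optional[Sequence[float]] = None,
) -> PrecisionConfidenceCurve:
    """Correlate confidence thresholds with the precision above them.

    For each threshold with at least one prediction (score strictly greater
    than the threshold) precision = TP / (TP + FP). Pearson's r between the
    retained thresholds and precisions is NaN when fewer than three
    thresholds are retained or the precisions are constant.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ParameterError("calibration requires both classes to be present")
    if thresholds is None:
        thresholds = np.arange(0.0, 0.951, 0.05)
    kept_t, kept_p = [], []
    for t in np.asarray(thresholds, dtype=float):
        c = confusion_at_threshold(scores, labels, t)
        if c.TP + c.FP == 0:
            continue
        kept_t.append(t)
        kept_p.append(c.TP / (c.TP + c.FP))
    kept_t = np.asarray(kept_t)
    kept_p = np.asarray(kept_p)
    if kept_t.size < 3 or np.ptp(kept_p) == 0.0 or np.ptp(kept_t) == 0.0:
        return PrecisionConfidenceCurve(float("nan"), kept_t, kept_p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(stats.pearsonr(kept_t, kept_p).statistic)
    return PrecisionConfidenceCurve(r, kept_t, kept_p)


@dataclass
class GroupComparisonTable:
    """Mean metric per feature group, classifier and namespace.

    ``table`` has feature-group rows and a (classifier, namespace)
    MultiIndex on the columns; the ``Opt`` classifier column holds the mean
    over terms of the per-term maximum across the four algorithms, so it
    dominates every single-classifier column by construction.
    """

    metric: str
    table: pd.DataFrame


def summarize_groups(
    results: Mapping,
    namespaces: Mapping,
    metric: str = "mcc",
) -> GroupComparisonTable:
    """Aggregate per-term scores into a group x (classifier, namespace) table.

    `results` maps term -> feature group -> algorithm -> (mcc, auroc);
    `namespaces` maps term -> BP/MF/CC. Every term must carry every
    group/algorithm cell; a missing cell raises naming the term and group.
    """
    if metric not in ("mcc", "auroc"):
        raise ParameterError(f"metric must be 'mcc' or 'auroc': {metric!r}")
    pos = 0 if metric == "mcc" else 1
    terms = sorted(results)
    if not terms:
        raise ParameterError("no per-term results supplied")
    groups = sorted(results[terms[0]])
    algorithms = [a for a in ALGORITHMS if a in results[terms[0]][groups[0]]]

    for term in terms:
        for group in groups:
            if group not in results[term]:
                raise ValidationError(f"term {term}: missing feature group {group!r}")
            for alg in algorithms:
                if alg not in results[term][group]:
                    raise ValidationError(
                        f"term {term}, group {group!r}: missing algorithm {alg!r}"
                    )

    present_ns = [ns for ns in NAMESPACES if ns in set(namespaces[t] for t in terms)]
    columns = pd.MultiIndex.from_product(
        [list(algorithms) + [OPT_LABEL], present_ns], names=["classifier", "namespace"]
    )
    table = pd.DataFrame(index=pd.Index(groups, name="feature_group"), columns=columns,
                         dtype=float)
    for group in groups:
        for ns in present_ns:
            ns_terms = [t for t in terms if namespaces[t] == ns]
            per_alg = {
                alg: np.mean([results[t][group][alg][pos] for t in ns_terms])
                for alg in algorithms
            }
            best = np.mean(
                [max(results[t][group][a][pos] for a in algorithms) for t in ns_terms]
            )
            for alg, value in per_alg.items():
                table.loc[group, (alg, ns)] = value
            table.loc[group, (OPT_LABEL, ns)] = best
    return GroupComparisonTable(metric, table)
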