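"""Ranking-derived statistics.

Everything the EFO learner optimizes or reports is a function of a *ranking*:
the instances sorted by descending model score.  This module provides the
enrichment factor (an early-recognition measure), the cluster distribution of
positives along the ranking, the asymmetry index (Pearson's moment
coefficient of skewness of the per-cluster positive percentages), the quality
function the optimizer maximizes (asymmetry index x first-cluster positive
percentage), confusion matrices obtained by cutting a ranking at a prefix,
and the usual binary classification metrics.

All of these are invariant under strictly increasing transforms of the
scores, because they depend on the ranking only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Ranking",
    "ClusterDistribution",
    "ConfusionMatrix",
    "ClassificationMetrics",
    "EvaluationReport",
    "rank",
    "rank_scores",
    "enrichment_factor",
    "top_fraction_size",
    "cluster_distribution",
    "asymmetry_index",
    "quality",
    "confusion_from_ranking",
    "classification_metrics",
    "evaluate_ranking",
]

_VAR_EPS = 1e-24


@dataclass
class Ranking:
    """Instances in descending score order (ties keep original row order)."""

    ordered_ids: list[str]
    scores: np.ndarray  # non-increasing
    labels: np.ndarray  # aligned with ordered_ids

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not (len(self.ordered_ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ids, scores and labels must have equal length")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing along the ranking")

    @property
    def n_total(self) -> int:
        return len(self.scores)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


def rank_scores(instance_ids, scores, labels) -> Ranking:
    """Build a Ranking from raw per-instance scores.

    Sorting is by descending score with a stable tie-break on the input row
    order, so results are reproducible for tied scores.
    """
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    labels = np.asarray(labels, dtype=np.int8)
    return Ranking(
        ordered_ids=[str(instance_ids[i]) for i in order],
        scores=scores[order],
        labels=labels[order],
    )


def rank(table, model) -> Ranking:
    """Rank a table's instances by a linear model's score, best first."""
    if table.labels is None:
        raise ValueError("ranking statistics need a labeled table")
    return rank_scores(table.instance_ids, model.score(table), table.labels)


def top_fraction_size(n_total: int, top_fraction: float) -> int:
    """Prefix length for a top fraction: round(f*N), half away from zero, >= 1."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    return min(n_total, max(1, int(math.floor(top_fraction * n_total + 0.5))))


def enrichment_factor(ranking: Ranking, top_fraction: float) -> float:
    """Enrichment factor in the top fraction of a ranking.

    EF = (positives in prefix / prefix size) / (total positives / N), i.e.
    the positive rate in the prefix relative to the overall positive rate.
    EF = 1 for a random ranking; the ceiling is min(m, P)*N/(m*P) for a
    prefix of m instances (2.0 at the top 5% of a perfectly balanced set).
    """
    N = ranking.n_total
    P = ranking.n_positive
    if P == 0:
        raise ValueError("enrichment factor is undefined without positives")
    m = top_fraction_size(N, top_fraction)
    h = int(ranking.labels[:m].sum())
    return (h / m) / (P / N)


@dataclass
class ClusterDistribution:
    """Positives per consecutive cluster of a ranking.

    The ranking is cut into consecutive blocks of ``cluster_size`` instances
    (the last block may be smaller).  ``percentages[i]`` is the positive
    percentage of cluster *i* relative to that cluster's actual size, so the
    possibly-smaller final cluster stays comparable.
    """

    cluster_size: int
    counts: np.ndarray
    sizes: np.ndarray
    percentages: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.counts)

    @property
    def mean_percentage(self) -> float:
        return float(self.percentages.mean())


def cluster_distribution(ranking: Ranking, cluster_size: int) -> ClusterDistribution:
    """Cut a ranking into consecutive clusters and count positives per cluster."""
    N = ranking.n_total
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    if cluster_size > N:
        raise ValueError(f"cluster_size {cluster_size} exceeds ranking size {N}")
    edges = np.arange(0, N, cluster_size)
    counts = np.add.reduceat(ranking.labels.astype(np.int64), edges)
    sizes = np.diff(np.append(edges, N))
    return ClusterDistribution(
        cluster_size=int(cluster_size),
        counts=counts,
        sizes=sizes,
        percentages=100.0 * counts / sizes,
    )


def asymmetry_index(dist: ClusterDistribution) -> float:
    """Pearson's moment coefficient of skewness of the cluster percentages.

    AI = m3 / m2^(3/2) with population moments m2, m3 of the per-cluster
    positive percentages.  A right-skewed profile (positives concentrated in
    the first clusters) gives a large positive AI.  Zero variance (all
    clusters equal) is degenerate and returns 0, so uninformative models
    score worst.
    """
    if dist.n_clusters < 2:
        raise ValueError("asymmetry index needs at least 2 clusters")
    p = dist.percentages
    d = p - p.mean()
    m2 = float(np.mean(d * d))
    if m2 < _VAR_EPS:
        return 0.0
    m3 = float(np.mean(d * d * d))
    return m3 / m2**1.5


def quality(dist: ClusterDistribution) -> float:
    """Ranking quality: asymmetry index x first-cluster positive percentage.

    This is the objective the coefficient optimizer maximizes.  The first
    factor rewards a right-skewed decay of positives along the ranking, the
    second rewards early recognition (a full first cluster).
    """
    return asymmetry_index(dist) * float(dist.percentages[0])


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
            setattr(self, name, int(v))

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_predicted_positive(self) -> int:
        return self.tp + self.fp


def confusion_from_ranking(ranking: Ranking, n_predicted_positive: int) -> ConfusionMatrix:
    """Confusion matrix obtained by predicting the top of the ranking positive.

    The first ``n_predicted_positive`` ranked instances are the predicted
    positives; the rest are predicted negative.  When the prefix length
    equals the number of true positives P, fp = P - tp and fn = P - tp
    coincide, reproducing the symmetric bookkeeping used when the first
    cluster plays the role of the predicted-positive set.
    """
    N = ranking.n_total
    if not 0 <= n_predicted_positive <= N:
        raise ValueError(
            f"n_predicted_positive must lie in [0, {N}], got {n_predicted_positive}"
        )
    P = ranking.n_positive
    tp = int(ranking.labels[:n_predicted_positive].sum())
    fp = n_predicted_positive - tp
    fn = P - tp
    tn = N - tp - fp - fn
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class ClassificationMetrics:
    precision: float
    accuracy: float
    mcc: float
    sensitivity: float
    specificity: float
    degenerate: set = field(default_factory=set)  # metrics hit by a 0/0


def _safe_ratio(num: float, den: float, name: str, flags: set) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Precision, accuracy, MCC, sensitivity, specificity from a 2x2 matrix.

    Any 0/0 is reported as 0 with the metric name recorded in ``degenerate``
    rather than raising, so sweeps over degenerate settings stay total.
    """
    flags: set = set()
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    precision = _safe_ratio(tp, tp + fp, "precision", flags)
    accuracy = _safe_ratio(tp + tn, cm.n_total, "accuracy", flags)
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity", flags)
    specificity = _safe_ratio(tn, tn + fp, "specificity", flags)
    denom = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        flags.add("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return ClassificationMetrics(
        precision=precision,
        accuracy=accuracy,
        mcc=mcc,
        sensitivity=sensitivity,
        specificity=specificity,
        degenerate=flags,
    )


@dataclass
class EvaluationReport:
    """Full evaluation of one model on one ranking."""

    confusion: ConfusionMatrix
    precision: float
    accuracy: float
    mcc: float
    sensitivity: float
    specificity: float
    ef_top1: float
    ef_top10: float
    quality: float
    top_cluster_positive_fraction: float
    degenerate: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
            },
            "precision": self.precision,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ef_top1": self.ef_top1,
            "ef_top10": self.ef_top10,
            "quality": self.quality,
            "top_cluster_positive_fraction": self.top_cluster_positive_fraction,
            "degenerate": sorted(self.degenerate),
        }

    def to_text(self) -> str:
        cm = self.confusion
        lines = [
            f"TP = {cm.tp}   FP = {cm.fp}   FN = {cm.fn}   TN = {cm.tn}",
            f"Precision = {self.precision:.2f}",
            f"Accuracy = {self.accuracy:.2f}",
            f"MCC = {self.mcc:.2f}",
            f"Sensitivity = {self.sensitivity:.2f}",
            f"Specificity = {self.specificity:.2f}",
            f"EF top 1% = {self.ef_top1:.2f}   EF top 10% = {self.ef_top10:.2f}",
            f"Quality = {self.quality:.2f}",
        ]
        return "\n".join(lines)


def evaluate_ranking(
    ranking: Ranking,
    n_predicted_positive: int | None = None,
    cluster_size: int | None = None,
) -> EvaluationReport:
    """Evaluate a ranking end to end.

    ``n_predicted_positive`` defaults to the number of true positives (the
    prefix-cut convention); ``cluster_size`` defaults to the same value.
    ``top_cluster_positive_fraction`` reports the positive fraction of the
    first cluster separately from the standard sensitivity, because the two
    coincide only when the cluster size equals the positive count.
    """
    P = ranking.n_positive
    if n_predicted_positive is None:
        n_predicted_positive = P
    if cluster_size is None:
        cluster_size = max(1, P)
    cm = confusion_from_ranking(ranking, n_predicted_positive)
    metrics = classification_metrics(cm)
    dist = cluster_distribution(ranking, cluster_size)
    q = quality(dist) if dist.n_clusters >= 2 else 0.0
    return EvaluationReport(
        confusion=cm,
        precision=metrics.precision,
        accuracy=metrics.accuracy,
        mcc=metrics.mcc,
        sensitivity=metrics.sensitivity,
        specificity=metrics.specificity,
        ef_top1=enrichment_factor(ranking, 0.01) if P else 0.0,
        ef_top10=enrichment_factor(ranking, 0.10) if P else 0.0,
        quality=q,
        top_cluster_positive_fraction=float(dist.percentages[0]) / 100.0,
        degenerate=metrics.degenerate,
    )
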