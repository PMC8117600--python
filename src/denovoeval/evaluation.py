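"""Retrospective classification, cluster overlap and score comparison.

Docking scores are physics-based binding estimates where lower (more
negative) is better.  A score threshold turns them into an active/inactive
classifier: predicted active iff score <= threshold (inclusive; lowering
the threshold is the more stringent criterion).  The sweep reports
accuracy, precision and recall per threshold:

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

Cluster overlap pools several named datasets, clusters the pooled
fingerprints by sphere exclusion + nearest-centroid assignment, and counts
clusters by which datasets contribute at least one member — the Venn-region
view of how much chemical space two generators and a reference set share.

Score distributions are compared with a one-tailed Welch t-test with
Bonferroni adjustment for the family of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from denovoeval.diversity import SphereConfig, cluster_assign

__all__ = [
    "ConfusionCounts",
    "ClassificationMetrics",
    "classification_metrics",
    "ThresholdSweepResult",
    "threshold_sweep",
    "OverlapTable",
    "cluster_overlap",
    "TTestResult",
    "compare_score_distributions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, precision, recall; precision/recall are None (flagged)
    when their denominator is zero."""

    accuracy: float
    precision: float | None
    recall: float | None


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    return ClassificationMetrics(
        accuracy=(c.tp + c.tn) / c.total, precision=precision, recall=recall
    )


@dataclass
class ThresholdSweepResult:
    """Per-threshold confusion counts and metrics, as a DataFrame.

    ``table`` columns: threshold, tp, fp, tn, fn, accuracy, precision,
    recall.  ``best_accuracy_threshold`` is the accuracy argmax, ties
    broken toward the most stringent (lowest) threshold.
    """

    table: pd.DataFrame
    best_accuracy_threshold: float

    def at(self, threshold: float) -> pd.Series:
        row = self.table[np.isclose(self.table["threshold"], threshold)]
        if row.empty:
            raise KeyError(f"threshold {threshold} not in sweep")
        return row.iloc[0]


def threshold_sweep(
    active_scores: Sequence[float],
    inactive_scores: Sequence[float],
    thresholds: Sequence[float],
) -> ThresholdSweepResult:
    """Classification sweep over docking-score thresholds.

    Lower score = better; a molecule is predicted active iff its score is
    <= the threshold.  Counts at every threshold total
    len(active_scores) + len(inactive_scores).
    """
    act = np.asarray(active_scores, dtype=float)
    inact = np.asarray(inactive_scores, dtype=float)
    if act.size == 0 or inact.size == 0:
        raise ValueError("both score lists must be non-empty")
    rows = []
    for t in thresholds:
        tp = int(np.count_nonzero(act <= t))
        fn = act.size - tp
        fp = int(np.count_nonzero(inact <= t))
        tn = inact.size - fp
        m = classification_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        rows.append(
            {
                "threshold": float(t),
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
                "accuracy": m.accuracy,
                "precision": m.precision,
                "recall": m.recall,
            }
        )
    table = pd.DataFrame(rows)
    best_acc = table["accuracy"].max()
    best = table.loc[np.isclose(table["accuracy"], best_acc), "threshold"].min()
    return ThresholdSweepResult(table=table, best_accuracy_threshold=float(best))


@dataclass
class OverlapTable:
    """Cluster membership flags per dataset and Venn-region counts.

    ``membership`` is a boolean DataFrame (cluster x dataset): True when
    the dataset contributes at least one member to the cluster.
    ``venn_counts`` maps each membership pattern (tuple of dataset names,
    in input order) to the number of clusters showing exactly that
    pattern; the counts sum to the total number of clusters.
    """

    membership: pd.DataFrame
    venn_counts: dict[tuple[str, ...], int]

    @property
    def n_clusters(self) -> int:
        return len(self.membership)

    def shared_count(self, *datasets: str) -> int:
        """Clusters with at least one member from every named dataset."""
        mask = np.ones(len(self.membership), dtype=bool)
        for d in datasets:
            mask &= self.membership[d].to_numpy()
        return int(mask.sum())


def cluster_overlap(
    datasets: Mapping[str, np.ndarray],
    config: SphereConfig | None = None,
) -> OverlapTable:
    """Cross-dataset cluster-overlap analysis.

    Fingerprints are pooled in dataset order (then input order within each
    dataset), clustered by sphere exclusion + nearest-centroid assignment,
    and each cluster is flagged for every dataset contributing a member.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    names = list(datasets)
    sizes = []
    mats = []
    for name in names:
        F = np.asarray(datasets[name], dtype=bool)
        if F.ndim == 1:
            F = F[None, :]
        if F.shape[0] == 0:
            raise ValueError(f"dataset {name!r} is empty")
        sizes.append(F.shape[0])
        mats.append(F)
    pooled = np.vstack(mats)
    origin = np.repeat(np.arange(len(names)), sizes)
    assignment = cluster_assign(pooled, config or SphereConfig(subsample_k=None))
    n_clusters = len(assignment.centroid_indices)
    flags = np.zeros((n_clusters, len(names)), dtype=bool)
    for cluster, ds in zip(assignment.membership, origin):
        flags[cluster, ds] = True
    membership = pd.DataFrame(flags, columns=names)
    venn: dict[tuple[str, ...], int] = {}
    for row in flags:
        pattern = tuple(n for n, f in zip(names, row) if f)
        venn[pattern] = venn.get(pattern, 0) + 1
    return OverlapTable(membership=membership, venn_counts=venn)


@dataclass(frozen=True)
class TTestResult:
    """One-tailed Welch t-test with Bonferroni-adjusted p-value."""

    t: float
    p: float
    p_adjusted: float
    alternative: str
    family_size: int
    degenerate: bool = False
    method: str = "welch_one_tailed_bonferroni"


def compare_score_distributions(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "less",
    family_size: int = 1,
) -> TTestResult:
    """Welch's unequal-variance one-tailed t-test between two score samples.

    ``alternative='less'`` tests that sample ``a`` has the lower mean
    (better docking scores).  The adjusted p-value is min(1, family_size *
    p) (Bonferroni).  Samples with zero variance in both groups and equal
    means leave t undefined and are flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two values")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return TTestResult(
            t=float("nan"),
            p=float("nan"),
            p_adjusted=float("nan"),
            alternative=alternative,
            family_size=family_size,
            degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    p_adj = min(1.0, family_size * float(res.pvalue))
    return TTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        p_adjusted=p_adj,
        alternative=alternative,
        family_size=family_size,
    )
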