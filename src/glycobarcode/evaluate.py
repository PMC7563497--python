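"""Repeated stratified holdout evaluation, ROC-AUC, confusion metrics, rank-sum tests.

The study design: train on a stratified 60% of samples, score the held-out
40%, summarize with ROC-AUC, repeat with freshly drawn splits, and compare
pipeline variants by a two-sided Wilcoxon rank-sum test over their per-repeat
AUC lists. Confusion-matrix metrics are reported at a fixed probability
cutoff as integer percents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .model import CNNClassifier

POSITIVE_LABEL = "EOC"


@dataclass
class SplitPlan:
    """One stratified train/test partition."""

    repeat: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    labels: Sequence,
    train_frac: float = 0.6,
    seed: int = 0,
    repeat: int = 0,
    stratify: bool = True,
) -> SplitPlan:
    """Random train/test partition with per-class test counts round(0.4 * n).

    Stratification reproduces the study's per-class test arithmetic (e.g.
    97 + 254 samples give a 39 + 102 = 141 test set at 60/40); pass
    ``stratify=False`` for a plain random split of the pooled cohort.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 members to split")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    if stratify:
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            n_test = _round_half_up((1.0 - train_frac) * len(idx))
            test_idx.extend(rng.choice(idx, size=n_test, replace=False))
    else:
        n_test = _round_half_up((1.0 - train_frac) * len(labels))
        test_idx.extend(rng.choice(len(labels), size=n_test, replace=False))
    test = np.sort(np.array(test_idx, dtype=int))
    train = np.setdiff1d(np.arange(len(labels)), test)
    return SplitPlan(repeat=repeat, train_idx=train, test_idx=test, seed=seed)


def roc_auc(scores: Sequence[float], labels: Sequence, positive_label=POSITIVE_LABEL) -> float:
    """Area under the ROC curve; equal to the normalized Mann-Whitney statistic.

    The AUC is the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    y = labels == positive_label
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(y.astype(int), scores))


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: int
    specificity: int
    ppv: int
    npv: int
    accuracy: int


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """Derive percent metrics (rounded half-up to integers) from a confusion table."""
    if tp + fp + fn + tn == 0:
        raise ValueError("empty confusion table")
    pct = lambda num, den: _round_half_up(100.0 * num / den) if den else 0
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
        accuracy=pct(tp + tn, tp + fp + fn + tn),
    )


def confusion_metrics(
    scores: Sequence[float],
    labels: Sequence,
    cutoff: float = 0.5,
    positive_label=POSITIVE_LABEL,
) -> ConfusionMetrics:
    """Confusion counts and percent metrics at a probability cutoff.

    A sample is called positive when its score is >= the cutoff (ties at the
    cutoff count as positive).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(labels) == 0:
        raise ValueError("empty input")
    pos = labels == positive_label
    called = scores >= cutoff
    return metrics_from_counts(
        tp=int((called & pos).sum()),
        fp=int((called & ~pos).sum()),
        fn=int((~called & pos).sum()),
        tn=int((~called & ~pos).sum()),
    )


def rank_sum_compare(aucs_a: Sequence[float], aucs_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value between AUC lists.

    Uses the exact null distribution when both samples have <= 12 values and
    no ties, and the tie-corrected normal approximation otherwise (no
    continuity correction, so identical inputs give p = 1 exactly).
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both AUC lists must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # every value tied: no evidence of a shift
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 12 and len(b) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


@dataclass
class EvalResult:
    """Outcome of a repeated-holdout evaluation of one pipeline variant."""

    aucs: list[float]
    seeds: list[int]
    test_scores: list[float] = field(default_factory=list)
    test_labels: list[str] = field(default_factory=list)
    confusion: ConfusionMetrics | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    def to_dict(self) -> dict:
        out = {
            "aucs": self.aucs,
            "mean_auc": self.mean_auc,
            "seeds": self.seeds,
            "test_scores": self.test_scores,
            "test_labels": self.test_labels,
        }
        if self.confusion is not None:
            out["confusion"] = asdict(self.confusion)
        return out


def repeated_holdout(
    images: np.ndarray,
    labels: Sequence,
    clf_params: dict | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    train_frac: float = 0.6,
    cutoff: float = 0.5,
    positive_label=POSITIVE_LABEL,
    metrics_repeat: int = -1,
) -> EvalResult:
    """Repeated stratified 60/40 holdout of a barcode CNN.

    Each repeat draws a fresh stratified split (seeds ``seed + r``), trains a
    classifier on the training portion, and scores the held-out samples; one
    AUC per repeat is recorded. Confusion metrics at ``cutoff`` come from the
    designated evaluation repeat (default: the last).
    """
    labels = np.asarray(labels)
    clf_params = dict(clf_params or {})
    aucs, seeds = [], []
    scores_kept: np.ndarray | None = None
    labels_kept: np.ndarray | None = None
    which = metrics_repeat % n_repeats
    for r in range(n_repeats):
        split_seed = seed + r
        plan = stratified_split(labels, train_frac=train_frac, seed=split_seed, repeat=r)
        clf = CNNClassifier(random_state=split_seed, **clf_params)
        clf.fit(images[plan.train_idx], labels[plan.train_idx])
        scores = clf.decision_scores(images[plan.test_idx], positive_label=positive_label)
        aucs.append(roc_auc(scores, labels[plan.test_idx], positive_label=positive_label))
        seeds.append(split_seed)
        if r == which:
            scores_kept = scores
            labels_kept = labels[plan.test_idx]
    confusion = confusion_metrics(
        scores_kept, labels_kept, cutoff=cutoff, positive_label=positive_label
    )
    return EvalResult(
        aucs=aucs,
        seeds=seeds,
        test_scores=[float(s) for s in scores_kept],
        test_labels=[str(l) for l in labels_kept],
        confusion=confusion,
    )
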