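"""Confusion metrics, ROC/PR summaries, threshold strategies and cross-validation.

The harness mirrors the standard protocol for residue-level binding-site
predictors: ten-fold cross-validation of the under-sampled ensemble, a
threshold chosen on the pooled out-of-fold probabilities by one of three
operating-point strategies (Sen ~ Spec, FPR pinned near a target, or
maximum MCC), and MCC as the headline number because the classes are
heavily imbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ranksums
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .ecrus import LabeledDataset, build_ensemble, predict
from .wsrc import BINDING, WsrcParams


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricSet:
    ACC: float
    SN: float
    Spec: float
    Pre: float
    MCC: float
    AUC: float | None = None
    AUPR: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class ThresholdStrategy:
    """Operating-point rule: 'sen_eq_spec', 'fpr_target' (target = desired
    FPR, e.g. 0.05), 'max_mcc', or 'fixed' (target = the threshold T)."""

    kind: str = "fpr_target"
    target: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("sen_eq_spec", "fpr_target", "max_mcc", "fixed"):
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "fpr_target" and not 0 <= self.target <= 1:
            raise ValueError("fpr_target must lie in [0, 1]")


def confusion(labels_true: np.ndarray, labels_pred: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN with 1 = binding as the positive class."""
    t = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted label vectors must have equal length")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FP=int(np.sum((t == 0) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, precision and MCC from counts.

    Any metric whose denominator is zero is reported as 0 (keeps MCC
    bounded and is the conservative convention for empty classes).
    """
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    n = tp + tn + fp + fn

    def safe(num, den):
        return num / den if den > 0 else 0.0

    mcc_den = np.sqrt((tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    return MetricSet(
        ACC=safe(tp + tn, n),
        SN=safe(tp, tp + fn),
        Spec=safe(tn, tn + fp),
        Pre=safe(tp, tp + fp),
        MCC=safe(tp * tn - fp * fn, mcc_den),
    )


def roc_and_pr(scores: np.ndarray, labels_true: np.ndarray):
    """AUC, AUPR and the corresponding curve points.

    AUC is the Mann-Whitney rank statistic (0.5 credit per tied
    positive-negative pair); AUPR is step-interpolated over the
    precision-recall staircase (no trapezoids).  Returns
    (AUC, AUPR, roc_points, pr_points) with the curves as DataFrames.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels_true, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined without both classes")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    aupr = float(average_precision_score(labels, scores))
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr})
    pr_points = pd.DataFrame({"recall": rec, "precision": prec})
    return float(auc), aupr, roc_points, pr_points


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus -inf/+inf sentinels.

    With the inclusive >= rule this visits every achievable confusion
    matrix exactly once.
    """
    s = np.unique(np.asarray(scores, dtype=float))
    mids = (s[:-1] + s[1:]) / 2.0 if s.size > 1 else np.empty(0)
    return np.unique(np.concatenate([[-np.inf], mids, [np.inf]]))


def _scan(scores: np.ndarray, labels: np.ndarray, thresholds: np.ndarray):
    """Confusion counts at every threshold (predict binding iff score >= T)."""
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    pos_sorted = (labels[order] == 1).astype(int)
    cum_pos = np.concatenate([[0], np.cumsum(pos_sorted)])
    n_pos = cum_pos[-1]
    n = scores.size
    idx = np.searchsorted(s_sorted, thresholds, side="left")
    pos_below = cum_pos[idx]
    neg_below = idx - pos_below
    tp = n_pos - pos_below
    fn = pos_below
    fp = (n - n_pos) - neg_below
    tn = neg_below
    return tp.astype(float), tn.astype(float), fp.astype(float), fn.astype(float)


def select_threshold(
    scores: np.ndarray,
    labels_true: np.ndarray,
    strategy: ThresholdStrategy,
) -> float:
    """Choose the operating threshold by exhaustive scan of the candidates.

    Ties on the selection criterion are broken toward higher sensitivity
    (so a perfectly separating threshold is preferred over a vacuous one),
    then toward the larger threshold (fewer predicted positives).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels_true, dtype=int)
    if scores.size == 0:
        raise ValueError("empty score list")
    if strategy.kind == "fixed":
        return float(strategy.target)
    if len(set(labels.tolist())) < 2:
        raise ValueError("threshold selection requires both classes")
    thr = candidate_thresholds(scores)
    tp, tn, fp, fn = _scan(scores, labels, thr)
    with np.errstate(invalid="ignore", divide="ignore"):
        sn = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        spec = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        fpr = 1.0 - spec
        den = np.sqrt((tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
        mcc = np.where(den > 0, (tp * tn - fp * fn) / np.where(den > 0, den, 1.0), 0.0)
    if strategy.kind == "sen_eq_spec":
        crit = np.abs(sn - spec)
    elif strategy.kind == "fpr_target":
        crit = np.abs(fpr - strategy.target)
    else:  # max_mcc
        crit = -mcc
    tied = np.flatnonzero(crit <= crit.min() + 1e-12)
    best_sn = sn[tied].max()
    i = int(tied[sn[tied] >= best_sn - 1e-12].max())
    return float(thr[i])


@dataclass
class CrossValResult:
    fold_metrics: list[MetricSet]
    pooled: MetricSet
    threshold: float
    oof_scores: np.ndarray = field(repr=False)
    oof_labels: np.ndarray = field(repr=False)
    fold_assignment: np.ndarray = field(repr=False)


def cross_validate(
    dataset: LabeledDataset,
    k: int = 10,
    m: int = 19,
    params: WsrcParams = WsrcParams(),
    seed: int = 0,
    strategy: ThresholdStrategy = ThresholdStrategy(),
    split_by: str = "protein",
) -> CrossValResult:
    """Stratified k-fold cross-validation of the under-sampled ensemble.

    Folds are stratified by class; with ``split_by='protein'`` all residues
    of a protein stay in one fold (no within-protein leakage; requires
    group ids), while ``split_by='residue'`` splits residues freely.
    Under-sampling happens inside each training fold only.  The threshold
    is selected on the pooled out-of-fold probabilities, and both per-fold
    and pooled metrics are reported at that single threshold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_min = min(dataset.minority_count, dataset.majority_count)
    if k > n_min:
        raise ValueError(f"k={k} exceeds the smaller class count ({n_min})")
    y = dataset.labels
    if split_by == "protein":
        if dataset.group_ids is None:
            raise ValueError("protein-wise splitting requires group_ids")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(dataset.features, y, groups=dataset.group_ids)
    elif split_by == "residue":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(dataset.features, y)
    else:
        raise ValueError("split_by must be 'protein' or 'residue'")

    oof = np.full(y.shape[0], np.nan)
    fold_assignment = np.full(y.shape[0], -1, dtype=int)
    for fold, (tr, te) in enumerate(splits):
        train = LabeledDataset(
            features=dataset.features[tr],
            labels=y[tr],
            group_ids=None if dataset.group_ids is None else dataset.group_ids[tr],
        )
        model = build_ensemble(train, m=m, params=params, seed=seed + 100_000 * (fold + 1))
        oof[te] = predict(model, dataset.features[te]).probabilities
        fold_assignment[te] = fold

    T = select_threshold(oof, y, strategy)
    pred = np.where(oof >= T, 1, 0)
    pooled = metrics(confusion(y, pred))
    pooled.AUC, pooled.AUPR, _, _ = roc_and_pr(oof, y)

    fold_metrics = []
    for fold in range(k):
        mask = fold_assignment == fold
        ms = metrics(confusion(y[mask], pred[mask]))
        if len(set(y[mask].tolist())) == 2:
            ms.AUC, ms.AUPR, _, _ = roc_and_pr(oof[mask], y[mask])
        fold_metrics.append(ms)
    return CrossValResult(
        fold_metrics=fold_metrics,
        pooled=pooled,
        threshold=T,
        oof_scores=oof,
        oof_labels=y.copy(),
        fold_assignment=fold_assignment,
    )


def grid_search(
    corpus,
    w_values,
    m_values,
    params: WsrcParams = WsrcParams(),
    seed: int = 0,
    k: int = 10,
    strategy: ThresholdStrategy = ThresholdStrategy(),
    split_by: str = "protein",
) -> pd.DataFrame:
    """Pooled-MCC surface over (window length w, ensemble size m).

    ``corpus`` must expose ``to_dataset(w)`` (features are re-extracted for
    every window length).  Returns a tidy table with columns w, m, MCC, AUC.
    """
    rows = []
    for w in w_values:
        dataset = corpus.to_dataset(w)
        for m in m_values:
            res = cross_validate(
                dataset, k=k, m=m, params=params, seed=seed,
                strategy=strategy, split_by=split_by,
            )
            rows.append({"w": w, "m": m, "MCC": res.pooled.MCC, "AUC": res.pooled.AUC})
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(a, b):
    """Two-sided Wilcoxon rank-sum comparison of two metric samples.

    Convenience wrapper over the standard test; returns (statistic, p-value).
    """
    res = ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


# re-export for callers assembling reports
__all__ = [
    "ConfusionCounts", "MetricSet", "ThresholdStrategy", "CrossValResult",
    "confusion", "metrics", "roc_and_pr", "candidate_thresholds",
    "select_threshold", "cross_validate", "grid_search", "wilcoxon_rank_sum",
    "BINDING", "WsrcParams",
]
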