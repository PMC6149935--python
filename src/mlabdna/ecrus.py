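"""Ensemble classifier with random under-sampling (EC-RUS).

Binding residues are heavily outnumbered by non-binding ones (roughly
11:1 to 19:1 in curated benchmarks), so each of the m base classifiers is
trained on a balanced dictionary: all minority (binding) samples plus a
with-replacement draw of equally many majority samples.  The ensemble
probability P(y) is the unweighted arithmetic mean of the m member scores,
and a threshold T on P(y) fixes the operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .wsrc import BINDING, NON_BINDING, Dictionary, WsrcParams, classify_batch

DEFAULT_M = 19


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels and per-sample protein ids."""

    features: np.ndarray
    labels: np.ndarray
    group_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels must have equal length")
        if self.group_ids is not None:
            self.group_ids = np.asarray(self.group_ids)
            if self.group_ids.shape[0] != self.labels.shape[0]:
                raise ValueError("group_ids must have one entry per sample")

    @property
    def minority_count(self) -> int:
        return int((self.labels == BINDING).sum())

    @property
    def majority_count(self) -> int:
        return int((self.labels == NON_BINDING).sum())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        """Build from a feature table (mlab_* / psa_* columns + label)."""
        cols = [c for c in df.columns if c.startswith(("mlab_", "psa_"))]
        return cls(
            features=df[cols].to_numpy(float),
            labels=df["label"].to_numpy(int),
            group_ids=df["protein_id"].to_numpy() if "protein_id" in df else None,
        )


@dataclass
class EnsembleModel:
    members: list[Dictionary]
    params: WsrcParams
    seed: int

    @property
    def m(self) -> int:
        return len(self.members)


@dataclass
class PredictionReport:
    """Per-sample ensemble probabilities plus the raw member score matrix."""

    probabilities: np.ndarray
    member_scores: np.ndarray
    threshold: float | None = None
    predicted_labels: np.ndarray | None = None
    member_labels: np.ndarray | None = field(default=None, repr=False)


def undersample(dataset: LabeledDataset, seed: int) -> Dictionary:
    """One balanced dictionary: all minority samples + an equal-size
    with-replacement draw of majority samples.  Deterministic given seed."""
    pos = np.nonzero(dataset.labels == BINDING)[0]
    neg = np.nonzero(dataset.labels == NON_BINDING)[0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty to under-sample")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(neg, size=pos.size, replace=True)
    idx = np.concatenate([pos, drawn])
    return Dictionary(X=dataset.features[idx], labels=dataset.labels[idx])


def build_ensemble(
    dataset: LabeledDataset,
    m: int = DEFAULT_M,
    params: WsrcParams = WsrcParams(),
    seed: int = 0,
) -> EnsembleModel:
    """m balanced dictionaries; member i draws with seed ``seed + i`` (i = 1..m)."""
    if m < 1:
        raise ValueError("ensemble size m must be >= 1")
    members = [undersample(dataset, seed + i) for i in range(1, m + 1)]
    return EnsembleModel(members=members, params=params, seed=seed)


def predict(model: EnsembleModel, samples: np.ndarray) -> PredictionReport:
    """Score samples with every member; P(y) is the mean member score."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[1] != model.members[0].X.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: samples have {samples.shape[1]}, "
            f"model expects {model.members[0].X.shape[1]}"
        )
    member_scores = np.empty((model.m, samples.shape[0]))
    member_labels = np.empty((model.m, samples.shape[0]), dtype=int)
    for i, member in enumerate(model.members):
        member_labels[i], member_scores[i] = classify_batch(
            samples, member, model.params
        )
    return PredictionReport(
        probabilities=member_scores.mean(axis=0),
        member_scores=member_scores,
        member_labels=member_labels,
    )


def apply_threshold(report: PredictionReport, T: float) -> np.ndarray:
    """Binding iff P(y) >= T (inclusive, so T = min P flags everything)."""
    labels = np.where(report.probabilities >= T, BINDING, NON_BINDING)
    report.threshold = float(T)
    report.predicted_labels = labels
    return labels


def report_to_frame(
    report: PredictionReport,
    protein_ids: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Prediction report as a table (protein_id, position, P, label)."""
    n = report.probabilities.shape[0]
    df = pd.DataFrame(
        {
            "protein_id": protein_ids if protein_ids is not None else [""] * n,
            "position": positions if positions is not None else np.arange(1, n + 1),
            "P": report.probabilities,
        }
    )
    if report.predicted_labels is not None:
        df["label"] = report.predicted_labels
    return df
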