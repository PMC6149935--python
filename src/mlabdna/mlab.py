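"""Multi-scale local average block (MLAB) features and PSA fusion.

The w x 20 normalized-PSSM window around a target residue is averaged over
six row blocks taken at three scales — the whole window (A), its two halves
(B, C) and its three thirds (D, E, F) — giving a 6 x 20 = 120-dimensional
descriptor that summarizes local evolutionary conservation at multiple
resolutions.  Predicted solvent accessibility (PSA) is fused in as one
windowed value per residue, for 120 + w features in total (131 at the
default w = 11).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pssm_io import PSSM_ALPHABET, NormalizedPssm, WindowMatrix, extract_window

BLOCK_LABELS = "ABCDEF"


@dataclass(frozen=True)
class BlockScheme:
    """Row-block partition of a w-row window: scales 1 (A), 2 (B,C), 3 (D,E,F).

    ``blocks`` holds 1-based inclusive (start, end) row ranges in A..F order.
    Block boundaries follow the ceiling rule: block t of scale s covers rows
    ceil((t-1)*w/s)+1 .. ceil(t*w/s), so w=11 splits into 11 / 6+5 / 4+4+3.
    """

    w: int
    blocks: tuple[tuple[int, int], ...]

    @property
    def sizes(self) -> tuple[int, ...]:
        """Row count B_k of each block."""
        return tuple(e - s + 1 for s, e in self.blocks)


def make_block_scheme(w: int) -> BlockScheme:
    if w < 3 or w % 2 == 0:
        raise ValueError(f"window length must be odd and >= 3, got {w}")
    blocks = []
    for scale in (1, 2, 3):
        for t in range(1, scale + 1):
            start = math.ceil((t - 1) * w / scale) + 1
            end = math.ceil(t * w / scale)
            blocks.append((start, end))
    return BlockScheme(w=w, blocks=tuple(blocks))


@dataclass
class MlabVector:
    """The 120 block-mean values, ordered block-major (A..F), 20 columns each."""

    values: np.ndarray
    center_position: int
    protein_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (120,):
            raise ValueError(f"MLAB vector must have 120 entries, got {self.values.shape}")


@dataclass
class PsaTrack:
    """Per-residue predicted solvent accessibility, min-max scaled to [0, 1]."""

    values: np.ndarray
    protein_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("PSA track must be one-dimensional")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("PSA track entries must lie in [0, 1]")

    @classmethod
    def from_raw(cls, raw: np.ndarray, protein_id: str = "") -> "PsaTrack":
        """Min-max normalize a raw accessibility vector (constant -> zeros)."""
        raw = np.asarray(raw, dtype=float)
        lo, hi = raw.min(), raw.max()
        values = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
        return cls(values=values, protein_id=protein_id)


@dataclass
class ResidueFeatureVector:
    """Fused per-residue features: 120 MLAB values then w windowed PSA values."""

    f_pssm_mlab: np.ndarray
    f_psa: np.ndarray
    label: int | None
    protein_id: str
    position: int

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.f_pssm_mlab, self.f_psa])


def mlab_transform(window: WindowMatrix, scheme: BlockScheme) -> MlabVector:
    """Average the window rows over each block of the scheme.

    Output entry (block k, column j) is the arithmetic mean over block k's
    rows of window column j; blocks are laid out A..F, 20 columns each.
    """
    if window.w != scheme.w:
        raise ValueError(f"window has {window.w} rows but scheme expects {scheme.w}")
    out = np.empty((6, 20))
    for k, (start, end) in enumerate(scheme.blocks):
        out[k] = window.values[start - 1: end].mean(axis=0)
    return MlabVector(values=out.ravel(), center_position=window.center_position)


def window_psa(psa: PsaTrack, position: int, w: int = 11) -> np.ndarray:
    """PSA values of the w residues centered at a 1-based position, zero-padded."""
    L = psa.values.shape[0]
    if not 1 <= position <= L:
        raise IndexError(f"position {position} outside 1..{L}")
    half = (w - 1) // 2
    out = np.zeros(w)
    lo = max(1, position - half)
    hi = min(L, position + half)
    out[lo - (position - half): hi - (position - half) + 1] = psa.values[lo - 1: hi]
    return out


def build_features(
    npssm: NormalizedPssm,
    psa: PsaTrack,
    labels: np.ndarray | None = None,
    w: int = 11,
) -> list[ResidueFeatureVector]:
    """Fuse MLAB and windowed-PSA features for every residue of one protein.

    Returns one vector per residue, ordered by position.  ``labels`` is an
    optional per-residue 0/1 array (1 = binding); omit it for unlabeled
    prediction inputs.
    """
    L = npssm.length
    if psa.values.shape[0] != L:
        raise ValueError(
            f"PSA length {psa.values.shape[0]} does not match PSSM length {L}"
        )
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != L:
            raise ValueError(f"labels length {labels.shape[0]} does not match {L}")
    scheme = make_block_scheme(w)
    out = []
    for pos in range(1, L + 1):
        mv = mlab_transform(extract_window(npssm, pos, w), scheme)
        out.append(
            ResidueFeatureVector(
                f_pssm_mlab=mv.values,
                f_psa=window_psa(psa, pos, w),
                label=None if labels is None else int(labels[pos - 1]),
                protein_id=npssm.protein_id,
                position=pos,
            )
        )
    return out


def feature_columns(w: int = 11) -> list[str]:
    """Column names: mlab_<block>_<aa> (block-major) then psa_<offset>."""
    half = (w - 1) // 2
    cols = [f"mlab_{b}_{aa}" for b in BLOCK_LABELS for aa in PSSM_ALPHABET]
    cols += [f"psa_{o:+d}" for o in range(-half, half + 1)]
    return cols


def features_to_frame(vectors: list[ResidueFeatureVector]) -> pd.DataFrame:
    """Stack residue feature vectors into a table (one row per residue)."""
    if not vectors:
        raise ValueError("no feature vectors to stack")
    w = vectors[0].f_psa.shape[0]
    data = np.stack([v.values for v in vectors])
    df = pd.DataFrame(data, columns=feature_columns(w))
    df.insert(0, "protein_id", [v.protein_id for v in vectors])
    df.insert(1, "position", [v.position for v in vectors])
    if vectors[0].label is not None:
        df["label"] = [v.label for v in vectors]
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
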