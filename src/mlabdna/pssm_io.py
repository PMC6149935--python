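"""Position-specific scoring matrix (PSSM) containers and I/O.

A PSSM is an L x 20 profile of per-position amino-acid scores produced by
iterative database search (PSI-BLAST ``-out_ascii_pssm``).  This module
provides the raw and min-max normalized matrix types, a reader/writer for
the PSI-BLAST ASCII dialect, construction of a PSSM from observed residue
frequencies and a substitution matrix, and window extraction around a
target residue.

Residue positions are 1-based inclusive in every public interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

#: Column order used by PSI-BLAST ASCII PSSM files.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWVY"


class PssmParseError(ValueError):
    """Raised when a PSSM file does not follow the expected ASCII dialect."""


@dataclass
class FrequencyMatrix:
    """Observed amino-acid frequencies per position (L x 20, entries >= 0)."""

    values: np.ndarray
    sequence: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"frequency matrix must be L x 20, got {self.values.shape}")
        if self.values.shape[0] != len(self.sequence):
            raise ValueError("row count must equal sequence length")
        if np.any(self.values < 0):
            raise ValueError("frequencies must be non-negative")


@dataclass
class SubstitutionMatrix:
    """A 20 x 20 amino-acid substitution (mutation-score) matrix."""

    values: np.ndarray
    alphabet: str = PSSM_ALPHABET

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError(f"substitution matrix must be 20 x 20, got {self.values.shape}")
        if len(set(self.alphabet)) != 20:
            raise ValueError("alphabet must contain 20 unique letters")

    @classmethod
    def dayhoff(cls) -> "SubstitutionMatrix":
        """Dayhoff mutation matrix (PAM250-family scores), in PSSM column order."""
        m = substitution_matrices.load("DAYHOFF")
        idx = [m.alphabet.index(a) for a in PSSM_ALPHABET]
        values = np.asarray(m)[np.ix_(idx, idx)]
        return cls(values=values, alphabet=PSSM_ALPHABET)


@dataclass
class Pssm:
    """Raw L x 20 evolutionary score matrix for one protein chain."""

    values: np.ndarray
    sequence: str
    protein_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"PSSM must be L x 20, got {self.values.shape}")
        if self.values.shape[0] != len(self.sequence):
            raise ValueError(
                f"PSSM rows ({self.values.shape[0]}) must equal sequence "
                f"length ({len(self.sequence)})"
            )

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class NormalizedPssm:
    """Min-max scaled PSSM with every entry in [0, 1].

    ``p_min`` / ``p_max`` are the extremes of the raw matrix the scaling
    was computed from (per protein, over the whole L x 20 matrix).
    """

    values: np.ndarray
    sequence: str
    protein_id: str = ""
    p_min: float = 0.0
    p_max: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("normalized PSSM entries must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class WindowMatrix:
    """A w x 20 slice of a normalized PSSM centered on a target residue.

    Rows overhanging the sequence termini are zero padding.
    """

    values: np.ndarray
    center_position: int
    w: int = field(default=11)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.w, 20):
            raise ValueError(f"window must be {self.w} x 20, got {self.values.shape}")


def compute_pssm(freq: FrequencyMatrix, subst: SubstitutionMatrix) -> Pssm:
    """Build a PSSM from position frequencies and a substitution matrix.

    Entry (i, j) is the frequency-weighted sum of substitution scores,
    ``sum_k freq[i, k] * subst[k, j]`` — i.e. the expected mutation score of
    position i toward residue type j.
    """
    if freq.values.shape[1] != subst.values.shape[0]:
        raise ValueError(
            f"shape mismatch: freq has {freq.values.shape[1]} columns, "
            f"subst has {subst.values.shape[0]} rows"
        )
    return Pssm(values=freq.values @ subst.values, sequence=freq.sequence)


def minmax_normalize(pssm: Pssm) -> NormalizedPssm:
    """Scale a PSSM to [0, 1] by min-max over the whole matrix.

    A constant matrix (max == min) maps to all zeros: it carries no
    conservation signal and this avoids division by zero.
    """
    p_min = float(pssm.values.min())
    p_max = float(pssm.values.max())
    if p_max > p_min:
        values = (pssm.values - p_min) / (p_max - p_min)
    else:
        values = np.zeros_like(pssm.values)
    return NormalizedPssm(
        values=values,
        sequence=pssm.sequence,
        protein_id=pssm.protein_id,
        p_min=p_min,
        p_max=p_max,
    )


def extract_window(npssm: NormalizedPssm, position: int, w: int = 11) -> WindowMatrix:
    """Return the w x 20 window centered at a 1-based residue position.

    Rows falling outside 1..L are zero rows (zero = minimally conserved in
    normalized space), so both termini yield full-size windows.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window length must be a positive odd integer, got {w}")
    L = npssm.length
    if not 1 <= position <= L:
        raise IndexError(f"position {position} outside 1..{L}")
    half = (w - 1) // 2
    out = np.zeros((w, 20))
    lo = max(1, position - half)
    hi = min(L, position + half)
    out[lo - (position - half): hi - (position - half) + 1] = npssm.values[lo - 1: hi]
    return WindowMatrix(values=out, center_position=position, w=w)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII dialect
# ---------------------------------------------------------------------------

_HEADER = (
    "\n"
    "Last position-specific scoring matrix computed\n"
    "            " + "   ".join(PSSM_ALPHABET) + "\n"
)


def read_psiblast_pssm(path: str | Path, protein_id: str | None = None) -> Pssm:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first 20 integer score columns (the log-odds block) are kept;
    the percentage columns of 40-column files and all footer statistics are
    ignored.  The sequence is reconstructed from the residue-letter column.
    """
    path = Path(path)
    rows: list[list[int]] = []
    letters: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            # data rows start "<pos> <letter> <20 or 40 ints> ..."
            if not tokens[0].lstrip("-").isdigit():
                continue
            if len(tokens) >= 2 and len(tokens[1]) == 1 and tokens[1].isalpha():
                if len(tokens) < 22:
                    raise PssmParseError(
                        f"{path.name}:{lineno}: data row has {len(tokens)} tokens, "
                        "expected at least 22 (position, residue, 20 scores)"
                    )
                try:
                    scores = [int(t) for t in tokens[2:22]]
                except ValueError as exc:
                    raise PssmParseError(
                        f"{path.name}:{lineno}: non-integer score field ({exc})"
                    ) from None
                rows.append(scores)
                letters.append(tokens[1])
    if not rows:
        raise PssmParseError(f"{path.name}: no PSSM data rows found")
    return Pssm(
        values=np.array(rows, dtype=float),
        sequence="".join(letters),
        protein_id=protein_id if protein_id is not None else path.stem,
    )


def write_psiblast_pssm(pssm: Pssm, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect read by :func:`read_psiblast_pssm`.

    Scores are rounded to the nearest integer (the dialect is integer-valued).
    """
    if np.any(~np.isfinite(pssm.values)):
        raise ValueError("PSSM contains NaN or infinite entries")
    scores = np.rint(pssm.values).astype(int)
    lines = [_HEADER.rstrip("\n")]
    for i, (letter, row) in enumerate(zip(pssm.sequence, scores), start=1):
        lines.append(f"{i:5d} {letter} " + " ".join(f"{v:3d}" for v in row))
    lines.append("")  # trailing newline
    Path(path).write_text("\n".join(lines))
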