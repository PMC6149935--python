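"""Synthetic corpus generator: proteins, PSSM files, PSA tracks and labels.

Real benchmarks for this task need database-searched PSSMs and a solvent
accessibility predictor, neither of which travels with a source tree.  The
generator emulates their statistical shape instead: random sequences,
integer PSSM scores with Gaussian noise, a conserved-block mean shift
injected into the rows around each binding residue (the local signal the
multi-scale block averages are designed to capture), PSA values elevated
at binding sites, and labels at a configurable majority:minority imbalance
(curated datasets run at roughly 11:1 to 19:1, so the default binding
fraction is 1/15).

Everything is emitted in the exact external dialects the pipeline
consumes, and every draw is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ecrus import LabeledDataset
from .mlab import PsaTrack, build_features
from .pssm_io import PSSM_ALPHABET, Pssm, minmax_normalize, write_psiblast_pssm

#: PSSM columns carrying the injected conservation signal (fixed so the
#: ground truth is known to every downstream test).
SIGNAL_COLUMNS = (2, 5, 8, 11, 14)

#: Signal extends this many rows on either side of a binding residue, so it
#: sits inside every window of length >= 5.
SIGNAL_HALF_WIDTH = 2


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic corpus.

    ``effect_size`` is the conserved-block mean shift in units of the PSSM
    noise standard deviation; ``noise_sd`` is that standard deviation on
    the integer PSSM score scale; ``psa_shift`` is the mean PSA elevation
    at binding sites on the raw [0, 1] accessibility scale.
    """

    n_proteins: int = 100
    length_range: tuple[int, int] = (100, 200)
    binding_fraction: float = 1.0 / 15.0
    effect_size: float = 2.0
    noise_sd: float = 4.0
    psa_shift: float = 0.3
    cluster_len: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.binding_fraction < 0.5:
            raise ValueError("binding_fraction must lie in [0, 0.5)")
        if self.length_range[0] < 11 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy 11 <= min <= max")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.n_proteins < 1 or self.cluster_len < 1:
            raise ValueError("n_proteins and cluster_len must be >= 1")


@dataclass
class SyntheticProtein:
    protein_id: str
    sequence: str
    pssm: Pssm
    psa_raw: np.ndarray
    labels: np.ndarray
    shifted_rows: np.ndarray  # bool mask of PSSM rows carrying signal


@dataclass
class SyntheticCorpus:
    proteins: list[SyntheticProtein]
    config: SimConfig
    _dataset_cache: dict = field(default_factory=dict, repr=False)

    @property
    def total_residues(self) -> int:
        return sum(len(p.sequence) for p in self.proteins)

    @property
    def n_binding(self) -> int:
        return int(sum(p.labels.sum() for p in self.proteins))

    def to_dataset(self, w: int = 11) -> LabeledDataset:
        """Extract fused MLAB + PSA features for every residue of the corpus."""
        if w in self._dataset_cache:
            return self._dataset_cache[w]
        feats, labels, groups = [], [], []
        for p in self.proteins:
            npssm = minmax_normalize(p.pssm)
            track = PsaTrack.from_raw(p.psa_raw, p.protein_id)
            vectors = build_features(npssm, track, p.labels, w=w)
            feats.append(np.stack([v.values for v in vectors]))
            labels.append(p.labels)
            groups.extend([p.protein_id] * len(p.sequence))
        ds = LabeledDataset(
            features=np.concatenate(feats),
            labels=np.concatenate(labels),
            group_ids=np.array(groups),
        )
        self._dataset_cache[w] = ds
        return ds

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA, per-protein PSSM files, PSA/label/truth TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pssm_dir = outdir / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        fasta = outdir / "proteins.fasta"
        with open(fasta, "w") as fh:
            for p in self.proteins:
                fh.write(f">{p.protein_id}\n{p.sequence}\n")
        rows_psa, rows_lab, rows_truth = [], [], []
        for p in self.proteins:
            write_psiblast_pssm(p.pssm, pssm_dir / f"{p.protein_id}.pssm")
            for i in range(len(p.sequence)):
                rows_psa.append((p.protein_id, i + 1, p.psa_raw[i]))
                rows_lab.append((p.protein_id, i + 1, int(p.labels[i])))
                rows_truth.append(
                    (p.protein_id, i + 1, int(p.labels[i]), int(p.shifted_rows[i]))
                )
        paths = {"fasta": fasta, "pssm_dir": pssm_dir}
        for name, rows, cols in (
            ("psa", rows_psa, ["protein_id", "position", "psa"]),
            ("labels", rows_lab, ["protein_id", "position", "label"]),
            ("truth", rows_truth, ["protein_id", "position", "binding", "shifted"]),
        ):
            path = outdir / f"{name}.tsv"
            pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
            paths[name] = path
        return paths


def _draw_labels(rng: np.random.Generator, L: int, cfg: SimConfig) -> np.ndarray:
    if cfg.cluster_len == 1:
        return (rng.random(L) < cfg.binding_fraction).astype(int)
    labels = np.zeros(L, dtype=int)
    starts = rng.random(L) < cfg.binding_fraction / cfg.cluster_len
    for i in np.nonzero(starts)[0]:
        labels[i: i + cfg.cluster_len] = 1
    return labels


def simulate(config: SimConfig) -> SyntheticCorpus:
    """Generate a corpus under the given study conditions.

    Sequences are uniform over the 20 amino acids; baseline PSSM scores are
    a discretized Gaussian (mean 0, sd ``noise_sd`` on the integer scale);
    each residue is marked binding independently with probability
    ``binding_fraction``; rows within +-2 of a binding residue receive a
    mean shift of ``effect_size * noise_sd`` (rounded to the integer scale)
    in five fixed columns; PSA is uniform noise plus ``psa_shift`` at
    binding residues.
    """
    rng = np.random.default_rng(config.seed)
    shift = int(round(config.effect_size * config.noise_sd))
    width = len(str(config.n_proteins))
    proteins = []
    for p in range(config.n_proteins):
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = "".join(rng.choice(list(PSSM_ALPHABET), size=L))
        labels = _draw_labels(rng, L, config)
        scores = np.rint(rng.normal(0.0, config.noise_sd, size=(L, 20)))
        shifted = np.zeros(L, dtype=bool)
        for i in np.nonzero(labels)[0]:
            lo = max(0, i - SIGNAL_HALF_WIDTH)
            hi = min(L, i + SIGNAL_HALF_WIDTH + 1)
            scores[lo:hi, list(SIGNAL_COLUMNS)] += shift
            shifted[lo:hi] = True
        psa = np.clip(rng.random(L) + config.psa_shift * labels, 0.0, None)
        pid = f"SYN{p:0{width}d}"
        proteins.append(
            SyntheticProtein(
                protein_id=pid,
                sequence=seq,
                pssm=Pssm(values=scores, sequence=seq, protein_id=pid),
                psa_raw=psa,
                labels=labels,
                shifted_rows=shifted,
            )
        )
    return SyntheticCorpus(proteins=proteins, config=config)


def make_fixture_pssm(L: int, seed: int = 0) -> Pssm:
    """Small deterministic PSSM for parser and round-trip tests."""
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(PSSM_ALPHABET), size=L))
    values = rng.integers(-10, 11, size=(L, 20)).astype(float)
    return Pssm(values=values, sequence=seq, protein_id=f"FIX{seed}")
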