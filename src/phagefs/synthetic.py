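"""Synthetic labeled protein datasets with planted class signal.

Sequences are sampled residue-by-residue, i.i.d. per position, from a
class-conditional residue distribution: a shared background (uniform 1/20
by default) with, for the positive class, a frequency multiplier on a
chosen set of residues followed by renormalisation.  This plants a
recoverable composition signal — the biased residues' AAC components — so
every pipeline stage (encoding, importance, selection, evaluation) is
testable without real data.  No motif or positional structure is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq_io import (
    AMINO_ACIDS,
    LabeledDataset,
    ProteinSequence,
    write_fasta,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``bias`` maps residues to a positive-class frequency multiplier (the
    effect size); 1.0 everywhere gives the null model with no class signal.
    """

    n_pos: int = 100
    n_neg: int = 100
    min_length: int = 80
    max_length: int = 120
    background: dict[str, float] | None = None  # None -> uniform 1/20
    bias: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one sample per class")
        if self.min_length < 2 or self.max_length < self.min_length:
            raise ValueError("invalid length range (min >= 2 required)")
        for aa in self.bias:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"biased residue {aa!r} not canonical")
        if any(m <= 0 for m in self.bias.values()):
            raise ValueError("bias multipliers must be positive")
        if self.background is not None:
            if set(self.background) - set(AMINO_ACIDS):
                raise ValueError("background contains non-canonical residues")
            if min(self.background.values(), default=0) < 0:
                raise ValueError("background frequencies must be >= 0")

    def class_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """(positive, negative) residue distributions, each summing to 1."""
        if self.background is None:
            base = np.full(20, 1 / 20)
        else:
            base = np.array(
                [self.background.get(aa, 0.0) for aa in AMINO_ACIDS]
            )
            if base.sum() <= 0:
                raise ValueError("background sums to zero")
            base = base / base.sum()
        pos = base.copy()
        for aa, mult in self.bias.items():
            pos[AMINO_ACIDS.index(aa)] *= mult
        pos = pos / pos.sum()
        return pos, base


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled dataset; byte-deterministic under the spec seed."""
    rng = np.random.default_rng(spec.seed)
    pos_freq, neg_freq = spec.class_frequencies()
    alphabet = np.array(list(AMINO_ACIDS))
    seqs: list[ProteinSequence] = []
    labels: list[int] = []
    for cls, n, freq, prefix in (
        (1, spec.n_pos, pos_freq, "pos"),
        (0, spec.n_neg, neg_freq, "neg"),
    ):
        for i in range(n):
            L = int(rng.integers(spec.min_length, spec.max_length + 1))
            residues = "".join(rng.choice(alphabet, size=L, p=freq))
            seqs.append(ProteinSequence(f"{prefix}_{i:04d}", residues))
            labels.append(cls)
    return LabeledDataset(seqs, labels)


def generate_files(
    spec: SyntheticSpec, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Generate and write ``<prefix>.fasta`` plus ``<prefix>.labels.tsv``."""
    data = generate(spec)
    fasta = Path(f"{out_prefix}.fasta")
    labels = Path(f"{out_prefix}.labels.tsv")
    write_fasta(data, fasta, labels_path=labels)
    return fasta, labels
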