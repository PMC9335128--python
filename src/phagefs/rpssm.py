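"""Reduced position-specific scoring matrix (RPSSM) encoding.

A PSSM is an L x 20 grid of per-position substitution scores, normally
produced by an iterative PSI-BLAST search.  Its 20 residue columns are
averaged into 10 reduced-alphabet groups — {F,Y,W}, {M,L}, {I,V}, {A,T,S},
{N,H}, {Q,E,D}, {R,K}, {P}, {C}, {G} — and the reduced grid is summarised
by 10 per-column variances (D_s) plus 100 consecutive-position squared
half-differences (D_{s,t}), 110 components in all.

Running the database search is out of scope: this module reads the
PSI-BLAST ``-out_ascii_pssm`` interchange format and also provides a
deterministic substitution-matrix fallback (``pseudo_pssm``) so the full
pipeline runs without any external search.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .encoders import FeatureVector
from .seq_io import AMINO_ACIDS, ProteinSequence

#: Fixed reduced-alphabet groups, in output column order.
REDUCED_GROUPS: tuple[tuple[str, ...], ...] = (
    ("F", "Y", "W"),
    ("M", "L"),
    ("I", "V"),
    ("A", "T", "S"),
    ("N", "H"),
    ("Q", "E", "D"),
    ("R", "K"),
    ("P",),
    ("C",),
    ("G",),
)

#: Residue column order used by PSI-BLAST ASCII PSSM files.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


class PSSMParseError(ValueError):
    """Malformed PSI-BLAST ASCII PSSM input."""


@dataclass
class PSSMatrix:
    """L x 20 per-position scores, columns in alphabetical residue order."""

    sequence_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM must be L x 20, got shape {self.scores.shape}"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class ReducedPSSM:
    """L x 10 reduced-alphabet scores, columns in REDUCED_GROUPS order."""

    sequence_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 10:
            raise ValueError(
                f"reduced PSSM must be L x 10, got shape {self.scores.shape}"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII I/O
# ---------------------------------------------------------------------------

def read_pssm(path: str | Path) -> PSSMatrix:
    """Parse the log-odds block of a PSI-BLAST ``-out_ascii_pssm`` file.

    The layout is two header lines, then one row per residue position:
    row index, residue letter, 20 log-odds, 20 weighted percentages and
    two trailing columns; only the 20 log-odds are consumed.  Columns are
    remapped from PSI-BLAST residue order to alphabetical order.
    """
    path = Path(path)
    rows: list[list[float]] = []
    expected_idx = 1
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) < 22 or not parts[0].isdigit():
            continue  # header, blank, or footer (lambda/K statistics)
        if int(parts[0]) != expected_idx:
            raise PSSMParseError(
                f"{path}: line {lineno}: expected position {expected_idx}, "
                f"got {parts[0]}"
            )
        try:
            scores = [float(x) for x in parts[2:22]]
        except ValueError as exc:
            raise PSSMParseError(
                f"{path}: line {lineno}: non-numeric score cell ({exc})"
            ) from exc
        if len(scores) != 20:
            raise PSSMParseError(
                f"{path}: line {lineno}: expected 20 score columns, "
                f"got {len(scores)}"
            )
        rows.append(scores)
        expected_idx += 1
    if not rows:
        raise PSSMParseError(f"{path}: no PSSM rows found")
    raw = np.array(rows)
    # remap PSI-BLAST column order -> alphabetical
    order = [PSIBLAST_ORDER.index(aa) for aa in AMINO_ACIDS]
    return PSSMatrix(sequence_id=path.stem, scores=raw[:, order])


def write_pssm(pssm: PSSMatrix, seq: ProteinSequence, path: str | Path) -> None:
    """Write a minimal PSI-BLAST-layout ASCII PSSM (log-odds block only)."""
    if len(pssm) != len(seq):
        raise ValueError("PSSM row count does not match sequence length")
    inv = [AMINO_ACIDS.index(aa) for aa in PSIBLAST_ORDER]
    with Path(path).open("w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed\n"
        )
        fh.write("    " + "  ".join(PSIBLAST_ORDER) + "\n")
        for i, row in enumerate(pssm.scores[:, inv], start=1):
            cells = " ".join(f"{v:g}" for v in row)
            # pad the percentage block with zeros + two trailing columns
            fh.write(
                f"{i} {seq.residues[i - 1]} {cells} "
                + " ".join(["0"] * 20)
                + " 0.00 0.00\n"
            )


def pseudo_pssm(
    seq: ProteinSequence, matrix: str = "BLOSUM62"
) -> PSSMatrix:
    """Substitution-matrix stand-in for a database-search PSSM.

    Row i is the substitution-matrix row of residue seq[i]; deterministic,
    so the downstream encoding is a pure function of the sequence.
    """
    try:
        sub = substitution_matrices.load(matrix.upper())
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    rows = np.array(
        [[float(sub[aa, bb]) for bb in AMINO_ACIDS] for aa in AMINO_ACIDS]
    )
    idx = [AMINO_ACIDS.index(aa) for aa in seq.residues]
    return PSSMatrix(sequence_id=seq.id, scores=rows[idx])


# ---------------------------------------------------------------------------
# Reduction and encoding
# ---------------------------------------------------------------------------

def reduce_pssm(pssm: PSSMatrix) -> ReducedPSSM:
    """Average the 20 PSSM columns into the 10 reduced-alphabet groups.

    Column s is the arithmetic mean of its group's source columns;
    singleton groups copy the source column unchanged.
    """
    cols = []
    for group in REDUCED_GROUPS:
        idx = [AMINO_ACIDS.index(aa) for aa in group]
        cols.append(pssm.scores[:, idx].mean(axis=1))
    return ReducedPSSM(pssm.sequence_id, np.column_stack(cols))


def rpssm_names() -> tuple[str, ...]:
    names = [f"RPSSM:Ds:{s}" for s in range(1, 11)]
    names += [
        f"RPSSM:Dst:{s}_{t}"
        for s in range(1, 11)
        for t in range(1, 11)
    ]
    return tuple(names)


def encode_rpssm(
    reduced: ReducedPSSM, literal_length_norm: bool = False
) -> FeatureVector:
    """The 110-component RPSSM feature vector.

    The first 10 components are the population variances of the reduced
    columns (D_s).  The remaining 100 are the consecutive-position
    statistics D_{s,t} = mean over i of (p_{i,s} - p_{i+1,t})^2 / 2,
    normalised by the number of summed pairs L-1; with
    ``literal_length_norm=True`` the sum is divided by L instead (the
    printed-formula convention).
    """
    L = len(reduced)
    if L < 2:
        raise ValueError(
            f"{reduced.sequence_id!r}: RPSSM dipeptide statistic requires "
            "length >= 2 (no consecutive position pair)"
        )
    p = reduced.scores
    d_s = p.var(axis=0)  # population variance (divide by L)
    denom = L if literal_length_norm else (L - 1)
    # D_{s,t}: p[:-1, s] vs p[1:, t] for all (s, t)
    diff = p[:-1, :, None] - p[1:, None, :]  # (L-1, 10 s, 10 t)
    d_st = (diff**2 / 2.0).sum(axis=0) / denom
    return FeatureVector(rpssm_names(), np.concatenate([d_s, d_st.ravel()]))


def encode_sequence(
    seq: ProteinSequence,
    *,
    pssm_dir: str | Path | None = None,
    substitution_matrix: str = "BLOSUM62",
    literal_length_norm: bool = False,
) -> FeatureVector:
    """Encode one sequence, loading ``<pssm_dir>/<id>.pssm`` when available.

    Falls back to the substitution-matrix pseudo-PSSM when no directory is
    given or the file is absent.
    """
    pssm: PSSMatrix | None = None
    if pssm_dir is not None:
        candidate = Path(pssm_dir) / f"{seq.id}.pssm"
        if candidate.exists():
            pssm = read_pssm(candidate)
            if len(pssm) != len(seq):
                raise ValueError(
                    f"{candidate}: {len(pssm)} rows but sequence "
                    f"{seq.id!r} has length {len(seq)}"
                )
    if pssm is None:
        pssm = pseudo_pssm(seq, substitution_matrix)
    return encode_rpssm(
        reduce_pssm(pssm), literal_length_norm=literal_length_norm
    )
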