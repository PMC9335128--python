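"""Sequence-derived protein feature encodings: AAC, CTD and CKSAAP.

AAC is the 20-component residue-frequency vector.  CTD maps residues to
three groups per physicochemical property and records group fractions
(Composition), cross-group adjacent-pair fractions (Transition) and the
normalised positions of each group's occurrences at five quantiles
(Distribution) — 21 components per property over 8 properties, 168 in all.
CKSAAP counts ordered residue pairs separated by exactly ``k`` intervening
residues, 400 components per ``k``.

The three-group assignments per property are not universal constants; this
module ships a versioned default table (``DEFAULT_GROUPING_VERSION``) based
on the widely used literature groupings, and accepts a user-supplied TSV so
results stay reproducible under any grouping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .seq_io import (
    AMINO_ACIDS,
    FeatureMatrix,
    LabeledDataset,
    ProteinSequence,
)


@dataclass(frozen=True)
class FeatureVector:
    """Named feature components for one sequence."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate component names")

    def __len__(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# CTD grouping tables
# ---------------------------------------------------------------------------

#: Version tag for the built-in three-group tables below.  The groupings for
#: hydrophobicity (PRAM900101), normalized van der Waals volume, polarity,
#: polarizability, charge, secondary structure and solvent accessibility are
#: the standard literature tables; surface tension follows the common
#: three-interval split of the free-energy-of-surface values.
DEFAULT_GROUPING_VERSION = "phagefs-ctd-groups-1"

CTD_PROPERTIES = (
    "hydrophobicity",
    "vdw_volume",
    "polarity",
    "polarizability",
    "charge",
    "surface_tension",
    "secondary_structure",
    "solvent_accessibility",
)

_DEFAULT_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "surface_tension": ("GQDNAHR", "KTSEC", "ILMFPWYV"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


@dataclass(frozen=True)
class GroupingTable:
    """Residue -> group index (1..3) maps for the 8 CTD properties."""

    groups: Mapping[str, Mapping[str, int]]
    version: str = DEFAULT_GROUPING_VERSION

    def __post_init__(self) -> None:
        if len(self.groups) != 8:
            raise ValueError(f"expected 8 properties, got {len(self.groups)}")
        for prop, mapping in self.groups.items():
            if set(mapping) != set(AMINO_ACIDS):
                missing = set(AMINO_ACIDS) - set(mapping)
                extra = set(mapping) - set(AMINO_ACIDS)
                raise ValueError(
                    f"property {prop!r}: bad residue coverage "
                    f"(missing {sorted(missing)}, extra {sorted(extra)})"
                )
            if set(mapping.values()) != {1, 2, 3}:
                raise ValueError(
                    f"property {prop!r}: groups must be exactly {{1,2,3}}"
                )

    @property
    def properties(self) -> tuple[str, ...]:
        return tuple(self.groups)


def default_grouping_table() -> GroupingTable:
    """The built-in three-group tables for the 8 physicochemical properties."""
    groups = {
        prop: {
            aa: g + 1
            for g, residues in enumerate(_DEFAULT_GROUPS[prop])
            for aa in residues
        }
        for prop in CTD_PROPERTIES
    }
    return GroupingTable(groups)


def read_grouping_table(path: str | Path) -> GroupingTable:
    """Load a grouping table from TSV (property, group-index, residues)."""
    groups: dict[str, dict[str, int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(
                f"{path}: line {lineno}: expected property<TAB>group<TAB>residues"
            )
        prop, gidx, residues = parts[0], parts[1], parts[2].strip().upper()
        if gidx not in ("1", "2", "3"):
            raise ValueError(f"{path}: line {lineno}: group index must be 1-3")
        for aa in residues:
            groups.setdefault(prop, {})[aa] = int(gidx)
    return GroupingTable(groups, version=str(path))


def write_grouping_table(table: GroupingTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# grouping table version: {table.version}\n")
        for prop, mapping in table.groups.items():
            for g in (1, 2, 3):
                residues = "".join(
                    aa for aa in AMINO_ACIDS if mapping[aa] == g
                )
                fh.write(f"{prop}\t{g}\t{residues}\n")


# ---------------------------------------------------------------------------
# AAC
# ---------------------------------------------------------------------------

_AAC_NAMES = tuple(f"AAC:{aa}" for aa in AMINO_ACIDS)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode_aac(seq: ProteinSequence) -> FeatureVector:
    """Amino-acid composition: component i = count(residue_i) / L.

    Returns 20 components in fixed alphabetical residue order, summing to 1.
    """
    counts = np.zeros(20)
    for aa in seq.residues:
        counts[_AA_INDEX[aa]] += 1
    return FeatureVector(_AAC_NAMES, counts / len(seq))


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

_T_PAIRS = ((1, 2), (1, 3), (2, 3))
_D_QUANTILES = (("first", None), ("25", 0.25), ("50", 0.50),
                ("75", 0.75), ("100", 1.00))


def ctd_names(table: GroupingTable | None = None) -> tuple[str, ...]:
    table = table or default_grouping_table()
    names: list[str] = []
    for prop in table.properties:
        names += [f"CTD:{prop}:C:{g}" for g in (1, 2, 3)]
        names += [f"CTD:{prop}:T:{a}-{b}" for a, b in _T_PAIRS]
        for g in (1, 2, 3):
            names += [f"CTD:{prop}:D:{g}:{q}" for q, _ in _D_QUANTILES]
    return tuple(names)


def encode_ctd(
    seq: ProteinSequence, groups: GroupingTable | None = None
) -> FeatureVector:
    """Composition/Transition/Distribution encoding (168 components).

    Per property: 3 C components (group fractions), 3 T components
    (fraction of adjacent pairs joining two distinct groups, both orders
    counted, over L-1 pairs), and 15 D components (position/L of the first
    occurrence and of the ceil(q*n_g)-th occurrence for q = 25/50/75/100%,
    per group; all 0 when the group is absent).
    """
    table = groups or default_grouping_table()
    L = len(seq)
    if L < 2:
        raise ValueError(
            f"sequence {seq.id!r}: CTD transition requires length >= 2"
        )
    values: list[float] = []
    for prop in table.properties:
        mapping = table.groups[prop]
        g = np.array([mapping[aa] for aa in seq.residues])
        # Composition
        for k in (1, 2, 3):
            values.append(float(np.sum(g == k)) / L)
        # Transition: unordered distinct-group adjacent pairs, both orders
        a, b = g[:-1], g[1:]
        for x, y in _T_PAIRS:
            n = np.sum(((a == x) & (b == y)) | ((a == y) & (b == x)))
            values.append(float(n) / (L - 1))
        # Distribution
        for k in (1, 2, 3):
            pos = np.flatnonzero(g == k) + 1  # 1-based positions
            n_g = pos.size
            if n_g == 0:
                values.extend([0.0] * 5)
                continue
            values.append(pos[0] / L)
            for _, q in _D_QUANTILES[1:]:
                values.append(pos[math.ceil(q * n_g) - 1] / L)
    return FeatureVector(ctd_names(table), np.array(values))


# ---------------------------------------------------------------------------
# CKSAAP
# ---------------------------------------------------------------------------

def cksaap_names(k: int) -> tuple[str, ...]:
    return tuple(
        f"CKSAAP{k}:{a}_{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS
    )


def encode_cksaap(
    seq: ProteinSequence, k: int = 1, pair_norm: bool = False
) -> FeatureVector:
    """Composition of k-spaced amino-acid pairs (400 components).

    Component (a, b) counts positions i with seq[i] = a and seq[i+k+1] = b.
    By default the count is divided by the sequence length L; with
    ``pair_norm=True`` it is divided by the number of valid pairs
    (L - k - 1), the convention of much of the descriptor literature.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    L = len(seq)
    if L < k + 2:
        raise ValueError(
            f"sequence {seq.id!r}: CKSAAP with k={k} requires length >= {k + 2}"
        )
    counts = np.zeros((20, 20))
    res = seq.residues
    for i in range(L - k - 1):
        counts[_AA_INDEX[res[i]], _AA_INDEX[res[i + k + 1]]] += 1
    denom = (L - k - 1) if pair_norm else L
    return FeatureVector(cksaap_names(k), counts.ravel() / denom)


# ---------------------------------------------------------------------------
# Dataset-level encoding
# ---------------------------------------------------------------------------

ENCODER_NAMES = ("aac", "ctd", "cksaap", "rpssm")


def encode_dataset(
    data: LabeledDataset,
    encoder: str,
    *,
    k: int = 1,
    groups: GroupingTable | None = None,
    pair_norm: bool = False,
    pssm_dir: str | Path | None = None,
    substitution_matrix: str = "BLOSUM62",
    literal_length_norm: bool = False,
) -> FeatureMatrix:
    """Encode every sequence of a labeled dataset with one encoder.

    Row order matches dataset order; labels are carried through.  Any
    per-sequence failure is re-raised with the offending sequence id.
    """
    from . import rpssm as _rpssm  # deferred: avoids import cycle

    if encoder not in ENCODER_NAMES:
        raise ValueError(f"unknown encoder {encoder!r}; expected {ENCODER_NAMES}")
    rows: list[np.ndarray] = []
    names: tuple[str, ...] | None = None
    for seq in data.sequences:
        try:
            if encoder == "aac":
                fv = encode_aac(seq)
            elif encoder == "ctd":
                fv = encode_ctd(seq, groups)
            elif encoder == "cksaap":
                fv = encode_cksaap(seq, k=k, pair_norm=pair_norm)
            else:
                fv = _rpssm.encode_sequence(
                    seq,
                    pssm_dir=pssm_dir,
                    substitution_matrix=substitution_matrix,
                    literal_length_norm=literal_length_norm,
                )
        except ValueError as exc:
            raise ValueError(f"encoder {encoder!r} failed on {seq.id!r}: {exc}") from exc
        if names is None:
            names = fv.names
        rows.append(fv.values)
    assert names is not None
    return FeatureMatrix(
        names=list(names),
        values=np.vstack(rows),
        labels=np.array(data.labels),
        sample_ids=[s.id for s in data.sequences],
    )


def encode_concatenated(
    data: LabeledDataset,
    encoders: tuple[str, ...] = ENCODER_NAMES,
    **kwargs,
) -> FeatureMatrix:
    """Column-concatenate several encodings (e.g. the 698-D full set)."""
    parts = [encode_dataset(data, e, **kwargs) for e in encoders]
    return FeatureMatrix.concat(parts)
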