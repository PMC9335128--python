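"""Reading, validating and writing protein sequence data and feature tables.

Protein records come in as FASTA (via Biopython); binary class labels come
either from a two-column TSV sidecar (``id<TAB>label``) or from a ``|1`` /
``|0`` suffix on the FASTA header.  Feature matrices are round-tripped as
TSV with the label column last, named ``label``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: residues treated as unknown/ambiguous and removed (or rejected) on input;
#: '*' stops and '-' gaps are handled the same way.
UNKNOWN_RESIDUES = frozenset("BJOUXZ*-")


class SequenceError(ValueError):
    """A sequence violates the 20-letter amino-acid alphabet contract."""


class FastaParseError(ValueError):
    """Malformed or empty FASTA input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 canonical amino acids.

    Residues are upper-cased on construction; any other character raises
    :class:`SequenceError`.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Parallel lists of sequences and binary labels (1=positive, 0=negative)."""

    sequences: list[ProteinSequence]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_positive(self) -> int:
        return int(sum(self.labels))

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive


@dataclass
class FeatureMatrix:
    """Samples x named feature components, with parallel binary labels.

    Component names carry encoder provenance (e.g. ``AAC:K``,
    ``CTD:charge:T:1-2``, ``CKSAAP1:A_G``, ``RPSSM:Ds:3``).
    """

    names: list[str]
    values: np.ndarray  # shape (n_samples, n_components), float64
    labels: np.ndarray  # shape (n_samples,), int
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.names)} names"
            )
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("row count does not match label count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate component names")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order (names must all exist)."""
        idx = [self.names.index(n) for n in names]
        return FeatureMatrix(
            names=list(names),
            values=self.values[:, idx],
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
        )

    @staticmethod
    def concat(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        """Column-wise concatenation; labels must agree across parts."""
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if not np.array_equal(p.labels, first.labels):
                raise ValueError("label vectors differ between parts")
        names: list[str] = []
        for p in parts:
            names.extend(p.names)
        return FeatureMatrix(
            names=names,
            values=np.hstack([p.values for p in parts]),
            labels=first.labels.copy(),
            sample_ids=list(first.sample_ids),
        )


# ---------------------------------------------------------------------------
# FASTA + labels
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    policy: str = "drop",
    labels_path: str | Path | None = None,
) -> LabeledDataset | list[ProteinSequence]:
    """Read protein records from FASTA, normalising case and handling ambiguity.

    Parameters
    ----------
    path:
        FASTA file (multi-record, wrapped or unwrapped lines).
    policy:
        ``"drop"`` removes any record containing an unknown residue
        (B, J, O, U, X, Z, ``*`` or ``-``) and counts it; ``"reject"``
        raises :class:`SequenceError` on the first such record.
    labels_path:
        Optional two-column TSV sidecar (``id<TAB>label``).  When given, a
        :class:`LabeledDataset` is returned; labels may instead be encoded
        as a ``|1`` / ``|0`` suffix on the FASTA id, which is detected
        automatically.  With neither convention present a plain sequence
        list is returned.

    Returns
    -------
    LabeledDataset or list[ProteinSequence]
    """
    if policy not in ("drop", "reject"):
        raise ValueError(f"unknown policy {policy!r}")
    path = Path(path)
    records = _parse_fasta_records(path)
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")

    kept: list[tuple[str, str]] = []
    n_dropped = 0
    for rec_id, residues in records:
        residues = residues.upper()
        unknown = set(residues) & UNKNOWN_RESIDUES
        other_bad = set(residues) - _AA_SET - UNKNOWN_RESIDUES
        if other_bad:
            raise SequenceError(
                f"{path}: record {rec_id!r} contains non-residue characters "
                f"{sorted(other_bad)}"
            )
        if unknown or not residues:
            if policy == "reject":
                raise SequenceError(
                    f"{path}: record {rec_id!r} contains unknown residues "
                    f"{sorted(unknown) if unknown else '(empty)'}"
                )
            n_dropped += 1
            continue
        kept.append((rec_id, residues))

    if not kept:
        raise FastaParseError(
            f"{path}: all {n_dropped} records dropped by ambiguity policy"
        )

    sidecar = _read_label_sidecar(labels_path) if labels_path else None
    suffix_labels = all(
        rid.rsplit("|", 1)[-1] in ("0", "1") and "|" in rid for rid, _ in kept
    )

    if sidecar is not None:
        seqs, labels = [], []
        for rid, res in kept:
            if rid not in sidecar:
                raise ValueError(f"no label for sequence id {rid!r} in sidecar")
            seqs.append(ProteinSequence(rid, res))
            labels.append(sidecar[rid])
        ds = LabeledDataset(seqs, labels)
        ds.n_dropped = n_dropped  # type: ignore[attr-defined]
        return ds
    if suffix_labels:
        seqs, labels = [], []
        for rid, res in kept:
            base, lab = rid.rsplit("|", 1)
            seqs.append(ProteinSequence(base, res))
            labels.append(int(lab))
        ds = LabeledDataset(seqs, labels)
        ds.n_dropped = n_dropped  # type: ignore[attr-defined]
        return ds

    out = [ProteinSequence(rid, res) for rid, res in kept]
    return out


def _parse_fasta_records(path: Path) -> list[tuple[str, str]]:
    """Parse FASTA via Biopython, mapping failures to FastaParseError."""
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i + 1 for i, ln in enumerate(text.splitlines()) if ln.strip()
        )
        raise FastaParseError(
            f"{path}: line {first_bad}: expected FASTA header starting with '>'"
        )
    try:
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython is permissive
        raise FastaParseError(f"{path}: {exc}") from exc
    return [(r.id, str(r.seq)) for r in records]


def _read_label_sidecar(path: str | Path) -> dict[str, int]:
    """Two-column TSV: sequence id, label in {0,1}."""
    out: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ValueError(
                f"{path}: line {lineno}: expected 'id<TAB>0|1', got {line!r}"
            )
        out[parts[0]] = int(parts[1])
    if not out:
        raise ValueError(f"{path}: empty label sidecar")
    return out


def write_fasta(
    data: LabeledDataset | Iterable[ProteinSequence],
    path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write sequences to FASTA; optionally a label sidecar TSV alongside."""
    path = Path(path)
    if isinstance(data, LabeledDataset):
        seqs, labels = data.sequences, data.labels
    else:
        seqs, labels = list(data), None
    with path.open("w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")
    if labels_path is not None:
        if labels is None:
            raise ValueError("labels requested but data carries none")
        with Path(labels_path).open("w") as fh:
            for s, l in zip(seqs, labels):
                fh.write(f"{s.id}\t{l}\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a TSV with component-name header, one row per sample, label last."""
    df = pd.DataFrame(matrix.values, columns=matrix.names)
    df.insert(0, "id", matrix.sample_ids)
    df["label"] = matrix.labels
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Inverse of :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ValueError(f"{path}: no 'label' column")
    sample_ids = (
        [str(x) for x in df.pop("id")] if "id" in df.columns else []
    )
    labels = df.pop("label").to_numpy(dtype=int)
    return FeatureMatrix(
        names=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        labels=labels,
        sample_ids=sample_ids,
    )
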