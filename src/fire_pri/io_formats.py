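"""Readers and writers for the external file formats.

Sequences travel as FASTA, interaction pairs and annotations as two-column
tab/whitespace-separated text (``#`` lines are comments), and feature
datasets as tab-separated numeric text with a header row of feature names
and a final ``label`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
RNA_ALPHABET = frozenset("AUCG")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier.

    Non-standard residue letters are permitted but flagged with a warning
    at load time; downstream feature windows overlapping them are skipped.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"protein {self.id!r}: sequence must be non-empty")


@dataclass(frozen=True)
class RnaRecord:
    """An RNA sequence over {A, U, C, G} with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("RNA id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"RNA {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"RNA {self.id!r}: letters outside AUCG after canonicalization: "
                f"{sorted(bad)}"
            )


@dataclass
class InteractionSet:
    """A labelled set of (protein id, RNA id) pairs.

    ``scores`` optionally carries a per-pair confidence score (the SPR
    score for negative sets produced by similarity-based selection).
    """

    pairs: frozenset[tuple[str, str]]
    label: str
    scores: dict[tuple[str, str], float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValidationError(f"label must be positive|negative, got {self.label!r}")
        self.pairs = frozenset(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __iter__(self):
        return iter(sorted(self.pairs))

    @property
    def proteins(self) -> set[str]:
        return {p for p, _ in self.pairs}

    @property
    def rnas(self) -> set[str]:
        return {r for _, r in self.pairs}


@dataclass
class AnnotationTable:
    """Protein id -> set of annotation identifiers (GO terms or Pfam domains).

    Lookup of an unannotated protein yields the empty set: annotation
    coverage is incomplete in practice and Jaccard similarity downstream is
    defined to 0 for empty sets.
    """

    mapping: dict[str, frozenset[str]]
    role: str  # "go" | "domain"

    def __post_init__(self) -> None:
        if self.role not in ("go", "domain"):
            raise ValidationError(f"role must be go|domain, got {self.role!r}")
        self.mapping = {k: frozenset(v) for k, v in self.mapping.items()}

    def get(self, protein_id: str) -> frozenset[str]:
        return self.mapping.get(protein_id, frozenset())

    def __getitem__(self, protein_id: str) -> frozenset[str]:
        return self.get(protein_id)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str):
    """Read a FASTA file into Protein/Rna records.

    For ``alphabet="rna"``, sequences are uppercased and T is mapped to U
    (public RNA sequences are frequently stored in the DNA alphabet); any
    remaining letter outside {A,U,C,G} is a validation error.  Duplicate
    ids are rejected; record order is preserved.
    """
    if alphabet not in ("protein", "rna"):
        raise ValidationError(f"alphabet must be protein|rna, got {alphabet!r}")
    path = Path(path)
    _precheck_fasta(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: record {rec.id!r} has an empty sequence")
        if alphabet == "rna":
            seq = seq.replace("T", "U")
            bad = set(seq) - RNA_ALPHABET
            if bad:
                raise ValidationError(
                    f"{path}: RNA record {rec.id!r} contains letters outside "
                    f"ACGTU: {sorted(bad)}"
                )
            records.append(RnaRecord(rec.id, seq))
        else:
            nonstd = set(seq) - STANDARD_AMINO_ACIDS
            if nonstd:
                logger.warning(
                    "protein %s contains non-standard letters %s; windows "
                    "overlapping them will be skipped during featurization",
                    rec.id,
                    sorted(nonstd),
                )
            records.append(ProteinRecord(rec.id, seq))
    return records


def _precheck_fasta(path: Path) -> None:
    # SeqIO silently skips leading junk; fail loudly with the line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected a '>' header, got {line.strip()!r}"
                )
            return


def write_fasta(records: Iterable[ProteinRecord | RnaRecord], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Pair / annotation tables


def _iter_rows(path: Path, n_cols: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < n_cols:
                raise FormatError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def read_pairs(path: str | Path, label: str) -> InteractionSet:
    """Read a two-column (protein id, RNA id) pair file.

    A literal header row whose first column is ``protein`` (case-insensitive)
    is skipped.  Duplicate rows are collapsed with a logged warning.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    n_rows = 0
    n_dupes = 0
    for lineno, fields in _iter_rows(path, 2):
        if n_rows == 0 and fields[0].lower() in ("protein", "protein_id"):
            continue
        pair = (fields[0], fields[1])
        n_rows += 1
        if pair in pairs:
            n_dupes += 1
        pairs.add(pair)
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate pair rows", path, n_dupes)
    logger.info("%s: read %d unique %s pairs", path, len(pairs), label)
    return InteractionSet(frozenset(pairs), label)


def write_pairs(iset: InteractionSet, path: str | Path) -> None:
    """Write pairs as tab-separated text; a third score column is added
    when the set carries scores."""
    with open(path, "w") as fh:
        if iset.scores is not None:
            fh.write("# protein\trna\tscore\n")
            for pair in iset:
                fh.write(f"{pair[0]}\t{pair[1]}\t{iset.scores[pair]:.10g}\n")
        else:
            fh.write("# protein\trna\n")
            for pair in iset:
                fh.write(f"{pair[0]}\t{pair[1]}\n")


def read_annotations(path: str | Path, role: str) -> AnnotationTable:
    """Read a two-column (protein id, annotation id) file into a table."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    for _, fields in _iter_rows(path, 2):
        mapping.setdefault(fields[0], set()).add(fields[1])
    return AnnotationTable({k: frozenset(v) for k, v in mapping.items()}, role)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# protein\t{table.role}\n")
        for pid in sorted(table.mapping):
            for term in sorted(table.mapping[pid]):
                fh.write(f"{pid}\t{term}\n")


def check_disjoint(negatives: InteractionSet, positives: InteractionSet) -> None:
    """A negative set must not overlap its paired positive set."""
    overlap = negatives.pairs & positives.pairs
    if overlap:
        raise ValidationError(
            f"negative set overlaps positives on {len(overlap)} pairs, "
            f"e.g. {sorted(overlap)[0]}"
        )


def resolve_ids(iset: InteractionSet, proteins, rnas) -> None:
    """Check that every id in the set resolves against the loaded sequences."""
    pids = {p.id for p in proteins}
    rids = {r.id for r in rnas}
    missing_p = iset.proteins - pids
    missing_r = iset.rnas - rids
    if missing_p or missing_r:
        raise ValidationError(
            f"unresolved ids in {iset.label} set: proteins {sorted(missing_p)[:5]}, "
            f"rnas {sorted(missing_r)[:5]}"
        )


# ---------------------------------------------------------------------------
# Feature datasets


def write_dataset(
    X: np.ndarray, y: np.ndarray, feature_names: list[str], path: str | Path
) -> None:
    """Write a labelled feature matrix as TSV: named feature columns plus a
    final integer ``label`` column."""
    df = pd.DataFrame(X, columns=feature_names)
    df["label"] = np.asarray(y, dtype=int)
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    y = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), y, list(df.columns)
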