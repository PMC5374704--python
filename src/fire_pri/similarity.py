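"""Aggregated protein-protein similarity.

Three evidence channels are combined by an unweighted mean:

* ``SS`` — sequence similarity, a self-score-normalized Smith-Waterman
  local alignment score,
  ``nsw(a, b) = sw(a, b) / (sqrt(sw(a, a)) * sqrt(sw(b, b)))``,
  symmetrized as ``SS = (nsw(a, b) + nsw(b, a)) / 2``;
* ``FS`` — Jaccard overlap of the proteins' GO term sets (all three
  ontologies pooled, directly assigned terms only);
* ``DS`` — Jaccard overlap of the proteins' Pfam domain fingerprints.

``AS = (SS + FS + DS) / 3``.  A protein with no annotation contributes 0
for that channel rather than renormalizing the mean: absence of evidence
is not evidence of similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .exceptions import ValidationError
from .io_formats import AnnotationTable, ProteinRecord


@dataclass(frozen=True)
class AlignmentParams:
    """Smith-Waterman scoring scheme.

    Defaults are the canonical local-alignment choices: BLOSUM62 with gap
    open 10 and gap extension 0.5 (a gap of length L costs
    ``10 + 0.5 * (L - 1)``).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties must be non-negative")


DEFAULT_PARAMS = AlignmentParams()


def make_aligner(params: AlignmentParams = DEFAULT_PARAMS) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def sw_score(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS, _aligner=None
) -> float:
    """Raw Smith-Waterman local alignment score (0 when no positive-scoring
    local alignment exists)."""
    if not a or not b:
        raise ValidationError("sequences must be non-empty")
    aligner = _aligner if _aligner is not None else make_aligner(params)
    return float(aligner.score(a, b))


def normalized_sw(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS, _aligner=None
) -> float:
    """Self-score-normalized Smith-Waterman similarity in [0, 1]."""
    aligner = _aligner if _aligner is not None else make_aligner(params)
    saa = sw_score(a, a, params, _aligner=aligner)
    sbb = sw_score(b, b, params, _aligner=aligner)
    if saa <= 0 or sbb <= 0:
        raise ValidationError(
            "normalization undefined: a self-alignment scored <= 0 "
            "(degenerate scoring parameters)"
        )
    return sw_score(a, b, params, _aligner=aligner) / (np.sqrt(saa) * np.sqrt(sbb))


def sequence_similarity(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> float:
    """SS(a, b): mean of the two argument orders of ``normalized_sw``.

    The two orders are identical under this symmetric normalization; the
    average is retained for fidelity to the defining formula.
    """
    aligner = make_aligner(params)
    return 0.5 * (
        normalized_sw(a, b, params, _aligner=aligner)
        + normalized_sw(b, a, params, _aligner=aligner)
    )


def jaccard(s1, s2) -> float:
    """|s1 ∩ s2| / |s1 ∪ s2|; 0 when both sets are empty (no evidence of
    similarity is not similarity)."""
    s1, s2 = set(s1), set(s2)
    union = s1 | s2
    if not union:
        return 0.0
    return len(s1 & s2) / len(union)


def aggregate_similarity(ss: float, fs: float, ds: float) -> float:
    """AS: unweighted mean of the three similarity channels."""
    for name, v in (("ss", ss), ("fs", fs), ("ds", ds)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name}={v} outside [0, 1]")
    return (ss + fs + ds) / 3.0


@dataclass
class SimilarityMatrix:
    """Symmetric aggregated similarity over an ordered protein id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        self._index = {pid: i for i, pid in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValidationError("duplicate protein ids in similarity matrix")

    def index_of(self, protein_id: str) -> int:
        try:
            return self._index[protein_id]
        except KeyError:
            raise ValidationError(f"unknown protein id {protein_id!r}") from None

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index_of(id_a), self.index_of(id_b)])


def build_similarity_matrix(
    proteins: list[ProteinRecord],
    go_table: AnnotationTable | None = None,
    domain_table: AnnotationTable | None = None,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> SimilarityMatrix:
    """Compute the full symmetric AS matrix over the given protein order.

    Sequence self-scores are cached so each unordered pair costs one
    alignment; the symmetric normalization makes the two argument orders
    of nsw identical.
    """
    ids = [p.id for p in proteins]
    seqs = [p.sequence for p in proteins]
    n = len(proteins)
    aligner = make_aligner(params)
    self_scores = np.array([sw_score(s, s, params, _aligner=aligner) for s in seqs])
    if np.any(self_scores <= 0):
        raise ValidationError("a self-alignment scored <= 0; normalization undefined")
    norm = np.sqrt(self_scores)

    def annot(table: AnnotationTable | None, pid: str) -> frozenset[str]:
        return table.get(pid) if table is not None else frozenset()

    values = np.empty((n, n), dtype=float)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                ss = 1.0
            else:
                ss = sw_score(seqs[i], seqs[j], params, _aligner=aligner) / (
                    norm[i] * norm[j]
                )
            fs = jaccard(annot(go_table, ids[i]), annot(go_table, ids[j]))
            ds = jaccard(annot(domain_table, ids[i]), annot(domain_table, ids[j]))
            values[i, j] = values[j, i] = aggregate_similarity(ss, fs, ds)
    return SimilarityMatrix(ids, values)


def write_similarity(matrix: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids).to_csv(
        path, sep="\t"
    )


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(list(df.columns), df.to_numpy(dtype=float))
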