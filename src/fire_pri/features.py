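"""Paired (k+3)-mer sequence features and the FScore filter.

A protein-RNA pair is encoded by pairing conjoint triads of the protein
with k-nucleotide units (k-NAs) of the RNA:

* the 20 amino acids are reduced to four physicochemical classes
  {D,E}, {H,R,K}, {C,G,N,Q,S,T,Y}, {A,F,I,L,M,P,V,W}; a conjoint triad is
  a width-3 sliding window identified up to this class alphabet, giving
  4^3 = 64 triad classes;
* a k-NA is a width-k sliding window of the RNA (k = 1, 2, 3), giving
  4, 16 and 64 distinct units;
* pairing triad classes with k-NAs yields 64x4 = 256 4-mers,
  64x16 = 1024 5-mers and 64x64 = 4096 6-mers — 5376 dimensions in all,
  arranged as the 6-mer block, then 5-mers, then 4-mers; within a block
  dimensions are ordered lexicographically by (k-NA string, triad class).

The raw value of a dimension is the product of its triad-class count and
its k-NA count (one occurrence per co-occurrence of the two components),
weighted by the concentration C_i = N_i / 5376 of its type, then min-max
normalized across the 5376 entries of the vector.

The FScore of a feature is the ratio of its min-max-normalized summed
frequency in the positive class to that in the negative class; filtering
keeps the k/2 largest-scoring and k/2 smallest-scoring features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

RESIDUE_CLASS_GROUPS: tuple[str, ...] = ("DE", "HRK", "CGNQSTY", "AFILMPVW")
RESIDUE_CLASS: dict[str, int] = {
    aa: i + 1 for i, group in enumerate(RESIDUE_CLASS_GROUPS) for aa in group
}
RNA_ALPHABET = "ACGU"

N_TRIAD_CLASSES = 64
#: number of unique (k+3)-mers per type, keyed by k (type i corresponds to k=i)
N_UNIQUE = {1: N_TRIAD_CLASSES * 4, 2: N_TRIAD_CLASSES * 16, 3: N_TRIAD_CLASSES * 64}
TOTAL_FEATURES = sum(N_UNIQUE.values())
#: block layout: 6-mers first, then 5-mers, then 4-mers
BLOCK_ORDER = (3, 2, 1)
BLOCK_OFFSET = {3: 0, 2: N_UNIQUE[3], 1: N_UNIQUE[3] + N_UNIQUE[2]}

TRIAD_CLASSES: list[tuple[int, int, int]] = list(
    itertools.product((1, 2, 3, 4), repeat=3)
)
_TRIAD_INDEX = {t: i for i, t in enumerate(TRIAD_CLASSES)}


def concentration(i: int) -> float:
    """C_i: fraction of the 5376-dimensional space occupied by type-i
    (k+3)-mers (type 1/2/3 = 4-mers/5-mers/6-mers)."""
    if i not in (1, 2, 3):
        raise ValidationError(f"type index must be 1, 2 or 3, got {i}")
    return N_UNIQUE[i] / TOTAL_FEATURES


def kna_index(kna: str) -> int:
    idx = 0
    for ch in kna:
        idx = idx * 4 + RNA_ALPHABET.index(ch)
    return idx


def feature_index(k: int, kna: str, triad_class: tuple[int, int, int]) -> int:
    """Flat index of the dimension pairing ``kna`` (length k) with a triad
    class; within a block, ordering is lexicographic by (k-NA, class)."""
    if len(kna) != k:
        raise ValidationError(f"k-NA {kna!r} does not have length {k}")
    return BLOCK_OFFSET[k] + kna_index(kna) * N_TRIAD_CLASSES + _TRIAD_INDEX[triad_class]


def feature_names() -> list[str]:
    """The 5376 dimension names, e.g. ``CCU-444``, in vector order."""
    names = []
    for k in BLOCK_ORDER:
        for kna in itertools.product(RNA_ALPHABET, repeat=k):
            for triad in TRIAD_CLASSES:
                names.append("".join(kna) + "-" + "".join(map(str, triad)))
    return names


def encode_residue_classes(seq: str) -> list[int | None]:
    """Map each residue to its class index 1-4; non-standard letters map to
    ``None`` and triads overlapping them are skipped."""
    return [RESIDUE_CLASS.get(aa) for aa in seq.upper()]


def triad_counts(seq: str) -> np.ndarray:
    """Counts of the 64 conjoint-triad classes over width-3 windows."""
    classes = encode_residue_classes(seq)
    counts = np.zeros(N_TRIAD_CLASSES, dtype=float)
    for i in range(len(classes) - 2):
        window = classes[i : i + 3]
        if None in window:
            continue
        counts[_TRIAD_INDEX[tuple(window)]] += 1
    return counts


def kna_counts(seq: str, k: int) -> np.ndarray:
    """Counts of the 4^k k-NAs over width-k windows of an RNA sequence."""
    if k not in (1, 2, 3):
        raise ValidationError(f"k must be 1, 2 or 3, got {k}")
    counts = np.zeros(4**k, dtype=float)
    for i in range(len(seq) - k + 1):
        counts[kna_index(seq[i : i + k])] += 1
    return counts


def min_max_normalize(v: np.ndarray) -> np.ndarray:
    """Min-max rescaling to [0, 1]; a constant vector maps to all zeros
    (it carries no information and 0/0 must be avoided)."""
    v = np.asarray(v, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def featurize_pair(
    protein_seq: str, rna_seq: str, normalize: bool = True
) -> np.ndarray:
    """Encode one protein-RNA pair as the 5376-dimensional vector.

    Raw value of dimension (triad class c, k-NA w):
    ``triad_counts[c] * kna_counts_k[w] * C_k``; the vector is then min-max
    normalized across all 5376 entries unless ``normalize=False``.
    """
    tri = triad_counts(protein_seq)
    blocks = []
    for k in BLOCK_ORDER:
        knas = kna_counts(rna_seq, k)
        blocks.append(np.outer(knas, tri).ravel() * concentration(k))
    raw = np.concatenate(blocks)
    return min_max_normalize(raw) if normalize else raw


class PairFeaturizer:
    """Featurize many pairs against fixed sequence collections, caching the
    per-sequence window counts."""

    def __init__(
        self, protein_seqs: Mapping[str, str], rna_seqs: Mapping[str, str]
    ) -> None:
        self._proteins = dict(protein_seqs)
        self._rnas = dict(rna_seqs)
        self._tri_cache: dict[str, np.ndarray] = {}
        self._kna_cache: dict[tuple[str, int], np.ndarray] = {}

    def _tri(self, pid: str) -> np.ndarray:
        if pid not in self._tri_cache:
            self._tri_cache[pid] = triad_counts(self._proteins[pid])
        return self._tri_cache[pid]

    def _kna(self, rid: str, k: int) -> np.ndarray:
        key = (rid, k)
        if key not in self._kna_cache:
            self._kna_cache[key] = kna_counts(self._rnas[rid], k)
        return self._kna_cache[key]

    def vector(self, protein_id: str, rna_id: str, normalize: bool = True) -> np.ndarray:
        tri = self._tri(protein_id)
        blocks = [
            np.outer(self._kna(rna_id, k), tri).ravel() * concentration(k)
            for k in BLOCK_ORDER
        ]
        raw = np.concatenate(blocks)
        return min_max_normalize(raw) if normalize else raw

    def matrix(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        X = np.empty((len(pairs), TOTAL_FEATURES), dtype=float)
        for row, (pid, rid) in enumerate(pairs):
            X[row] = self.vector(pid, rid)
        return X


# ---------------------------------------------------------------------------
# Worked-example enumeration: literal units before class collapsing


@dataclass
class PairUnits:
    """Inventory of the distinct literal units of one protein-RNA pair.

    ``triads_by_class`` groups the distinct literal triads by triad class;
    ``knas[k]`` lists the distinct k-NAs; ``literal_mers[k]`` pairs every
    distinct k-NA with every distinct literal triad, named ``<kNA>-<triad>``.
    """

    triads_by_class: dict[tuple[int, int, int], list[str]]
    knas: dict[int, list[str]]
    literal_mers: dict[int, list[str]]

    @property
    def n_triad_classes(self) -> int:
        return len(self.triads_by_class)


def enumerate_units(protein_seq: str, rna_seq: str) -> PairUnits:
    """Enumerate the distinct literal triads, k-NAs and their pairings for
    one pair (the pre-collapse inventory; the feature vector itself
    identifies triads up to class)."""
    classes = encode_residue_classes(protein_seq)
    triads_by_class: dict[tuple[int, int, int], list[str]] = {}
    seen: set[str] = set()
    for i in range(len(protein_seq) - 2):
        window = classes[i : i + 3]
        if None in window:
            continue
        literal = protein_seq[i : i + 3].upper()
        if literal in seen:
            continue
        seen.add(literal)
        triads_by_class.setdefault(tuple(window), []).append(literal)
    knas: dict[int, list[str]] = {}
    for k in (1, 2, 3):
        distinct: list[str] = []
        for i in range(len(rna_seq) - k + 1):
            unit = rna_seq[i : i + k]
            if unit not in distinct:
                distinct.append(unit)
        knas[k] = distinct
    all_triads = [t for group in triads_by_class.values() for t in group]
    literal_mers = {
        k: [f"{kna}-{t}" for kna in knas[k] for t in all_triads] for k in (1, 2, 3)
    }
    return PairUnits(triads_by_class, knas, literal_mers)


# ---------------------------------------------------------------------------
# FScore filter

#: floor applied to both normalized class profiles so never-seen features
#: get a finite, neutral score
FSCORE_EPS = 1.0 / (2 * TOTAL_FEATURES)


@dataclass
class FScoreTable:
    """Per-feature class-enrichment scores.

    ``ff_pos``/``ff_neg`` are the min-max-normalized (then floored) summed
    frequency profiles of the positive and negative class; ``scores`` is
    their element-wise ratio.  Scores > 1 mark positive-enriched features,
    < 1 negative-enriched ones.
    """

    scores: np.ndarray
    ff_pos: np.ndarray
    ff_neg: np.ndarray


def fscore_table(X: np.ndarray, y: np.ndarray) -> FScoreTable:
    """Compute FScores from a labelled feature matrix (rows = pairs,
    labels 1 = positive, 0 = negative)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("fscore_table needs at least one sample of each class")
    ff_pos = np.maximum(min_max_normalize(pos.sum(axis=0)), FSCORE_EPS)
    ff_neg = np.maximum(min_max_normalize(neg.sum(axis=0)), FSCORE_EPS)
    return FScoreTable(ff_pos / ff_neg, ff_pos, ff_neg)


def select_features(table: FScoreTable | np.ndarray, k: int = 1000) -> np.ndarray:
    """Indices of the k/2 largest- and k/2 smallest-FScore features.

    Ties are broken by ascending feature index; the returned indices are
    sorted ascending.  ``k`` must be even; if score ties make the two
    halves overlap the selection is ambiguous and an error is raised.
    """
    scores = table.scores if isinstance(table, FScoreTable) else np.asarray(table)
    n = len(scores)
    if k % 2 != 0:
        raise ValidationError(f"k must be even, got {k}")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of features {n}")
    half = k // 2
    by_score = sorted(range(n), key=lambda i: (scores[i], i))
    bottom = set(by_score[:half])
    top = set(sorted(range(n), key=lambda i: (-scores[i], i))[:half])
    selected = bottom | top
    if len(selected) < k:
        raise ValidationError(
            "top and bottom halves overlap (too few distinct FScore values "
            f"for k={k})"
        )
    return np.array(sorted(selected), dtype=int)
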