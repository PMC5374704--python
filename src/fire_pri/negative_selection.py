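"""Negative-sample construction for protein-RNA interaction datasets.

The candidate universe is the cross product of the proteins and RNAs that
appear in the positive set, minus the positive pairs themselves.  Three
selection strategies are provided:

* **random** — uniform sampling without replacement (the traditional
  approach: an unvalidated pair is presumed negative);
* **similarity-ranked (FIRE)** — each candidate (p_i, r_j) receives the
  confidence score ``SPR_ij = sum_k SP_ik`` over all proteins p_k (k != i)
  known to bind r_j, where SP is the aggregated protein-protein similarity;
  candidates are sorted by ascending score and the lowest m are taken as
  reliable negatives (a protein dissimilar to every known partner of an RNA
  is unlikely to bind it);
* **threshold** — the m candidates whose scores are closest to a target
  value st, used to probe how negative-set quality degrades as scores rise.

High-scoring candidates are conversely plausible *positive* predictions;
``rank_candidate_positives`` reports, per RNA, the top-scoring candidate
proteins above a score floor.

All orderings break score ties lexicographically by (protein id, RNA id)
so results are reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CapacityError, ValidationError
from .io_formats import InteractionSet
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class ScoredPair:
    """A candidate (protein, RNA) pair with its SPR confidence score."""

    protein_id: str
    rna_id: str
    spr: float

    def __post_init__(self) -> None:
        if self.spr < 0:
            raise ValidationError(f"spr must be non-negative, got {self.spr}")


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of one negative-selection run."""

    method: str = "fire"  # random | fire | threshold
    m: int = 1
    st: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("random", "fire", "threshold"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if self.st < 0:
            raise ValidationError("st must be >= 0")


def _ids(items) -> list[str]:
    return [x.id if hasattr(x, "id") else x for x in items]


def candidate_pairs(proteins, rnas, positives: InteractionSet) -> set[tuple[str, str]]:
    """Cross product of proteins x RNAs minus the positive pairs."""
    pids, rids = _ids(proteins), _ids(rnas)
    missing = (positives.proteins - set(pids)) | (positives.rnas - set(rids))
    if missing:
        raise ValidationError(f"positive pairs reference unknown ids: {sorted(missing)[:5]}")
    return {
        (p, r) for p in pids for r in rids if (p, r) not in positives.pairs
    }


def _check_capacity(m: int, n_candidates: int) -> None:
    if m > n_candidates:
        raise CapacityError(
            f"requested m={m} negatives but only {n_candidates} candidate "
            f"pairs exist"
        )


def random_negatives(
    proteins, rnas, positives: InteractionSet, m: int, seed: int
) -> InteractionSet:
    """m candidates sampled uniformly without replacement; reproducible for
    a fixed seed."""
    cands = sorted(candidate_pairs(proteins, rnas, positives))
    _check_capacity(m, len(cands))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cands), size=m, replace=False)
    return InteractionSet(frozenset(cands[i] for i in idx), "negative")


def spr_score(
    protein_id: str,
    rna_id: str,
    positives: InteractionSet,
    sp_matrix: SimilarityMatrix,
) -> float:
    """SPR_ij: summed similarity between p_i and every other protein with a
    known interaction with r_j; 0 when r_j has no other partners."""
    if (protein_id, rna_id) in positives:
        raise ValidationError(
            f"({protein_id}, {rna_id}) is a positive pair; SPR is defined "
            "for candidates only"
        )
    sp_matrix.index_of(protein_id)  # raises on unknown id
    total = 0.0
    for pk, rj in positives.pairs:
        if rj == rna_id and pk != protein_id:
            total += sp_matrix.get(protein_id, pk)
    return total


def score_candidates(
    proteins, rnas, positives: InteractionSet, sp_matrix: SimilarityMatrix
) -> list[ScoredPair]:
    """Score every candidate pair (vectorized over the similarity matrix)."""
    pids, rids = _ids(proteins), _ids(rnas)
    cands = candidate_pairs(proteins, rnas, positives)
    p_index = {pid: sp_matrix.index_of(pid) for pid in pids}
    r_index = {rid: i for i, rid in enumerate(rids)}
    # indicator: partner[k, j] = 1 iff (p_k, r_j) is a known interaction
    partner = np.zeros((len(sp_matrix.ids), len(rids)))
    for pk, rj in positives.pairs:
        partner[sp_matrix.index_of(pk), r_index[rj]] = 1.0
    # SPR_ij = sum_k partner[k, j] * SP_ik; the k = i term vanishes for
    # candidates because (p_i, r_j) is not a positive pair
    spr = sp_matrix.values @ partner
    return [
        ScoredPair(p, r, float(spr[p_index[p], r_index[r]])) for p, r in sorted(cands)
    ]


def _to_interaction_set(selected: list[ScoredPair]) -> InteractionSet:
    return InteractionSet(
        frozenset((s.protein_id, s.rna_id) for s in selected),
        "negative",
        scores={(s.protein_id, s.rna_id): s.spr for s in selected},
    )


def fire_negatives(
    proteins, rnas, positives: InteractionSet, sp_matrix: SimilarityMatrix, m: int
) -> InteractionSet:
    """The m candidates with the lowest SPR scores (ascending sort, ties by
    (protein id, RNA id))."""
    scored = score_candidates(proteins, rnas, positives, sp_matrix)
    _check_capacity(m, len(scored))
    scored.sort(key=lambda s: (s.spr, s.protein_id, s.rna_id))
    return _to_interaction_set(scored[:m])


def threshold_negatives(
    proteins,
    rnas,
    positives: InteractionSet,
    sp_matrix: SimilarityMatrix,
    m: int,
    st: float,
) -> InteractionSet:
    """The m candidates whose SPR scores are closest to the target st."""
    scored = score_candidates(proteins, rnas, positives, sp_matrix)
    _check_capacity(m, len(scored))
    scored.sort(key=lambda s: (abs(s.spr - st), s.protein_id, s.rna_id))
    return _to_interaction_set(scored[:m])


def rank_candidate_positives(
    proteins,
    rnas,
    positives: InteractionSet,
    sp_matrix: SimilarityMatrix,
    top_per_rna: int = 4,
    min_score: float = 0.0,
) -> dict[str, list[ScoredPair]]:
    """Per RNA, the top-scoring candidate proteins with spr > min_score,
    descending — candidate *positive* predictions."""
    if top_per_rna < 1:
        raise ValidationError("top_per_rna must be >= 1")
    scored = score_candidates(proteins, rnas, positives, sp_matrix)
    by_rna: dict[str, list[ScoredPair]] = {}
    for s in scored:
        if s.spr > min_score:
            by_rna.setdefault(s.rna_id, []).append(s)
    report: dict[str, list[ScoredPair]] = {}
    for rid in sorted(by_rna):
        ranked = sorted(by_rna[rid], key=lambda s: (-s.spr, s.protein_id, s.rna_id))
        report[rid] = ranked[:top_per_rna]
    return report
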