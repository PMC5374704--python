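import numpy as np
import pytest
from scipy import stats

from fire_pri.exceptions import CapacityError, ValidationError
from fire_pri.io_formats import InteractionSet
from fire_pri.negative_selection import (
    candidate_pairs,
    fire_negatives,
    random_negatives,
    rank_candidate_positives,
    spr_score,
    threshold_negatives,
)
from fire_pri.similarity import SimilarityMatrix

from .oracles import fire_select_brute


def _positives(*pairs):
    return InteractionSet(frozenset(pairs), "positive")


def _sp(ids, values):
    return SimilarityMatrix(ids, np.array(values, dtype=float))


@pytest.fixture()
def toy_system():
    """4 proteins x 3 RNAs with a hand-built similarity matrix and 4
    positives."""
    ids = ["p1", "p2", "p3", "p4"]
    values = [
        [1.0, 0.8, 0.2, 0.1],
        [0.8, 1.0, 0.3, 0.2],
        [0.2, 0.3, 1.0, 0.6],
        [0.1, 0.2, 0.6, 1.0],
    ]
    positives = _positives(("p1", "r1"), ("p2", "r1"), ("p3", "r2"), ("p4", "r3"))
    return ids, ["r1", "r2", "r3"], _sp(ids, values), positives


class TestCandidatePairs:
    def test_cross_product_minus_positives(self):
        cands = candidate_pairs(["p1", "p2"], ["r1", "r2"], _positives(("p1", "r1")))
        assert len(cands) == 3 and ("p1", "r1") not in cands

    def test_full_positive_set_leaves_nothing(self):
        pos = _positives(("p1", "r1"), ("p1", "r2"))
        assert candidate_pairs(["p1"], ["r1", "r2"], pos) == set()

    def test_no_positives(self):
        assert candidate_pairs(["p1"], ["r1"], _positives()) == {("p1", "r1")}

    def test_unresolved_ids_rejected(self):
        with pytest.raises(ValidationError):
            candidate_pairs(["p1"], ["r1"], _positives(("pX", "r1")))


class TestRandomNegatives:
    def test_m_equals_universe(self):
        pos = _positives(("p1", "r1"))
        neg = random_negatives(["p1", "p2"], ["r1", "r2"], pos, 3, seed=0)
        assert neg.pairs == candidate_pairs(["p1", "p2"], ["r1", "r2"], pos)

    def test_seed_determinism(self):
        pos = _positives(("p1", "r1"))
        args = (["p1", "p2", "p3"], ["r1", "r2", "r3"], pos, 4)
        assert random_negatives(*args, seed=11).pairs == random_negatives(*args, seed=11).pairs

    def test_capacity_error_states_maximum(self):
        with pytest.raises(CapacityError, match="3"):
            random_negatives(["p1", "p2"], ["r1", "r2"], _positives(("p1", "r1")), 4, 0)

    def test_uniformity_over_repetitions(self):
        """On a 3x3 grid with one positive, each of the 8 candidates is
        sampled with equal frequency (chi-square)."""
        prot, rna = ["p1", "p2", "p3"], ["r1", "r2", "r3"]
        pos = _positives(("p1", "r1"))
        counts: dict = {}
        for rep in range(1000):
            for pair in random_negatives(prot, rna, pos, 2, seed=rep).pairs:
                counts[pair] = counts.get(pair, 0) + 1
        assert len(counts) == 8
        result = stats.chisquare(list(counts.values()))
        assert result.pvalue > 1e-3

    def test_disjoint_from_positives(self):
        pos = _positives(("p1", "r1"), ("p2", "r2"))
        neg = random_negatives(["p1", "p2"], ["r1", "r2"], pos, 2, seed=5)
        assert not neg.pairs & pos.pairs


class TestSprScore:
    def test_rna_without_partners_scores_zero(self, toy_system):
        prot, rna, sp, _ = toy_system
        assert spr_score("p1", "rX", _positives(("p2", "r1")), sp) == 0.0

    def test_single_partner(self):
        sp = _sp(["p1", "p2"], [[1.0, 0.7], [0.7, 1.0]])
        assert spr_score("p1", "r1", _positives(("p2", "r1")), sp) == pytest.approx(0.7)

    def test_two_partners_sum(self):
        sp = _sp(
            ["p1", "p2", "p3"],
            [[1.0, 0.2, 0.7], [0.2, 1.0, 0.0], [0.7, 0.0, 1.0]],
        )
        pos = _positives(("p2", "r1"), ("p3", "r1"))
        assert spr_score("p1", "r1", pos, sp) == pytest.approx(0.9)

    def test_positive_pair_rejected(self):
        sp = _sp(["p1"], [[1.0]])
        with pytest.raises(ValidationError):
            spr_score("p1", "r1", _positives(("p1", "r1")), sp)

    def test_unknown_id_rejected(self):
        sp = _sp(["p1"], [[1.0]])
        with pytest.raises(ValidationError):
            spr_score("pX", "r1", _positives(), sp)

    def test_adding_partner_adds_exactly_its_similarity(self, toy_system):
        prot, rna, sp, pos = toy_system
        before = spr_score("p1", "r2", pos, sp)
        richer = InteractionSet(pos.pairs | {("p4", "r2")}, "positive")
        after = spr_score("p1", "r2", richer, sp)
        assert after - before == pytest.approx(sp.get("p1", "p4"))


class TestFireNegatives:
    def test_ordering_prefers_low_scores(self):
        sp = _sp(["p1", "p2", "p3"], [[1, 0.1, 0.9], [0.1, 1, 0.0], [0.9, 0.0, 1]])
        pos = _positives(("p3", "r1"), ("p1", "r2"), ("p2", "r2"), ("p3", "r2"))
        neg = fire_negatives(["p1", "p2", "p3"], ["r1", "r2"], pos, sp, 1)
        # candidates: SPR(p1, r1) = SP(p1, p3) = 0.9, SPR(p2, r1) = 0.0
        assert neg.pairs == {("p2", "r1")}
        assert neg.scores[("p2", "r1")] == pytest.approx(0.0)

    def test_all_tie_case_uses_lexicographic_break(self):
        sp = _sp(["p1", "p2"], [[1.0, 0.5], [0.5, 1.0]])
        pos = _positives(("p1", "r9"), ("p2", "r9"))  # r1, r2 isolated
        neg = fire_negatives(["p1", "p2"], ["r1", "r2", "r9"], pos, sp, 2)
        assert neg.pairs == {("p1", "r1"), ("p1", "r2")}

    def test_toy_system_matches_exhaustive_oracle(self, toy_system):
        prot, rna, sp, pos = toy_system
        lookup = {
            (a, b): sp.get(a, b) for a in prot for b in prot
        }
        for m in (1, 3, 5, 8):
            got = fire_negatives(prot, rna, pos, sp, m).pairs
            assert got == fire_select_brute(prot, rna, pos.pairs, lookup, m)

    def test_disjoint_and_scored(self, toy_system):
        prot, rna, sp, pos = toy_system
        neg = fire_negatives(prot, rna, pos, sp, 4)
        assert not neg.pairs & pos.pairs
        assert set(neg.scores) == neg.pairs
        assert all(s >= 0 for s in neg.scores.values())


class TestThresholdNegatives:
    def test_zero_threshold_equals_ascending_selection(self, toy_system):
        prot, rna, sp, pos = toy_system
        assert (
            threshold_negatives(prot, rna, pos, sp, 4, st=0.0).pairs
            == fire_negatives(prot, rna, pos, sp, 4).pairs
        )

    def test_huge_threshold_takes_highest_scores(self, toy_system):
        prot, rna, sp, pos = toy_system
        from fire_pri.negative_selection import score_candidates

        scored = score_candidates(prot, rna, pos, sp)
        top = sorted(scored, key=lambda s: (-s.spr, s.protein_id, s.rna_id))[:2]
        neg = threshold_negatives(prot, rna, pos, sp, 2, st=1e9)
        assert neg.pairs == {(s.protein_id, s.rna_id) for s in top}

    def test_closest_to_target(self):
        sp = _sp(
            ["p1", "p2", "p3", "p4"],
            [
                [1.0, 0.1, 0.3, 0.8],
                [0.1, 1.0, 0.0, 0.0],
                [0.3, 0.0, 1.0, 0.0],
                [0.8, 0.0, 0.0, 1.0],
            ],
        )
        pos = _positives(("p2", "r1"), ("p3", "r2"), ("p4", "r3"))
        # p1's candidates score 0.1 (r1), 0.3 (r2), 0.8 (r3); all other
        # candidates score 0, which is 0.35 away from the target
        prot, rna = ["p1", "p2", "p3", "p4"], ["r1", "r2", "r3"]
        neg = threshold_negatives(prot, rna, pos, sp, 1, st=0.35)
        assert neg.pairs == {("p1", "r2")}


class TestRankCandidatePositives:
    def test_score_floor_silences_rna(self, toy_system):
        prot, rna, sp, pos = toy_system
        report = rank_candidate_positives(prot, rna, pos, sp, top_per_rna=4, min_score=1e9)
        assert report == {}

    def test_top1_matches_argmax(self, toy_system):
        prot, rna, sp, pos = toy_system
        from fire_pri.negative_selection import score_candidates

        scored = score_candidates(prot, rna, pos, sp)
        report = rank_candidate_positives(prot, rna, pos, sp, top_per_rna=1)
        for rid, ranked in report.items():
            pool = [s for s in scored if s.rna_id == rid and s.spr > 0]
            best = max(pool, key=lambda s: s.spr)
            assert ranked[0].spr == pytest.approx(best.spr)

    def test_no_limit_returns_all_descending(self, toy_system):
        prot, rna, sp, pos = toy_system
        report = rank_candidate_positives(
            prot, rna, pos, sp, top_per_rna=10**9, min_score=-1.0
        )
        n_listed = sum(len(v) for v in report.values())
        assert n_listed == len(candidate_pairs(prot, rna, pos))
        for ranked in report.values():
            sprs = [s.spr for s in ranked]
            assert sprs == sorted(sprs, reverse=True)


def test_fire_less_contaminated_than_random(core_claim_trials):
    """On synthetic interactomes, similarity-ranked negatives contain fewer
    hidden true interactions than random negatives (one-sided sign test)."""
    wins = sum(
        t.contamination_fire < t.contamination_random for t in core_claim_trials
    )
    ties = sum(
        t.contamination_fire == t.contamination_random for t in core_claim_trials
    )
    n = len(core_claim_trials) - ties
    assert stats.binomtest(wins, n, 0.5, alternative="greater").pvalue < 0.05
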