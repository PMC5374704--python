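"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity by the most direct method available —
explicit dynamic programming, exhaustive enumeration, or plain arithmetic —
without calling the implementation path it checks.
"""

from __future__ import annotations

import numpy as np


def sw_local_brute(a: str, b: str, sub, gap_open: float = 10.0, gap_ext: float = 0.5):
    """Gotoh local-alignment score by explicit O(nm) dynamic programming.

    A gap of length L costs ``gap_open + (L - 1) * gap_ext``.
    """
    n, m = len(a), len(b)
    neg = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), neg)  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_ext)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + sub[a[i - 1], b[j - 1]], E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


def nsw_brute(a: str, b: str, sub, gap_open: float = 10.0, gap_ext: float = 0.5):
    saa = sw_local_brute(a, a, sub, gap_open, gap_ext)
    sbb = sw_local_brute(b, b, sub, gap_open, gap_ext)
    return sw_local_brute(a, b, sub, gap_open, gap_ext) / (
        np.sqrt(saa) * np.sqrt(sbb)
    )


RESIDUE_CLASS_ORACLE = {}
for cls, group in enumerate(("DE", "HRK", "CGNQSTY", "AFILMPVW"), start=1):
    for aa in group:
        RESIDUE_CLASS_ORACLE[aa] = cls

RNA_ORDER = "ACGU"


def featurize_raw_brute(protein: str, rna: str) -> np.ndarray:
    """Materialize every (triad window, k-NA window) co-occurrence pair
    explicitly, one increment per pair, then apply concentration weights."""
    vec = np.zeros(5376)
    n_unique = {1: 256, 2: 1024, 3: 4096}
    offset = {3: 0, 2: 4096, 1: 5120}
    for i in range(len(protein) - 2):
        triad = protein[i : i + 3].upper()
        if any(aa not in RESIDUE_CLASS_ORACLE for aa in triad):
            continue
        c = [RESIDUE_CLASS_ORACLE[aa] - 1 for aa in triad]
        t_idx = c[0] * 16 + c[1] * 4 + c[2]
        for k in (1, 2, 3):
            for j in range(len(rna) - k + 1):
                w = rna[j : j + k]
                w_idx = 0
                for ch in w:
                    w_idx = w_idx * 4 + RNA_ORDER.index(ch)
                vec[offset[k] + w_idx * 64 + t_idx] += 1
    for k in (1, 2, 3):
        vec[offset[k] : offset[k] + n_unique[k]] *= n_unique[k] / 5376
    return vec


def minmax_brute(v: np.ndarray) -> np.ndarray:
    lo, hi = min(v), max(v)
    if hi == lo:
        return np.zeros_like(v)
    return (np.asarray(v) - lo) / (hi - lo)


def fire_select_brute(protein_ids, rna_ids, positives, sp_lookup, m):
    """Enumerate and score every candidate pair directly, then take the m
    lowest-scoring with the lexicographic tie-break.

    ``sp_lookup`` maps (protein id, protein id) -> similarity.
    """
    scored = []
    for p in protein_ids:
        for r in rna_ids:
            if (p, r) in positives:
                continue
            s = sum(
                sp_lookup[(p, pk)]
                for (pk, rj) in positives
                if rj == r and pk != p
            )
            scored.append((s, p, r))
    scored.sort()
    return {(p, r) for _, p, r in scored[:m]}


def fscore_brute(pos_vectors, neg_vectors, eps=1.0 / (2 * 5376)):
    """Spreadsheet-style FScore: per-feature class sums, min-max of each
    profile, floor, ratio — in plain Python arithmetic."""
    n = len(pos_vectors[0])
    fp = [sum(v[i] for v in pos_vectors) for i in range(n)]
    fn = [sum(v[i] for v in neg_vectors) for i in range(n)]

    def norm(vals):
        lo, hi = min(vals), max(vals)
        if hi == lo:
            return [0.0] * len(vals)
        return [(x - lo) / (hi - lo) for x in vals]

    ffp = [max(x, eps) for x in norm(fp)]
    ffn = [max(x, eps) for x in norm(fn)]
    return [p / q for p, q in zip(ffp, ffn)]
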