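"""Independent reference computations used only by the tests.

These deliberately avoid the library's code paths: the alignment oracle is
a plain-Python Gotoh DP, the rating oracle walks a literal feature table,
and the clustering/counting oracles are direct transliterations of the
stated rules.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith-Waterman optimal local score, affine gaps (Gotoh), BLOSUM62.

    A gap of length k costs gap_open + k*gap_extend (BLAST convention).
    """
    first = gap_open + gap_extend
    m, n = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (move along b)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (move along a)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def table_rating(q2h: str, h2q: str, accepted_cutoffs, identity: float, is_ref: bool) -> float:
    """Sum the rating feature table row by row.

    Each row is (applies?, points); the table is written out literally so a
    bookkeeping error in the library cannot hide here.
    """
    direction_points = {"true": 1.0, "false": 0.0, "na": 0.25}
    rows = [
        direction_points[q2h],
        direction_points[h2q],
        0.5 if 60 in accepted_cutoffs else 0.0,
        0.5 if 50 in accepted_cutoffs else 0.0,
        0.5 if 40 in accepted_cutoffs else 0.0,
        0.5 if identity > 60 else 0.0,
        0.5 if identity > 50 else 0.0,
        0.5 if identity > 40 else 0.0,
        1.0 if is_ref else 0.0,
    ]
    return sum(rows)


def greedy_clusters(
    seqs, pair_stats, identity_cutoff: float = 97.0, coverage_cutoff: float = 90.0
):
    """Direct transliteration of the greedy clustering rule.

    ``pair_stats(a, b) -> (identity, coverage_of_shorter)`` is supplied by
    the caller. Returns protein_id -> representative_id.
    """
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i].residues), i))
    reps = []
    mapping = {}
    for idx in order:
        seq = seqs[idx]
        assigned = False
        for rep in reps:
            identity, coverage = pair_stats(seq, rep)
            if identity >= identity_cutoff and coverage >= coverage_cutoff:
                mapping[seq.protein_id] = rep.protein_id
                assigned = True
                break
        if not assigned:
            reps.append(seq)
            mapping[seq.protein_id] = seq.protein_id
    return mapping


def counting_ratio(stats, identity_cutoff: float, min_coverage: float = 50.0) -> float:
    """Filtered hit ratio by direct counting over (identity, coverage) pairs."""
    if not stats:
        return 0.0
    hit = [1 for ident, cov in stats if ident >= identity_cutoff and cov >= min_coverage]
    return len(hit) / len(stats)
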