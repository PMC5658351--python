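"""Independent brute-force oracles used to check the package's algorithms.

These are deliberately naive re-implementations (exhaustive dynamic
programming, full overlap enumeration) kept separate from the package so the
two routes cannot share a bug.
"""

from __future__ import annotations

MATCH = 1.0
MISMATCH = -2.0
GAP_OPEN = -2.5   # charged once per gap
GAP_EXT = -0.5    # charged per gap column (a k-gap costs 2.5 + 0.5k)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _sub(a: str, b: str) -> float:
    return MATCH if (a == b and a != "N") else MISMATCH


def local_affine_score(query: str, subject: str) -> float:
    """Optimal affine-gap local alignment score (Gotoh, plus strand only)."""
    n, m = len(query), len(subject)
    neg = float("-inf")
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in query (horizontal)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in subject (vertical)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + GAP_OPEN + GAP_EXT, E[i][j - 1] + GAP_EXT)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN + GAP_EXT, F[i - 1][j] + GAP_EXT)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + _sub(query[i - 1], subject[j - 1]),
                E[i][j],
                F[i][j],
            )
            if H[i][j] > best:
                best = H[i][j]
    return best


def best_local_score(query: str, subject: str) -> float:
    """Optimal local score over both query strands."""
    return max(local_affine_score(query, subject),
               local_affine_score(revcomp(query), subject))


def best_suffix_prefix_overlap(
    a: str, b: str, min_overlap: int, max_mismatches: int
) -> int | None:
    """Longest suffix(a)/prefix(b) overlap with at most ``max_mismatches``
    substitutions, found by trying every overlap length."""
    for overlap in range(min(len(a), len(b)), min_overlap - 1, -1):
        mism = sum(1 for x, y in zip(a[-overlap:], b[:overlap]) if x != y)
        if mism <= max_mismatches:
            return overlap
    return None


def global_identity_naive(a: str, b: str) -> float:
    """Matches over alignment columns of an optimal global alignment,
    maximising matches among minimum-edit-distance alignments is not needed:
    identity from a unit-cost Needleman-Wunsch path is enough for the
    clustered sequences checked here (substitution-only differences)."""
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][0] = i
    for j in range(m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = min(
                D[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
                D[i - 1][j] + 1,
                D[i][j - 1] + 1,
            )
    dist = D[n][m]
    columns = max(n, m)  # substitution-dominated comparisons
    return (columns - dist) / columns
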