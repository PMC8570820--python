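"""Independent brute-force oracles used only by the test suite.

Deliberately written without reference to the package's alignment kernels:
plain-Python dynamic programming over explicit three-state matrices, with the
affine gap cost ``gap_open + (L - 1) * gap_extend`` for a gap of length L.
"""

from __future__ import annotations

NEG = float("-inf")


def brute_force_local_score(q: str, s: str, score, gap_open: int, gap_extend: int) -> int:
    """Optimal local alignment score by explicit three-matrix recursion."""
    m, n = len(q), len(s)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + score(q[i - 1], s[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return int(best)


def brute_force_kword_matches(q: str, s: str, k: int) -> set[tuple[int, int]]:
    """All (q_pos, s_pos) pairs sharing an exact k-word, by double loop."""
    out = set()
    for i in range(len(q) - k + 1):
        for j in range(len(s) - k + 1):
            if q[i : i + k] == s[j : j + k]:
                out.add((i, j))
    return out
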