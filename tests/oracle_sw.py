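"""Brute-force Gotoh local-alignment oracle, independent of the package.

Plain-Python affine-gap Smith-Waterman used only as a cross-check of the
production aligner.  Gap of length k scores gap_open + (k-1) * gap_extend,
matching the package's scoring convention.
"""

from __future__ import annotations

NEG = float("-inf")


def local_alignment_score(
    target: str,
    query: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal local alignment score by full dynamic programming."""
    n, m = len(target), len(query)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (query consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (target consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if target[i - 1] == query[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best
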