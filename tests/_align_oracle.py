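"""Independent exhaustive dynamic-programming oracle for local alignment.

Textbook Smith-Waterman with affine gaps (Gotoh three-matrix recurrence),
written in plain Python and kept deliberately separate from the package's
aligner so the two can be compared as independent routes. A gap of length L
costs ``gap_open + L * gap_extend`` (BLAST convention).
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

NEG = float("-inf")


def sw_affine_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal local alignment score; 0 when no positive-scoring alignment."""
    sub = substitution_matrices.load(matrix_name)

    def s(x: str, y: str) -> float:
        if x in sub.alphabet and y in sub.alphabet:
            return float(sub[x, y])
        return -1.0

    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of opening a length-1 gap
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + s(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            if H[i][j] > best:
                best = H[i][j]
    return best
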