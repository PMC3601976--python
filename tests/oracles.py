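"""Independent oracles used by the test suite.

These deliberately avoid the package's own implementations: the alignment
oracle is a plain-Python Gotoh dynamic program, and the codon-site oracle is
a brute-force enumeration of all single-nucleotide mutations.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

from xenoscan._codons import NUCS, STOP_CODONS, translate_codon

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_oracle(a: str, b: str, open_cost: float = 11.0, extend_cost: float = 1.0) -> float:
    """Affine-gap local alignment score (gap of length k costs
    open_cost + (k - 1) * extend_cost), straight from the recurrences."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - extend_cost)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - extend_cost)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def site_counts_oracle(codon: str) -> tuple[float, float]:
    """Brute-force synonymous/nonsynonymous site counts of a sense codon."""
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        muts = [codon[:pos] + b + codon[pos + 1 :] for b in NUCS if b != codon[pos]]
        non_stop = [m for m in muts if m not in STOP_CODONS]
        if non_stop:
            s += sum(translate_codon(m) == aa for m in non_stop) / len(non_stop)
    return s, 3.0 - s
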