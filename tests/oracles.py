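"""Independent brute-force oracles used by the test suite.

These deliberately re-derive alignment scores and translations from first
principles (plain-Python Gotoh dynamic programming, a literal codon table)
so they share no code path with the package implementations they check.

Gap convention everywhere: a gap of length L costs open + (L-1)*extend.
"""

NEG = float("-inf")


def sw_score(a: str, b: str, matrix, gap_open: int = 11,
             gap_extend: int = 1) -> int:
    """Smith-Waterman optimal local score, affine gaps (Gotoh)."""
    m, n = len(a), len(b)
    best = 0
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]],
                          E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def nw_score(a: str, b: str, matrix, gap_open: int = 11,
             gap_extend: int = 1) -> int:
    """Needleman-Wunsch optimal global score, affine gaps, end gaps scored."""
    m, n = len(a), len(b)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    for j in range(1, n + 1):
        E[0][j] = -(gap_open + (j - 1) * gap_extend)
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        F[i][0] = -(gap_open + (i - 1) * gap_extend)
        H[i][0] = F[i][0]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]],
                          E[i][j], F[i][j])
    return int(H[m][n])


# literal standard genetic code, bases in TCAG order
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    b1 + b2 + b3: _AAS[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def translate_frame(nt: str, frame: int) -> str:
    """Translate one of six frames by literal codon lookup; N -> X."""
    src = nt if frame > 0 else "".join(_COMP[c] for c in reversed(nt))
    off = abs(frame) - 1
    out = []
    for i in range(off, len(src) - 2, 3):
        codon = src[i:i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)
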