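"""Independent brute-force oracles used to validate the package's optimized
implementations.  Everything here is written from first principles (quadratic
DP, exhaustive enumeration) and stays independent of the code paths it
checks."""

from __future__ import annotations

NEG = float("-inf")

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Gotoh affine-gap DP (local and global)
# ---------------------------------------------------------------------------

def gotoh_local(a: str, b: str, sub, gap_open: float = 10, gap_extend: float = 1) -> float:
    """Smith-Waterman with affine gaps: a gap of length k costs
    gap_open + (k-1)*gap_extend.  ``sub(x, y)`` is the substitution score."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a_i aligned to -)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - gap_open)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - gap_open)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + sub(a[i - 1], b[j - 1]))
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


def gotoh_global(a: str, b: str, sub, gap_open: float = 10, gap_extend: float = 1) -> float:
    """Needleman-Wunsch with affine gaps, end gaps penalized."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Iy[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - gap_open)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - gap_open)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = diag + sub(a[i - 1], b[j - 1])
    return max(M[n][m], Ix[n][m], Iy[n][m])


# ---------------------------------------------------------------------------
# exhaustive IR / DR enumeration
# ---------------------------------------------------------------------------

def brute_force_irs(seq: str, min_len=8, max_len=20, end_window=6, min_loop=3):
    """All maximal (arm5_offset, arm3_offset_from_end, arm_len) IR triples by
    full enumeration."""
    n = len(seq)

    def valid(o5, o3, L):
        if L < 1 or o5 + L + min_loop + L + o3 > n:
            return False
        arm5 = seq[o5 : o5 + L]
        arm3 = seq[n - o3 - L : n - o3]
        return "N" not in arm5 and "N" not in arm3 and arm3 == rc(arm5)

    out = set()
    for o5 in range(end_window):
        for o3 in range(end_window):
            for L in range(min_len, max_len + 1):
                if valid(o5, o3, L) and (L == max_len or not valid(o5, o3, L + 1)):
                    out.add((o5, o3, L))
    return out


def brute_force_drs(exon5, intron, exon3, min_len=3, max_len=8, bw=8):
    """All reported (offset5, offset3, length, seq) DR tuples by full
    enumeration over both boundary windows."""
    w5 = exon5[-bw:].rjust(bw, "N") + intron[:bw].ljust(bw, "N")
    w3 = intron[-bw:].rjust(bw, "N") + exon3[:bw].ljust(bw, "N")

    def valid(p5, p3, L):
        if p5 < 0 or p3 < 0 or p5 + L > len(w5) or p3 + L > len(w3):
            return False
        s = w5[p5 : p5 + L]
        return "N" not in s and s == w3[p3 : p3 + L]

    out = set()
    for L in range(min_len, max_len + 1):
        for p5 in range(len(w5) - L + 1):
            for p3 in range(len(w3) - L + 1):
                if not valid(p5, p3, L):
                    continue
                if L == max_len or not (valid(p5, p3, L + 1) or valid(p5 - 1, p3 - 1, L + 1)):
                    out.add((p5 - bw, p3 - bw, L, w5[p5 : p5 + L]))
    return out


# ---------------------------------------------------------------------------
# brute-force co-oriented blocks
# ---------------------------------------------------------------------------

def brute_force_blocks(strands: str):
    """Greedy-leftmost maximal co-oriented blocks by exhaustive interval
    validity checks.  Returns (first, last, orientation, n_genes) tuples."""

    def valid(i, j):
        o = strands[i]
        if strands[j] != o:
            return False
        run = 0
        for s in strands[i : j + 1]:
            run = run + 1 if s != o else 0
            if run > 2:
                return False
        return sum(1 for s in strands[i : j + 1] if s == o) >= 5

    n = len(strands)
    blocks = []
    i = 0
    while i < n:
        found = None
        for j in range(n - 1, i - 1, -1):
            if valid(i, j):
                found = j
                break
        if found is None:
            i += 1
        else:
            o = strands[i]
            n_o = sum(1 for s in strands[i : found + 1] if s == o)
            blocks.append((i, found, o, n_o))
            i = found + 1
    return blocks
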