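"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python dynamic
programming without vectorization or shortcut pruning, direct
enumerations, and naive recomputations.  They exist so the package's
operations can be checked against something that cannot fail the same
way.
"""

from __future__ import annotations

import re

NEG = float("-inf")


def affine_local_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Smith-Waterman score, affine gaps, gap of length k costs
    gap_open + k * gap_extend.  Quadratic space, no optimizations."""
    go = gap_open + gap_extend
    ge = gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge)
            best = max(best, M[i][j])
    return int(round(best))


def affine_global_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Needleman-Wunsch score, affine gaps, end gaps penalized."""
    go = gap_open + gap_extend
    ge = gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Y[0][j] = -(go + (j - 1) * ge)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge)
    return int(round(max(M[n][m], X[n][m], Y[n][m])))


_CODON_TABLE = {}


def _codon_table():
    if not _CODON_TABLE:
        bases = "TCAG"
        aas = (
            "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        )
        i = 0
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    _CODON_TABLE[b1 + b2 + b3] = aas[i]
                    i += 1
    return _CODON_TABLE


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def six_frame_orfs(seq: str, min_aa: int) -> set[tuple[int, int, int, str]]:
    """Enumerate all maximal stop-free codon runs in all six frames.

    Returns (frame, fwd_start, fwd_end, peptide) tuples with coordinates
    on the forward strand, like the package's ORF finder, but derived by
    direct codon-walking with an inline codon table.
    """
    table = _codon_table()
    n = len(seq)
    rc = seq.translate(_COMPLEMENT)[::-1]
    out = set()
    for frame in (1, 2, 3, -1, -2, -3):
        s = seq if frame > 0 else rc
        off = abs(frame) - 1
        codons = [s[k : k + 3] for k in range(off, n - 2, 3)]
        aa = "".join(table.get(c, "X") for c in codons)
        for mo in re.finditer(r"[^*]+", aa):
            pep = mo.group()
            if len(pep) < min_aa:
                continue
            cs = off + 3 * mo.start()
            ce = off + 3 * mo.end()
            if frame > 0:
                out.add((frame, cs, ce, pep))
            else:
                out.add((frame, n - ce, n - cs, pep))
    return out


def g_runs_by_regex(seq: str) -> list[tuple[int, int, str]]:
    """Maximal G-runs of length >= 2 via regex: (start, length, follower)."""
    out = []
    for mo in re.finditer(r"G{2,}", seq):
        follower = seq[mo.end()] if mo.end() < len(seq) else "$"
        out.append((mo.start(), mo.end() - mo.start(), follower))
    return out


def windowed_mean(values: list[float], window: int) -> list[float]:
    half = window // 2
    out = []
    for i in range(len(values)):
        chunk = values[max(0, i - half) : i + half + 1]
        out.append(sum(chunk) / len(chunk))
    return out
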