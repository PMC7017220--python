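"""Global alignment, progressive MSA, block trimming and consensus calling.

The family-level analyses (signal-peptide conservation, the glycine-rich
consensus of the Armadillidiidae armadillidins, conserved-cysteine
columns of crustins) all run on a multiple alignment.  The MSA is built
progressively: pairwise identity distances feed a UPGMA guide tree, and
profiles are merged in guide order under "once a gap, always a gap".
A two-rule block trimmer stands in for conventional alignment cleaning
(drop columns gappier than a fraction, then drop short retained runs),
and the consensus caller emits, per column, the modal residue when the
column is conserved at the similarity threshold - either as an exact
residue or within a physico-chemical class - and ``-`` otherwise.

Physico-chemical classes used for "similarity" are the Dayhoff-style
groups {AVLIM} {FWY} {ST} {DE} {NQ} {KRH} {C} {G} {P}; X is its own
class.  Gaps always count against conservation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage

from .homology_search import ScoringScheme, _check_alphabet
from .seqio_core import PeptideRecord

RESIDUE_CLASSES = ("AVLIM", "FWY", "ST", "DE", "NQ", "KRH", "C", "G", "P", "X")
CLASS_OF = {aa: grp for grp in RESIDUE_CLASSES for aa in grp}

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must be parallel")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("all alignment rows must have equal length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass
class ConsensusResult:
    consensus: str
    column_conservation: list[float]


def global_align(
    a: str, b: str, scheme: ScoringScheme = ScoringScheme()
) -> MultipleAlignment:
    """Needleman-Wunsch optimum with affine gaps, end gaps penalized."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(a, "first sequence")
    _check_alphabet(b, "second sequence")
    aln = scheme.make_aligner("global").align(a, b)[0]
    return MultipleAlignment(ids=["a", "b"], rows=[str(aln[0]), str(aln[1])])


def pairwise_identity(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Identical columns / total columns of the global alignment."""
    msa = global_align(a, b, scheme)
    ra, rb = msa.rows
    same = sum(1 for x, y in zip(ra, rb) if x == y and x not in "-X")
    return same / len(ra)


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """Per-column residue count vectors, gaps excluded (cols x 21)."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, len(_ALPHABET)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                counts[j, _AA_INDEX[ch]] += 1
    return counts


def _submatrix(scheme: ScoringScheme) -> np.ndarray:
    m = scheme.matrix
    out = np.zeros((len(_ALPHABET), len(_ALPHABET)))
    for i, x in enumerate(_ALPHABET):
        for j, y in enumerate(_ALPHABET):
            out[i, j] = m[x, y]
    return out


def _align_profiles(
    pa: tuple[list[str], list[str]],
    pb: tuple[list[str], list[str]],
    scheme: ScoringScheme,
) -> tuple[list[str], list[str]]:
    """Affine-gap Needleman-Wunsch between two profiles.

    Column score is the average substitution score over residue pairs
    (gap-containing pairs contribute 0).  Existing gaps are never
    removed: new gaps enter only as whole columns of '-'.
    """
    ids_a, rows_a = pa
    ids_b, rows_b = pb
    sub = _submatrix(scheme)
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    na = max(ca.sum(axis=1).max(), 1)
    nb = max(cb.sum(axis=1).max(), 1)
    S = ca @ sub @ cb.T / (len(rows_a) * len(rows_b))
    la, lb = S.shape
    go, ge = -(scheme.gap_open + scheme.gap_extend), -scheme.gap_extend
    NEG = -1e12
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in profile B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in profile A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = go + ge * (j - 1)
    ptrM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrX[2:, 0] = 1  # boundary gaps extend back to the origin
    ptrY[0, 2:] = 1
    # Ties prefer the gap states, which flushes gaps to the right of
    # runs of identical residues during traceback; without this, gap
    # placement inside glycine runs is arbitrary and scatters otherwise
    # identical motif columns.
    for i in range(1, la + 1):
        Srow = S[i - 1]
        for j in range(1, lb + 1):
            best_prev, ptr = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best_prev:
                best_prev, ptr = Y[i - 1, j - 1], 2
            if M[i - 1, j - 1] > best_prev:
                best_prev, ptr = M[i - 1, j - 1], 0
            M[i, j] = best_prev + Srow[j - 1]
            ptrM[i, j] = ptr
            xo, xe = M[i - 1, j] + go, X[i - 1, j] + ge
            X[i, j], ptrX[i, j] = (xe, 1) if xe >= xo else (xo, 0)
            yo, ye = M[i, j - 1] + go, Y[i, j - 1] + ge
            Y[i, j], ptrY[i, j] = (ye, 1) if ye >= yo else (yo, 0)
    i, j = la, lb
    state = [1, 2, 0][int(np.argmax([X[i, j], Y[i, j], M[i, j]]))]
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            nxt = ptrM[i, j]
            i, j = i - 1, j - 1
            state = nxt
        elif state == 1:
            ops.append("U")
            nxt = ptrX[i, j]
            i = i - 1
            state = 0 if nxt == 0 else 1
        else:
            ops.append("L")
            nxt = ptrY[i, j]
            j = j - 1
            state = 0 if nxt == 0 else 2
    ops.reverse()
    new_rows_a = ["" for _ in rows_a]
    new_rows_b = ["" for _ in rows_b]
    ai = bi = 0
    for op in ops:
        if op in ("D", "U"):
            for k, row in enumerate(rows_a):
                new_rows_a[k] += row[ai]
            ai += 1
        else:
            for k in range(len(rows_a)):
                new_rows_a[k] += "-"
        if op in ("D", "L"):
            for k, row in enumerate(rows_b):
                new_rows_b[k] += row[bi]
            bi += 1
        else:
            for k in range(len(rows_b)):
                new_rows_b[k] += "-"
    return ids_a + ids_b, new_rows_a + new_rows_b


def progressive_msa(
    seqs: Sequence[PeptideRecord], scheme: ScoringScheme = ScoringScheme()
) -> MultipleAlignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Pairwise distances are 1 - global-alignment identity; profiles are
    merged bottom-up in guide-tree order with "once a gap, always a
    gap".  Row order follows the input order.
    """
    if not seqs:
        raise ValueError("at least one sequence required")
    if len(seqs) == 1:
        return MultipleAlignment(ids=[seqs[0].id], rows=[seqs[0].seq])
    n = len(seqs)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(1.0 - pairwise_identity(seqs[i].seq, seqs[j].seq, scheme))
    tree = linkage(np.array(condensed), method="average")
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([seqs[i].id], [seqs[i].seq]) for i in range(n)
    }
    for k, (left, right, _, _) in enumerate(tree):
        pa = profiles.pop(int(left))
        pb = profiles.pop(int(right))
        profiles[n + k] = _align_profiles(pa, pb, scheme)
    ids, rows = profiles.popitem()[1]
    order = {rec.id: i for i, rec in enumerate(seqs)}
    paired = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    return MultipleAlignment(ids=[p[0] for p in paired], rows=[p[1] for p in paired])


def trim_blocks(
    msa: MultipleAlignment, max_gap_fraction: float = 0.5, min_block: int = 5
) -> MultipleAlignment:
    """Remove gappy columns, then retained runs shorter than ``min_block``.

    A column is dropped when its gap fraction exceeds ``max_gap_fraction``;
    surviving columns are then required to form runs of at least
    ``min_block`` consecutive (original) columns.  Row order is preserved.
    """
    nrow = len(msa.rows)
    ncol = msa.column_count
    if nrow == 0 or ncol == 0:
        return MultipleAlignment(ids=list(msa.ids), rows=list(msa.rows))
    keep = []
    for j in range(ncol):
        gaps = sum(1 for row in msa.rows if row[j] == "-")
        keep.append(gaps / nrow <= max_gap_fraction)
    # kill short retained runs
    j = 0
    while j < ncol:
        if keep[j]:
            k = j
            while k < ncol and keep[k]:
                k += 1
            if k - j < min_block:
                for t in range(j, k):
                    keep[t] = False
            j = k
        else:
            j += 1
    cols = [j for j in range(ncol) if keep[j]]
    if not cols:
        warnings.warn("block trimming removed every alignment column")
    rows = ["".join(row[j] for j in cols) for row in msa.rows]
    return MultipleAlignment(ids=list(msa.ids), rows=rows)


def column_consensus(
    msa: MultipleAlignment, similarity_threshold: float = 0.70
) -> ConsensusResult:
    """Consensus by modal residue or modal physico-chemical class.

    Per column: if the most frequent residue reaches the threshold it is
    emitted; otherwise, if the most frequent residue *class* reaches the
    threshold, the modal residue of that class is emitted; otherwise
    '-'.  Conservation is the modal class frequency (which bounds the
    modal residue frequency from above), so the emitted symbol is a
    letter exactly when conservation >= threshold.
    """
    if len(msa.rows) < 2:
        raise ValueError("consensus requires at least two rows")
    nrow = len(msa.rows)
    consensus = []
    conservation = []
    for j in range(msa.column_count):
        col = msa.column(j)
        res_counts: dict[str, int] = {}
        cls_counts: dict[str, int] = {}
        for ch in col:
            if ch == "-":
                continue
            res_counts[ch] = res_counts.get(ch, 0) + 1
            grp = CLASS_OF[ch]
            cls_counts[grp] = cls_counts.get(grp, 0) + 1
        if not res_counts:
            consensus.append("-")
            conservation.append(0.0)
            continue
        modal_res = max(sorted(res_counts), key=lambda a: res_counts[a])
        modal_cls = max(sorted(cls_counts), key=lambda g: cls_counts[g])
        cons = cls_counts[modal_cls] / nrow
        conservation.append(cons)
        if res_counts[modal_res] / nrow >= similarity_threshold:
            consensus.append(modal_res)
        elif cons >= similarity_threshold:
            in_cls = {a: c for a, c in res_counts.items() if CLASS_OF[a] == modal_cls}
            consensus.append(max(sorted(in_cls), key=lambda a: in_cls[a]))
        else:
            consensus.append("-")
    return ConsensusResult("".join(consensus), conservation)
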