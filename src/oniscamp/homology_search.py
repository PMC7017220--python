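"""Exhaustive local-alignment homology search with E-value filtering.

The mining step that identifies AMP candidates is a protein homology
search of family query peptides against the translated transcriptome.
Here it is done exhaustively: every query/subject pair is aligned with
the optimal affine-gap Smith-Waterman algorithm (no seeding heuristics),
and alignment scores are converted to E-values with the Karlin-Altschul
statistics E = K * m * n * exp(-lambda * S), using published gapped
BLOSUM62/11/1 parameters.  Candidates are kept at E <= 1e-10 and then
confirmed by a reciprocal search against the packaged family references:
a hit is retained only when its subject, searched back against all
references, finds a member of the same family as its best hit.

The dynamic programming itself is delegated to Biopython's
:class:`Bio.Align.PairwiseAligner` (an exact affine-gap implementation);
this module owns the statistics, filtering and reciprocal logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio_core import PROTEIN_LETTERS, PeptideRecord

#: Gapped Karlin-Altschul parameters published for BLOSUM62 with gap
#: open 11 / extend 1 (the BLASTP defaults this search stands in for).
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass(frozen=True)
class ScoringScheme:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = DEFAULT_LAMBDA
    karlin_K: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def make_aligner(self, mode: str) -> Align.PairwiseAligner:
        """Aligner where a gap of length k costs open + k * extend."""
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = self.matrix
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity_fraction: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_query: str
    aligned_subject: str

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_query)


def _check_alphabet(seq: str, label: str) -> None:
    bad = set(seq) - PROTEIN_LETTERS
    if bad:
        raise ValueError(f"{label}: symbol {sorted(bad)[0]!r} outside amino-acid alphabet")


def _identity(a: str, b: str) -> float:
    # Identical columns over all alignment columns; X never matches.
    same = sum(1 for x, y in zip(a, b) if x == y and x not in "-X")
    return same / len(a) if a else 0.0


def local_align(
    query: str, subject: str, scheme: ScoringScheme = ScoringScheme()
) -> AlignmentResult:
    """Optimal Smith-Waterman alignment with affine gaps.

    One optimal traceback is reported; the aligner's enumeration order
    is deterministic, so repeated calls give the identical alignment.
    E-value/bit score are filled in by :func:`search` context; here they
    are computed with n = len(subject) so a standalone call is coherent.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(query, "query")
    _check_alphabet(subject, "subject")
    aligner = scheme.make_aligner("local")
    if aligner.score(query, subject) <= 0:
        # nothing aligns better than the empty alignment
        return AlignmentResult(
            "query", "subject", 0, bit_score(0, scheme),
            evalue(0, len(query), len(subject), scheme),
            0.0, (0, 0), (0, 0), "", "",
        )
    aln = aligner.align(query, subject)[0]
    raw = int(round(aln.score))
    aq, asub = str(aln[0]), str(aln[1])
    coords = aln.coordinates
    return AlignmentResult(
        query_id="query",
        subject_id="subject",
        raw_score=raw,
        bit_score=bit_score(raw, scheme),
        evalue=evalue(raw, len(query), len(subject), scheme),
        identity_fraction=_identity(aq, asub),
        query_span=(int(coords[0][0]), int(coords[0][-1])),
        subject_span=(int(coords[1][0]), int(coords[1][-1])),
        aligned_query=aq,
        aligned_subject=asub,
    )


def bit_score(raw_score: int, scheme: ScoringScheme = ScoringScheme()) -> float:
    return (scheme.karlin_lambda * raw_score - math.log(scheme.karlin_K)) / math.log(2)


def evalue(
    raw_score: int, m: int, n: int, scheme: ScoringScheme = ScoringScheme()
) -> float:
    """Karlin-Altschul expected number of chance hits at this score."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return scheme.karlin_K * m * n * math.exp(-scheme.karlin_lambda * raw_score)


def search(
    queries: Sequence[PeptideRecord],
    database: Sequence[PeptideRecord],
    scheme: ScoringScheme = ScoringScheme(),
    evalue_max: float = 1e-10,
) -> list[AlignmentResult]:
    """Exhaustive all-vs-all search, keeping pairs with E <= ``evalue_max``.

    The search space n is the total residue count of the database, as in
    a database search.  Results are sorted by ascending E-value (ties by
    query then subject id for reproducibility).
    """
    if not database:
        raise ValueError("database must be non-empty")
    n_total = sum(len(r.seq) for r in database)
    aligner = scheme.make_aligner("local")
    hits: list[AlignmentResult] = []
    for q in queries:
        _check_alphabet(q.seq, f"query {q.id}")
        for s in database:
            score = int(round(aligner.score(q.seq, s.seq)))
            e = evalue(score, len(q.seq), n_total, scheme)
            if e <= evalue_max:
                res = local_align(q.seq, s.seq, scheme)
                res.query_id = q.id
                res.subject_id = s.id
                res.evalue = evalue(score, len(q.seq), n_total, scheme)
                hits.append(res)
    hits.sort(key=lambda h: (h.evalue, h.query_id, h.subject_id))
    return hits


def best_reference_family(
    seq: str,
    references: Mapping[str, Sequence[PeptideRecord]],
    scheme: ScoringScheme = ScoringScheme(),
) -> Optional[str]:
    """Family whose reference scores highest against ``seq`` (ties: name order)."""
    aligner = scheme.make_aligner("local")
    best: tuple[float, str] | None = None
    for family in sorted(references):
        for ref in references[family]:
            score = aligner.score(seq, ref.seq)
            if best is None or score > best[0]:
                best = (score, family)
    return best[1] if best else None


def reciprocal_confirm(
    hits: Sequence[AlignmentResult],
    query_set: Mapping[str, Sequence[PeptideRecord]],
    database: Sequence[PeptideRecord],
    scheme: ScoringScheme = ScoringScheme(),
) -> list[AlignmentResult]:
    """Keep hits whose subject, searched back, lands in the query's family.

    ``query_set`` maps family name -> reference peptides; each hit's
    query id must appear among the references of exactly one family.
    """
    by_id = {r.id: r for r in database}
    family_of_query: dict[str, str] = {}
    for family, refs in query_set.items():
        for ref in refs:
            family_of_query[ref.id] = family
    confirmed = []
    for hit in hits:
        family = family_of_query.get(hit.query_id)
        if family is None:
            raise ValueError(f"hit query {hit.query_id!r} not in any reference family")
        subject = by_id.get(hit.subject_id)
        if subject is None:
            continue
        if best_reference_family(subject.seq, query_set, scheme) == family:
            confirmed.append(hit)
    return confirmed


OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def hits_to_rows(hits: Sequence[AlignmentResult]) -> list[list]:
    """BLAST outfmt-6-style rows (1-based inclusive coordinates)."""
    rows = []
    for h in hits:
        cols = len(h.aligned_query)
        gaps_q = h.aligned_query.count("-")
        gaps_s = h.aligned_subject.count("-")
        ident_cols = round(h.identity_fraction * cols)
        mismatch = cols - ident_cols - gaps_q - gaps_s
        gapopen = _count_gap_openings(h.aligned_query) + _count_gap_openings(
            h.aligned_subject
        )
        rows.append(
            [
                h.query_id,
                h.subject_id,
                round(100.0 * h.identity_fraction, 2),
                cols,
                mismatch,
                gapopen,
                h.query_span[0] + 1,
                h.query_span[1],
                h.subject_span[0] + 1,
                h.subject_span[1],
                f"{h.evalue:.2e}",
                round(h.bit_score, 1),
            ]
        )
    return rows


def _count_gap_openings(row: str) -> int:
    openings = 0
    in_gap = False
    for ch in row:
        if ch == "-":
            if not in_gap:
                openings += 1
            in_gap = True
        else:
            in_gap = False
    return openings
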