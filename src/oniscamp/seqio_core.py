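"""Sequence I/O, open-reading-frame finding and redundancy collapse.

This module covers the front end of the mining pipeline: reading FASTA
transcript assemblies and peptide sets, translating contigs in all six
frames, picking the longest open reading frame per contig, and collapsing
near-identical contigs (>= 95% nucleotide identity by default) into
clusters so splice variants and assembly duplicates do not inflate
downstream repertoire counts.

Conventions
-----------
* Coordinates are 0-based, half-open, always on the forward strand.
* An ORF is a maximal stop-free codon run (stop-to-stop); contig edges
  count as boundaries.  ORFs are not anchored at a methionine, which
  maximizes the coding sequence recovered from fragmentary contigs.
* ``N`` translates to ``X``; neither ``N`` nor ``X`` ever counts as a
  match when computing percent identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from Bio import Align
from Bio.Seq import Seq

DNA_LETTERS = set("ACGTN")
PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")

#: Frames are numbered +1, +2, +3 on the forward strand and -1, -2, -3 on
#: the reverse complement, in the conventional six-frame order.
FRAMES = (1, 2, 3, -1, -2, -3)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, carrying the offending line number."""


@dataclass(frozen=True)
class NucleotideRecord:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.seq) - DNA_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid DNA symbol {sorted(bad)[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfRecord:
    """One stop-free codon run on either strand of a parent contig."""

    parent_id: str
    frame: int
    start: int  # forward-strand nucleotide coordinates, half-open
    end: int
    peptide: str

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")
        if "*" in self.peptide:
            raise ValueError("ORF peptide must not contain an internal stop")


@dataclass(frozen=True)
class PeptideRecord:
    id: str
    seq: str
    source: Optional[OrfRecord] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.seq) - PROTEIN_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid amino-acid symbol {sorted(bad)[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RedundancyCluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)


def read_fasta(
    path: str | Path, alphabet: Literal["dna", "protein"]
) -> list[NucleotideRecord] | list[PeptideRecord]:
    """Read a multi-FASTA file into typed records.

    Headers are parsed up to the first whitespace as the record id.
    Sequences are uppercased; for DNA, ``U`` is mapped to ``T``.  A
    sequence line before any header raises :class:`FastaParseError`
    naming the line; so does a duplicate id.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list = []
    seen: set[str] = set()
    current_id: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        if alphabet == "dna":
            seq = seq.replace("U", "T")
            records.append(NucleotideRecord(current_id, seq))
        else:
            records.append(PeptideRecord(current_id, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                if current_id in seen:
                    raise FastaParseError(
                        f"line {lineno}: duplicate record id {current_id!r}"
                    )
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any FASTA header"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records (anything with ``.id`` and ``.seq``) as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _translate(codon_seq: str) -> str:
    # Table 1; any N-containing codon becomes X (never a stop).
    if "N" not in codon_seq:
        return str(Seq(codon_seq).translate(table=1))
    out = []
    for k in range(0, len(codon_seq) - 2, 3):
        codon = codon_seq[k : k + 3]
        out.append("X" if "N" in codon else str(Seq(codon).translate(table=1)))
    return "".join(out)


def find_orfs(rec: NucleotideRecord, min_aa: int) -> list[OrfRecord]:
    """Scan all six frames for maximal stop-free codon runs.

    Returns ORFs translating to at least ``min_aa`` residues, sorted by
    peptide length descending; ties keep the frame order +1, +2, +3, -1,
    -2, -3 and then the smaller forward-strand start.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(rec.seq)
    if n < 3:
        return []
    rc = str(Seq(rec.seq).reverse_complement())
    orfs: list[OrfRecord] = []
    for frame in FRAMES:
        strand_seq = rec.seq if frame > 0 else rc
        offset = abs(frame) - 1
        ncod = (n - offset) // 3
        if ncod == 0:
            continue
        aa = _translate(strand_seq[offset : offset + 3 * ncod])
        # maximal stop-free runs over the translated frame
        i = 0
        while i < ncod:
            if aa[i] == "*":
                i += 1
                continue
            j = i
            while j < ncod and aa[j] != "*":
                j += 1
            pep = aa[i:j]
            if len(pep) >= min_aa:
                s = offset + 3 * i
                e = offset + 3 * j
                if frame > 0:
                    start, end = s, e
                else:
                    start, end = n - e, n - s
                orfs.append(OrfRecord(rec.id, frame, start, end, pep))
            i = j
    frame_rank = {f: k for k, f in enumerate(FRAMES)}
    orfs.sort(key=lambda o: (-len(o.peptide), frame_rank[o.frame], o.start))
    return orfs


def longest_orf_peptide(rec: NucleotideRecord) -> Optional[PeptideRecord]:
    """Translate the single longest ORF of a contig.

    Returns ``None`` when no ORF of at least one residue exists (rather
    than raising), mirroring how untranslatable contigs are simply
    dropped from the peptide set.
    """
    orfs = find_orfs(rec, min_aa=1)
    if not orfs:
        return None
    best = orfs[0]
    return PeptideRecord(id=rec.id, seq=best.peptide, source=best)


def _dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def global_nucleotide_identity(a: str, b: str) -> float:
    """Identity of a global DNA alignment, over the shorter sequence.

    Matches are columns with equal letters, never counting ``N``.  The
    shorter-sequence denominator mirrors common CD-HIT behavior.
    """
    aln = _dna_aligner().align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(ra, rb) if x == y and x not in "-N"
    )
    return matches / min(len(a), len(b))


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def collapse_redundant(
    records: Sequence[NucleotideRecord], identity_threshold: float = 0.95
) -> list[RedundancyCluster]:
    """Greedy incremental clustering at a nucleotide-identity threshold.

    Records are sorted by length descending (stable); each joins the
    first existing cluster whose representative aligns with identity at
    or above the threshold, otherwise founds a new cluster.

    A shared-word prefilter skips hopeless alignments: at >= 95%
    identity with substitution-dominated divergence, the shorter
    sequence (if >= 36 nt) must share an exact 12-mer with the
    representative (pigeonhole over its <= 5% mismatched positions), so
    pairs without one cannot reach the threshold.  For lower thresholds
    every pair is aligned.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: -len(r.seq))
    clusters: list[RedundancyCluster] = []
    reps: list[NucleotideRecord] = []
    use_prefilter = identity_threshold >= 0.95
    kmers: list[set[str]] = []
    for rec in ordered:
        rec_kmers = _kmer_set(rec.seq, 12) if use_prefilter else set()
        placed = False
        for ci, rep in enumerate(reps):
            if use_prefilter and len(rec.seq) >= 36 and not (rec_kmers & kmers[ci]):
                continue
            if global_nucleotide_identity(rep.seq, rec.seq) >= identity_threshold:
                clusters[ci].member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(RedundancyCluster(rec.id, [rec.id]))
            reps.append(rec)
            kmers.append(rec_kmers)
    return clusters


def cluster_representatives(
    records: Sequence[NucleotideRecord], clusters: Sequence[RedundancyCluster]
) -> list[NucleotideRecord]:
    """Return the representative record of each cluster, in cluster order."""
    by_id = {r.id: r for r in records}
    return [by_id[c.representative_id] for c in clusters]
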