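"""Synthetic transcriptomes with planted AMP precursors.

Every pipeline stage is testable without downloads: this module emits
transcript sets that emulate the real inputs - contigs carrying an AMP
precursor (signal peptide + mature peptide with the family's
cysteine/glycine signature) embedded between random UTRs, on a random
strand, diverged from the family template by point mutations - plus a
truth table recording what was planted where.

The family templates are synthetic constructs written to the published
hallmarks of each family (they are NOT database sequences):

* the armadillidin template uses the first characterized armadillidin
  mature peptide behind the family's conserved 19-residue A/F-rich
  signal;
* the ALF template has a hydrophobic 25-residue mature N-terminus and
  four cysteines spaced so that the first-pair spacing stays in the
  15-55 band even if any single cysteine is lost to mutation;
* the crustin template carries a glycine-rich N-terminal region and a
  C-terminal WAP domain with 10 cysteines.

The extra cysteines relative to the minimal family rules make single
point mutations unlikely to knock a planted peptide out of its own
family, so recovery measures the pipeline rather than template
fragility.  Planted coding sequences are reverse-translated with
uniform synonymous codon choice; point mutations that would introduce
an in-frame stop inside the precursor are reverted (a stop would
truncate the open reading frame and change the planted truth), and an
in-frame stop codon is placed on each side of the coding sequence so
the precursor is exactly one stop-to-stop ORF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .seqio_core import NucleotideRecord

#: Conserved 19-residue secretion signals (synthetic constructs).
ARMADILLIDIN_SIGNAL = "MKFSAIVLAIFAVVMVASA"
ALF_SIGNAL = "MKVLIVLSLLAAVVLFSSA"
CRUSTIN_SIGNAL = "MKVFSLVLLAVIAFVHTSA"

#: First characterized armadillidin mature peptide (family template).
ARMADILLIDIN_MATURE = "GHLGRPYIGGGGGFNRGGGFHRGGGFHRGGGFHSGGGFHRGGGFHSGGSFGYR"

#: Synthetic ALF-like mature: hydrophobic N-terminus, Cys at 28/58/75/95.
ALF_MATURE = (
    "LFVALIPAVLGAVLFIGAVLAIMVAESQ"  # 0-27  hydrophobic start
    "CRYSQKTLKGRLEYWRSPFNGKVTKAGWSE"  # 28-57 C28, LPS-loop-like
    "CAKTHSPEAYAAYGVR"  # 58-73 C58
    "CLADSPQKVTGYSNKVTEYAR"  # 74-94 C74
    "CDYQANMRGWRVSK"  # 95-108 C95
)

#: Synthetic crustin-like mature: G-rich region then a WAP domain with
#: the canonical 12 cysteines (so point mutations rarely drop a planted
#: crustin below the 8-Cys detection rule).
CRUSTIN_MATURE = (
    "QVGGPSGGGVYGPSGGGIVGPSGGGVHGPSGGGVYGPSGGGL"  # G-rich N region
    "PRYEKKS"
    "PVRKGSCPPNECIESCRPDCSDCSGNKCCSNGCGHVCTPMCKGCVESCR"  # WAP, 12 Cys
)

FAMILY_TEMPLATES = {
    "armadillidin": (ARMADILLIDIN_SIGNAL, ARMADILLIDIN_MATURE),
    "ALF": (ALF_SIGNAL, ALF_MATURE),
    "crustin": (CRUSTIN_SIGNAL, CRUSTIN_MATURE),
}

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Codon table 1, amino acid -> codons (uniform choice at generation).
_CODONS: dict[str, list[str]] = {}
for _c in (a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"):
    _aa = str(Seq(_c).translate())
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_c)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the recovery experiment.

    Defaults emulate the real survey: 21 species, one planted member of
    each family per species, 5% nucleotide divergence from the family
    template, and a handful of random background transcripts per
    species.
    """

    n_species: int = 21
    transcripts_per_species: int = 8
    planted: dict = field(
        default_factory=lambda: {"armadillidin": 1, "ALF": 1, "crustin": 1}
    )
    mutation_rate: float = 0.05
    utr_length_range: tuple[int, int] = (50, 200)
    background_length_range: tuple[int, int] = (300, 600)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if any(v < 0 for v in self.planted.values()):
            raise ValueError("planted counts must be >= 0")
        unknown = set(self.planted) - set(FAMILY_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown family {sorted(unknown)[0]!r}")


@dataclass(frozen=True)
class TruthRow:
    species: str
    transcript_id: str
    family: str
    strand: str  # "+" or "-"
    precursor_span: tuple[int, int]  # nt, forward strand of the transcript
    signal_span: tuple[int, int]
    mature_seq: str
    precursor_seq: str


def mutate_sequence(
    seq: str, rate: float, seed: int, alphabet: str = "ACGT"
) -> str:
    """Independently substitute each position with probability ``rate``.

    Substitutions are uniform over the alternative letters, so at rate 1
    no position keeps its original letter.  Deterministic given seed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return _mutate_with_rng(seq, rate, rng, alphabet)


def _mutate_with_rng(
    seq: str, rate: float, rng: np.random.Generator, alphabet: str = "ACGT"
) -> str:
    letters = list(seq)
    hit = rng.random(len(letters)) < rate
    for i in np.nonzero(hit)[0]:
        alternatives = [a for a in alphabet if a != letters[i]]
        letters[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(letters)


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Uniform synonymous-codon reverse translation (no codon-bias model)."""
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in peptide)


def _revert_inframe_stops(cds: str, original: str) -> str:
    """Undo mutations that created an in-frame stop codon."""
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        out.append(original[i : i + 3] if codon in STOP_CODONS else codon)
    return "".join(out)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))


def _plant_transcript(
    tid: str,
    species: str,
    family: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> tuple[NucleotideRecord, TruthRow]:
    """Build one transcript carrying a mutated family precursor.

    The precursor must come back as the (unique) longest ORF of its own
    transcript; glycine-rich coding sequence is nearly stop-free in
    shifted reading frames, so codon choice and UTRs are redrawn until
    the check passes (a bounded rejection loop on the same seeded
    stream, hence still deterministic).
    """
    from .seqio_core import longest_orf_peptide  # local import, avoids cycle

    signal, mature = FAMILY_TEMPLATES[family]
    precursor = signal + mature
    lo_u, hi_u = cfg.utr_length_range
    last = None
    for _ in range(60):
        cds = reverse_translate(precursor, rng)
        mutated = _mutate_with_rng(cds, cfg.mutation_rate, rng)
        cds_mut = _revert_inframe_stops(mutated, cds)
        precursor_mut = str(Seq(cds_mut).translate())
        utr5 = _random_dna(rng, int(rng.integers(lo_u, hi_u + 1)))
        utr3 = _random_dna(rng, int(rng.integers(lo_u, hi_u + 1)))
        construct = utr5 + "TAA" + cds_mut + "TAA" + utr3
        cds_start = len(utr5) + 3
        cds_end = cds_start + len(cds_mut)
        sig_end = cds_start + 3 * len(signal)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            seq = construct
            span = (cds_start, cds_end)
            sig_span = (cds_start, sig_end)
        else:
            seq = str(Seq(construct).reverse_complement())
            L = len(construct)
            span = (L - cds_end, L - cds_start)
            sig_span = (L - sig_end, L - cds_start)
        rec = NucleotideRecord(tid, seq)
        row = TruthRow(
            species,
            tid,
            family,
            strand,
            span,
            sig_span,
            precursor_mut[len(signal) :],
            precursor_mut,
        )
        last = (rec, row)
        best = longest_orf_peptide(rec)
        if best is not None and best.seq == precursor_mut:
            return rec, row
    return last  # pragma: no cover - rejection loop exhausts only by chance


def generate_transcriptome(
    cfg: SynthConfig,
) -> tuple[list[NucleotideRecord], list[TruthRow]]:
    """Emit synthetic transcripts and the truth table of planted AMPs."""
    rng = np.random.default_rng(cfg.seed)
    records: list[NucleotideRecord] = []
    truth: list[TruthRow] = []
    lo_b, hi_b = cfg.background_length_range
    for s in range(cfg.n_species):
        species = f"species_{s + 1:02d}"
        tnum = 0
        for family in sorted(cfg.planted):
            for _ in range(cfg.planted[family]):
                tnum += 1
                tid = f"{species}_t{tnum:03d}_{family}"
                rec, row = _plant_transcript(tid, species, family, cfg, rng)
                records.append(rec)
                truth.append(row)
        n_planted = tnum
        for _ in range(max(0, cfg.transcripts_per_species - n_planted)):
            tnum += 1
            tid = f"{species}_t{tnum:03d}_bg"
            records.append(
                NucleotideRecord(tid, _random_dna(rng, int(rng.integers(lo_b, hi_b + 1))))
            )
    return records, truth


def write_truth_table(truth: Sequence[TruthRow], path) -> None:
    """Tab-delimited truth table, one planted AMP per row."""
    with open(path, "w") as fh:
        fh.write(
            "species\ttranscript_id\tfamily\tstrand\t"
            "precursor_start\tprecursor_end\tsignal_start\tsignal_end\tmature_seq\n"
        )
        for r in truth:
            fh.write(
                f"{r.species}\t{r.transcript_id}\t{r.family}\t{r.strand}\t"
                f"{r.precursor_span[0]}\t{r.precursor_span[1]}\t"
                f"{r.signal_span[0]}\t{r.signal_span[1]}\t{r.mature_seq}\n"
            )
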