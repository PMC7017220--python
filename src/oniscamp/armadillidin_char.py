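"""Armadillidin mature-peptide characterization.

Armadillidins are glycine-rich antimicrobial peptides of terrestrial
isopods (Oniscidea), built from repeated GGGX tetrapeptide motifs behind
a highly conserved 19-residue secretion signal.  This module computes
the structural description of a mature armadillidin:

* glycine-run and GGGX-motif scan (run positions, the identity of the
  variable fourth residue X, GGGF copy number),
* amino-acid composition and the set of over-represented residues
  (> 10% of the mature length, glycine excluded - arginine being the
  typical one, consistent with the cationic character of the family),
* average molecular mass (ExPASy average residue masses, free unmodified
  termini) and theoretical isoelectric point (Bjellqvist pKa set, as in
  the ProtParam method, solved by bisection),
* a per-peptide physicochemical table (length, mass, G%, pI).

Motif-counting conventions: a G-run is a maximal stretch of two or more
consecutive glycines; every run of three or more contributes one GGGX
motif whose X is the residue immediately following the run (an end
marker ``$`` when the run is terminal).  Counting conventions for G-rich
motifs vary in the literature, so the scan reports runs of both depths
rather than asserting a single per-species motif count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping, Sequence

from .domain_annot import SignalPeptide
from .seqio_core import PeptideRecord, read_fasta

#: Mature armadillidins of the Armadillidiidae family (genera
#: Armadillidium and Eluma); the H variant represents A. vulgare.
ARMADILLIDIIDAE_IDS = (
    "A_assimile",
    "A_depressum",
    "A_maculatum",
    "A_nasatum",
    "A_tunisiense",
    "A_versicolor",
    "A_vulgare_H",
    "E_purpurascens",
)


def _packaged_fasta(name: str) -> list[PeptideRecord]:
    with resources.as_file(resources.files("oniscamp.data") / name) as path:
        return read_fasta(path, "protein")


def load_mature_armadillidins() -> list[PeptideRecord]:
    """The 18 published mature armadillidin peptides (17 organisms; two
    A. vulgare variants, ids suffixed _H and _Q)."""
    return _packaged_fasta("table2_armadillidins.fasta")


def load_assay_peptides() -> list[PeptideRecord]:
    """The two synthetic peptides used in the growth-inhibition assays."""
    return _packaged_fasta("assay_peptides.fasta")


def organism_to_mature() -> dict[str, str]:
    """One mature sequence per organism (A. vulgare: the H variant)."""
    out: dict[str, str] = {}
    for rec in load_mature_armadillidins():
        if rec.id == "A_vulgare_Q":
            continue
        key = rec.id.removesuffix("_H")
        out[key] = rec.seq
    return out

#: ExPASy/IUPAC average residue masses (Da) for peptide chains.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

#: Bjellqvist pKa values as used by the ProtParam pI method.
PKA_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM_DEFAULT = 7.5
PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PKA_CTERM_DEFAULT = 3.55
PKA_CTERM = {"D": 4.55, "E": 4.75}

END_MARKER = "$"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, as used for all reported table values."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GRun:
    start: int
    length: int
    following_residue: str  # residue after the run, or END_MARKER


@dataclass
class MotifScan:
    g_runs: list[GRun]
    gggx_motifs: list[tuple[int, str]]  # (run start, X)
    gggf_count: int
    fourth_residue_table: dict[str, int]


@dataclass
class CompositionProfile:
    counts: dict[str, int]
    fractions: dict[str, float]
    overrepresented: set[str]


@dataclass
class PhysicoChem:
    id: str
    length: int
    avg_mass: float
    gly_pct: float
    pI: float


def extract_mature(precursor: PeptideRecord, signal: SignalPeptide) -> PeptideRecord:
    """Cut the secretion signal off a precursor peptide.

    Requires a positive signal call; for peptides without one, treat the
    input as already mature instead of calling this.
    """
    if not signal.present:
        raise ValueError(
            "no signal peptide detected: treat the input as already mature"
        )
    return PeptideRecord(
        id=precursor.id + "_mature",
        seq=precursor.seq[signal.cleavage_index :],
        source=precursor.source,
    )


def scan_g_runs(seq: str) -> MotifScan:
    """Scan maximal glycine runs and derive GGGX motifs."""
    if not seq:
        raise ValueError("empty sequence")
    runs: list[GRun] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= 2:
                follower = seq[j] if j < n else END_MARKER
                runs.append(GRun(i, j - i, follower))
            i = j
        else:
            i += 1
    motifs = [(r.start, r.following_residue) for r in runs if r.length >= 3]
    table = Counter(x for _, x in motifs)
    return MotifScan(
        g_runs=runs,
        gggx_motifs=motifs,
        gggf_count=sum(1 for _, x in motifs if x == "F"),
        fourth_residue_table=dict(table),
    )


def composition_profile(seq: str, threshold: float = 0.10) -> CompositionProfile:
    """Residue counts, fractions and the > threshold over-represented set.

    Glycine is always excluded from the over-represented set (it is the
    defining residue of the family); the threshold is strict.
    """
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq)
    n = len(seq)
    fractions = {a: c / n for a, c in counts.items()}
    over = {a for a, f in fractions.items() if a != "G" and f > threshold}
    return CompositionProfile(dict(counts), fractions, over)


def average_mass(seq: str) -> float:
    """Average molecular mass in Da, free unmodified termini."""
    if not seq:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for a in seq:
        try:
            total += AVERAGE_RESIDUE_MASS[a]
        except KeyError:
            raise ValueError(f"mass undefined for residue {a!r}") from None
    return total


def net_charge(seq: str, pH: float) -> float:
    """Henderson-Hasselbalch net charge with the Bjellqvist pKa set."""
    pos = [PKA_NTERM.get(seq[0], PKA_NTERM_DEFAULT)]
    pos += [PKA_POSITIVE[a] for a in seq if a in PKA_POSITIVE]
    neg = [PKA_CTERM.get(seq[-1], PKA_CTERM_DEFAULT)]
    neg += [PKA_NEGATIVE[a] for a in seq if a in PKA_NEGATIVE]
    charge = sum(1.0 / (1.0 + 10 ** (pH - pk)) for pk in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (pk - pH)) for pk in neg)
    return charge


def isoelectric_point(seq: str, tolerance: float = 1e-4) -> float:
    """Theoretical pI by bisection on the strictly decreasing charge curve."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(AVERAGE_RESIDUE_MASS)
    if bad:
        raise ValueError(f"pI undefined for residue {sorted(bad)[0]!r}")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid)
        if abs(q) < tolerance:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def physicochem_table(seqs: Sequence[PeptideRecord]) -> list[PhysicoChem]:
    """One row of reported structural parameters per mature peptide.

    Mass, G% and pI are rounded half-up to one decimal, the precision at
    which such tables are conventionally reported.
    """
    if not seqs:
        raise ValueError("at least one sequence required")
    rows = []
    for rec in seqs:
        n = len(rec.seq)
        rows.append(
            PhysicoChem(
                id=rec.id,
                length=n,
                avg_mass=round_half_up(average_mass(rec.seq), 1),
                gly_pct=round_half_up(100.0 * rec.seq.count("G") / n, 1),
                pI=round_half_up(isoelectric_point(rec.seq), 1),
            )
        )
    return rows


def arg_overrepresentation_count(
    species_to_seq: Mapping[str, str], threshold: float = 0.10
) -> int:
    """Number of organisms whose mature peptide is > threshold arginine."""
    return sum(
        1
        for seq in species_to_seq.values()
        if seq.count("R") / len(seq) > threshold
    )
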