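"""Length filtering and crustin type classification.

Crustins divide into two types under two published schemes.  The first
(Vargas-Albores & Martinez-Porchas) looks at three characteristics of
the glycine-rich region preceding the WAP domain: its size, its glycine
content and the number of repetitive tetrapeptides it contains.  Type II
crustins carry a long (>= ~130 aa), G-rich (~25-32%) region with several
repeated tetrapeptides; type I crustins have at most a short, G-poor
region with none.  The classification thresholds used here (size >= 100,
G fraction >= 0.20, >= 3 repeats) sit inside the empty gap between the
two groups' observed ranges, so either side classifies unambiguously.
The second scheme (Tassanakajon et al.) is architectural: type II has a
glycine-rich hydrophobic domain before the WAP domain, multi-WAP
variants carry two or more WAP domains, and type I has neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .domain_annot import DomainAnnotation
from .seqio_core import PeptideRecord

CLASSIFY_THRESHOLDS = {
    "grich_min_density": 0.20,
    "grich_window": 20,
    "vargas_min_size": 100,
    "vargas_min_gly_fraction": 0.20,
    "vargas_min_repeats": 3,
    "tassanakajon_min_region": 20,
}


@dataclass
class GRichStats:
    region_span: tuple[int, int]
    region_size: int
    gly_fraction: float
    repetitive_tetrapeptide_count: int


@dataclass
class CrustinType:
    vargas_type: str  # "I" or "II"
    tassanakajon_type: str  # "I", "II" or "multi-WAP"
    evidence: GRichStats
    wap_count: int


@dataclass
class FamilySummary:
    mean: float
    sd: float
    minimum: int
    maximum: int
    n_species: int
    sd_defined: bool


def length_filter(
    records: Sequence[PeptideRecord], min_len: int
) -> list[PeptideRecord]:
    """Keep records of at least ``min_len`` residues (boundary inclusive)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in records if len(r.seq) >= min_len]


def detect_grich_region(
    seq: str,
    min_density: float = CLASSIFY_THRESHOLDS["grich_min_density"],
    window: int = CLASSIFY_THRESHOLDS["grich_window"],
) -> GRichStats:
    """Locate the glycine-rich region of a peptide.

    The best ``window``-residue stretch by G density seeds the region
    (leftmost on ties); the region is then extended one residue at a
    time, left and right, while its overall G density stays at or above
    ``min_density``.  If no window reaches the density floor the region
    is empty.
    """
    n = len(seq)
    if n < window:
        raise ValueError("sequence shorter than scan window")
    is_g = [1 if a == "G" else 0 for a in seq]
    prefix = [0]
    for v in is_g:
        prefix.append(prefix[-1] + v)

    def gcount(lo: int, hi: int) -> int:
        return prefix[hi] - prefix[lo]

    best_lo, best_count = 0, -1
    for lo in range(n - window + 1):
        c = gcount(lo, lo + window)
        if c > best_count:
            best_lo, best_count = lo, c
    if best_count / window < min_density:
        return GRichStats((0, 0), 0, 0.0, 0)
    lo, hi = best_lo, best_lo + window
    changed = True
    while changed:
        changed = False
        if hi < n and gcount(lo, hi + 1) / (hi + 1 - lo) >= min_density:
            hi += 1
            changed = True
        if lo > 0 and gcount(lo - 1, hi) / (hi - lo + 1) >= min_density:
            lo -= 1
            changed = True
    region = seq[lo:hi]
    return GRichStats(
        (lo, hi),
        hi - lo,
        gcount(lo, hi) / (hi - lo),
        count_repetitive_tetrapeptides(region),
    )


def count_repetitive_tetrapeptides(region: str) -> int:
    """Count repeated tetrapeptides in a non-overlapping left-to-right scan.

    A tetrapeptide counts when the same 4-mer occurs at least twice in
    the region (occurrences counted with overlaps); the scan then walks
    the region left to right, consuming four residues whenever it sits
    on such a repeated 4-mer, and returns the number of consumed
    occurrences.
    """
    if len(region) < 4:
        return 0
    occurrences: dict[str, int] = {}
    for i in range(len(region) - 3):
        tet = region[i : i + 4]
        occurrences[tet] = occurrences.get(tet, 0) + 1
    count = 0
    i = 0
    while i <= len(region) - 4:
        if occurrences[region[i : i + 4]] >= 2:
            count += 1
            i += 4
        else:
            i += 1
    return count


def classify_crustin(
    seq: str, ann: DomainAnnotation, thresholds: Optional[dict] = None
) -> CrustinType:
    """Type a crustin under both published schemes."""
    if ann.family != "crustin":
        raise ValueError("classify_crustin requires a crustin annotation")
    t = {**CLASSIFY_THRESHOLDS, **(thresholds or {})}
    stats = detect_grich_region(seq, t["grich_min_density"], t["grich_window"])
    vargas = (
        "II"
        if (
            stats.region_size >= t["vargas_min_size"]
            and stats.gly_fraction >= t["vargas_min_gly_fraction"]
            and stats.repetitive_tetrapeptide_count >= t["vargas_min_repeats"]
        )
        else "I"
    )
    if ann.n_wap_windows >= 2:
        tassanakajon = "multi-WAP"
    elif (
        stats.region_size >= t["tassanakajon_min_region"]
        and stats.region_span[0] < ann.domain_span[0]
    ):
        tassanakajon = "II"
    else:
        tassanakajon = "I"
    return CrustinType(vargas, tassanakajon, stats, ann.n_wap_windows)


def family_summary(per_species_counts: Mapping[str, int]) -> FamilySummary:
    """Mean and sample standard deviation of per-species transcript counts."""
    if not per_species_counts:
        raise ValueError("at least one species required")
    counts = list(per_species_counts.values())
    n = len(counts)
    mean = sum(counts) / n
    if n > 1:
        var = sum((c - mean) ** 2 for c in counts) / (n - 1)
        sd, defined = var**0.5, True
    else:
        sd, defined = 0.0, False
    return FamilySummary(mean, sd, min(counts), max(counts), n, defined)
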