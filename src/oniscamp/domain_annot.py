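"""Rule-based signal-peptide and AMP-domain annotation.

Candidate peptides coming out of the homology search are validated
against transparent, fully specified family rules instead of opaque
profile models:

* Signal peptides are called from a Kyte-Doolittle hydropathy profile:
  a cleavage site between positions 10 and 40 whose upstream region
  carries a hydrophobic core (best 8-residue window mean >= 1.5) ending
  close to the cleavage point, with small residues (A, G, S, C, T) at
  the -1 and -3 positions, as in the classic von Heijne signal-peptidase
  pattern.  Alanine at -1 is preferred when several sites qualify.
* ALF (anti-lipopolysaccharide factor) candidates must have a mature
  peptide of 70-160 residues, a hydrophobic N-terminal stretch, and at
  least two cysteines whose first pair is 15-55 residues apart (the
  LPS-binding loop).
* Crustin candidates must carry a cysteine-dense WAP (whey acidic
  protein) window - at least 8 Cys within 35-60 residues - in the
  C-terminal half.  The classic "12 conserved cysteines" of malacostracan
  crustins is a family-level alignment statement (signal flag), not a
  per-sequence discard rule, since a canonical single WAP domain has 8.

All thresholds live in :data:`ANNOT_THRESHOLDS` and can be overridden
per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align_consensus import MultipleAlignment, progressive_msa
from .homology_search import ScoringScheme
from .seqio_core import PeptideRecord

#: Kyte-Doolittle hydropathy scale; X (unknown) is treated as neutral.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

SMALL_RESIDUES = set("AGSCT")

ANNOT_THRESHOLDS = {
    "signal_min_cleavage": 10,
    "signal_max_cleavage": 40,
    "signal_core_window": 8,
    "signal_core_hydropathy": 1.5,
    "signal_core_max_gap": 8,  # residues between core end and cleavage
    "alf_min_mature": 70,
    "alf_max_mature": 160,
    "alf_cys_gap_min": 15,
    "alf_cys_gap_max": 55,
    "alf_nterm_window": 25,
    "alf_nterm_hydropathy": 0.5,
    "wap_window_min": 35,
    "wap_window_max": 60,
    "wap_min_cys": 8,
    "conserved_cys_fraction": 0.90,
}


@dataclass(frozen=True)
class SignalPeptide:
    present: bool
    cleavage_index: int  # first residue of the mature peptide (0-based)
    hydropathy_score: float

    def __post_init__(self) -> None:
        if self.present and not (10 <= self.cleavage_index <= 40):
            raise ValueError("cleavage index must lie in [10, 40]")


@dataclass
class DomainAnnotation:
    family: str  # ALF, crustin, armadillidin or none
    domain_span: tuple[int, int]
    cys_positions: list[int]
    checks: dict[str, bool] = field(default_factory=dict)
    n_wap_windows: int = 0


def hydropathy_profile(seq: str, window: int = 9) -> list[float]:
    """Centered sliding-window mean hydropathy; truncated at the ends."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if len(seq) < window:
        raise ValueError("sequence shorter than window")
    vals = [KYTE_DOOLITTLE[a] for a in seq]
    half = window // 2
    out = []
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        out.append(sum(vals[lo:hi]) / (hi - lo))
    return out


def mean_hydropathy(seq: str) -> float:
    return sum(KYTE_DOOLITTLE[a] for a in seq) / len(seq) if seq else 0.0


def _best_core(vals: Sequence[float], end: int, width: int, max_gap: int) -> float:
    """Best mean over ``width``-windows inside vals[1:end] that end within
    ``max_gap`` residues of ``end`` (the h-region must abut the cleavage
    site, not float anywhere in the precursor)."""
    best = float("-inf")
    for i in range(max(1, end - width - max_gap), end - width + 1):
        m = sum(vals[i : i + width]) / width
        if m > best:
            best = m
    return best


def detect_signal_peptide(seq: str, thresholds: Optional[dict] = None) -> SignalPeptide:
    """Hydropathy-based secretion-signal call on a precursor peptide.

    Scans cleavage candidates 10-40; a candidate needs small residues at
    -1 and -3 and a hydrophobic core (best 8-mer mean >= 1.5) ending
    within 8 residues of the cleavage point.  The best-scoring candidate
    wins, with a bonus for the canonical Ala at -1; ties go to the
    later site (of two equally supported A-X-A sites, cleavage happens
    at the distal one, downstream of the h-region).  Absence is a
    result, not an error.
    """
    t = {**ANNOT_THRESHOLDS, **(thresholds or {})}
    if len(seq) < 25:
        raise ValueError("precursor too short for signal detection (< 25 aa)")
    vals = [KYTE_DOOLITTLE[a] for a in seq]
    width = t["signal_core_window"]
    best_candidate: tuple[float, int, float] | None = None  # (-score, -c, core)
    hi = min(t["signal_max_cleavage"], len(seq) - 5)
    for c in range(t["signal_min_cleavage"], hi + 1):
        if seq[c - 1] not in SMALL_RESIDUES or seq[c - 3] not in SMALL_RESIDUES:
            continue
        core = _best_core(vals, c, width, t["signal_core_max_gap"])
        if core < t["signal_core_hydropathy"]:
            continue
        score = core + (0.5 if seq[c - 1] == "A" else 0.0)
        cand = (-score, -c, core)
        if best_candidate is None or cand < best_candidate:
            best_candidate = cand
    if best_candidate is None:
        return SignalPeptide(False, 0, 0.0)
    _, neg_c, core = best_candidate
    return SignalPeptide(True, -neg_c, core)


def validate_alf(
    seq: str, signal: SignalPeptide, thresholds: Optional[dict] = None
) -> DomainAnnotation:
    """Check the ALF hallmarks on the mature region of a candidate."""
    t = {**ANNOT_THRESHOLDS, **(thresholds or {})}
    start = signal.cleavage_index if signal.present else 0
    mature = seq[start:]
    cys = [start + i for i, a in enumerate(mature) if a == "C"]
    # the disulfide-loop rule asks for SOME cysteine pair at loop-like
    # spacing; extra cysteines must not disqualify a candidate
    pair_ok = any(
        t["alf_cys_gap_min"] <= cys[j] - cys[i] <= t["alf_cys_gap_max"]
        for i in range(len(cys))
        for j in range(i + 1, len(cys))
    )
    checks = {
        "length": t["alf_min_mature"] <= len(mature) <= t["alf_max_mature"],
        "two_cysteines": len(cys) >= 2,
        "cys_spacing": pair_ok,
        "hydrophobic_nterm": mean_hydropathy(mature[: t["alf_nterm_window"]])
        >= t["alf_nterm_hydropathy"],
    }
    family = "ALF" if all(checks.values()) else "none"
    return DomainAnnotation(family, (start, len(seq)), cys, checks)


def _wap_windows(seq: str, t: dict) -> list[tuple[int, int, int]]:
    """Greedy non-overlapping (start, width, n_cys) windows with >= 8 Cys."""
    found = []
    pos = 0
    n = len(seq)
    while pos <= n - t["wap_window_min"]:
        best = None
        for w in range(t["wap_window_min"], t["wap_window_max"] + 1):
            if pos + w > n:
                break
            ncys = seq[pos : pos + w].count("C")
            if ncys >= t["wap_min_cys"] and (best is None or ncys > best[2]):
                best = (pos, w, ncys)
        if best:
            found.append(best)
            pos = best[0] + best[1]
        else:
            pos += 1
    return found


def validate_wap(seq: str, thresholds: Optional[dict] = None) -> DomainAnnotation:
    """Check for a cysteine-dense WAP window in the C-terminal half."""
    t = {**ANNOT_THRESHOLDS, **(thresholds or {})}
    windows = _wap_windows(seq, t)
    # exhaustive scan of windows starting in the C-terminal half; best by
    # cysteine count, ties to the earlier, narrower window
    half = len(seq) // 2
    best = None
    for start in range(half, len(seq) - t["wap_window_min"] + 1):
        for w in range(t["wap_window_min"], t["wap_window_max"] + 1):
            if start + w > len(seq):
                break
            ncys = seq[start : start + w].count("C")
            if ncys >= t["wap_min_cys"] and (best is None or ncys > best[2]):
                best = (start, w, ncys)
    checks = {"wap_in_cterm_half": best is not None}
    if best is not None:
        span = (best[0], best[0] + best[1])
    else:
        span = (0, 0)
    cys = [i for i, a in enumerate(seq) if a == "C"]
    family = "crustin" if all(checks.values()) else "none"
    return DomainAnnotation(family, span, cys, checks, n_wap_windows=len(windows))


def conserved_cysteine_columns(
    seqs: Sequence[PeptideRecord],
    scheme: ScoringScheme = ScoringScheme(),
    min_fraction: Optional[float] = None,
    msa: Optional[MultipleAlignment] = None,
) -> tuple[int, bool]:
    """Count Cys-conserved alignment columns across a crustin family set.

    Returns ``(n_columns, flag)`` where the flag marks the classic
    malacostracan pattern of 12 conserved cysteines (>= 12 columns whose
    Cys frequency reaches ``min_fraction``).
    """
    frac = ANNOT_THRESHOLDS["conserved_cys_fraction"] if min_fraction is None else min_fraction
    if msa is None:
        msa = progressive_msa(seqs, scheme)
    nrow = len(msa.rows)
    n_cols = 0
    for j in range(msa.column_count):
        col = msa.column(j)
        if col.count("C") / nrow >= frac:
            n_cols += 1
    return n_cols, n_cols >= 12
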