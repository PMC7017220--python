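# Methods

`oniscamp` mines antimicrobial peptide (AMP) candidates from terrestrial
isopod (Oniscidea) transcript assemblies and characterizes the
glycine-rich armadillidin family. This note documents the models,
conventions and parameter choices, what the synthetic data emulate, and
the limits of what the tests demonstrate.

## Pipeline model

The pipeline treats a transcriptome as a bag of contigs and proceeds:

1. **Redundancy collapse.** Greedy incremental clustering by global
   nucleotide identity, threshold 0.95. Records are visited longest
   first; each joins the first cluster whose representative aligns at or
   above the threshold, else founds a new one. Identity is
   matches / length of the shorter sequence (the usual convention of
   word-based clustering tools at this threshold); `N` never counts as a
   match. A shared exact 12-mer is required before aligning a pair when
   the threshold is >= 0.95 and the shorter sequence is >= 36 nt: at
   <= 5% substitution divergence the pigeonhole principle forces such a
   word, so the filter cannot reject a pair that would pass. Pathological
   divergence patterns (an indel every few bases at constant identity)
   could evade this bound but do not occur between splice variants or
   assembly duplicates, which is what the collapse is for.
2. **Translation.** Six-frame scan; an ORF is a maximal stop-to-stop
   codon run (contig edges count as boundaries), not anchored at ATG,
   which maximizes coding sequence recovered from fragmentary contigs.
   Each contig contributes its single longest ORF (ties: frame order
   +1, +2, +3, -1, -2, -3, then smaller forward-strand start).
   Coordinates are 0-based half-open on the forward strand. `N`-containing
   codons translate to `X`.
3. **Homology search.** One query per family against all translated
   peptides, scored with exhaustive affine-gap Smith-Waterman
   (BLOSUM62, gap open 11, extend 1; a gap of length k costs 11 + k).
   Significance uses Karlin-Altschul statistics
   E = K m n exp(-lambda S) with the published gapped BLOSUM62/11/1
   parameters lambda = 0.267, K = 0.041; n is the total residue count of
   the database. The cutoff is E <= 1e-10. Exhaustive DP needs no word
   size or two-hit heuristics, so results are exactly reproducible;
   the DP itself is Biopython's `PairwiseAligner`, checked in the test
   suite against an independent brute-force DP.
4. **Reciprocal confirmation.** Each hit's subject is searched back
   against all family references; the hit survives only if the best
   back-hit belongs to the query's family. This replaces verification
   against a remote non-redundant database with a closed, packaged
   reference set.
5. **Domain validation.** Transparent rules in place of profile-HMM and
   signal-prediction services (thresholds in
   `domain_annot.ANNOT_THRESHOLDS`):
   * *Signal peptide*: cleavage candidates at positions 10-40 need small
     residues (A, G, S, C, T) at -1 and -3 and a hydrophobic core — the
     best Kyte-Doolittle 8-residue window ending within 8 residues of
     the site — with mean >= 1.5. Highest core wins, +0.5 for the
     canonical Ala at -1, ties to the later (distal) site. This is a
     deliberately simple von Heijne-style heuristic: adequate for the
     conserved 19-residue A/F-rich armadillidin signal, not a general
     signal predictor.
   * *ALF*: mature peptide 70-160 aa, mean hydropathy of the first 25
     mature residues >= 0.5, and at least two cysteines with some pair
     spaced 15-55 apart (the LPS-binding loop). "Some pair" rather than
     "the first pair": an extra cysteine must not disqualify an
     otherwise canonical candidate.
   * *Crustin*: a window of 35-60 residues in the C-terminal half with
     >= 8 cysteines (a WAP domain). The classical 12 conserved
     cysteines of malacostracan crustins is reported as a family-level
     alignment flag (>= 12 columns with >= 90% Cys), not a per-sequence
     requirement, because a canonical single WAP domain has 8.
   * *Armadillidin*: confirmed hits additionally need a glycine-rich
     region of >= 20 residues.
6. **Length filters** as published: ALF >= 100 aa, crustin >= 90 aa.
7. **Crustin typing.** Two schemes. The region-based scheme calls type
   II when the G-rich region is >= 100 aa with >= 20% G and >= 3
   repetitive tetrapeptides — thresholds placed inside the empty gap
   between the published type-II ranges (130-166 aa, 24.6-32.3% G, 3-11
   repeats) and type-I ranges (<= 62 aa, <= 9.8% G, 0 repeats), so any
   sequence matching either published range classifies unambiguously.
   The architectural scheme calls multi-WAP at >= 2 WAP windows, type II
   when a G-rich region precedes the WAP domain, else type I.
8. **Armadillidin characterization** (below), plus reports: cluster,
   hit (BLAST tabular column order), classification and
   physicochemical TSVs, consensus table, run log with all thresholds.
   Reruns with the same inputs and seed are byte-identical.

## Armadillidin characterization

* **G-runs and GGGX motifs.** A G-run is a maximal stretch of >= 2
  consecutive glycines; each run of >= 3 contributes one GGGX motif
  whose X is the residue after the run (end marker if terminal). GGGF
  copy number and the distribution of X are reported. Published
  per-species "G-rich motif" counts mix conventions (no single run
  depth reproduces all of them), so the scanner reports runs at both
  depths and asserts neither.
* **Composition.** A residue is over-represented when its fraction of
  the mature length is strictly > 0.10; glycine, the defining residue,
  is always excluded.
* **Average mass.** Sum of ExPASy average residue masses + 18.01524 Da
  water, free unmodified termini. The table is pinned in the module; on
  the 18 packaged sequences it agrees with the published values to
  <= 0.04 Da.
* **Theoretical pI.** Bisection on [0, 14] of the Henderson-Hasselbalch
  net charge with the Bjellqvist pKa set (N-terminal pKa by residue,
  side chains D, E, C, Y, H, K, R, C-terminal 3.55/4.55/4.75), to
  |charge| < 1e-4. The charge curve is strictly decreasing so the root
  is unique. Several armadillidins have pI > 12; the bisection interval
  deliberately covers the full pH scale.
* **Reporting.** Table values round half-up to one decimal.
* **Consensus.** Progressive MSA: UPGMA guide tree on pairwise
  global-alignment identity distances, profile-profile merge under
  "once a gap, always a gap", column score = mean BLOSUM62 over residue
  pairs. DP ties prefer gap states, which flushes gaps to the right of
  runs of identical residues; since armadillidins are built of glycine
  runs, this canonical placement is what keeps homologous motif columns
  together (with arbitrary tie-breaking the consensus of the eight
  Armadillidiidae sequences loses its RPYIGGGG block purely to gap
  shuffling). Consensus per column: modal residue if its frequency is
  >= 0.70, else the modal residue of the modal physico-chemical class
  ({AVLIM} {FWY} {ST} {DE} {NQ} {KRH} {C} {G} {P}) if the class reaches
  0.70, else '-'; gaps count against conservation. Exact inter-motif
  spacer lengths depend on gap placement and are not asserted anywhere —
  only motif content is.
* **Block trimming** (for alignment cleaning): drop columns with gap
  fraction > 0.5, then drop surviving runs shorter than 5 columns; a
  deliberately simple stand-in for conventional trimmers, idempotent by
  construction.

The G-rich region detector seeds on the densest 20-residue window
(>= 20% G to qualify) and extends one residue at a time while the whole
region stays at or above the density floor. With a dense core the region
can therefore absorb glycine-poor flanks until dilution stops it; region
size should be read together with its G fraction, and the crustin-typing
thresholds are placed so this convention cannot flip a published-range
sequence across types.

## Synthetic data

`synthetic_data` emulates the study conditions: by default 21 species,
one armadillidin + one ALF + one crustin precursor planted per species
at 5% per-nucleotide divergence from the family template, 5 random
background transcripts per species (300-600 nt), UTRs of 50-200 nt,
random strand. Planted precursors are template signal + mature peptides
reverse-translated with uniform synonymous codons. Three guards make
the truth table exact: an in-frame stop flanks the CDS on each side;
mutations that would create an in-frame stop inside the precursor are
reverted (they would truncate the ORF and silently change the planted
truth); and codon/UTR draws are re-sampled (bounded, within the same
seeded stream) until the precursor is the unique longest ORF of its
transcript — glycine-rich coding sequence is nearly stop-free in
shifted reading frames, so without this check a shifted-frame ORF
frequently ties or exceeds the real one.

The templates are synthetic constructs written to the published family
hallmarks, not database sequences: the armadillidin template is the
first characterized mature armadillidin behind a 19-residue A/F-rich
signal; the ALF template has a hydrophobic mature N-terminus and four
cysteines spaced so that losing any single one still leaves a pair in
the 15-55 band; the crustin template has a G-rich N-terminal region and
a WAP domain with the canonical 12 cysteines. The margins are
deliberate: recovery experiments should measure the pipeline, not
template fragility at the rule boundary.

What the generator does **not** model: expression levels, isoforms,
sequencing error, codon bias, indels, GC heterogeneity, and real
inter-species phylogenetic structure (each species diverges
independently from one template). Passing recovery tests therefore
shows the pipeline's machinery is sound under substitution divergence
at the stated rate; it does not certify sensitivity on real
assemblies, where fragmentation and isoforms dominate.

## Problem sizes and numerical choices

The recovery experiment uses the full 21-species condition (168
transcripts, 63 planted AMPs) and completes in a few seconds; oracle
equivalence checks use 200 random 20-40-mer pairs for alignment scores
and 1000 random G-rich strings for the motif scanner. Determinism:
every stochastic component takes a seed; the alignment enumeration
order of the underlying aligner is deterministic, and all report
iteration orders are sorted.

## Known limitations

* The domain rules are operationalizations of qualitative family
  descriptions; they are transparent and tested but are not
  profile-HMM equivalents, and absolute repertoire counts from real
  data will differ from heuristic-search tools with different
  statistics.
* The arginine over-representation statistic on the packaged 17
  organisms evaluates to 16 under the strict >10% rule (the module's
  documented convention); see the acceptance suite.
* The signal-peptide heuristic is tuned for the conserved secretion
  signals of these AMP families and will miss atypical signals.
* Maximum-likelihood phylogenetics, database verification and
  wet-lab activity measurements are out of scope.
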