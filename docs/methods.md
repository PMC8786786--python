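# Methods

This note records the models and procedures implemented in `aglscan`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Sequences, ORFs and the PG screen

Sequences are plain residue strings with a declared alphabet (DNA:
`ACGTN`; protein: the 20 standard letters plus `X` and `*`). Translation
uses the standard genetic code; a codon containing `N` translates to `X`,
and `X` never counts toward any composition percentage numerator although
it does count toward length. Minus-strand frames are numbered from the 5'
end of the reverse complement.

ORFs are **stop-to-stop**: every maximal stop-free codon run in each of
the six frames, with runs truncated by the sequence ends kept and marked
(`stop_flanked = False`). This deliberately tolerates a missing initiator
methionine, because low-complexity transcripts are often assembled without
their 5' end; an ATG-anchored mode is available via `require_start`. The
default minimum ORF length is 50 aa — comfortably below the shortest
mature proteins of interest (~100 aa) — and is configurable. The candidate
screen retains ORFs whose PG% (100·(#P+#G)/length, computed on the ORF
peptide as found, not the mature protein) **strictly** exceeds 20%.

## Composition, molecular weight, isoelectric point

Percentages are computed at full precision and displayed to one decimal.
Molecular weight is the sum of average residue masses plus one water;
`X` is an error in strict mode or the mean residue mass otherwise. The
isoelectric point is the root of the Henderson–Hasselbalch net-charge
model (free termini plus D, E, C, Y, H, K, R side chains) found by
bisection on pH 0–14 to a tolerance of 0.005. The pKa set is Bjellqvist's
(the ExPASy convention), held in a single table so an alternative set
(e.g. EMBOSS values) can be passed in; published pI values computed under
a different pKa convention can differ in the first decimal.

pI classes use the cut points acidic < 6.0, neutral 6.0–7.5,
basic > 7.5 (configurable). Note that an uncharged peptide (free termini
only) titrates near pH 5.5 and therefore classifies as "acidic" under
these cut points; the classes describe the convention used for reporting
this protein family, not a general-purpose scale.

Reporting flags use non-strict comparisons: individual residues ≥ 15%
(restricted to the disorder-relevant panel P, G, A, S, T, N, Q),
PGA ≥ 40%, DE ≥ 8%, KR ≥ 8%. "Charged residues" means D, E, K, R;
histidine is not counted.

## Signal regions

Two sources of ER-signal and GPI ω-site annotation exist and are never
silently mixed; every annotation carries a provenance (`imported` or
`heuristic`), because external predictor output is treated as
authoritative where available.

- **Imported**: tab-separated predictor summaries, dialect (a)
  `id, er_cleavage_end, YES/NO` and dialect (b)
  `id, omega_pos, YES/NO, score`.
- **Heuristic ER signal**: within the first 40 residues, require an
  8-residue window of mean Kyte–Doolittle hydropathy ≥ 1.6 (the h-region)
  followed by a cleavage position in 15–35 obeying the (−3, −1)
  small-residue rule (both positions in {A,G,S,C,T,V}); the first
  qualifying position wins.
- **Heuristic GPI ω-site**: require a hydrophobic C-terminal tail (mean
  KD ≥ 1.0 over the final 12 residues) and a small residue
  ({G,A,S,N,D,C}) at a position 17–31 from the C-terminus with a small
  residue at ω+2; among qualifying positions the one closest to
  25-from-end wins. Consequence: an ω planted exactly 25 residues from
  the C-terminus is always recovered; ω positions elsewhere in the window
  can be outcompeted by small residues in a low-complexity mature region,
  which is why imported predictions take precedence.

The mature protein is `er_end+1 .. ω−1`; the GPI propeptide is removed
from ω onward. If only one signal is annotated, only that end is trimmed.

## Tandem repeats and Psim

The detector finds arrays of adjacent near-identical units within one
sequence:

1. **Candidate periods** are k-mer occurrence distances (k = 3 for
   protein, 5 for DNA) with aggregate support ≥ 2; periods below k are
   seeded by a direct adjacent-unit scan so unit lengths 1 and 2
   (homorepeats, dipeptide repeats) are not missed.
2. From each seed, the array is **grown** unit by unit in steps of the
   period; a new unit is accepted while its global-alignment identity to
   the running column-majority consensus (edit-distance based, so a
   single-residue indel costs one mismatch) stays ≥ the Psim threshold.
3. **Psim** is the mean identity of the full units to the final
   consensus; Psim = 1.0 iff all full units are identical. A partial
   terminal unit matching the consensus prefix extends the span but does
   not count as a copy.
4. Regions with Psim ≥ threshold and ≥ 2 full copies are reported.
   Subsumption rules keep the output interpretable: a fragment too short
   to carry its own period information inside a larger array (e.g. a
   doubled letter) is dropped, and a period-multiple of a kept region at
   the same span and Psim is dropped, so the smallest qualifying period
   wins. With `filter_overlaps` the highest-scoring
   (copies × unit length × Psim) regions are retained greedily.

Detection requires at least one exact shared w-mer (w = min(k, period))
between adjacent units, so arrays in which *every* adjacent unit pair
differs within every window can escape detection at low Psim thresholds;
at the working thresholds (1.0 for protein, 0.7 for DNA with roughly one
substitution per unit) this is not a practical limitation. The working
thresholds reflect the biology: protein repeat units are near-perfect,
while their coding DNA drifts by codon degeneracy.

Repeat properties are computed on the consensus unit: P% and G%, the
zwitterionic flag (at least one of D/E **and** one of K/R), and the
property zone.

## Property zones (elastic / intermediate / amyloid)

Repeat units are classified in the (G%, P%) plane against two
piecewise-linear boundary curves read from a JSON config. The default
boundaries are the straight lines **P+G = 20** (amyloid/intermediate) and
**P+G = 40** (intermediate/elastic). These defaults are a calibration —
chosen so that well-characterised exemplar units fall in their reported
zones (a G-only unit at 14.3% G is amyloid; units at 16.7/16.7 or
12.5/25 are intermediate; 20/20 and above are elastic) — not a measured
constant; edit the JSON to recalibrate. Symmetric straight-line defaults
also make the classification independent of which axis is P% and which
G%. Loading validates that the curves do not cross, and the classifier is
monotone: increasing P% or G% never moves a unit from elastic toward
amyloid.

## Codon usage

Codon counts are grouped by encoded amino acid within a stated 1-based
interval of a CDS; the interval must be in frame unless an explicit frame
offset shifts it (trailing partial codons are then dropped). Per-amino-acid
fractions sum to 1.

## Read baiting

A bait index stores every canonical k-mer (lexicographic minimum of the
k-mer and its reverse complement; k = 31 by default, k-mers containing N
skipped) of every bait sequence. A read matches when at least `n_min`
(default 1) of its canonical k-mers are in the index; under the default
`either` pair policy a pair is kept when either mate matches. Base
qualities are ignored — baiting runs on raw, untrimmed reads — and
selection preserves input order, making runs byte-deterministic.
Canonicalisation makes baiting strand-symmetric; an implementation that
checked both strands explicitly would select the same reads. Iterated
(two-round) baiting is a CLI loop, not bespoke logic.

## Alignment and region identity

Global alignment is Needleman–Wunsch with affine gaps and free end gaps,
match +5 / mismatch −4, gap open 10, gap extend 0.5 for DNA (the defaults
of the widely used EMBOSS-style global aligners), delegated to Biopython's
`PairwiseAligner`; ties break on the aligner's deterministic enumeration
order. Region identity assigns every alignment column to the region
covering its a-residue (gap-in-a columns inherit the enclosing region) and
divides identical columns by **all** columns assigned to the region — the
stricter convention, so percentages from alignment viewers that ignore gap
columns may differ; cross-study comparisons should rely on the ordering of
regions (signals > intron > mature), which is convention-independent.
Frameshift gaps are maximal gap runs inside coding regions whose length is
not a multiple of three, reported on the ungapped coordinates of sequence
a. Genomic spans are 1-based inclusive (`end − start + 1`), printed in kb
to one decimal.

## Classifier and elimination

Class labels are a pure function of the report fields, applied in this
order: class 5 if neither signal is present; class 3/4 if an imported
domain-hit table marks the candidate chimeric (3 for the "insignificant
PF10342" category, 4 otherwise); class 1 if PGA > 40% (strict — PGA of
exactly 40.0 falls in class 2, resolving the ambiguity between "> 40" and
"15–39.9" in favour of the strict reading); class 2 if PGA ∈ [15, 40];
below 15% PGA the candidate is reported unclassified. `is_agl` requires
class 1 **and** an ER signal **and** mature length ≤ 200 aa.

A candidate with no ER signal is eliminated (not secreted) unless it is a
partial sequence (missing initiator Met or truncated at a contig end) with
global identity ≥ 90% to an ER-bearing peer; the 90% default quantifies
"high identity" and is configurable. Signal predictions keyed by a source
record apply only to forward-strand ORFs of that record.

## Synthetic data: what it emulates and what it does not

A synthetic gene is `[exon 1: ER-signal CDS + 3 codons] + [GT..AG intron,
default 80 nt] + [exon 2: mature repeat array + GPI-signal CDS]`, echoing
the family's conserved architecture of a short first exon and a single
intron adjacent to the ER-signal cleavage site. The mature region is a
repeat array (default: the 14-residue unit GKAPAGGAAPGADA × 5) mutated at
a configurable per-residue rate and back-translated under a restricted
codon model (single codons for P, D, K; two for G and A); a strict mode
with one codon per amino acid reproduces 100% codon usage in the repeat
region. Signal peptides come from curated templates engineered so the
built-in heuristics fire at exactly the planted positions (the template's
FNEAS spacer blocks earlier (−3,−1) sites; the GPI signal is 25 aa so ω
sits at the heuristic's preferred distance). Cohorts add decoy transcripts
(random ORFs, resampled until every ORF ≥ 50 aa stays below 15% PG, no
planted signals) and paired 100-nt reads with uniform fragment starts and
substitution errors only. The cohort's planted units carry copy numbers
(14-mer × 5, hexamer × 12, 15-mer × 5) chosen so each whole ORF clears the
20% PG screen, as the real repeat arrays do.

All stochastic calls flow from one explicitly seeded generator; the same
spec and seed give byte-identical output.

Not emulated: expression-level variation, sequencing quality profiles,
indel read errors, chimeric/misassembled contigs, and genuinely novel
signal peptides (the heuristics are validated on templates, not on the
diversity of real signals). Passing the synthetic suites therefore shows
the pipeline's logic is correct under the family's assumed architecture;
it does not certify the heuristics' sensitivity on real proteins, which is
why imported predictor calls take precedence in real analyses.

## Problem sizes used in the test and acceptance suites

Property suites run at sizes chosen to finish in seconds while exercising
the full code paths: 200 random 300-nt sequences for the ORF/brute-force
equivalence, 200 random pairs ≤ 12 nt for the alignment/DP-oracle
equivalence (with an additional exhaustive-enumeration check of the oracle
itself at ≤ 6 nt), 100 random peptides ≤ 40 aa for the pI grid-scan
comparison (±0.01), cohorts of 3 planted genes + 7–8 decoys for end-to-end
recovery, and a 101×101 grid for zone monotonicity.

## Known limitations

- The Psim definition (mean unit-to-consensus identity) is this package's
  stated definition; other repeat finders compute similarity differently,
  so region coordinates and Psim values are comparable only within this
  package.
- Repeat detection within one sequence only; no cross-sequence or
  profile-HMM repeat modelling.
- The signal heuristics are coarse approximations of neural/HMM
  predictors and are marked as such in every report.
- No splice-aware ORF finding; genes must be provided spliced (or the
  intron-bearing gene analysed as DNA with region annotations).
- No assembly: the pipeline consumes assembled contigs and emits baited
  reads for an external assembler.
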