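# Methods

`srnakit` re-implements, as a tested library, the inference chain used in
plant small-RNA studies that combine miRNA discovery, digital expression
analysis, phased-siRNA (tasiRNA) detection and target prediction. This
note records the models, the parameter choices and their rationale, the
numerical conventions, and what the synthetic-data validation does and
does not demonstrate.

## Read preprocessing

Raw FASTQ reads pass through a fixed filter chain:

1. **3'-adapter trimming.** The insert is everything before the leftmost
   match of an adapter prefix (>= `min_overlap` = 7 bases, up to the full
   adapter) found internally or as a suffix-prefix overlap at the 3' end.
   Reads with no detectable adapter are discarded by default
   (`keep_untrimmed = false`): without the adapter boundary the insert
   length is unknown. Trimming precedes quality filtering; the order is a
   convention of this package.
2. **Quality filter.** A read is kept iff it contains no `N` and at most
   6 bases with Phred quality < 13 (Phred+33).
3. **Length filter.** Inserts outside 16-30 nt are dropped.
4. **Collapsing.** Identical insert sequences become one unique tag with
   per-library counts. All sequences are normalised to the DNA alphabet
   (U -> T) and stored 5'->3'.
5. **Contaminant removal.** A tag is removed when it is an exact
   substring of any t/rRNA database sequence or its reverse complement.
   Exact matching is consistent with the pipeline's overall exact-match
   stance; no mismatches are tolerated anywhere downstream either.

Conservation holds per library: raw = discarded (per category) + clean,
and the clean total equals the count sum over surviving tags. The clean
totals are the TPM denominators later.

## Exact genome mapping

Unique tags are matched to both genome strands with zero mismatches via
a 12-mer anchor table plus verification; `N` never matches. Tags with no
placement are rejected (not identical to the genome), tags with more
than 16 placements are rejected as repeats (multi-hit cap 16). A
reverse-complement-palindromic tag counts one hit per interval (the `+`
label is kept) so it is not double-counted toward the cap.

## Hairpin-based miRNA discovery

For every placement of a candidate tag, a window of the read plus 100-nt
flanks is folded at thermodynamic minimum free energy (ViennaRNA 2.x,
default parameters; folding is deterministic). The discovery chain then:

1. **Stem-loop isolation.** From the window fold, the longest unbranched
   stem-loop containing the read on one arm is excised: starting at a
   terminal loop's closing pair, the stem is grown outward through
   interior loops and bulges, stopping at branching or when one step
   would bridge more than 6 unpaired nt (incidental flank pairs past a
   large loop are not precursor stem). The excision is refolded in
   isolation — flanking genomic sequence can distort the fold of the
   true precursor — and re-validated. The read may reach at most 3 nt
   into the terminal loop (terminal-pair fraying in MFE structures can
   nudge the loop boundary past an intact duplex); reads inside or
   spanning the loop disqualify the window. Hairpins under 60 nt are
   rejected.
2. **miRNA\* location.** In the canonical duplex the two strands leave
   2-nt 3' overhangs: the star 5' end pairs with (mature 3' end − 2) and
   the star 3' end is the partner of the mature 5' start plus 2 nt.
   When an anchor position is unpaired it may slide up to 2 nt to the
   nearest paired base, compensated antiparallel on the partner side;
   beyond that no star is declared.
3. **Duplex validation.** Mismatches are mature duplex positions
   (excluding the 2-nt overhang) not base-paired to a star position; a
   symmetric interior loop contributes its mature-side length. An
   asymmetric bulge is the length excess of one side over the other
   between consecutive duplex pairs. A candidate passes with <= 4
   mismatches, <= 1 bulge, and no bulge over 2 nt.
4. **MFEI.** AMFE = MFE / length x 100 (kcal/mol per 100 nt);
   MFEI = AMFE / (GC x 100). MFE is negative, so the filter compares
   |MFEI| >= 0.85, the conventional reading of the published cutoff.
5. **Randomisation test.** p = (1 + #{shuffles with MFE <= observed}) /
   (1 + n) over n = 99 dinucleotide-preserving (Altschul-Erikson)
   shuffles; pass at p <= 0.1. Each locus derives its shuffle seed from
   the run seed and the locus coordinates (CRC32), so results are
   deterministic and independent of call order. 99 shuffles give a
   resolution of 0.01, an order of magnitude below the cutoff.
6. **Reporting.** A genomic locus is reported once, seeded by its most
   abundant read (ties to the lexicographically smallest sequence);
   reads falling inside an accepted precursor (the star, isomiRs) do not
   found further loci. The miRNA\* is reported when a tag exactly
   matching the predicted star sequence exists in any library.

**Classification.** A mature within 3 mismatches of a same-species
reference entry (best ungapped alignment over offsets with length
difference <= 2, overhangs counted as mismatches) is *known* and
inherits the reference family; within 3 of another species, *conserved*;
otherwise *novel*. Novel matures cluster into families by single linkage
at <= 2 mismatches — the conventional family criterion — and are named
`novel-<prefix>-miR-<n>` with letter suffixes per locus. Because the
"known" rule tolerates up to 3 mismatches, exact (0-mismatch) hits are
distinguishable through the reported `ref_mismatches` column.

## Differential expression

Counts are normalised as TPM = count / clean-library total x 1e6.
Fold change is log2(TPM_stress / TPM_ctrl); when one count is zero a
pseudocount equivalent to one raw read in the zero library is added to
both sides (applied only then). Significance uses the exact Poisson
model for unreplicated libraries: conditional on x counts in a library
of N1 clean reads, the count y in a library of N2 clean reads follows

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

a negative binomial with x+1 successes and failure probability
N2/(N1+N2); tails are evaluated through that law in a numerically stable
form (scipy's regularized-beta backend), accurate for counts up to 1e7.
The two-sided p doubles the smaller tail (capped at 1), chosen for
monotonicity in |x − y|. Note the test conditions on x, so it is not
symmetric under exchanging (x, y).

Per genotype, a miRNA is **ND** below 1 TPM in both conditions, **up**
(resp. **down**) at log2FC >= 1 (<= −1) with p <= alpha, else
**unchanged**. The default alpha is 0.05 — the threshold that gates the
headline drought-response counts in this analysis tradition — with 0.01
(the alternative convention) one config key away. The two-genotype
pattern maps to `up_both`, `down_both`, `up_T_down_S`, `down_T_up_S` or
`mixed_or_unchanged` (T = tolerant, S = susceptible genotype). No
multiple-testing correction is applied, matching the unreplicated-
library practice this pipeline reproduces.

## Phased tasiRNA detection

Only exact-length 21-nt tags with total abundance >= 2 participate.
Minus-strand starts are projected to forward coordinates shifted +2 nt —
the RNase III 2-nt overhang places the complementary strand's products
two positions upstream of the register. A window of 11 cycles x 21 nt =
231 nt is anchored at every occupied start; within it, the register with
maximal occupancy is chosen (ties to the smaller offset) and scored with
the exact hypergeometric upper tail

    P(X >= k) = sum_{x=k}^{min(n,m)} C(m,x) C((p−1)m, n−x) / C(pm, n)

for n occupied positions among pm = 231, of which m = 11 are in-register
(big-integer arithmetic; no approximation). Windows at p <= 1e-4 are
kept; overlapping or book-ended windows with equal register (mod 21) are
merged, keeping the minimum p. The reported TAS interval pads the 231-nt
window by 10 nt per side to 251 bp — the package's reconstruction of an
11-cycle register inside a 251-bp locus; both numbers are configurable
and no equivalence with any external tool's internal geometry is
claimed. No correction across windows is applied (fixed threshold).

**Trigger (phase-initiator) assignment.** For each candidate miRNA, the
target scanner predicts sites on the TAS sequence (searched with a 40-nt
upstream extension, since the site's 3' half reaches past the cleavage
point). The cleavage position is the transcript base paired to miRNA
nucleotide 10; an assignment requires that position to equal the first
phased position (D1) exactly — no slack, which is what makes the 10th-nt
rule informative. The hit model is `two_hit` when a second predicted
site of the same family cleaves on a register boundary (equal to D1 mod
21); requiring two sites to cleave at D1 itself would be geometrically
impossible. Among competing miRNAs the lowest penalty score wins, ties
to the lexicographically first id.

**Nomenclature.** Observed phased units are named
`<TAS>-siR<family>-<5'|3'>D<n>(<+|->)`: D-indices count registers
outward from the cleavage site starting at 1, the prefix gives the
processing direction, the suffix the strand. Duplicate sequences within
a cluster are reported once.

## Target prediction

Gapless scanning of every transcript window of miRNA length in the
antiparallel register. Per miRNA position (1-based from the 5' end):
Watson-Crick pair 0, G:U wobble 0.5, mismatch 1.0; penalties double
within positions 2-13 (the pairing-critical region); the site threshold
is 3.0. Runs of overlapping qualifying windows collapse to their score
minimum (leftmost on ties). A true mismatch — wobble excluded — at
positions 9-11 predicts translational inhibition; otherwise cleavage.
The published tools this scheme condenses print thresholds but not their
scoring formulas; the table above is the simplest published-style
penalty scheme and is documented rather than claimed equivalent. Target
accessibility (ensemble-energy) scoring and gapped alignment are out of
scope.

## Synthetic data generator

The generator is the package's test harness: it plants loci whose
ground truth is known exactly, then emulates the sequencing process.

* **MIR loci.** Precursors are built as extension-stem + mature + loop +
  star + complementary extension (arm chosen at random), with GC-biased
  stems (60% GC), G/C clamps at the duplex anchors, helix ends and
  around every designed defect, and loops drawn from {A, C} so the
  terminal loop cannot zip shut. Designed mismatches (0-4 per locus,
  uniform) are identity substitutions — a base never pairs with itself,
  not even as a wobble — spaced >= 4 nt apart; an optional single 1-nt
  star-side bulge is inserted with probability 0.2. These constraints
  exist so the thermodynamic MFE fold reproduces the designed pairing:
  isolated weak pairs between close defects do not close
  thermodynamically, which would corrupt the planted duplex. Planted
  precursors are >= 60 nt (extensions of 10-18 nt per side), and the
  designed star obeys the 2-nt 3'-overhang geometry by construction.
* **TAS loci.** A trigger site (reverse complement of a planted,
  always-expressed mature) is placed so its cleavage point — opposite
  trigger nucleotide 10 — starts 4-6 consecutive 21-nt phased units; 40%
  of loci carry a second in-register site downstream of the units
  (two-hit configuration).
* **Contaminants.** Verbatim genomic copies of the shipped synthetic
  t/rRNA fixtures, with expressed fragments, so the contaminant filter
  is exercised by construction.
* **Background.** 500 fragments of 16-30 nt (uniform) at random
  non-planted positions — degradation-like noise. Only 1/15 of them are
  exactly 21 nt, which keeps the density of phasing-eligible background
  reads low, as in real degradation products.
* **Count model.** Per-locus library counts are Poisson(lambda x
  multiplier), with base means lambda ~ Uniform(20, 100) and stress
  multipliers per drought class: 4x up, 0.25x down, (4x, 0.25x) and
  (0.25x, 4x) for the genotype-contrasting classes, 1x unchanged; the
  ND class is silent in the tolerant genotype and 0.25x in the
  susceptible one. A 4x effect is a 2 log2-fold change — comfortably
  past the >= 2-fold reporting threshold. Poisson (not negative
  binomial) keeps the significance test exactly calibrated on its own
  generative model; reads carry no sequencing errors since mapping is
  exact-match. Star reads are emitted at 10% of the mature mean; 2% of
  reads carry an injected N or seven sub-Q13 bases to exercise the
  quality filter. Reads are insert + adapter truncated to 36 nt at
  constant quality.

**What passing tests show — and don't.** End-to-end recovery on this
generator demonstrates the internal consistency of the chain: the rules
as implemented recover structures planted to satisfy those rules, at
realistic coverage, against random-sequence background, and reject
contaminants and background. It does not demonstrate performance on real
genomes (repeat families, near-identical paralogs, heterogeneous
processing, sequencing error, nucleotide composition) — none of which
the generator emulates. One caveat is inherent to the count model: for a
down-regulated locus with base mean near 20, Poisson sampling
occasionally produces count pairs that genuinely look unchanged, so
perfect per-scene category recovery is a high-probability event, not a
certainty.

## Numerical conventions and tie-breaks

* Coordinates are 0-based half-open internally; GFF3 output is 1-based
  inclusive.
* Mature selection: highest abundance, ties to 5'-most/lexicographic
  order; register selection: maximal k, ties to smaller offset; merged
  cluster p: minimum of members.
* All randomness flows from a single seed: numpy for counts, Python
  `random` for sequence construction, CRC32-derived per-locus seeds for
  shuffles. Identical seed and config give byte-identical outputs.
* Degenerate inputs: GC fraction 0 or 1 makes MFEI undefined (error);
  sequences under 4 nt cannot be dinucleotide-shuffled (error); an empty
  reference set classifies everything novel; precision on an empty call
  set is reported as 1.0 (0/0 convention).

## Problem sizes

The validation scene is a 100-kb genome with 20 MIR, 5 TAS and 5
contaminant loci plus 500 background fragments across 4 libraries
(~35k reads each) — desk-scale sizes at which every stage, including
99-shuffle randomisation for each surviving candidate, completes in
about a minute on one core. The statistic oracles run exhaustively
(all count pairs up to 200; full enumeration of position subsets for
the phasing tail at phase 3).

## Known limitations

* The hairpin-trimming heuristic is this package's own (documented
  above); equivalence with any specific discovery tool is not claimed.
* Target scoring omits accessibility/UPE energetics and gaps.
* Libraries are treated as unreplicated by design; no dispersion
  estimation or multiple-testing correction is offered.
* The contaminant filter is exact-substring only.
* miRNA classification reference sets ship as small synthetic fixtures;
  real analyses should point the config at full reference FASTA files.
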