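# Methods

`mirburst` implements an evidence-based miRNA analysis pipeline for
repeat-rich insect genomes: discovery of precursor hairpins from small-RNA
read stacks, authenticity statistics (folding stability, processing
precision, biogenesis-knockdown response), cross-species conservation and
mature-region variation, tissue-specificity calling, and local-duplication
scanning.  Every stage is exercised against a synthetic-data generator that
plants full ground truth, so the pipeline's operating characteristics
(sensitivity, precision, calibration) are measured, not assumed.

## The folding model

Secondary structure is predicted by a weighted Nussinov dynamic program:
the nested (pseudoknot-free) structure minimising the sum of base-pair
weights GC = −3.0, AU = −2.0, GU = −1.0 kcal/mol-equivalents, with a
minimum hairpin loop of 3 nt.  Ties are broken deterministically (pairing
the 5′-most free base beats leaving it unpaired; the 5′-most partner wins).
This model is fully specified and brute-force verifiable — the test suite
checks it against exhaustive enumeration of all nested structures for
sequences up to 12 nt — and it ranks hairpins well, but its energies are
not thermodynamic free energies: absolute MFE values from nearest-neighbour
models are not comparable and are not targets.

Because every admissible pair is stabilising, the model pairs aggressively:
long windows fold into dense nested scaffolds, and one or two spurious
pairs routinely decorate otherwise clean hairpins.  Two consequences shape
the pipeline:

- **Hairpin-shape testing** (`fold.is_hairpin`) requires a single ladder —
  pairs sorted by 5′ index have strictly decreasing 3′ partners; bulges and
  internal loops pass, multiloops fail.  Before applying it, the discovery
  path removes helices shorter than 3 pairs (`discover._drop_short_ladders`):
  a 1–2-pair helix is thermodynamically marginal under any realistic model
  and, under maximal pairing, almost every random window grows a few.
- **Candidate excision** scans nested sub-windows anchored at the read
  stack (largest first) rather than folding the full 110-nt-extension
  window once: the full window's global optimum usually buries the
  precursor hairpin inside larger background structure.  The first
  sub-window whose stack-overlapping ladder refolds into a clean single
  stem-loop is taken.

Folding significance uses dinucleotide-shuffled controls
(Altschul–Erickson Eulerian-walk shuffling, exact dinucleotide counts, end
bases preserved): `z = (E − mean E_shuffled)/sd(E_shuffled)`.  A candidate
window passes when `z ≤ −1.5` and `E ≤ −0.2 × length`.  These two numbers
are package defaults (the folding-stability criterion has no published
numeric value); they were chosen so that planted hairpins (z typically −4
to −10) pass with a wide margin while random background windows (z near 0,
sd 1) pass at a few percent — the permutation-calibrated score cutoff
removes the remainder.  Discovery computes z with 30 shuffles per window
(100 in the standalone `mfe_z` default) purely as a cost/precision
trade-off at the rejection thresholds used.

## Discovery and the evidence score

Collapsed reads (copy number ≥ 3 after QC, following the read-processing
conventions of small-RNA studies: per-base Phred ≥ Q20, ≤ 3 Ns, 18–30 nt
after 3′-adapter trimming, low-complexity reads removed) are mapped to both
genome strands at 0 mismatches; reads with more than 5 genomic hits are
discarded as repeat-derived multimappers.  Overlapping same-strand hits
form read stacks; each stack is excised with 110-nt extensions on either
side, folded and filtered as above.  All same-strand reads overlapping the
trimmed window are attached to the candidate — the 5P and 3P stacks of one
precursor must see each other for duplex evidence.

Each candidate receives a three-part score:

- `S_reads = log2((n_c + 1)/(n_i + 1))`, where `n_c` counts (copy-weighted)
  reads lying fully in an arm with 5′ ends within ±2 nt of their arm's
  modal 5′ end, and `n_i` counts all other reads.  Arms are defined from
  the hairpin's innermost pair with 3 nt of slack into the loop, so the
  imprecise 3′ ends characteristic of real Dicer products do not evict
  reads from their arm.
- `S_duplex = +2` if the modal 5P and 3P products form a duplex on the
  structure with a 2 ± 1 nt 3′ overhang on both strands (the RNase III
  signature), else −2.
- `S_struct = −z` from the folding-stability test.

The score cutoff is not fixed: 100 rounds of permutations re-draw read
positions uniformly within each window and rescore (structure unchanged),
and the signal-to-noise ratio `N_real(≥c)/mean N_perm(≥c)` is tabulated
over cutoffs; the smallest cutoff reaching S/N ≥ 10 is used.  On the
default simulation this lands near 5–6 and yields sensitivity and
precision ≥ 0.9 against planted truth; on signal-free libraries the same
procedure yields ≤ 1 false call per run on average.

Candidates explaining the same locus are collapsed before calibration:
two candidates are duplicates when their loci overlap ≥ 20 bp (either
strand) and they cover ≥ 50% of the smaller span or share ≥ 50% of the
smaller one's read mass.  The read-sharing clause matters because a
hairpin's 3′ arm is the reverse complement of its 5′ arm: arm reads map to
both strands of the locus and would otherwise seed a shadow call.

The homology path maps reference matures (≤ 3 mismatches, both strands),
excises and folds the same two windows, and keeps hairpin hits scoring
`50(1 − mm/len) + 50 × (fraction of mature bases paired) ≥ 70` — a 0–100
surrogate scale whose default threshold is a package choice, configurable.
Sequence- and homology-derived calls merge on ≥ 50% reciprocal locus
overlap, with provenance recorded.  Conserved/lineage-specific
classification requires zero mismatches at mature positions 2–8 (the seed)
and no mismatch run longer than 2 elsewhere, against the reference set in
an ungapped sliding comparison.

## Expression, knockdown, tissue specificity

Expression counts are copy-weighted sums of reads whose 5′ ends fall
within ±2 nt of an annotated mature 5′ end; multi-compatible reads split
1/k.  TPM = count/library size × 10⁶; expression groups use a strict
`TPM > cutoff` rule (default 10; 5 and 15 produce nested groups).

Processing precision (p5, p3) is the copy-weighted fraction of an arm's
reads whose 5′/3′ end coincides exactly with the annotated mature end,
with miRNAs ranked so percentile 1 is the most precise.  Precision is
measured on all mapped reads (collapse floor 1): the copy ≥ 3 floor
preferentially deletes jittered end variants of lowly expressed miRNAs and
would inflate both fractions.

The knockdown analysis library-size-normalises, adds a pseudocount of 1 to
both sides, and reports per-row log2 fold changes, class means, ECDFs, and
Mann–Whitney tests of each control class against miRNAs.

Tissue specificity uses a one-vs-aggregate contrast: for each
(miRNA, tissue), Fisher's exact conditional test on the 2×2 table of
(assigned, unassigned) counts in that tissue's library versus the pooled
other libraries, Benjamini–Hochberg across all tests, flagging at
q < 0.05 with a ≥ 4-fold normalised change in the "higher" direction.
The FDR and fold-floor defaults are package choices.  The exact
conditional test is valid when counts within a row are Poisson across
tissues; strong overdispersion between biological replicates would
require a dispersion-aware test and is out of scope here.

## Cross-species analysis

Sister-species collapsed reads align ungapped to precursor sequences with
≤ 2 mismatches, sense orientation only (mature reads are sense-stranded;
antisense alignment would pour each arm's reads into the opposite arm's
pileup).  A read contributes only to the precursor(s) it matches with the
fewest mismatches, so paralogous family members do not contaminate each
other.  A precursor is "detected" with ≥ 1 aligned distinct read
(configurable).  Variants are called per mature position at coverage ≥ 10
and modal non-reference allele fraction ≥ 0.5, never within the first or
last 3 mature bases (un-templated end modifications).  Contingency tables
contrast variant incidence between conserved and lineage-specific miRNAs
and, within lineage-specific, between expression groups; the Pearson χ²
(df = 1) is reported without Yates' correction by default (both provided).

## Duplication scanning

All-vs-all Smith–Waterman local alignment (match +1, mismatch −2, gap open
−5, extend −2, a gap of length L costing open + (L−1)·extend) with
Karlin–Altschul E-values (λ solved from the scoring scheme; K fixed at
0.35, a documented approximation absorbed into the configurable E-value
threshold).  Pairs with E < 10⁻⁵ and > 50% coverage of the shorter
precursor are similar; connected components define families;
majority-rule consensus is built over glocal alignments to the longest
member (ties take the alphabetically first base and are flagged).
Divergence is the percentage of non-identical alignment columns, gaps
counted as mismatches by default.

Flank scanning extracts ± 50 kb around each precursor and aligns the
precursor glocally (query global, target local) against both strands,
reporting non-overlapping hits at ≥ 60% identity with edge-to-edge
distances binned at 5 kb over 0–50 kb; hits overlapping the original span
are excluded.  The identity floor replaces E-values here because the
search space per flank is small and fixed.  The alignment engine is a
row-vectorised affine-gap DP over the target axis; horizontal gaps use a
single-opening prefix-scan closed form, valid because open ≤ extend ≤ 0
makes merged gaps optimal.

## The synthetic-data generator

`synthio` plants precursors of the form
`flank5 + mature5P + loop + revcomp(flank5 + mature5P)` (16 + 22 + 15 + 38
nt = 91 nt) in i.i.d. uniform-ACGT scaffolds: a perfect stem with the 3P
mature defined as the reverse complement of the 5P mature shifted 2 nt,
leaving the canonical 2-nt 3′ overhang on both strands of the Dicer
duplex.  Two constructions keep planted precursors clean single stem-loops
under the maximal-pairing fold: the loop is poly-C and the last four
mature bases are A/T-only, so the loop cannot pair with itself or with the
stem-loop junction.  Family copies diverge by structure-preserving
mutation — stem positions mutate mostly as compensatory pair replacements,
a configurable minority as one-sided mismatches, the loop untouched —
emulating the purifying selection on folding that real duplicated
precursors experience; the firing rate is rescaled (boost 1.25) so the
realised per-base divergence tracks the configured rate (0.13 by default,
the regime where duplicate divergence distributions peak).  Families are
planted in tandem with spacings drawn from an exponential (scale 5 kb,
clipped to 0.1–50 kb), so the edge-to-edge distance distribution has its
mode below 5 kb.

Reads: 22-nt matures at a 4:1 5P:3P ratio, 5′ ends exact with probability
0.9 (else ±1–2 nt), 3′ ends exact with probability 0.5 (else ±1–3 nt),
log-normal (σ = 0.8) abundances, constant Q30 qualities, 3′ adapter
appended.  30% of reads are genomic background fragments, half of them
drawn from a small pool of "degradation hotspot" loci: uniform singleton
fragments would almost never survive the copy ≥ 3 collapse, and the
hotspots provide the decoy read stacks the permutation calibration must
reject.  The knockdown simulator scales miRNA rows by 2^x,
x ~ N(−1.04, 0.3), control classes by 2^y, y ~ N(0, 0.3), Poisson-resamples
both, and assigns both libraries the same library size (the modelled
small-RNA classes are a minor fraction of total depth, so the knockdown
does not shift the normaliser).  The sister species applies i.i.d.
substitutions at rate 0.01 and records every substitution inside a mature
span as variant truth.  Tissue profiles draw from a shared Gamma–Poisson
with flagged miRNAs boosted 25-fold in their tissue.

What the generator does **not** emulate: transposable-element landscapes
(multimapper filtering is exercised with explicit repeated plantings in
tests, not a TE model), sequencing errors beyond end jitter, piRNAs, the
27–28-nt read population, isomiR edits, expression correlation between
tissues, or biological replicates.  All planted precursors sit on the
forward strand; reverse-strand handling is exercised by explicit
reverse-complement reads in unit tests.  Passing recovery tests therefore
demonstrates the pipeline's logic and calibration under a clean,
controlled model of the data — not robustness to every artefact of a real
library.

## Reproducibility and problem sizes

All randomness flows through per-stage generators derived from one global
seed by stable hashing of stage names, so identical configurations produce
byte-identical outputs and any stage can be reproduced independently of
execution order.  The default study simulates 60 precursors (6 tandem
families of 3, the rest singletons, 12 conserved) on four 150-kb
scaffolds with one 20,000-read library; noise calibration uses 50
signal-free 20-kb/2,000-read libraries; the knockdown analysis uses 350
miRNA and 3 × 150 control rows.  These sizes give the recovery statistics
reported by `scripts/acceptance.py` stable margins while keeping a full
run in minutes on one core.

## Known limitations

- The Nussinov energy model over-pairs; all shape decisions are therefore
  comparative (z-scores, ladder structure), never absolute energies.
- The evidence score is a defined surrogate with interpretable components,
  not a probabilistic posterior; its cutoff is meaningful only through the
  permutation S/N calibration.
- Fisher's exact test for tissue specificity assumes within-row Poisson
  sampling across libraries (no biological-replicate overdispersion).
- The K = 0.35 constant scales all E-values by a common factor; rankings
  and the calibrated threshold are unaffected.
- Cross-species detection is ungapped; indel variants are out of scope.
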