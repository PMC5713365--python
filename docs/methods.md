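# Methods

This note documents the statistical conventions, numerical choices and
simulator design behind mitocomp, and states what the synthetic-data tests
do and do not demonstrate about real data.

## Coordinates, strands and the reference annotation

All coordinates are 1-based and fully closed (GenBank convention); a feature
whose end precedes its start wraps the origin of the circular molecule. The
deposited sequence is treated as the heavy/majority strand; light-strand
("L") features are reverse-complemented before any codon-level analysis.
Gene names are funnelled through a versioned alias table
(`config.GENE_NAME_ALIASES`) because depositor naming is inconsistent
(ND1/nad1, COI/cox1, s-rRNA/12S, tRNA-Ser(AGN)/trnS1, …).

The packaged reference table transcribes the published annotation of the
*C. meridianus* mitogenome (GenBank MG518617) verbatim. One internal
inconsistency of the published report is preserved rather than repaired: its
per-class summary gives a PCG total of 11,186 bp while the per-gene sizes it
lists sum to 11,190 bp. The per-gene annotation is taken as ground truth, so
this package reports 11,190.

## Composition and skews

AT and GC skew are computed on the deposited strand regardless of the strand
of individual genes: a single per-class skew value is only well defined
under one fixed strand convention, and this is the convention mitogenome
reports use. Overlapping features contribute their full spans to their own
classes, so class sizes match per-feature sums (bases in an overlap are
counted once per class). A skew whose denominator is zero is reported as
missing (NaN), never as 0. Report tables round half-up, AT% to 1 decimal and
skews to 2; full precision is kept internally. Note that the genome GC skew
reconstructed from the published *rounded* base fractions is −0.245, exactly
on the rounding boundary between −0.24 and the published −0.25; tests
therefore hold skews to a ±0.01 band unless raw counts are available.

## Codon usage

The genetic code is fixed to NCBI translation table 5 (invertebrate
mitochondrial). Stop classification follows CDS length mod 3: remainder 0
requires a terminal TAA/TAG, remainder 2 a terminal "TA" (token `TA*`),
remainder 1 a terminal "T" (token `T**`); anything else is a hard error
naming the gene. RSCU is computed on codons pooled across the 13 PCGs,
start codons included as ordinary codons and terminators (complete or
incomplete) excluded; synonymous families follow the isoacceptor split
(Ser → AGN/UCN, Leu → CUN/UUR), so family sizes are 4,4 and 4,2. The mean
RSCU over an observed family is exactly 1 by construction.

## Ka/Ks (NG86)

Site counting is fractional with one deliberate convention: at each codon
position the synonymous fraction is renormalised over the *non-stop*
alternatives, so every aligned codon contributes exactly three sites and
N + S = 3 × codons holds identically. Codons differing at 2–3 positions are
resolved by enumerating all minimal substitution pathways, discarding
pathways that pass through a stop codon and re-weighting the survivors
equally; in the (rare, degenerate) case that every pathway is blocked the
codon is skipped from the difference counts with a warning. Proportions are
Jukes–Cantor corrected (K = −3/4·ln(1 − 4/3·p)); p ≥ 3/4 is flagged as
saturated and the ratio reported as missing rather than complex. Estimates
are symmetric in their arguments and are cross-checked in the test suite
against an independent brute-force pathway-enumeration oracle to 1e−9.

Codon-aware alignment translates both CDSs (incomplete terminal codons
stripped first), aligns the amino-acid sequences globally with fixed scores
(match +1, mismatch 0, gap open −5, extend −1, no substitution matrix) and
back-translates; gap columns are excluded downstream. For equal-length pairs
at ≥85% amino-acid identity — the regime of congeneric mitochondrial
proteins, and of all simulated data here, which contains no indels — the
ungapped pairing is returned directly: under these scores a gap run costs at
least 10 while a mismatch only forfeits a +1 match, so near-identical
equal-length pairs cannot profit from gaps. This avoids quadratic DP on
multi-kilobase genes.

Per-gene profiles average **ratios** over species pairs (mean-of-ratios);
the alternative (ratio of mean rates) is not computed, and the convention is
recorded in the profile's metadata and in report headers.

## Spacers, gene orders and rearrangements

The intergenic spacer between consecutive features is
`start(downstream) − end(upstream) − 1`; the origin-wrapping adjacency adds
the genome length. This convention reproduces every signed value in the
reference annotation's IGS column and yields the exact conservation law
Σ sizes + Σ signed gaps = genome length, asserted on the fixture and on
1,000 random synthetic layouts. "Long" spacers are flagged at a configurable
threshold, default 50 nt — reports on this genome treat its 62/147/174 bp
spacers as long while leaving a 7 bp one unremarked, so the cut sits between
those.

Gene orders are circular signed permutations of the 37-gene alphabet,
canonically rotated to start at trnI; the control region is excluded from
the permutation (control-region boundaries are unreliably annotated) but
kept for gap accounting. Breakpoints are query adjacencies absent from the
reference, reading direction closed. The moved-gene set is the smallest
subset whose removal makes the orders equal up to rotation, found
exhaustively up to 4 genes (mitogenome rearrangements of interest involve
very few genes); ties at minimal size prefer tRNA movers, then lexicographic
order. Classification: strand flip → inversion (in place) or
inverted-translocation (if also moved); same strand → shuffling when the
shorter circular arc between old and new insertion slots crosses no PCG,
translocation otherwise.

Identifiability caveat: a single gene that jumps over exactly one neighbour
is an adjacent transposition, equally explainable by the neighbour moving
the other way; no detector can name the mover, and the tie-break then
prefers the tRNA. The recovery simulations therefore draw moves with
displacement ≥ 2, where single-gene moves are uniquely identifiable (the
detector then scores 100/100).

## Synthetic genomes

The generator emulates the statistical structure of an AT-rich insect
mitogenome. Defaults mirror the reference annotation: per-gene lengths,
start codons and stop tokens from the packaged table; genome composition
target (A, C, G, T) = (0.452, 0.1606, 0.0974, 0.29); spacers and control
region drawn from a D-loop-like composition (0.531, 0.171, 0.054, 0.244 —
AT 77.5% with strong positive AT skew), echoing the elevated AT content of
real control regions and spacers; gene order ancestral unless rearrangement
events (move, inversion, TDRL) are applied. All randomness flows from one
`numpy` generator seeded by the spec, so identical specs give byte-identical
FASTA/TSV/GenBank output.

Coding sequence is sampled codon-wise from a product distribution over bases
*calibrated* by fixed-point iteration so that, conditional on not producing
a stop codon, the realised base frequencies hit the target (naive rejection
would undershoot A by ~1% genome-wide). Light-strand genes are sampled from
the complement-swapped composition so the deposited strand stays on target —
matching real mitogenomes, where the minority strand shows mirrored codon
bias. An optional `codon_bias` parameter instead fixes the within-family
weight of the NNA codon in four-codon families (weight b ⇒ RSCU(NNA) = 4b),
for experiments that need controlled synonymous bias.

Overlapping features share genome bases, with the downstream feature's
sequence winning the overlap. Consequence: in layouts mirroring the real
annotation, a gene whose terminator lies inside a downstream gene (atp8
under the 7 bp atp8/atp6 overlap) does not retain a legal stop — real
genomes satisfy both constraints simultaneously, the generator does not try
to. Codon-level contract tests therefore use overlap-free layouts; the
mirrored layout is used for coordinate-level statistics (gaps, totals,
conservation), which are exact. The origin-wrapping spacer must be
non-negative, as the record model does not represent features overlapping
across the origin.

`evolve_pair` derives related genomes by codon-substitution simulation:
proposals uniform over single-base changes in internal codons (start codon
and terminator are kept so the annotation stays valid), synonymous proposals
always accepted, non-synonymous accepted with probability ω, stop-creating
proposals rejected; `divergence` is the expected number of proposals per
coding site. Non-coding regions are left untouched — only Ka/Ks consumes
these pairs. At ω = 1 the estimated Ka/Ks is 1 within sampling error
(checked at 20,000 codons); ω = 0.3 is recovered within ±20% from 6,000
codons, with ~8% relative sampling noise at that size.

## Problem sizes and run times

The shipped analyses run at desk scale: annotation statistics are instant;
recovery simulations use 15 kb genomes, 6,000–20,000-codon genes for single
ω checks, and a 13-gene × 770-codon trio for the Ka/Ks profile. The full
test suite and the acceptance script each finish in a few seconds on one
CPU.

## Known limitations

- No ab initio annotation, assembly or primer handling; records must arrive
  annotated (GenBank or TSV).
- No sliding-window skews or replication-origin inference.
- The alignment stage targets closely related (congeneric) sequences; it is
  not a substitute for a proper aligner on deeply diverged proteins.
- NG86 only: no maximum-likelihood codon models, no branch- or site-level
  selection tests; duplicated-gene alphabets are rejected rather than
  resolved.
- The TDRL simulator edits gene order only; it does not model the sequence
  decay of duplicated copies, and the generator does not model indels or
  tRNA secondary structure.
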