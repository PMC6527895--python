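# Methods

## Model and assumptions

The package operates on a rectangular multiple sequence alignment over
`{A, C, G, T, N, -}` together with a partition of the samples into
Operational Phylogenetic Units (OPUs) — clades chosen on an independent
reference phylogeny. It does not build alignments or trees: the alignment
and the OPU assignment are inputs, assumed correct. All inference is
column-wise and character-based; there is no substitution model, distance
threshold, or likelihood anywhere in the identification path. This is
deliberate: the intended downstream use is a pharmacopoeial pass/fail test
in which a sample either matches a published state vector or does not.

Coordinates are 0-based half-open internally and 1-based inclusive in
every human-facing report (matrix column labels are `region:pos_1based`).

## Column classification

A column is **variable** iff ≥2 distinct states among `{A,C,G,T}` occur in
it, and **parsimony-informative** iff ≥2 such states each occur in ≥2
samples. `N` and `-` are both treated as missing by default: masked
regions are coded `N` upstream, and counting gap as a fifth state would
let indel-rich alignment stretches dominate the variability signal. A
`gaps_as_state` flag restores gap-as-character for users who want it.
IUPAC ambiguity codes other than `N` are demoted to `N` on read (with a
warning) rather than rejected, because upstream consensus callers emit
them routinely.

Percentages (%Var, %PIS) are `100·count/length` rounded **half-up** to two
decimals. Half-up (not banker's) rounding reproduces all 22 published
percentage cells of the barcode-candidate table from their integer
count/length pairs; `round()` would differ on exact ties such as 1/800.

## Window scan

Windows are non-overlapping tiles from column 0 (the "bins" of a circular
density plot), default 500 bp; a trailing partial window keeps its true
length as the variability denominator. There is no sliding step in v1.
The masked fraction is computed over *cells* (samples × columns), not
columns, because masking is applied per-region to subsets of samples; a
column-level alternative would call a window clean even when one taxon is
fully masked in it. Selection uses strict inequalities (variability
> 5%, masked < 3%), so 25 SNPs in 500 bp — exactly 5% — fails.

Refinement tiles a merged region into 50 bp sub-windows and keeps the
longest contiguous run of sub-windows with variability ≥ 2% (leftmost on
ties). The published account shows the outcome of refinement, not the
rule; end-trimming below a sub-window threshold is this package's
formalization, and the threshold is exposed as a parameter. If no
sub-window reaches the threshold the single best sub-window is returned
with a warning rather than an empty region.

## Haplotypes

Haplotype identity is exact string equality; `N` matches only `N`.
Ambiguity-aware collapsing can merge `A...` with `N...` or not depending
on comparison order, so exactness is the reproducible default; a
`collapse_missing` flag enables "identical over mutually non-missing
columns" with greedy merging in sample order, documented as
order-dependent. Network layout is out of scope — the package emits the
haplotype table plus a pairwise Hamming matrix (missing-aware) that any
network tool can consume.

## Diagnostic characters

Per OPU and column, the state is the shared nucleotide if all non-missing
members agree, requiring ≥1 observed member and a missing fraction ≤50%
(the `max_missing_in_group` default; the choice is exposed because no
published convention exists). Otherwise the state is `polymorphic`, or
`N` when unobserved. A fixed state is diagnostic iff it is absent from
the non-missing members of every other OPU — the strict "simple pure
diagnostic character". Columns are also retained when two OPUs carry
fixed, different states without either being diagnostic: such columns
separate profiles and feed profile-based identification.

Profile uniqueness is exact vector equality with `N` equal only to `N`
and `polymorphic` a symbol of its own. Two notions are reported
separately and should not be conflated: an OPU can lack any single
diagnostic site yet still have a unique profile (in the packaged matrix,
clade 6 is profile-unique with no private SNP).

## Minimal and redundant sets

The minimal-set search maximizes the number of profile-unique OPUs (the
full matrix's count is the ceiling — colliding OPUs are unresolvable by
any subset), then minimizes cardinality, breaking ties by lexicographic
column order for reproducibility. With ≤20 candidates (`exhaustive_limit`)
subsets are enumerated by increasing cardinality, so the result is a true
optimum; beyond that a greedy forward selection is used and labelled as
such in the report. On the packaged nine-position matrix the optimum is 7
positions for the same 7 unique OPUs.

Because a minimal set leaves one point of failure per OPU, the tool also
reports a redundant set: the minimal set united with up to `redundancy`
(default 2) diagnostic positions per OPU. On the packaged matrix this
reconstitutes all nine published positions, which suggests the published
barcode was chosen with exactly this robustness in mind.

## Classification

An OPU is compatible with a query iff at every position the query state
(A/C/G/T) equals the OPU state, where `N` on either side and `polymorphic`
matrix cells exclude nothing — those cells carry no exclusionary
information. The default mismatch budget is 0, matching the
pharmacopoeial framing; `max_mismatch` exists for degraded-DNA work.
Calls: `unique` (one compatible OPU), `ambiguous` (several), `no_match`
(none), `unidentifiable` (query all `N`; then every OPU is trivially
compatible). Missing data is monotone by construction: masking a query
state can only grow the compatible set.

## Synthetic data

The generator targets *exact* column-class counts, so the background is
constant (one random base per column) rather than drawn from a
substitution model, whose counts would only hold in expectation. Planted
diagnostic columns are fixed for the requested state inside the OPU and
for one different state outside. Noise columns are either singleton
substitutions (variable, not PIS) with the carrier drawn from an OPU with
≥2 members — so a lone minor allele can never be fixed in a whole OPU —
or PIS columns whose two minor-allele carriers sit in *different* OPUs,
making both OPUs polymorphic and the column non-diagnostic and
non-separating. Masked blocks overwrite chosen samples with `N`;
variable columns are placed outside masked intervals so the recorded
truth (variable/PIS counts, diagnostic columns) holds exactly. All
randomness flows from one mandatory integer seed. A Jukes-Cantor
star-tree mode exists for stress tests only; its counts are random.

What the simulations do not emulate: homoplasy, recombination,
rate heterogeneity along the genome, realistic indel structure, and
phylogenetic autocorrelation between columns. Passing the planted-recovery
tests therefore shows the diagnostic definition is implemented correctly,
not that real plastome alignments are free of convergent states that
would narrow the diagnostic set.

## Problem sizes and verification

The test suite and the acceptance script run on simulated alignments of
10–20 samples and 300–6,000 columns, window-conservation checks on 200
random alignments, minimal-set oracle comparisons on matrices with ≤12
candidate positions (brute force over all subsets), and 20 recovery
simulations — sizes at which the exhaustive oracles are exact and the
whole suite completes in seconds. The published worked example (nine OPUs,
nine positions, three market samples) is packaged verbatim as a fixture;
results that depend on the unpublished ~160 kb, 85-sample alignment (the
real-data bin counts and haplotype network compositions) are not asserted
anywhere and are treated as documentation only.

## Known limitations

- Diagnostics are as good as the OPU assignment; the package does not
  check that OPUs are monophyletic or even compatible with any tree.
- The strict diagnostic definition ignores near-diagnostic sites (fixed
  inside, rare outside); no frequency-based relaxation is offered.
- The greedy fallback for >20 candidate positions is not guaranteed
  minimal (it is guaranteed to reach the full matrix's uniqueness count
  when single additions can, and is labelled `greedy` in reports).
- Region-aware coordinates require the user's BED regions; the package
  does not snap region edges to gene annotations.
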