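# Methods

This note documents the models and procedures implemented in `clearclip`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that a
user extending or auditing the package should know about.

## Synthetic study generator (`clearclip.simulate`)

The generator builds a desk-scale analogue of a CLEAR-CLIP time-course
experiment so that every pipeline stage can be scored against planted
truth.

**Reference.** By default 60 mRNA transcripts of 800–2000 nt of uniform
random sequence, partitioned into contiguous 5'UTR/CDS/3'UTR blocks at
fractions (0.15, 0.50, 0.35); six ncRNA decoys (annotated rRNA/tRNA) of
120–300 nt at GC 0.72 — deliberately distinctive composition so that
mis-mapping into decoys is detectable, not a realistic rRNA model; 30
unique mature miRNAs of 21–23 nt.

**Planted interactome.** 300 interactions by default. Each site is
assigned a class with mix {canonical 0.60, 3'-supplementary 0.15, central
0.15, seedless 0.10} and a transcript region with mix {5'UTR 10.66%, CDS
47.01%, 3'UTR 42.32%} — the region distribution observed for chimeric
targets in deep CLEAR-CLIP libraries. Register-bearing classes overwrite
the site with the reverse complement of the corresponding miRNA segment
(canonical: nt 2–7; 3'-supplementary: nt 13–19; central: nt 9–15, all
1-based inclusive); seedless sites are loci verified to contain no 6-mer
complementary to miRNA nt 1–8 within ±20 nt. Sites are ≥ 100 nt apart and
≥ 60 nt from transcript ends so fragments and clusters stay separable.
miRNAs are assigned to interactions with lognormal(0, 1) weights —
small-RNA abundance is heavy-tailed in real libraries, and this is what
makes miRNA abundance and chimera frequency rank-correlate, a property the
pipeline is tested on. Each interaction follows one of five stage-peaked
activity archetypes (Gaussian bumps over the ordered time points, width
0.8 stages) with ±25% multiplicative noise; neighbouring stages therefore
share programmes, which is what the stage-correlation analysis expects of
real data.

**Libraries.** Default 50,000 reads per time point with class mix
chimera/CLIP/miRNA-only/ncRNA = 1.70/77.07/10.30/10.96 (normalized to sum
to one). A read is 3-nt degenerate barcode + insert + 3' adapter
`AGATCGGAAGAGCACACGTCT`, truncated at 100 nt. Chimeric inserts concatenate
the full mature miRNA with a target fragment that always contains the
planted site, in miR-first or miR-last orientation (default 50/50); target
fragment lengths are truncated-normal (mean 42, sd 10, min 16 nt) — the
mean reflects the observation that chimeras preferentially carry ~42-nt
mRNA fragments; the distribution shape itself is a stand-in, as no source
specifies one. CLIP inserts are site-containing fragments sampled with
probability proportional to interaction activity at the time point. PCR
duplicates (default rate 0.15) re-emit an existing (barcode, insert)
template; substitution errors are applied per base (default 0.005).
Quality is constant Phred 37; an optional `low_quality_frac` emits
all-Phred-8 reads to exercise the quality filter.

**What it does not emulate** (and hence what passing tests cannot show
about real data): realistic base composition and k-mer bias, indels,
spliced/genomic alignment ambiguity, isomiRs, ligation-sequence biases,
transcript-abundance-coupled CLIP background, and paired-end layout.

## Read preprocessing (`clearclip.prep`)

Mean-Phred ≥ 20 quality filter (the choice of 20 is ours; only "remove
low-quality reads" is specified by convention), leftmost adapter-prefix
trim (min overlap 5, mismatch rate ≤ 0.1), 3-nt barcode strip, collapse of
identical (barcode, sequence) pairs, 16-nt length floor. The degenerate
barcode is UMI-like, so collapsing on the pair preserves its purpose;
`collapse_on_sequence_only=True` reproduces a stricter sequence-only
collapse. Collapsing sums `dup_count`, making the operation idempotent.

## Chimera calling (`clearclip.align`, `clearclip.chimera`)

A bespoke Smith-Waterman (Gotoh) with blastn-like scoring — match +2,
mismatch −3, gap open −5, gap extend −2 — runs against candidates found by
exact-word seeding (word 11 for miRNA-in-read, 12 for transcript mapping).
E-values use ungapped Karlin-Altschul statistics computed for the score
matrix at import time: λ solves Σ pᵢpⱼ e^{λs_ij} = 1 and K comes from the
lattice-case series K = dλe^{−2σ}/(H(1 − e^{−λd})); the implementation
reproduces the published ungapped values (λ = 1.33, K = 0.621 for +1/−2)
and is unit-tested against them. A miRNA hit requires E < 0.4 **and** an
alignment spanning ≥ 16 nt of the read: at desk-scale database sizes the
E-value threshold alone admits chance ~11-nt matches (E ≈ 0.01), and the
16-nt floor — mirroring the global minimum read length — is the explicit
counterpart of the long exact word a short-query BLAST search implies.

Read splitting: the residual on one side of the miRNA is the target
candidate; < 6 nt on the minor side is tolerated as linker slack, more is
flagged ambiguous; residuals < 16 nt on both sides mean miRNA-only. Target
segments mapping to rRNA/tRNA/miRNA-locus transcripts remove the read as
ncRNA; equal-best-score hits on two transcripts flag it multimapped
(excluded from interaction building, counted in stats). Regions are
assigned by the interval midpoint. All coordinates are 0-based half-open
transcript space.

## Peak calling (`clearclip.peaks`)

Clusters are maximal sets of transitively overlapping intervals (≥ 1 nt;
abutting half-open intervals do not merge). The summit comes from a cubic
`scipy` `UnivariateSpline` over per-position coverage: interpolating
(s = 0) below 10 positions, smoothing (s = n) otherwise — the smoothing
switch stabilizes plateau coverage; ties on the 0.1-nt evaluation grid
resolve to the midpoint of the tied stretch, so constant coverage yields
the interval midpoint; height is floored at the observed maximum depth.
Significance is the Poisson upper tail with λ = total transcript reads ×
cluster width / transcript length, α = 0.01 — a uniform-placement null
stated explicitly here because the upstream literature it descends from
does not specify one. Replicates are pooled before clustering. One summit
per cluster is reported (`all_local_maxima` is deliberately out of the
default surface).

## Interactions (`clearclip.interactions`)

Per (miRNA, transcript), transitively overlapping target intervals merge;
`unique_reads` counts collapsed chimera records — PCR multiplicity is not
re-counted. Peak support = ≥ 1 nt overlap with a significant peak at the
same time point; interactions are built per time point and then joined on
(miRNA, transcript, overlapping site) into cross-stage groups, because the
alternative (merge first, support later) is not distinguishable from the
available description and per-time-point support is the more conservative
reading. Composition summaries weight by `dup_count` so fractions refer to
raw reads.

## Duplex energetics (`clearclip.energy`)

An intermolecular-only nearest-neighbor model: stacking free energies for
adjacent base pairs (Watson-Crick and G:U wobble; shipped as
`data/rna_stack.tsv`, Turner-style values for Watson-Crick stacks,
representative values for wobble stacks), length-dependent bulge and
internal-loop penalties with Jacobson-Stockmayer extrapolation beyond 6 nt
(1.75·RT·ln(n/6), RT = 0.616 kcal/mol), duplex initiation +4.09, terminal
AU/GU +0.45, loop span capped at `max_loop` = 15 (keeps the DP at
O(n·m·max_loop²) while longer loops would be irrelevant to miRNA-scale
duplexes). Loop asymmetry penalties and terminal-mismatch stacking are not
modeled. The DP minimizes over all non-crossing intermolecular pairings;
ties prefer more paired bases, then the leftmost start; a duplex that
cannot go below 0 kcal/mol is reported unstable (mfe = 0, no pairing).
Correctness is established against an exhaustive enumeration oracle
(lengths ≤ 8) and an independently structured memoized recursion (lengths
≤ 12), plus a rank-correlation cross-check against ViennaRNA's RNAduplex —
the parameterizations differ by design, the ranking must not. This module
does not attempt parity with RNAhybrid's exact parameterization; its
acceptance surface is internal consistency and the direction/significance
of the cognate-vs-shuffled gap. Target sequences for interaction scoring
are the planted/observed site extended ±10 nt (configurable) bounded by
transcript ends, since nuclease trimming truncates true sites.

The shuffled null reassigns every target a miRNA different from its own
(a derangement), found by seeded random transpositions; it fails fast when
one miRNA owns more than half the targets (no derangement exists — the
pipeline then skips the gap statistic rather than fabricating one). The
gap statistic is Δ = stat(real) − stat(null) for mean and median, with a
two-sided label-permutation p (default 10,000 permutations, seeded).

## Motif analysis (`clearclip.motifs`)

Seed-match density scans ±100 nt (configurable) around the ligation point
(target 5' end for miR-first, 3' end for miR-last) for the reverse
complement of miRNA nt 2–7, normalized per chimera; the control repeats
the computation after derangement reassignment. Enrichment is an explicit
ZOOPS k-mer procedure replacing MEME/Homer-style discovery: presence
counts (once per target) against background sequences drawn 5× from other
miRNAs' targets, hypergeometric upper tail, Bonferroni over 4⁷ tests,
α = 0.05, minimum 30 targets per miRNA. The opaque external "confidence"
filter of Homer-style pipelines has no public closed form and is replaced
by the corrected-p filter — a deliberate substitution. Registers slide the
k-mer along the reverse-complemented miRNA and report offsets with ≥ 6/7
matches as 1-based miRNA positions. The usage matrix takes, per (miRNA,
time point), the single best passing motif (mirroring one-motif-per-miRNA
reporting), requires a register and mean occurrence information content
≥ 1.5 bits/position (occurrences collected at ≤ 1 mismatch), and records
the proportion of targets carrying it at each covered miRNA position;
time points without 30 targets are NaN. Threshold knobs: 30 targets for
usage, 50 for cross-stage motif comparisons, both configurable —
descriptions of this analysis vary between "at least 30", "more than 30"
and "over 50", and the discrepancy is surfaced as configuration rather
than silently resolved.

## Temporal dynamics (`clearclip.dynamics`)

The interaction matrix holds peak height ÷ mRNA abundance (floor 0.1
abundance units against division blow-ups; abundance units are taken
as-is, making the ratio unit-agnostic; `log_ratio=True` gives
log₂(ratio+1) instead — the plain ratio is the default reading).
Missing heights are 0; interactions on transcripts absent from the
expression table are dropped and reported. Rows are z-normalized
(constant rows → zeros). The SOM is a batch Kohonen map: codebook
initialized from randomly drawn rows, Gaussian neighbourhood with radius
decaying linearly from max(grid)/2 to 1 over 50 epochs, assignment by
best-matching unit, fully seeded. The published-scale grid default is
26×25; desk-scale analyses use 8×8. The training schedule of the original
GEDI tool is unpublished, so the schedule above is this package's own,
stated choice; the topographic check (mean adjacent-tile distance < mean
random-pair distance) is asserted on every fit in tests. For archetype
recovery, tile mean profiles are clustered with k-means (no k-medoids
implementation is available in the supported environment; on 64 tile
means the two are interchangeable for this purpose). Synthetic archetype
fixtures use profile noise sd 0.15 in z-units — with four programs on an
8×8 map this is the level at which same-program pairs remain within
Chebyshev distance 2 at the stated ≥ 90% rate; it is a property of map
geometry, not of the algorithm, that higher noise spreads each program
over a ~4×4 tile block and lowers that fraction. Hierarchical clustering
(average linkage, Euclidean on z-rows) sorts rows by id before linkage so
leaf order is permutation-invariant, and exports Newick with merge-height
branch lengths.

## Validation statistics (`clearclip.validation`)

Two-sample KS on log₂ fold changes between disjoint transcript sets, with
exported CDF curves. Translational efficiency: size factors are fit by
median-of-ratios on the **combined** ribo+mRNA count matrix — per-assay
normalization cannot be invariant to a global rescaling of one assay,
which is a property TE must have — then TE = mean normalized ribo / mean
normalized mRNA, dropping transcripts with mean raw counts < 10 in either
assay (the floor is this package's documented choice). Differential
modeling (DESeq2/RiboDiff-style dispersion inference) is out of scope;
the module consumes count and fold-change tables from any upstream tool
or from the built-in simulators.

## Pipeline (`clearclip.pipeline`, CLI `clearclip`)

`run_all` executes simulate → prep → chimeras → peaks → interactions →
energy → motifs → dynamics. Each stage writes a manifest with a config
hash (computed over the config with the output location normalized away)
and the seed; `--resume` skips stages whose manifest matches. Outputs are
byte-identical across runs with the same config and seed. Exit codes:
0 ok, 1 user error, 2 internal.

## Problem sizes

Default test and acceptance analyses use: one 50,000-read library for
recovery/composition; 10,000 Monte-Carlo clusters and 100 planted sites
for peak calibration; 250 random pairs for the duplex oracles; 500
canonical interactions with 10,000 permutations for the energy gap; 12
miRNAs × 40 targets for register recovery; 400 interactions on an 8×8
grid for the SOM; 100 simulations for KS power. These sizes were chosen
so the full suite and the acceptance script each complete in about a
minute on a single CPU while keeping every statistic comfortably away
from its decision boundary.

## Known limitations

- E-value agreement with any specific BLAST build is not attempted; only
  the threshold semantics (< 0.4) are preserved.
- The duplex energy model is internally consistent but not calibrated to
  RNAhybrid/ViennaRNA absolute energies; published kcal/mol gaps from
  deep datasets are not comparable quantities.
- Genome-space (spliced) alignment, isomiR discovery, IDR-style replicate
  analysis and GO/KEGG annotation are out of scope; functional categories
  enter only as a user-supplied table for subset clustering.
- The generator's uniform-random transcriptome understates mapping
  ambiguity; multimapping handling is exercised by planted duplications
  in tests rather than by realistic paralogy.
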