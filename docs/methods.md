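# Methods

## Scope and model

`cohortviz` implements the computational core of a declarative visualization
toolkit for cancer cohort genomics: given tabular copy-number segments,
short variants and clinical metadata, a JSON view grammar describes how the
data flow through transforms onto genome-wide tracks, and a set of
reversible collection actions stratifies the sample axis with full
provenance. The package renders static scenes (SVG/PNG); interactive
navigation is modelled as state (`ZoomState`, bookmarks) rather than as a
GUI, which keeps every behaviour testable.

## Genome coordinates

Assemblies are ordered chromosome lists read verbatim from a `chrom.sizes`
file — order is significant, never natural-sorted, so the linear axis is
reproducible from the input alone. Coordinates are 0-based, half-open
(BED convention); 1-based inputs are shifted at the reader boundary via the
`one_based` option. The linearized genome axis concatenates chromosomes
with no gaps: the bijection is exact and interval lengths are preserved,
which the tests verify exhaustively on toy assemblies. Chromosome
boundaries are a rendering concern (boundary ticks), not part of the
coordinate model.

## Grammar and dataflow

The accepted grammar subset is closed: marks `rect|point|text|rule`,
channels `x x2 y y2 color opacity size text sample`, field types
`quantitative|ordinal|nominal|locus`, transforms
`filter|formula|flattenSequence|coverage|semanticZoom`, composition via
`layer` and `vconcat`. Anything outside the subset is a validation error
with a JSON path, never a silent ignore — a partial grammar that drops
properties silently would corrupt analyses undetectably. Inheritance is
per-channel override, and ancestor transforms run before a leaf's own.

Transform expressions are a closed, side-effect-free language (field and
parameter references, arithmetic, comparisons, boolean operators, `abs`,
`log2`, `pow2`, `min`, `max`) compiled through Python's `ast` with a strict
node whitelist; no user code is ever executed. Missing-value semantics are
uniform and explicit: arithmetic on missing is missing, predicates on
missing are false, division by zero is missing. These rules follow common
tabular conventions and are stated here because upstream descriptions of
such pipelines usually leave them implicit.

`coverage` computes the piecewise-constant sum of interval weights by an
event-point sweep, merging adjacent equal-valued pieces and omitting
zero-coverage gaps — the canonical minimal representation, chosen so that
equality against a per-base brute-force oracle is well defined. The tests
enforce that equivalence on random interval sets and on ≥50 random toy
cohorts of ≤100 kb genomes.

## Scales, zoom, and semantic zoom

Linear scales are affine maps with optional clamping; band scales divide the
range into equal, unpadded bands; the `locus` scale linearizes
`(chrom, pos)` through the assembly and then maps affinely, defaulting its
domain to the whole genome (the zoomed-out start state). Color defaults are
a fixed diverging blue–white–red scheme for signed copy-number values and a
10-color categorical palette; the choices are stable identifiers but
otherwise arbitrary.

Zooming multiplies the visible width by `1/factor` about an anchor that
keeps its relative window position, clipped to the full domain. Score-based
semantic zoom uses a count budget: at zoom level `z` at most
`ceil(budget × z)` items are shown, filled in descending score order with
ties broken by (position, id). This coupling function is the package's own
design: it is deterministic, yields nested visible sets (zooming in only
adds items), and bounds overplotting — the three properties that matter for
progressive disclosure. Scores come from a data column (e.g. CADD); the
package never re-scores.

## Collection actions and provenance

The sample axis is an ordered, grouped list. Actions (`filterCategory`,
`filterQuant`, `sortBy`, `retainFirstOfEach`, `groupByCategory`,
`groupByThreshold`) are pure: each returns a new state, so undo/redo is a
pointer into the action log and replay from the initial state is the
provenance contract. Quantitative sources are either metadata attributes or
locus probes (the covering segment's log2R/BAF/LOH at a position).
Decisions that were genuinely open and are fixed here: threshold grouping
puts strictly greater values in the upper group; missing probe values sort
last and fail quantitative filters; new group splits nest inside existing
groups; "highest-purity sample per patient" is expressed as
`sortBy(purity, desc)` + `retainFirstOfEach(patient)`. Bookmarks serialize
the action log, scale domains, view visibility and free-form Markdown notes
to JSON (schema shipped in `cohortviz/schemas/`).

## Copy-number mathematics

Copy ratios are held as linear R internally; files store `log2R` and the
conversion happens at I/O, because the purification formulas are written in
R. With purity *p* and tumor ploidy *ψ*:

- `purity_from_tp53(CN, VAF) = 2 / ((CN/VAF) − (CN − 2))` — exact inverse of
  the homozygous-mutation dilution `VAF = p·CN/(p·CN + 2(1−p))`; the tests
  check recovery to 1e−12 on a grid.
- `purifiedR = (p·ψ·R + 2(1−p)(R−1)) / (p·ψ)`; `purifiedBaf =
  f(b)/(f(1−b)+f(b))` with `f(a) = p − 1 + R·a·(2(1−p) + p·ψ)`. Purified
  BAF is clamped to [0, 1] — low purity plus extreme BAF can push the raw
  ratio outside the interval, and a clamped value is what the LOH
  transform expects. A zero denominator yields a missing value.
- `LOH = |BAF − 0.5| × 2`: 0 is full heterozygosity, 1 total loss.
- `mix` is the algebraic inverse of purification, used by the generator and
  the roundtrip tests (`purify(mix(x)) = x` to 1e−9 over a ≥1000-point grid
  of purity × ploidy × R × BAF).

The G-score summary processes amplifications and deletions separately:
segments qualify only when `|purified log2R| > 0.7` (strict), amplitudes
are clamped to 2.5, and the amplitude-weighted coverage is divided by the
number of samples in the group — the group size, not the number of aberrant
samples, so stratified groups get comparable profiles. Output is exact
breakpoint-partitioned intervals; a fixed-width binning post-step
(`GScoreParams.bin_size`) is available but off by default, since exact
intervals are the lossless representation and bin resolution is a display
choice.

The normal-panel blacklist includes a region when `|log2R| > 0.2` (strict)
in at least 3 panel samples; missing panel values count as no evidence.
Short variants are kept when CADD ≥ 10.0 (inclusive) or flagged
ClinVar-pathogenic — pathogenicity is an input flag column, not a database
lookup, keeping the package self-contained.

## Synthetic cohort generator

The generator emulates the table shapes of a multi-sample HGSC WGS cohort
on a 5-chromosome toy genome (≤1 Mb per chromosome, with `chr17` and
`chr19` present by name because the planted biology lives there). Per
sample, true (pure-tumor) segment values are planted first and the observed
`log2R`/`baf` are produced through `mix` at the sample's purity and ploidy,
so purification must recover the planted truth exactly; the TP53-like SSV's
VAF follows the homozygous-mutation relation, so the purity approximation
recovers the planted purity exactly. Default conditions: 12 patients with
1–3 samples each, purity uniform on [0.15, 0.95], ~40 % of patients
whole-genome duplicated (ploidy ≈ 3.1–3.9 vs ≈ 2.0), chr17-wide LOH in all
but a configurable number of outlier patients, tandem-duplicator patients
with many short high-amplitude segments plus a deleterious CDK12-like SSV,
25 passenger SSVs per sample with an exponential CADD tail, and a
114-normal panel with 5 planted artifact regions. Sizes are reduced from a
real cohort so the whole suite runs in seconds; the structure, not the
scale, is what the tests exercise.

Observed values carry no noise by default, making recovery tests exact; a
Gaussian jitter (`noise_sd`) is available for robustness experiments. All
randomness flows from a single seeded `numpy` generator and tables are
emitted sorted with lossless float formatting, so identical (config, seed)
produces byte-identical files.

What the generator does *not* emulate: read-level sequencing noise,
GC-wave artifacts, segmentation uncertainty, germline SNP panels, or
platform effects. Passing tests therefore demonstrate the correctness of
the mathematics and the pipeline plumbing on idealized inputs, not
robustness to real-world measurement error.

## Numerical choices and limitations

- Coverage sweep treats values within 1e−12 of zero as zero when dropping
  uncovered stretches.
- `purify_log2r` floors the log of a non-positive purified ratio at −10
  rather than erroring, since deep deletions under noise can cross zero.
- Label placement breaks equal-priority ties by extent start; kept labels
  occupy their unpadded extents and an incoming candidate is tested with
  its extent padded by the minimum gap.
- Scene determinism is guaranteed by construction (view order, then row
  order) and checked by byte-comparing SVG output.
- The grammar subset is intentionally partial; `hconcat`, conditional
  encodings, lazy window-keyed loading and GPU rendering are out of scope.
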