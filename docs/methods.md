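# Methods

This note records the models, conventions and numerical choices behind
`sdspatial`, and what the synthetic-data tests do and do not establish.

## Coordinates and containers

All internal coordinates are 0-based half-open `[start, end)`; BED emission
is native, and any 1-based format would be converted at the boundary.
Contacts live in a `BinInteractionSet`: one chromosome, fixed bin width,
one row per unordered bin pair with `binA_start <= binB_start`. Duplicate
unordered pairs are an integrity error at load time. Interaction *span* is
the difference of bin start coordinates, matching the triplet file content.

## Filtering

* Count and span thresholds are inclusive: "at least 15 counts" keeps 15,
  "at least 25 Mb" keeps exactly 25 Mb.
* A 20 kb bin overlaps an SD when the intersection is non-empty (1 bp
  suffices); no minimum overlap is imposed.
* `paralog_pairs` mode removes a row iff one bin overlaps an SD interval S
  and the other overlaps S's paralog (either orientation) — the signature
  of a short-range contact misread as long-range through mismapping.
  `any_sd` mode tests each bin against the union of SD intervals and
  paralog intervals; its removal set is a superset of `paralog_pairs` by
  construction. Removal is reported both as interaction rows and as
  distinct genomic windows, since "removed bins" is ambiguous between the
  two tallies.

## Unique-k-mer mask and re-normalisation

The merged SD footprint is tiled into k-mers (k = 30) fully contained in a
footprint interval; a start position is *unique* when its k-mer has no
second occurrence in the genome within the edit bound. The default distance
is Hamming with `max_edits = 0` (exact hashing over all genome k-mers),
which is the right desk-scale default for synthetic genomes; substitutions-
only Hamming at larger bounds and a full Levenshtein mode (quadratic scan,
small genomes only) are available, preserving the "edit distance ≤ 2"
semantics of read mappers as an option. A read-pair is excluded when either
end lies in the footprint but starts outside the mask; ends outside SDs are
never a reason for exclusion.

Re-normalisation divides the observed filtered count of a bin pair at bin
distance d by `expected(d)` = total unfiltered count at distance d divided
by the number of possible bin pairs at that distance. This distance-only
expectation deliberately replaces the fragment-level normalisation model of
full Hi-C pipelines: the input is already normalised and the distance
stratum mean is the reproducible core of the correction. Strata with zero
expectation are dropped.

## Bundling

Two links are adjacent when the gap between their start-side bin intervals
and the gap between their target-side bin intervals are both ≤ 500 kb
(boundary inclusive; overlapping or touching bins have gap 0). Groups are
transitive single-linkage components of this relation; groups smaller than
the membership minimum (5) are discarded, and bundle regions are the
bounding spans of member bins. Single linkage reproduces the chained
merging of streaming bundlers whose exact behaviour is version-dependent; a
sorted-order greedy chaining mode is provided for comparison. The
implementation hashes links to grid cells of width gap+1 bins so that exact
single linkage needs pairwise checks only between neighbouring cells; an
O(n²) union-find oracle verifies it in the tests.

The default sweep preset is 12 configurations: count cut-offs {≥10, ≥15,
10–50} × span minima {10 Mb, 25 Mb} × SD handling {none, paralog-pair
removal}. The composition is a declared choice — three count options, two
spans and three SD modes would give 18, and the original 12 combinations
are not fully enumerated anywhere — so the preset is data-driven and fully
overridable; "adapted" bundling criteria after aggressive SD filtering are
likewise exposed as free parameters rather than hard-coded. Per-bin
frequency is the fraction of configurations whose bundle regions cover the
bin; core bins have frequency 1. Core bundles "mapping to the same target
sites" are candidates from the first configuration whose start and target
regions touch core bins and are matched within the bundle gap on both sides
in every other configuration.

## Monte-Carlo overlap test

Feature and bundle sets are merged before testing. The null relocates each
feature interval uniformly on the same chromosome, preserving sizes,
avoiding exclusion gaps and mutual overlap, by rejection sampling (longest
interval first, 1000 redraws per interval, 20 restarts of the whole set
before a placement error). With `b` = number of simulations whose overlap
is ≥ the observed value (inclusive, so p never returns 0),
`p = (b + 1) / (n_sim + 1)`; fold change is observed over the null mean and
is flagged undefined when the null mean is 0. The BH adjustment family is
exactly the set of categories passed to one panel call — family composition
is the caller's explicit declaration, since the original family size behind
any particular adjusted value is not recoverable. The suite verifies
calibration: under a null where features are themselves placed by the same
shuffler, p is uniform on the achievable grid (chi-square GOF over 1000
replicates at n_sim = 199).

## Minimum hypergeometric

For binary labels in ranked order, `HGT(b; N, B, n)` is the upper
hypergeometric tail of observing ≥ b labels in an n-prefix; mHG is the
minimum over all prefixes (1 by convention when B = 0), with the first
arg-min reported. The exact p-value `P(mHG ≤ m)` under uniform label
permutations is computed by lattice path counting: cells whose tail is ≤ m
block paths, and the surviving count at (N, B) is compared with C(N, B).
Path counts are exact Python integers at any N (no overflow, no log-space
error); only tail comparisons are floating point, guarded by a 1e-9
relative tolerance. The DP is verified against exhaustive enumeration of
all orderings for every N ≤ 10.

Ranking direction is genuinely ambiguous in the source description (bins
ranked "ascending" versus enrichment "within the highest scoring bins"), so
it is a parameter: the default `descending` puts feature-rich bins first,
and `ascending` is equally supported; results record the direction used.
Ties between bins with equal counts are broken by a seeded pre-shuffle of
the natural bin order before a stable sort, so genomic order cannot leak
into the ranking.

## Inversion reversal

Reverting `[s, e)` maps an interior interval `[a, b)` to `[s+e−b, s+e−a)`;
exterior intervals are unchanged. Intervals straddling a breakpoint are
rejected into a report rather than split — conservative and auditable,
since how the original coordinate recalculation handled straddlers is
unstated; a split mode (cut at breakpoints, remap the pieces) is available
behind a flag. Series application reverts events most recent first (the
paracentric before the pericentric event for the chromosome-7-style
history). Reverted link endpoints generally leave the bin grid (breakpoints
are not bin-aligned), so remapped interaction sets carry a flag that
relaxes the grid-alignment check; lengths and counts are always conserved.

## Profiles

* Span classes are half-open with inclusive lower bounds: <0.5, 0.5–1, 1–5,
  5–10, 10–25, ≥25 Mb. Every interaction credits its full count to both
  endpoint bins (the per-bin sums are not split between ends), and class
  fractions divide by the per-bin total; inactive bins are all-zero rows.
  Interaction intensity divides per-bin totals by the median over *all*
  tiling bins of the chromosome, and a zero median is an error.
* The G4 scanner defines a motif as four maximal G-runs of ≥3 separated by
  loops of 1–7 bases. Loops may contain G-runs shorter than the tract
  minimum but never a qualifying tract (maximal-run semantics); a long
  G-run is never split into tract + loop + tract. The loop bound is a
  declared convention — the motif's loop length is unspecified in its
  G≥3NxG≥3... form and unbounded loops are degenerate — and is
  configurable. Overlapping calls on one strand are merged; the minus
  strand is scanned as the C-pattern and reported on plus-strand
  coordinates, making the scanner exactly mirror-symmetric under reverse
  complement. Ambiguous bases never extend a tract.
* `count_track` assigns each interval to the bin containing its start
  (conserves totals; an overlap-assignment mode exists). GC content is
  computed over non-N bases, with all-N bins missing.
* Gene density p-values use `p = (1 + #{null ≥ observed}) / (n_sim + 1)`
  with uniformly re-placed same-length regions (gap exclusions honoured).
  The Fisher density comparison builds the 2×2 table
  `[[count_A, count_B], [windows_A − count_A, windows_B − count_B]]` with
  windows counted in 100 kb units — a declared convention, because the
  original contingency construction is not printed; its p-values are
  therefore not reproduction targets. Intron sets come from gaps between
  consecutive exons; significance on intron sizes is left to the caller
  (dichotomise-then-Fisher or rank-sum), since Fisher on raw lengths is
  undefined.

## Synthetic world

The generator's defaults state the world the analysis assumes:

* 20 kb bins; contacts `E[count] = 30 · d^(−1)` (d in bins) — a count of 30
  between adjacent bins with 1/d decay, the canonical intrachromosomal
  decay shape; Poisson noise on top when enabled, zero rows dropped.
* Similarity classes are realised as fixed per-pair substitution counts:
  3%, 1.5% and 0.5% of positions for the <98%, 98–99% and >99% classes —
  midpoints/representatives of the class intervals, since classes are
  defined only by identity thresholds.
* The demo world (56 Mb) plants one proximal group of three 1 Mb regions
  with pairwise separations >25 Mb, so group contacts survive the span
  filter between every region pair; the boost of 2000× lifts long-range
  group contacts to ~20–50 expected counts against a ~0.02 background,
  i.e. planted signal passes the ≥10/≥15 count cut-offs and the 10–50 band
  while background essentially never does. Artifact contacts between SD
  paralog bins get +40 counts. Six SD pairs (two per class, 40 kb) are
  planted inside the group regions, which also carry the synteny label.
* Mismapped read pairs are short-range contacts at an SD copy whose far
  end is reported at the homologous offset of the paralog; the true origin
  is recorded so recall is computable.

What a green synthetic test does *not* establish: the generator has no
fragment-level or coverage biases (contacts are conditionally independent
Poisson draws), no indels or rearrangements within SD copies (substitutions
only), no interchromosomal contacts, no realistic gene/repeat sequence
composition, and one chromosome per world (multi-chromosome analyses
compose independent single-chromosome worlds). Conclusions about real
Hi-C artifact structure, mappability or normalisation quality therefore do
not follow from these tests; what does follow is that each algorithm
implements its stated contract and that the statistical engines are
calibrated under their own null.

## Scaling choices in the shipped checks

The overlap-test panel in the demo pipeline uses 500 simulations rather
than 10000, and the gene-density examples use hundreds rather than 100000
— the estimators are identical and the defaults remain 10000/100000; the
reductions only keep the test suite and the acceptance run inside their
time budgets. The full-scale reproduction of published per-chromosome
tallies would require the original public Hi-C, SD and synteny downloads
and is outside the desk-scale scope.
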