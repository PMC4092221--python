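# sdspatial

Analysis pipeline for studying the distribution of **segmental duplications
(SDs)** in the context of higher-order (3D) chromatin organisation, at the
scale of a single chromosome. SDs are sequences >1 kb present at least twice
in a genome with >90% identity; they cluster in interstitial hubs, mediate
recurrent genomic disorders (e.g. the Williams-Beuren 7q11.23 deletion via
NAHR between flanking SD blocks), and — seen through Hi-C contact maps —
preferentially occupy chromosomal segments that maintain long-range spatial
proximity even after evolutionary inversions have torn them apart on the
linear chromosome.

The package is aimed at computational genomicists who want to reproduce or
extend this style of analysis: it implements the full chain from binned Hi-C
contact filtering to enrichment statistics, exercisable end-to-end on
synthetic data with planted ground truth (no downloads needed).

## What it computes

* **Hi-C filtering** (`sdspatial.hic`). Binned intrachromosomal contacts
  (20 kb triplets) are filtered by minimum normalised count (default ≥15),
  minimum span (default ≥25 Mb), and SD overlap — either removing
  interactions that bridge two SD paralogs, or any interaction touching an
  SD. A read-level alternative builds a unique-k-mer mask (30-mers over the
  merged SD footprint, unique within an edit bound), filters ambiguous read
  pairs, and re-normalises binned counts by the distance-stratified expected
  contact frequency of the unfiltered reads.
* **Bundling** (`sdspatial.bundling`). Long-distance interactions are fused
  into start-region/target-region bundles when ≥5 links fall within 500 kb
  on both sides (transitive single linkage; greedy chaining available). A
  threshold sweep over 12 filter configurations yields a per-bin coverage
  frequency; bins covered in *every* configuration form the
  threshold-independent core pattern.
* **Enrichment statistics** (`sdspatial.enrichment`).
  - Monte-Carlo base-pair-overlap test: features are relocated by a
    constrained shuffle (same chromosome, same sizes, non-overlapping,
    gap exclusions); with b simulations at or above the observed overlap,
    `p = (b + 1) / (n_sim + 1)`, fold change = observed / mean(null), and
    per-category p-values are Benjamini-Hochberg adjusted.
  - Minimum hypergeometric (mHG): for a ranked binary label vector,
    `mHG = min_n HGT(b_n; N, B, n)` over all prefixes, with the exact
    p-value `P(mHG ≤ m)` computed by path counting on the (n, b) lattice
    (exact integer arithmetic; no sampling).
  - Spearman rank correlation between binned tracks.
* **Inversion reversal** (`sdspatial.rearrange`). In-silico reversal of
  chromosomal inversions (reflection of `[a, b)` within `[s, e)` onto
  `[s+e−b, s+e−a)`), applied in series most-recent-first, remapping SDs,
  features and contact endpoints; breakpoint-straddling intervals are
  rejected and reported. Synteny blocks label bins for enrichment tests.
* **Profiles and tracks** (`sdspatial.profiles`). Per-bin span-size
  decomposition (six classes from <0.5 Mb to ≥25 Mb), interaction intensity
  relative to the chromosome median, G4 motif scanning
  (G≥3 N1–7 G≥3 N1–7 G≥3 N1–7 G≥3, both strands), GC content, per-bin
  feature counts, gene density with permutation p-values, Fisher exact
  density comparisons, and intron size statistics.
* **Synthetic data** (`sdspatial.synthetic`). Generates a chromosome with
  SD paralog pairs in three similarity classes (<98%, 98–99%, >99%),
  distance-decay contacts (`E[count] = c·d^−α`) with a multiplicative boost
  inside planted proximal groups, artifact contacts between SD paralog
  bins, mismapped read pairs with recorded true origins, genes with
  introns, Alu-like repeats, G4 motifs and synteny blocks — all
  deterministic given a seed.

## Worked example

`run_demo_pipeline` builds a 56 Mb synthetic chromosome in which three 1 Mb
regions, mutually >25 Mb apart, form one planted spatially proximal group;
six SD pairs (two per similarity class) are planted inside those regions,
which also carry the synteny label `cj2`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints

```
links simulated:            342617
headline bundles:           3 covering 3000000 bp (5.4% of the chromosome)
core bins (12-config sweep): 150; planted-group coverage 100.0%
overlap test [gt99]: observed 160000 bp, fold 18.1, p 0.001996, BH-adjusted 0.001996
overlap test [lt98]: observed 160000 bp, fold 16.6, p 0.001996, BH-adjusted 0.001996
overlap test [s98to99]: observed 160000 bp, fold 19.2, p 0.001996, BH-adjusted 0.001996
mHG (synteny labels in SD-count ranking): mhg 2.59e-10 at prefix 7, exact p 1.46e-09 (N=280, B=15)
read-level mask: 6364 of 20000 pairs excluded; 46 of 1998 planted mismapped pairs survive
```

Reading this: the count/span filter plus bundling recovers exactly the three
planted regions (3 bundles, 3 Mb); the 12-configuration sweep's core bins
cover 100% of the planted-group bins, i.e. the pattern is
threshold-independent; every SD similarity class overlaps bundles ~16–19×
more than the constrained-shuffle null (minimum achievable p at 500
simulations, surviving BH); the 15 synteny-labelled 200 kb bins concentrate
at the top of the SD-count ranking (exact mHG p ≈ 1.5e-9); and the
unique-30-mer mask removes >97% of planted paralog-mismapped read pairs.

A `sdspatial` command-line tool exposes the same stages (`simulate`,
`filter`, `bundle`, `sweep`, `overlap-test`, `mhg`, `revert`, `tracks`,
`span-profile`, `gene-stats`); run `sdspatial --help`.

## Acceptance script

`scripts/acceptance.py --seed <int> --out <path>` re-runs the full pipeline
on the synthetic world from scratch — genome generation, contact simulation,
filtering, the 12-configuration sweep, both enrichment engines, the profile
tracks and the read-level masking stage — prints the summary above, and
writes the target JSON object to `--out`.

## Layout

```
src/sdspatial/
  synthetic.py    genome/contact/read-pair generators
  hic.py          interaction container, filters, unique mask, renormalise
  bundling.py     bundle_links, coverage, threshold sweep, core extraction
  enrichment.py   overlap permutation test, BH, mHG (+ exact p), Spearman
  rearrange.py    inversion reversal, link remapping, synteny labels
  profiles.py     span classes, intensity, G4/GC/count tracks, gene stats
  workflows.py    demo world and end-to-end pipeline
  io.py           FASTA/BED/BED12/triplet/TSV readers and writers
  cli.py          thin click CLI
docs/methods.md   model assumptions, parameter defaults, numerical choices
```
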