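"""End-to-end demonstration pipeline on the built-in synthetic world.

The demo world is a 56 Mb chromosome with one planted proximal group of three
1 Mb regions whose pairwise linear separations all exceed 25 Mb, SD paralog
pairs of all three similarity classes planted inside those regions, synteny
blocks labelling them as homologous to one target chromosome (plus decoy
blocks), artifact contacts bridging SD paralog bins, and Poisson-sampled
distance-decay Hi-C contacts.  ``run_demo_pipeline`` exercises every stage:
threshold sweep with core-bin extraction, SD-vs-bundle overlap enrichment,
ranked-bin mHG enrichment on the synteny labels, span-size/intensity
profiles, feature tracks, and read-level SD masking on a small companion
genome.
"""

from __future__ import annotations

import numpy as np

from .bundling import bundle_coverage, bundle_links, default_sweep_configs, threshold_sweep
from .enrichment import overlap_enrichment_panel, ranked_bin_enrichment
from .hic import (bin_and_renormalise, build_unique_mask, filter_count_span,
                  filter_reads_by_mask)
from .intervals import merge_intervals, overlaps_any
from .profiles import count_track, g4_scan, gc_track, interaction_intensity, span_profile
from .rearrange import label_by_synteny
from .synthetic import (ContactModel, GenomeBundle, SyntheticGenomeSpec,
                        generate_genome, simulate_hic, simulate_read_pairs)

__all__ = ["demo_world", "run_demo_pipeline", "read_level_demo"]

DEMO_GROUP_REGIONS = [(1_000_000, 2_000_000),
                      (27_000_000, 28_000_000),
                      (54_000_000, 55_000_000)]


def demo_world(seed: int = 0) -> tuple[GenomeBundle, ContactModel]:
    """The default synthetic chromosome and contact model.

    Three 1 Mb regions, mutually >25 Mb apart on the linear chromosome, form
    one spatially proximal group (contact boost 2000x compensates the ~1/d
    decay at >1250 bin distances, giving boosted long-range counts of roughly
    20-50 against a background of ~0.02).  SD pairs of every similarity class
    are planted inside the group regions; the group regions carry the synteny
    label ``cj2`` and two decoy blocks elsewhere carry ``cj8``.
    """
    spec = SyntheticGenomeSpec(
        chrom_name="chrS",
        chrom_length=56_000_000,
        bin_size=20_000,
        sd_pairs={"lt98": 2, "s98to99": 2, "gt99": 2},
        sd_length=40_000,
        sd_region_pool=DEMO_GROUP_REGIONS,
        proximal_groups=[DEMO_GROUP_REGIONS],
        synteny_blocks=[(r, "cj2") for r in DEMO_GROUP_REGIONS]
        + [((10_000_000, 12_000_000), "cj8"), ((40_000_000, 41_000_000), "cj8")],
        n_genes=30,
        n_alus=200,
        n_g4=100,
        seed=seed,
    )
    model = ContactModel(decay_exponent=1.0, base_count_at_1bin=30.0,
                         proximity_boost=2000.0, artifact_count=40.0, noise=True)
    return generate_genome(spec), model


def read_level_demo(seed: int = 0, n_pairs: int = 20_000) -> dict:
    """Read-level SD masking and re-normalisation on a small genome.

    Simulates paired-end reads with 10% of pairs mismapped between SD
    paralogs, builds the unique 30-mer mask over the SD footprint, filters,
    and reports recall on the planted mismapped ends within non-unique
    sequence plus the retained-pair tally after re-normalisation.
    """
    spec = SyntheticGenomeSpec(
        chrom_name="chrR", chrom_length=400_000, bin_size=20_000,
        sd_pairs={"gt99": 1}, sd_length=30_000, seed=seed)
    genome = generate_genome(spec)
    model = ContactModel(decay_exponent=1.0, base_count_at_1bin=30.0)
    reads = simulate_read_pairs(genome, model, n_pairs, mismap_fraction=0.1,
                                seed=seed + 1)
    mask = build_unique_mask(genome.sequence, genome.sds, k=30, max_edits=0,
                             chrom=spec.chrom_name)
    retained, excluded = filter_reads_by_mask(reads, mask)
    mismapped = reads[reads["flag"] == "mismapped"]
    caught = (retained["flag"] == "mismapped").sum()
    renorm = bin_and_renormalise(retained, reads, spec.bin_size,
                                 spec.chrom_length, chrom=spec.chrom_name)
    return {
        "n_pairs": n_pairs,
        "n_mismapped": int(len(mismapped)),
        "n_excluded": int(excluded),
        "mismapped_surviving": int(caught),
        "renormalised_rows": len(renorm),
    }


def run_demo_pipeline(seed: int = 0, n_sim_overlap: int = 500) -> dict:
    """Run every pipeline stage on the demo world and return a summary."""
    genome, model = demo_world(seed)
    spec = genome.spec
    links = simulate_hic(genome, model, seed=seed + 1)

    # threshold sweep over the default 12 filter combinations
    configs = default_sweep_configs()
    sweep = threshold_sweep(links, configs, spec.chrom_length, sds=genome.sds)
    core = sweep.core_bins
    group_iv = merge_intervals(DEMO_GROUP_REGIONS)
    w = spec.bin_size
    starts = sweep.bin_starts
    group_bins = starts[overlaps_any(starts, starts + w, group_iv)]
    covered = np.isin(group_bins, core)
    core_group_coverage = float(covered.mean()) if len(group_bins) else 0.0

    # headline single-configuration bundling (>=15 counts, >=25 Mb span)
    headline = bundle_links(filter_count_span(links, 15.0, 25_000_000))
    covered_bp, covered_frac = bundle_coverage(headline, spec.chrom_length)

    # SD enrichment in bundle regions, per similarity class, BH-adjusted
    bundle_regions = np.array(
        [b.start_region for b in headline] + [b.target_region for b in headline])
    categories = {}
    for cls, sub in genome.sds.groupby("similarity_class"):
        categories[cls] = np.vstack([
            sub[["start", "end"]].to_numpy(),
            sub[["paralog_start", "paralog_end"]].to_numpy()])
    panel = overlap_enrichment_panel(categories, bundle_regions,
                                     spec.chrom_length, n_sim=n_sim_overlap,
                                     seed=seed + 2)

    # mHG enrichment of synteny-labelled 200 kb bins in the SD-count ranking
    mhg_bin = 200_000
    sd_starts = np.vstack([
        genome.sds[["start", "end"]].to_numpy(),
        genome.sds[["paralog_start", "paralog_end"]].to_numpy()])
    sd_track = count_track(sd_starts, spec.chrom_length, mhg_bin)
    labels = label_by_synteny(sd_track["bin_start"].to_numpy(), mhg_bin,
                              genome.synteny_blocks, "cj2")
    mhg_res = ranked_bin_enrichment(sd_track["value"].to_numpy(), labels,
                                    seed=seed + 3)

    # profiles and feature tracks
    spans = span_profile(links, spec.chrom_length)
    intensity = interaction_intensity(links, spec.chrom_length)
    gc = gc_track(genome.sequence, 100_000)
    g4 = g4_scan(genome.sequence)
    read_level = read_level_demo(seed=seed + 4)

    return {
        "n_links": len(links),
        "headline_bundles": len(headline),
        "headline_coverage_bp": covered_bp,
        "headline_coverage_frac": covered_frac,
        "core_bins": int(len(core)),
        "core_group_coverage": core_group_coverage,
        "overlap_panel": panel,
        "mhg": mhg_res,
        "span_profile_bins": int((spans["total_score"] > 0).sum()),
        "median_intensity": float(np.median(intensity["value"])),
        "mean_gc": float(np.nanmean(gc["value"])),
        "n_g4_motifs": int(len(g4)),
        "read_level": read_level,
    }
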