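"""Synthetic genomes, annotations, Hi-C contacts and read pairs.

The generator plants the structures the downstream analysis assumes so every
stage is testable without downloads: SD paralog pairs in three similarity
classes, distance-decay Hi-C contacts with a multiplicative proximity boost
between designated region groups, alignment-artifact contacts between SD
paralog bins, mismapped read pairs with a recorded true origin, synteny
blocks, intron-bearing gene models, Alu-like repeats and G4 motifs.

Everything is deterministic given the spec seed.  Coordinates are 0-based
half-open throughout; contacts are emitted once per unordered bin pair with
``binA_start <= binB_start`` and distance measured between bin starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PlacementError
from .hic import BinInteractionSet, validate_sds
from .intervals import merge_intervals, overlaps_any, shuffle_intervals
from .profiles import Gene

__all__ = [
    "SIMILARITY_RATES",
    "SyntheticGenomeSpec",
    "ContactModel",
    "GenomeBundle",
    "generate_genome",
    "simulate_hic",
    "simulate_read_pairs",
]

# similarity classes realised as per-base substitution rates: the planted
# pair identity is 1 - rate, inside the class boundaries (<98, 98-99, >99%)
SIMILARITY_RATES = {"lt98": 0.03, "s98to99": 0.015, "gt99": 0.005}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticGenomeSpec:
    """Declarative description of a synthetic chromosome."""

    chrom_name: str = "chr7"
    chrom_length: int = 2_000_000
    bin_size: int = 20_000
    sd_pairs: dict = field(default_factory=dict)   # class -> number of pairs
    sd_length: int = 10_000
    sd_region_pool: list | None = None             # restrict SD placement
    proximal_groups: list = field(default_factory=list)  # [[(s,e), ...], ...]
    synteny_blocks: list = field(default_factory=list)   # [((s,e), target), ...]
    inversions: list = field(default_factory=list)       # [(s,e), ...] ordered
    n_genes: int = 0
    n_alus: int = 0
    n_g4: int = 0
    mean_intron_bp: int = 5_000
    seed: int = 0

    def validate(self) -> None:
        if self.chrom_length <= 0 or self.chrom_length % self.bin_size != 0:
            raise ValueError("chrom_length must be a positive multiple of bin_size")
        for s, e in self.inversions:
            if not (0 <= s < e < self.chrom_length):
                raise ValueError(f"inversion ({s}, {e}) outside the chromosome")
        for cls in self.sd_pairs:
            if cls not in SIMILARITY_RATES:
                raise ValueError(f"unknown similarity class {cls!r}")


@dataclass
class ContactModel:
    """Distance-decay contact model with planted structure.

    Expected normalised count for a bin pair at distance d bins is
    ``base_count_at_1bin * d ** -decay_exponent``, multiplied by
    ``proximity_boost`` when both bins fall in the same planted proximal
    group; bin pairs bridging SD paralogs additionally receive
    ``artifact_count``.  With ``noise`` on, counts are Poisson draws.
    """

    decay_exponent: float = 1.0
    base_count_at_1bin: float = 30.0
    proximity_boost: float = 1.0
    artifact_count: float = 0.0
    noise: bool = False

    def __post_init__(self):
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.proximity_boost < 1:
            raise ValueError("proximity_boost must be >= 1")
        if self.base_count_at_1bin < 0 or self.artifact_count < 0:
            raise ValueError("expected counts must be non-negative")


@dataclass
class GenomeBundle:
    """Everything generate_genome emits for one chromosome."""

    spec: SyntheticGenomeSpec
    sequence: str
    sds: pd.DataFrame
    synteny_blocks: pd.DataFrame
    genes: list
    alus: np.ndarray
    g4_motifs: np.ndarray

    @property
    def chrom_length(self) -> int:
        return self.spec.chrom_length


def _place(rng, n: int, size: int, chrom_length: int, taken, pool=None) -> np.ndarray:
    """Place n non-overlapping intervals of one size, avoiding taken regions
    and (optionally) restricted to a pool of allowed intervals."""
    if n == 0:
        return np.empty((0, 2), dtype=np.int64)
    exclusions = merge_intervals(taken) if len(taken) else np.empty((0, 2), np.int64)
    if pool is not None:
        from .intervals import complement_intervals

        outside = complement_intervals(pool, chrom_length)
        exclusions = merge_intervals(np.vstack([exclusions, outside])) \
            if len(exclusions) else outside
    template = np.column_stack([np.zeros(n, np.int64),
                                np.full(n, size, np.int64)])
    return shuffle_intervals(template, chrom_length, exclusions, rng=rng)


def generate_genome(spec: SyntheticGenomeSpec) -> GenomeBundle:
    """Build the sequence and all annotation sets declared by the spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.chrom_length
    codes = _BASES[rng.integers(0, 4, size=L)]
    taken: list = []

    # G4 motifs: four G3 tracts with random 1-3 bp non-G loops, written into
    # the sequence (flanking context may extend a tract; overlap-based
    # recovery is the contract)
    g4_list = []
    if spec.n_g4:
        motif_len = 12 + 9  # worst case 3 loops x 3 bp
        placed = _place(rng, spec.n_g4, motif_len, L, np.asarray(taken).reshape(-1, 2))
        for s, _ in placed:
            pos = int(s)
            piece = []
            for t in range(4):
                piece.append(b"GGG")
                if t < 3:
                    loop_len = int(rng.integers(1, 4))
                    loop = _BASES[rng.integers(0, 3, size=loop_len)]  # A/C/G->no
                    loop = np.where(loop == ord("G"), ord("T"), loop).astype(np.uint8)
                    piece.append(loop.tobytes())
            motif = b"".join(piece)
            codes[pos:pos + len(motif)] = np.frombuffer(motif, dtype=np.uint8)
            g4_list.append((pos, pos + len(motif)))
        taken.extend(g4_list)
    g4 = np.asarray(g4_list, dtype=np.int64).reshape(-1, 2)

    # SD pairs per similarity class: copy the source segment onto the paralog
    # site with an exact number of substitutions fixing the pair identity
    sd_rows = []
    taken_arr = np.asarray(taken, dtype=np.int64).reshape(-1, 2)
    for cls, n_pairs in spec.sd_pairs.items():
        rate = SIMILARITY_RATES[cls]
        for _ in range(int(n_pairs)):
            pair = _place(rng, 2, spec.sd_length, L, taken_arr, spec.sd_region_pool)
            (a0, a1), (b0, b1) = pair
            src = codes[a0:a1].copy()
            n_sub = int(round(rate * spec.sd_length))
            sub_pos = rng.choice(spec.sd_length, size=n_sub, replace=False)
            for p in sub_pos:
                choices = _BASES[_BASES != src[p]]
                src[p] = choices[rng.integers(0, len(choices))]
            codes[b0:b1] = src
            identity = 1.0 - n_sub / spec.sd_length
            sd_rows.append((spec.chrom_name, int(a0), int(a1), spec.chrom_name,
                            int(b0), int(b1), identity))
            taken_arr = merge_intervals(np.vstack([taken_arr, pair]))
    sds = pd.DataFrame(sd_rows, columns=["chrom", "start", "end", "paralog_chrom",
                                         "paralog_start", "paralog_end", "identity"])
    if len(sds):
        sds = validate_sds(sds)
    else:
        sds["similarity_class"] = pd.Series(dtype=str)

    # genes: random exon/intron structures, gene spans mutually disjoint
    genes = []
    for gi in range(spec.n_genes):
        n_exons = int(rng.integers(2, 6))
        exon_lens = rng.integers(100, 400, size=n_exons)
        intron_lens = np.maximum(
            1, rng.exponential(spec.mean_intron_bp, size=n_exons - 1)).astype(np.int64)
        span = int(exon_lens.sum() + intron_lens.sum())
        placed = _place(rng, 1, span, L, taken_arr)
        start = int(placed[0, 0])
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(spec.chrom_name, start, pos, f"gene{gi}", strand, exons))
        taken_arr = merge_intervals(np.vstack([taken_arr, placed]))

    # Alu-like repeats: 300 bp intervals, mutually non-overlapping, anywhere
    alus = _place(rng, spec.n_alus, 300, L, np.empty((0, 2), np.int64))

    synteny = pd.DataFrame(
        [(spec.chrom_name, s, e, tgt) for (s, e), tgt in spec.synteny_blocks],
        columns=["chrom", "start", "end", "target_chrom"])

    return GenomeBundle(spec, codes.tobytes().decode("ascii"), sds, synteny,
                        genes, alus, g4)


def _bin_group_ids(spec: SyntheticGenomeSpec) -> np.ndarray:
    """Group index per bin (-1 outside every planted proximal group)."""
    w = spec.bin_size
    n_bins = spec.chrom_length // w
    starts = np.arange(n_bins, dtype=np.int64) * w
    gid = np.full(n_bins, -1, dtype=np.int64)
    for g, intervals in enumerate(spec.proximal_groups):
        hit = overlaps_any(starts, starts + w, merge_intervals(intervals))
        gid[hit & (gid < 0)] = g
    return gid


def expected_contacts(genome: GenomeBundle, model: ContactModel
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected count for every unordered bin pair (iA < iB, bin indices)."""
    spec = genome.spec
    w = spec.bin_size
    n_bins = spec.chrom_length // w
    iA, iB = np.triu_indices(n_bins, k=1)
    d = (iB - iA).astype(float)
    expected = model.base_count_at_1bin * d ** (-model.decay_exponent)
    gid = _bin_group_ids(spec)
    boost = (gid[iA] >= 0) & (gid[iA] == gid[iB])
    expected[boost] *= model.proximity_boost
    if model.artifact_count > 0 and len(genome.sds):
        starts = np.arange(n_bins, dtype=np.int64) * w
        for sd in genome.sds.itertuples(index=False):
            in_s = np.flatnonzero(overlaps_any(starts, starts + w,
                                               [[sd.start, sd.end]]))
            in_p = np.flatnonzero(overlaps_any(starts, starts + w,
                                               [[sd.paralog_start, sd.paralog_end]]))
            aa, bb = np.meshgrid(in_s, in_p, indexing="ij")
            lo = np.minimum(aa, bb).ravel()
            hi = np.maximum(aa, bb).ravel()
            keep = lo < hi
            lo, hi = lo[keep], hi[keep]
            # linear index of (lo, hi) in row-major upper-triangle order
            lin = lo * n_bins - lo * (lo + 1) // 2 + (hi - lo - 1)
            np.add.at(expected, np.unique(lin), model.artifact_count)
    return iA, iB, expected


def simulate_hic(genome: GenomeBundle, model: ContactModel,
                 seed: int | None = None) -> BinInteractionSet:
    """Draw a binned contact map from the model.

    With noise off, counts equal expectations exactly (rows with zero
    expectation are dropped); with noise on, counts are independent Poisson
    draws and zero-count rows are dropped, mimicking a sparse triplet file.
    """
    spec = genome.spec
    iA, iB, expected = expected_contacts(genome, model)
    if model.noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    keep = counts > 0
    df = pd.DataFrame({
        "binA_start": iA[keep] * spec.bin_size,
        "binB_start": iB[keep] * spec.bin_size,
        "count": counts[keep],
    })
    return BinInteractionSet(df, bin_size=spec.bin_size, chrom=spec.chrom_name)


def simulate_read_pairs(
    genome: GenomeBundle,
    model: ContactModel,
    n_pairs: int,
    mismap_fraction: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample paired-end read positions from the contact model.

    A ``mismap_fraction`` of pairs emulate alignment artifacts: the pair is a
    short-range contact at an SD copy, but its B end is reported at the
    homologous offset of the paralog copy.  The true origin of the relocated
    end is recorded in ``true_posB`` (-1 for clean pairs) so filter recall
    and precision are computable.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not (0 <= mismap_fraction <= 1):
        raise ValueError("mismap_fraction must lie in [0, 1]")
    spec = genome.spec
    rng = np.random.default_rng(seed)
    w = spec.bin_size
    iA, iB, expected = expected_contacts(genome, model)
    p = expected / expected.sum()
    idx = rng.choice(len(expected), size=n_pairs, p=p)
    posA = iA[idx] * w + rng.integers(0, w, size=n_pairs)
    posB = iB[idx] * w + rng.integers(0, w, size=n_pairs)
    strands = np.array(["+", "-"])
    df = pd.DataFrame({
        "chromA": spec.chrom_name,
        "posA": posA,
        "strandA": strands[rng.integers(0, 2, size=n_pairs)],
        "chromB": spec.chrom_name,
        "posB": posB,
        "strandB": strands[rng.integers(0, 2, size=n_pairs)],
        "pair_id": np.arange(n_pairs),
        "flag": "ok",
        "true_posB": -1,
    })
    flagged = np.flatnonzero(rng.random(n_pairs) < mismap_fraction)
    if len(flagged):
        if len(genome.sds) == 0:
            raise ValueError("mismap_fraction > 0 requires planted SD pairs")
        sd_idx = rng.integers(0, len(genome.sds), size=len(flagged))
        offs = rng.integers(0, spec.sd_length, size=len(flagged))
        src = genome.sds.iloc[sd_idx]
        true_pos = src["start"].to_numpy() + offs
        mapped = src["paralog_start"].to_numpy() + offs
        # the partner end really sits near the true origin (short-range pair)
        near = np.clip(true_pos + rng.integers(-2000, 2001, size=len(flagged)),
                       0, spec.chrom_length - 1)
        df.loc[flagged, "posA"] = near
        df.loc[flagged, "posB"] = mapped
        df.loc[flagged, "true_posB"] = true_pos
        df.loc[flagged, "flag"] = "mismapped"
    return df
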