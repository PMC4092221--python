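"""Plain-text readers and writers for the formats the pipeline exchanges.

BED-like files are emitted natively in 0-based half-open coordinates; the
SD table follows the UCSC genomicSuperDups column idea (own interval, paralog
interval, fractional identity).  Contacts travel as tab-separated triplets
(binA_start, binB_start, normalised count).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bundling import Bundle
from .hic import validate_sds
from .profiles import Gene
from .rearrange import Inversion

__all__ = [
    "write_fasta", "read_fasta",
    "write_sd_bed", "read_sd_bed",
    "write_bed", "read_bed",
    "write_synteny_bed", "read_synteny_bed",
    "write_genes_bed12", "read_genes_bed12",
    "write_inversions", "read_inversions",
    "write_bundles", "write_track",
    "write_read_pairs", "read_read_pairs",
]


def write_fasta(path, name: str, sequence: str) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_sd_bed(path, sds: pd.DataFrame) -> None:
    """BED6+ with paralog chrom/start/end and fracMatch as extra columns."""
    out = pd.DataFrame({
        "chrom": sds["chrom"],
        "start": sds["start"],
        "end": sds["end"],
        "name": [f"sd{i}" for i in range(len(sds))],
        "score": 0,
        "strand": "+",
        "paralog_chrom": sds["paralog_chrom"],
        "paralog_start": sds["paralog_start"],
        "paralog_end": sds["paralog_end"],
        "fracMatch": sds["identity"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sd_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "paralog_chrom", "paralog_start", "paralog_end", "fracMatch"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    df = df.rename(columns={"fracMatch": "identity"})
    return validate_sds(df[["chrom", "start", "end", "paralog_chrom",
                            "paralog_start", "paralog_end", "identity"]])


def write_bed(path, chrom: str, intervals) -> None:
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    pd.DataFrame({"chrom": chrom, "start": arr[:, 0], "end": arr[:, 1]}).to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_synteny_bed(path, blocks: pd.DataFrame) -> None:
    blocks[["chrom", "start", "end", "target_chrom"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_synteny_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "target_chrom"])


def write_genes_bed12(path, genes: list[Gene]) -> None:
    rows = []
    for g in genes:
        exons = sorted(g.exons)
        sizes = ",".join(str(e - s) for s, e in exons) + ","
        offs = ",".join(str(s - g.start) for s, _ in exons) + ","
        rows.append((g.chrom, g.start, g.end, g.name, 0, g.strand, g.start,
                     g.end, "0,0,0", len(exons), sizes, offs))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed12(path) -> list[Gene]:
    genes = []
    df = pd.read_csv(path, sep="\t", header=None)
    for row in df.itertuples(index=False):
        chrom, start, end, name, _score, strand = row[:6]
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offs = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
        genes.append(Gene(chrom, int(start), int(end), str(name), strand, exons))
    return genes


def write_inversions(path, inversions: list[Inversion]) -> None:
    pd.DataFrame([(i.chrom, i.start, i.end) for i in inversions]).to_csv(
        path, sep="\t", header=False, index=False)


def read_inversions(path) -> list[Inversion]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
    return [Inversion(r.chrom, int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def write_bundles(path, chrom: str, bundles: list[Bundle]) -> None:
    """Circos-compatible link text: chrom start end chrom start end members."""
    rows = [(chrom, b.start_region[0], b.start_region[1],
             chrom, b.target_region[0], b.target_region[1], b.members)
            for b in bundles]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_track(path, track: pd.DataFrame) -> None:
    """Binned track as TSV (bin_start, value ... any further columns kept)."""
    track.to_csv(path, sep="\t", index=False)


def write_read_pairs(path, reads: pd.DataFrame) -> None:
    cols = ["chromA", "posA", "strandA", "chromB", "posB", "strandB",
            "pair_id", "flag"]
    reads[cols].to_csv(path, sep="\t", header=False, index=False)


def read_read_pairs(path) -> pd.DataFrame:
    cols = ["chromA", "posA", "strandA", "chromB", "posB", "strandB",
            "pair_id", "flag"]
    return pd.read_csv(path, sep="\t", header=None, names=cols)


def write_genome_bundle(outdir, genome) -> dict[str, Path]:
    """Emit every artifact of a synthetic genome bundle into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = genome.spec.chrom_name
    paths = {
        "fasta": outdir / "genome.fa",
        "sds": outdir / "sds.bed",
        "synteny": outdir / "synteny.bed",
        "genes": outdir / "genes.bed12",
        "alus": outdir / "alus.bed",
        "g4": outdir / "g4_planted.bed",
    }
    write_fasta(paths["fasta"], name, genome.sequence)
    write_sd_bed(paths["sds"], genome.sds)
    write_synteny_bed(paths["synteny"], genome.synteny_blocks)
    write_genes_bed12(paths["genes"], genome.genes)
    write_bed(paths["alus"], name, genome.alus)
    write_bed(paths["g4"], name, genome.g4_motifs)
    return paths
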