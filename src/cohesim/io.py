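"""Plain-text readers and writers for the pipeline's external formats.

Genomes travel as FASTA (one record per chromosome), reads as FASTQ with
uniform 'I' qualities, anchors as 6-column BED (0-based half-open, one 1-bp
interval per chromosome), gel lanes and absorbance series as tab-separated
tables with header rows.  Simulation runs also drop a YAML manifest of the
parameters used.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay_quant import AbsorbanceSeries
from .entrapment_model import LaneQuantification, quantify_lane
from .synthetic_data import SimRead, ToyGenomePair

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_anchors_bed",
    "read_anchors_bed",
    "write_genome_pair",
    "read_genome_pair",
    "write_lanes_tsv",
    "read_lanes_tsv",
    "write_absorbance_tsv",
    "read_absorbance_tsv",
    "write_manifest",
]


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable, path: str | Path) -> None:
    """Write SimReads or (id, sequence) pairs as FASTQ, quality all 'I'."""
    with open(path, "w") as fh:
        for read in reads:
            if isinstance(read, SimRead):
                rid, seq = read.id, read.sequence
            else:
                rid, seq = read
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_anchors_bed(anchors: dict[str, int], path: str | Path) -> None:
    """Anchors as 6-column BED; the 1-based anchor base becomes [pos-1, pos)."""
    with open(path, "w") as fh:
        for chrom, pos in anchors.items():
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\tanchor\t0\t+\n")


def read_anchors_bed(path: str | Path) -> dict[str, int]:
    anchors: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end - start != 1:
                raise ValueError(f"anchor interval on {chrom} is not 1 bp wide")
            anchors[chrom] = start + 1
    return anchors


def write_genome_pair(pair: ToyGenomePair, outdir: str | Path) -> dict[str, Path]:
    """Write experimental.fa, calibration.fa and anchors.bed into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "experimental": outdir / "experimental.fa",
        "calibration": outdir / "calibration.fa",
        "anchors": outdir / "anchors.bed",
    }
    write_fasta(pair.experimental, paths["experimental"])
    write_fasta(pair.calibration, paths["calibration"])
    write_anchors_bed(pair.anchors, paths["anchors"])
    return paths


def read_genome_pair(
    experimental_fa: str | Path,
    calibration_fa: str | Path,
    anchors_bed: str | Path,
    read_length: int,
) -> ToyGenomePair:
    return ToyGenomePair(
        experimental=read_fasta(experimental_fa),
        calibration=read_fasta(calibration_fa),
        anchors=read_anchors_bed(anchors_bed),
        read_length=read_length,
    )


def write_lanes_tsv(lanes: Sequence[LaneQuantification], path: str | Path) -> None:
    """One row per replicate lane, one column per band (raw intensities)."""
    rows = [{"replicate": i + 1, **lane.bands} for i, lane in enumerate(lanes)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_lanes_tsv(path: str | Path) -> list[LaneQuantification]:
    df = pd.read_csv(path, sep="\t")
    bands = [c for c in df.columns if c != "replicate"]
    return [quantify_lane({b: float(row[b]) for b in bands}) for _, row in df.iterrows()]


def write_absorbance_tsv(series: AbsorbanceSeries, path: str | Path) -> None:
    pd.DataFrame({"time_min": series.times, "absorbance_au": series.values}).to_csv(
        path, sep="\t", index=False
    )


def read_absorbance_tsv(path: str | Path) -> AbsorbanceSeries:
    df = pd.read_csv(path, sep="\t")
    return AbsorbanceSeries(
        times=df["time_min"].to_numpy(), values=df["absorbance_au"].to_numpy()
    )


def write_manifest(params: dict, outdir: str | Path, name: str = "manifest.yaml") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
    return path
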