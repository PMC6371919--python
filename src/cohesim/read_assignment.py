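"""Sequential two-genome read assignment for spike-in calibrated ChIP.

Reads from a mixed-species sample are partitioned by aligning first to the
calibration genome and passing only the *unaligned* leftovers to the
experimental genome, so each read is attributed to exactly one genome.  At
desk scale the aligner is an exact-match mapper over both strands: a read is
assigned only when its sequence (or reverse complement) matches exactly one
location in the genome under test.  A read that matches the calibration
genome at more than one location is consumed by the calibration pass but
left unassigned — it aligned, just not uniquely — mirroring how a
multi-mapping read never reaches the second aligner's input.  Externally
produced SAM alignments are accepted as an alternative input path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

from .synthetic_data import SimRead, ToyGenomePair, revcomp

__all__ = [
    "AssignedRead",
    "CalibrationCounts",
    "ExactMatchIndex",
    "assign_reads_sequential",
    "tally_calibration_counts",
    "assignments_from_sam",
    "write_assignments_sam",
    "write_unassigned_fastq",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssignedRead:
    """One read's genome-of-origin call.

    ``genome`` is ``"experimental"``, ``"calibration"`` or ``"unassigned"``;
    locus fields are ``None`` exactly when unassigned.  ``start`` is 1-based
    leftmost on the forward strand (SAM convention, also for ``-`` matches).
    """

    read_id: str
    genome: str
    chrom: str | None
    start: int | None
    strand: str | None
    aligned_length: int

    def __post_init__(self) -> None:
        loci_none = (self.chrom is None, self.start is None, self.strand is None)
        if self.genome == "unassigned":
            if not all(loci_none):
                raise ValueError("unassigned read must have null locus fields")
        elif any(loci_none):
            raise ValueError("assigned read must have chrom, start and strand")


@dataclass(frozen=True)
class CalibrationCounts:
    """The four uniquely-assigned read counts feeding the occupancy ratio."""

    W_x: int  # WCE reads on the experimental genome
    W_c: int  # WCE reads on the calibration genome
    IP_x: int  # IP reads on the experimental genome
    IP_c: int  # IP reads on the calibration genome


class ExactMatchIndex:
    """Exact-match k-mer index of one genome over both strands.

    Indexes every forward k-mer; a query hits the ``-`` strand when its
    reverse complement occurs on the forward strand, reported at the
    leftmost base of the match in forward coordinates.
    """

    def __init__(self, genome: dict[str, str], k: int):
        if k <= 0:
            raise ValueError("k must be positive")
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i + 1))

    def lookup(self, seq: str) -> list[tuple[str, int, str]]:
        """All (chrom, 1-based leftmost, strand) matches of ``seq``."""
        hits = [(c, p, "+") for c, p in self._index.get(seq, ())]
        hits += [(c, p, "-") for c, p in self._index.get(revcomp(seq), ())]
        return hits


def _read_id_and_seq(read) -> tuple[str, str]:
    if isinstance(read, SimRead):
        return read.id, read.sequence
    if isinstance(read, tuple):
        return read[0], read[1]
    # Bio.SeqRecord and similar
    return str(read.id), str(read.seq)


def assign_reads_sequential(
    reads: Iterable, pair: ToyGenomePair
) -> list[AssignedRead]:
    """Assign each read to the calibration genome first, leftovers second.

    Accepts ``SimRead`` objects, ``(id, sequence)`` tuples or Biopython
    ``SeqRecord``s.  Input order is preserved.  Reads longer than every
    chromosome are unassigned with a logged warning.
    """
    indexes: dict[int, tuple[ExactMatchIndex, ExactMatchIndex]] = {}
    max_chrom = max(
        len(s) for s in list(pair.calibration.values()) + list(pair.experimental.values())
    )
    out: list[AssignedRead] = []
    for read in reads:
        read_id, seq = _read_id_and_seq(read)
        k = len(seq)
        if k > max_chrom:
            logger.warning("read %s longer than every chromosome; unassigned", read_id)
            out.append(AssignedRead(read_id, "unassigned", None, None, None, k))
            continue
        if k not in indexes:
            indexes[k] = (
                ExactMatchIndex(pair.calibration, k),
                ExactMatchIndex(pair.experimental, k),
            )
        cal_index, exp_index = indexes[k]
        cal_hits = cal_index.lookup(seq)
        if len(cal_hits) == 1:
            chrom, pos, strand = cal_hits[0]
            out.append(AssignedRead(read_id, "calibration", chrom, pos, strand, k))
            continue
        if len(cal_hits) > 1:
            # aligned (non-uniquely) to the calibration genome: consumed there
            out.append(AssignedRead(read_id, "unassigned", None, None, None, k))
            continue
        exp_hits = exp_index.lookup(seq)
        if len(exp_hits) == 1:
            chrom, pos, strand = exp_hits[0]
            out.append(AssignedRead(read_id, "experimental", chrom, pos, strand, k))
        else:
            out.append(AssignedRead(read_id, "unassigned", None, None, None, k))
    return out


def tally_calibration_counts(
    assignments_ip: Iterable[AssignedRead], assignments_wce: Iterable[AssignedRead]
) -> CalibrationCounts:
    """Count uniquely assigned reads per (sample, genome) cell."""

    def _count(assignments: Iterable[AssignedRead]) -> tuple[int, int]:
        x = c = 0
        for a in assignments:
            if a.genome == "experimental":
                x += 1
            elif a.genome == "calibration":
                c += 1
        return x, c

    ip_x, ip_c = _count(assignments_ip)
    w_x, w_c = _count(assignments_wce)
    return CalibrationCounts(W_x=w_x, W_c=w_c, IP_x=ip_x, IP_c=ip_c)


# ---------------------------------------------------------------------------
# SAM interface


def assignments_from_sam(
    path: str, pair: ToyGenomePair, mapq_floor: int = 10
) -> list[AssignedRead]:
    """Ingest externally produced alignments against one of the two genomes.

    The SAM header's @SQ names must all belong to exactly one genome of the
    pair; mapped records with MAPQ >= ``mapq_floor`` become assignments to
    that genome, everything else is unassigned.
    """
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        refs = set(sam.references)
        if refs and refs <= set(pair.calibration):
            genome = "calibration"
        elif refs and refs <= set(pair.experimental):
            genome = "experimental"
        else:
            raise ValueError(
                "SAM @SQ names must match exactly one genome of the pair"
            )
        out: list[AssignedRead] = []
        for rec in sam:
            length = rec.query_length or (rec.infer_query_length() or 0)
            if rec.is_unmapped or (rec.mapping_quality < mapq_floor):
                out.append(AssignedRead(rec.query_name, "unassigned", None, None, None, length))
            else:
                out.append(
                    AssignedRead(
                        rec.query_name,
                        genome,
                        rec.reference_name,
                        rec.reference_start + 1,
                        "-" if rec.is_reverse else "+",
                        rec.query_alignment_length or length,
                    )
                )
    return out


def _sam_header(genome: dict[str, str]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": chrom, "LN": len(seq)} for chrom, seq in genome.items()],
    }


def write_assignments_sam(
    assignments: Sequence[AssignedRead],
    genome: dict[str, str],
    genome_label: str,
    path: str,
    sequences: dict[str, str] | None = None,
) -> int:
    """Write the assignments for one genome as a SAM text file.

    Only records with ``genome == genome_label`` are written; returns the
    number written.  ``sequences`` optionally supplies read sequences by id.
    """
    header = pysam.AlignmentHeader.from_dict(_sam_header(genome))
    n = 0
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for a in assignments:
            if a.genome != genome_label:
                continue
            rec = pysam.AlignedSegment(header)
            rec.query_name = a.read_id
            rec.flag = 16 if a.strand == "-" else 0
            rec.reference_id = list(genome).index(a.chrom)
            rec.reference_start = a.start - 1
            rec.mapping_quality = 255
            rec.cigartuples = [(0, a.aligned_length)]
            if sequences and a.read_id in sequences:
                seq = sequences[a.read_id]
                rec.query_sequence = revcomp(seq) if a.strand == "-" else seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(rec)
            n += 1
    return n


def write_unassigned_fastq(
    assignments: Sequence[AssignedRead], sequences: dict[str, str], path: str
) -> int:
    """Write unassigned reads to a separate FASTQ file (quality all 'I')."""
    n = 0
    with open(path, "w") as fh:
        for a in assignments:
            if a.genome != "unassigned":
                continue
            seq = sequences.get(a.read_id)
            if seq is None:
                continue
            fh.write(f"@{a.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n
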