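"""Synthetic inputs for the calibrated ChIP pipeline and the gel/ATPase assays.

Spike-in calibrated ChIP-seq mixes experimental cells (*S. cerevisiae*-like)
with calibration cells of a diverged species (*C. glabrata*-like) at a fixed
cell ratio before fixation, so that read counts on the calibration genome
report the IP efficiency of each sample.  This module fabricates the whole
study at desk scale:

* paired toy genomes with guaranteed-unique k-mers (so exact matching maps
  every error-free read unambiguously) and one centromere-like anchor per
  experimental chromosome;
* IP and whole-cell-extract (WCE) read sets with known ground truth, where
  IP coverage is enriched at each anchor and decays linearly to background
  over a configurable span (default 30 kb, matching centromeric cohesin
  spreading into peri-centric sequence);
* minichromosome-IP gel lanes under a given ring-stoichiometry model, with
  multiplicative log-normal band noise;
* phosphate-release absorbance time series with a linear phase.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay_quant import AbsorbanceSeries, StandardCurve
from .entrapment_model import (
    LaneQuantification,
    StoichiometryModel,
    expected_species_fractions,
    quantify_lane,
)

__all__ = [
    "ToyGenomePair",
    "SimRead",
    "OccupancyProfileSpec",
    "make_toy_genome_pair",
    "simulate_chip_experiment",
    "simulate_entrapment_assay",
    "simulate_atpase_series",
    "revcomp",
    "profile_weights",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Desk-scale cap on a single chromosome (bp).
MAX_CHROM_LENGTH = 200_000


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ToyGenomePair:
    """Paired experimental/calibration genomes with per-chromosome anchors.

    Invariants: every ``read_length``-mer occurs at most once across both
    strands of both genomes combined (unique exact mapping); chromosome
    names are disjoint between genomes; each anchor lies within its
    chromosome (1-based).
    """

    experimental: dict[str, str]
    calibration: dict[str, str]
    anchors: dict[str, int]
    read_length: int

    def validate(self) -> None:
        shared = set(self.experimental) & set(self.calibration)
        if shared:
            raise ValueError(f"chromosome names shared between genomes: {sorted(shared)}")
        for chrom, pos in self.anchors.items():
            if chrom not in self.experimental:
                raise ValueError(f"anchor for unknown chromosome {chrom!r}")
            if not 1 <= pos <= len(self.experimental[chrom]):
                raise ValueError(f"anchor {pos} outside chromosome {chrom!r}")
        if missing := set(self.experimental) - set(self.anchors):
            raise ValueError(f"chromosomes without anchors: {sorted(missing)}")
        if not _kmers_unique(
            list(self.experimental.values()) + list(self.calibration.values()),
            self.read_length,
        ):
            raise ValueError("k-mer uniqueness violated")


@dataclass(frozen=True)
class SimRead:
    """A simulated read with its ground-truth origin.

    ``truth_pos`` is the 1-based leftmost base of the read on the forward
    strand of ``truth_chrom`` (SAM convention), regardless of strand.
    """

    id: str
    sequence: str
    sample: str  # "IP" | "WCE"
    truth_genome: str  # "experimental" | "calibration"
    truth_chrom: str
    truth_pos: int
    truth_strand: str  # "+" | "-"


@dataclass(frozen=True)
class OccupancyProfileSpec:
    """Anchor-centered enrichment shape for IP coverage.

    The per-base sampling weight is ``background`` far from the anchor and
    rises linearly to ``background * peak_enrichment`` at the anchor over
    ``decay_span`` bp on each side.
    """

    background: float = 1.0
    peak_enrichment: float = 1.0
    decay_span: int = 30_000

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.peak_enrichment < 1:
            raise ValueError("peak_enrichment must be >= 1")
        if self.decay_span < 0:
            raise ValueError("decay_span must be >= 0")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASE_LUT[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _kmers_unique(sequences: Sequence[str], k: int) -> bool:
    """True iff each k-mer occurs at most once over both strands combined."""
    seen: set[str] = set()
    for seq in sequences:
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - k + 1):
                kmer = strand_seq[i : i + k]
                if kmer in seen:
                    return False
                seen.add(kmer)
    return True


def make_toy_genome_pair(
    n_chrom: int,
    chrom_length: int,
    n_cal_chrom: int,
    cal_length: int,
    read_length: int,
    seed: int,
    max_retries: int = 20,
) -> ToyGenomePair:
    """Random genome pair with unique k-mers and midpoint anchors.

    Sequences are resampled wholesale until every ``read_length``-mer is
    unique across both strands of both genomes; persistent failure (e.g. a
    read length too short for the genome size) raises ``ValueError("genome
    too repetitive")``.
    """
    if min(n_chrom, chrom_length, n_cal_chrom, cal_length, read_length) <= 0:
        raise ValueError("all sizes must be positive")
    if chrom_length <= 2 * read_length or cal_length <= 2 * read_length:
        raise ValueError("chromosome lengths must exceed 2 * read_length")
    if max(chrom_length, cal_length) > MAX_CHROM_LENGTH:
        raise ValueError(f"chromosome length exceeds desk scale ({MAX_CHROM_LENGTH} bp)")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        experimental = {
            f"exp_chr{i + 1}": _random_sequence(rng, chrom_length) for i in range(n_chrom)
        }
        calibration = {
            f"cal_chr{i + 1}": _random_sequence(rng, cal_length) for i in range(n_cal_chrom)
        }
        seqs = list(experimental.values()) + list(calibration.values())
        if _kmers_unique(seqs, read_length):
            anchors = {c: (len(s) + 1) // 2 for c, s in experimental.items()}
            return ToyGenomePair(experimental, calibration, anchors, read_length)
    raise ValueError("genome too repetitive: could not satisfy k-mer uniqueness")


def profile_weights(length: int, anchor: int, spec: OccupancyProfileSpec) -> np.ndarray:
    """Per-base sampling weight over positions 1..length (0-indexed array).

    Linear decay from ``background * peak_enrichment`` at the anchor to
    ``background`` at ``|offset| >= decay_span``; a zero span confines the
    enrichment to the anchor base itself.
    """
    pos = np.arange(1, length + 1)
    offset = np.abs(pos - anchor)
    if spec.decay_span > 0:
        tri = np.maximum(0.0, 1.0 - offset / spec.decay_span)
    else:
        tri = (offset == 0).astype(float)
    return spec.background * (1.0 + (spec.peak_enrichment - 1.0) * tri)


def _draw_reads(
    rng: np.random.Generator,
    pair: ToyGenomePair,
    sample: str,
    n_reads: int,
    segments: list[tuple[str, str, np.ndarray]],
    start_id: int = 0,
) -> list[SimRead]:
    """Sample reads from concatenated per-start-position weights.

    ``segments`` is a list of (genome_label, chrom, weight-per-valid-start).
    """
    rl = pair.read_length
    weights = np.concatenate([w for _, _, w in segments])
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    idx = rng.choice(weights.size, size=n_reads, p=weights / total)
    strands = rng.integers(0, 2, size=n_reads)
    bounds = np.cumsum([w.size for _, _, w in segments])
    seg_of = np.searchsorted(bounds, idx, side="right")
    offsets = idx - np.concatenate(([0], bounds[:-1]))[seg_of]
    reads: list[SimRead] = []
    genomes = {"experimental": pair.experimental, "calibration": pair.calibration}
    for i in range(n_reads):
        genome_label, chrom, _ = segments[seg_of[i]]
        pos = int(offsets[i]) + 1  # 1-based leftmost
        seq = genomes[genome_label][chrom][pos - 1 : pos - 1 + rl]
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            seq = revcomp(seq)
        reads.append(
            SimRead(
                id=f"{sample}_{start_id + i:07d}",
                sequence=seq,
                sample=sample,
                truth_genome=genome_label,
                truth_chrom=chrom,
                truth_pos=pos,
                truth_strand=strand,
            )
        )
    return reads


def simulate_chip_experiment(
    pair: ToyGenomePair,
    profile: OccupancyProfileSpec,
    cell_ratio_exp_to_cal: float = 3.0,
    n_reads_ip: int = 10_000,
    n_reads_wce: int = 10_000,
    seed: int = 0,
    calibration_profile: OccupancyProfileSpec | None = None,
) -> list[SimRead]:
    """Simulate one calibrated ChIP experiment (IP + WCE read sets).

    WCE reads are drawn uniformly from both genomes with per-genome weight
    proportional to ``cell_ratio_exp_to_cal`` x genome length (the default
    3:1 mirrors mixing three parts experimental cells with one part
    calibration cells).  IP reads are drawn with per-start weight equal to
    the anchor-centered profile on the experimental genome (times the cell
    ratio) and to a flat background profile on the calibration genome.
    Returns IP reads followed by WCE reads; ground-truth fields record each
    read's origin.
    """
    if n_reads_ip <= 0 or n_reads_wce <= 0:
        raise ValueError("read counts must be positive")
    if cell_ratio_exp_to_cal <= 0:
        raise ValueError("cell ratio must be positive")
    if not pair.experimental or not pair.calibration:
        raise ValueError("empty genome")
    cal_profile = calibration_profile or OccupancyProfileSpec(
        background=profile.background, peak_enrichment=1.0, decay_span=0
    )
    rl = pair.read_length
    rng = np.random.default_rng(seed)

    ip_segments: list[tuple[str, str, np.ndarray]] = []
    for chrom, seq in pair.experimental.items():
        w = profile_weights(len(seq), pair.anchors[chrom], profile)[: len(seq) - rl + 1]
        ip_segments.append(("experimental", chrom, cell_ratio_exp_to_cal * w))
    for chrom, seq in pair.calibration.items():
        n_starts = len(seq) - rl + 1
        ip_segments.append(
            ("calibration", chrom, np.full(n_starts, cal_profile.background))
        )

    wce_segments: list[tuple[str, str, np.ndarray]] = []
    for chrom, seq in pair.experimental.items():
        wce_segments.append(
            ("experimental", chrom, np.full(len(seq) - rl + 1, cell_ratio_exp_to_cal))
        )
    for chrom, seq in pair.calibration.items():
        wce_segments.append(("calibration", chrom, np.ones(len(seq) - rl + 1)))

    reads = _draw_reads(rng, pair, "IP", n_reads_ip, ip_segments)
    reads += _draw_reads(rng, pair, "WCE", n_reads_wce, wce_segments)
    return reads


def simulate_entrapment_assay(
    model: StoichiometryModel,
    n_replicates: int,
    noise_sd: float,
    seed: int,
    monomer_level: float = 0.6,
    concatemer_level: float = 0.2,
) -> list[LaneQuantification]:
    """Simulate replicate minichromosome-IP gel lanes.

    Each lane carries the model's expected detectable CM and CD fractions
    multiplied by independent mean-one log-normal noise of multiplicative SD
    ``noise_sd`` (so the noiseless limit reproduces the expectation exactly),
    plus monomer and concatemer background bands at fixed nominal levels.
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    if not 0.0 <= noise_sd < 1.0:
        raise ValueError("noise_sd must be in [0, 1)")
    fractions = expected_species_fractions(model)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        sigma = np.sqrt(np.log1p(noise_sd**2))
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=(n_replicates, 2))
    else:
        factors = np.ones((n_replicates, 2))
    lanes = []
    for r in range(n_replicates):
        lanes.append(
            quantify_lane(
                {
                    "monomer": monomer_level,
                    "concatemer": concatemer_level,
                    "CM": fractions["CM_detectable"] * factors[r, 0],
                    "CD": fractions["CD_detectable"] * factors[r, 1],
                }
            )
        )
    return lanes


def simulate_atpase_series(
    true_rate: float,
    duration: float = 90.0,
    interval: float = 0.5,
    curve: StandardCurve = StandardCurve(slope=0.01, intercept=0.1),
    saturation_time: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AbsorbanceSeries:
    """Absorbance series with a linear phase: 30-s sampling over 90 min.

    Absorbance rises at ``true_rate * curve.slope`` AU/min until
    ``saturation_time`` (default: never saturates), then stays constant;
    additive Gaussian noise of SD ``noise_sd`` AU is applied per point.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if saturation_time is None:
        saturation_time = duration
    if not 0.0 <= saturation_time <= duration:
        raise ValueError("need 0 <= saturation_time <= duration")
    times = np.arange(0.0, duration + interval / 2, interval)
    values = curve.intercept + curve.slope * true_rate * np.minimum(times, saturation_time)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, times.size)
    return AbsorbanceSeries(times=times, values=values)
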