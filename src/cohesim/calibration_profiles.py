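"""Occupancy-ratio calibration, per-base pileups and anchor meta-profiles.

The occupancy ratio (OR) converts ChIP read depth into a quantitatively
comparable scale across samples using the spike-in calibration genome:

    OR = (W_c * IP_x) / (W_x * IP_c)

where W and IP are whole-cell-extract and immunoprecipitate read counts on
the experimental (x) and calibration (c) genomes.  Coverage is summarised as
zero-filled per-base depth tracks (every position present, gaps at depth 0),
averaged across chromosomes around a per-chromosome anchor (the
centromere-proximal CDEIII element in the motivating assay, window up to
60 kb either side), then scaled by OR x (1e6 / IP_x) — "multiplied by the
occupancy ratio and normalized to 1 million reads".  Tracks export to plain
bedGraph or fixedStep wiggle text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .read_assignment import (
    AssignedRead,
    CalibrationCounts,
    assign_reads_sequential,
    tally_calibration_counts,
)
from .synthetic_data import SimRead, ToyGenomePair

__all__ = [
    "CoverageTrack",
    "MetaProfile",
    "CalibrationResult",
    "occupancy_ratio",
    "zero_filled_pileup",
    "anchor_meta_profile",
    "calibrate_profile",
    "export_track",
    "parse_track",
    "meta_profile_table",
    "calibration_report",
    "run_calibrated_profile",
]


@dataclass
class CoverageTrack:
    """Zero-filled per-base read depth for one chromosome (1..length)."""

    chrom: str
    length: int
    depth: np.ndarray
    state: str = "raw"  # "raw" | "calibrated"

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (self.length,):
            raise ValueError("depth vector length must equal chromosome length")
        if np.any(self.depth < 0):
            raise ValueError("negative depth")
        if self.state not in ("raw", "calibrated"):
            raise ValueError(f"unknown state {self.state!r}")


@dataclass
class MetaProfile:
    """Cross-chromosome average depth at integer offsets -W..+W from anchors.

    ``values`` is NaN at offsets no chromosome covers; ``n_contributing``
    counts the chromosomes whose coordinates cover each offset (windows
    truncated at chromosome ends contribute only in-bounds offsets).
    """

    window: int
    offsets: np.ndarray
    values: np.ndarray
    n_contributing: np.ndarray
    state: str = "raw"

    def __post_init__(self) -> None:
        expected = 2 * self.window + 1
        if not (len(self.offsets) == len(self.values) == len(self.n_contributing) == expected):
            raise ValueError(f"profile must have exactly {expected} offsets")


@dataclass(frozen=True)
class CalibrationResult:
    """The occupancy ratio and the per-million denominator."""

    OR: float
    total_ip_experimental_reads: int


def occupancy_ratio(
    counts: CalibrationCounts, denominator: str = "ip_experimental"
) -> CalibrationResult:
    """Occupancy ratio OR = (W_c * IP_x) / (W_x * IP_c).

    ``denominator`` selects the per-million read count: uniquely assigned
    experimental-genome IP reads (default) or all uniquely assigned IP
    reads (``"ip_all"``).
    """
    for name, value in (("W_x", counts.W_x), ("IP_c", counts.IP_c)):
        if value == 0:
            raise ValueError(f"occupancy ratio undefined: {name} is zero")
    if denominator == "ip_experimental":
        total = counts.IP_x
    elif denominator == "ip_all":
        total = counts.IP_x + counts.IP_c
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if total == 0:
        raise ValueError("occupancy ratio denominator is zero")
    return CalibrationResult(
        OR=(counts.W_c * counts.IP_x) / (counts.W_x * counts.IP_c),
        total_ip_experimental_reads=total,
    )


def zero_filled_pileup(
    assignments: Iterable[AssignedRead], chrom: str, length: int
) -> CoverageTrack:
    """Per-base read depth with every position 1..length present.

    ``depth[i]`` counts the reads whose aligned interval covers base i+1.
    Assignments on other chromosomes (and unassigned reads) are ignored; a
    read interval that leaves the chromosome is a hard error, because the
    upstream assignment contract forbids it.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    diff = np.zeros(length + 1)
    for a in assignments:
        if a.chrom != chrom:
            continue
        end = a.start + a.aligned_length - 1
        if a.start < 1 or end > length:
            raise ValueError(
                f"read {a.read_id} interval [{a.start}, {end}] exceeds "
                f"chromosome {chrom} bounds (1..{length})"
            )
        diff[a.start - 1] += 1
        diff[end] -= 1
    return CoverageTrack(chrom=chrom, length=length, depth=np.cumsum(diff[:length]))


def anchor_meta_profile(
    tracks: Sequence[CoverageTrack], anchors: Mapping[str, int], window: int
) -> MetaProfile:
    """Average depth across chromosomes at each offset from their anchors.

    For offset d in [-window, +window] the value is the mean of
    ``depth[anchor + d]`` over the chromosomes where that coordinate is in
    bounds; chromosomes whose window is truncated by an end contribute only
    to their in-bounds offsets.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not tracks:
        raise ValueError("no coverage tracks given")
    states = {t.state for t in tracks}
    if len(states) > 1:
        raise ValueError("mixed raw/calibrated tracks")
    offsets = np.arange(-window, window + 1)
    sums = np.zeros(offsets.size)
    n = np.zeros(offsets.size, dtype=int)
    for track in tracks:
        if track.chrom not in anchors:
            raise ValueError(f"no anchor for chromosome {track.chrom!r}")
        idx = anchors[track.chrom] - 1 + offsets
        valid = (idx >= 0) & (idx < track.length)
        sums[valid] += track.depth[idx[valid]]
        n[valid] += 1
    values = np.full(offsets.size, np.nan)
    covered = n > 0
    values[covered] = sums[covered] / n[covered]
    return MetaProfile(
        window=window, offsets=offsets, values=values, n_contributing=n,
        state=states.pop(),
    )


def calibrate_profile(
    profile: MetaProfile | CoverageTrack, calib: CalibrationResult
):
    """Scale a raw profile/track by OR x (1e6 / IP reads); no double scaling."""
    if profile.state != "raw":
        raise ValueError("profile is already calibrated")
    factor = calib.OR * (1_000_000 / calib.total_ip_experimental_reads)
    if isinstance(profile, CoverageTrack):
        return replace(profile, depth=profile.depth * factor, state="calibrated")
    return replace(profile, values=profile.values * factor, state="calibrated")


# ---------------------------------------------------------------------------
# Text track export


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else format(float(v), ".17g")


def export_track(track: CoverageTrack, dialect: str = "bedGraph") -> str:
    """Render a coverage track as bedGraph (0-based half-open, run-length
    collapsed) or fixedStep wiggle text; the round trip through
    :func:`parse_track` reproduces the depth vector exactly."""
    if dialect == "bedGraph":
        depth = track.depth
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [track.length]))
        lines = [
            f"{track.chrom}\t{s}\t{e}\t{_fmt(depth[s])}"
            for s, e in zip(starts, ends)
        ]
        return "\n".join(lines) + "\n"
    if dialect == "wiggle":
        lines = [f"fixedStep chrom={track.chrom} start=1 step=1"]
        lines += [_fmt(v) for v in track.depth]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


def parse_track(text: str, length: int | None = None, state: str = "raw") -> CoverageTrack:
    """Read back a track written by :func:`export_track` (either dialect)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty track document")
    if lines[0].startswith("fixedStep"):
        fields = dict(kv.split("=") for kv in lines[0].split()[1:])
        depth = np.array([float(v) for v in lines[1:]])
        return CoverageTrack(fields["chrom"], depth.size, depth, state=state)
    chrom = lines[0].split("\t")[0]
    intervals = []
    end_max = 0
    for ln in lines:
        c, s, e, v = ln.split("\t")
        intervals.append((int(s), int(e), float(v)))
        end_max = max(end_max, int(e))
    n = length or end_max
    depth = np.zeros(n)
    for s, e, v in intervals:
        depth[s:e] = v
    return CoverageTrack(chrom, n, depth, state=state)


def meta_profile_table(profile: MetaProfile):
    """Meta-profile as a pandas DataFrame (offset, value, n_contributing)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "offset": profile.offsets,
            "value": profile.values,
            "n_contributing": profile.n_contributing,
        }
    )


def calibration_report(counts: CalibrationCounts, calib: CalibrationResult) -> str:
    """JSON report of the four counts, the OR and the per-million denominator."""
    return json.dumps(
        {
            "W_x": counts.W_x,
            "W_c": counts.W_c,
            "IP_x": counts.IP_x,
            "IP_c": counts.IP_c,
            "OR": calib.OR,
            "per_million_denominator": calib.total_ip_experimental_reads,
        },
        indent=2,
    )


# ---------------------------------------------------------------------------
# End-to-end convenience


def run_calibrated_profile(
    pair: ToyGenomePair,
    reads: Sequence[SimRead],
    window: int = 60_000,
    denominator: str = "ip_experimental",
) -> dict:
    """Full pipeline: assign -> tally -> OR -> pileup -> meta-profile -> calibrate.

    ``reads`` must carry IP and WCE samples (``SimRead.sample``).  Returns a
    dict with the assignments, counts, calibration, raw IP tracks and the
    raw and calibrated anchor meta-profiles.
    """
    ip_reads = [r for r in reads if r.sample == "IP"]
    wce_reads = [r for r in reads if r.sample == "WCE"]
    if not ip_reads or not wce_reads:
        raise ValueError("need both IP and WCE reads")
    assign_ip = assign_reads_sequential(ip_reads, pair)
    assign_wce = assign_reads_sequential(wce_reads, pair)
    counts = tally_calibration_counts(assign_ip, assign_wce)
    calib = occupancy_ratio(counts, denominator=denominator)
    tracks = [
        zero_filled_pileup(assign_ip, chrom, len(seq))
        for chrom, seq in pair.experimental.items()
    ]
    raw_profile = anchor_meta_profile(tracks, pair.anchors, window)
    return {
        "assignments_ip": assign_ip,
        "assignments_wce": assign_wce,
        "counts": counts,
        "calibration": calib,
        "tracks": tracks,
        "raw_profile": raw_profile,
        "calibrated_profile": calibrate_profile(raw_profile, calib),
    }
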