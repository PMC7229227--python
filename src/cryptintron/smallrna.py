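"""Strand-resolved small-RNA coverage and locus-level siRNA-loss calls.

siRNA libraries are length-filtered (21–24 nt by default, the Dicer
product range), piled up per strand, normalised to reads per million
mapped reads (RPM), and compared between genotypes to flag loci where
siRNA production has been abolished.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from . import io as cio

DEFAULT_LEN_MIN = 21
DEFAULT_LEN_MAX = 24
DEFAULT_FLOOR_RPM = 1.0
ABOLISHED_CONTRAST = 10.0  # reference locus mass must exceed floor by this factor


@dataclass(frozen=True)
class SmallRNARead:
    """A mapped small-RNA read: contig, 0-based start, length, strand."""

    contig: str
    start: int
    length: int
    strand: str

    def __post_init__(self) -> None:
        if not 15 <= self.length <= 35:
            raise ValueError(f"small-RNA length {self.length} outside [15, 35]")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.start < 0:
            raise ValueError("negative start")

    @property
    def end(self) -> int:
        return self.start + self.length


def filter_by_length(
    reads: Iterable[SmallRNARead],
    min_len: int = DEFAULT_LEN_MIN,
    max_len: int = DEFAULT_LEN_MAX,
) -> tuple[list[SmallRNARead], dict[int, int]]:
    """Retain reads with min_len <= length <= max_len (inclusive).

    Also returns the full-range length histogram of the *input* for QC —
    a broad histogram is the signature of degradation products rather
    than bona fide siRNAs.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    histogram: dict[int, int] = {}
    retained = []
    for read in reads:
        histogram[read.length] = histogram.get(read.length, 0) + 1
        if min_len <= read.length <= max_len:
            retained.append(read)
    return retained, dict(sorted(histogram.items()))


@dataclass
class StrandedCoverageTrack:
    """Per-base (or per-bin), per-strand RPM-normalised signal.

    ``normalization`` is the factor 10^6 / total_mapped_reads applied to
    raw counts; ``metadata`` carries genotype label and length window.
    """

    top: dict[str, np.ndarray]
    bottom: dict[str, np.ndarray]
    normalization: float
    bin_size: int = 1
    metadata: dict = field(default_factory=dict)

    def mass(self) -> tuple[float, float]:
        top = sum(float(v.sum()) for v in self.top.values())
        bottom = sum(float(v.sum()) for v in self.bottom.values())
        return top, bottom

    def region_mass(self, contig: str, start: int, end: int) -> tuple[float, float]:
        if contig not in self.top:
            raise ValueError(f"unknown contig {contig}")
        n = self.top[contig].size
        lo, hi = start // self.bin_size, -(-end // self.bin_size)
        if start < 0 or hi > n:
            raise ValueError(f"region {contig}:{start}-{end} outside contig")
        return (
            float(self.top[contig][lo:hi].sum()),
            float(self.bottom[contig][lo:hi].sum()),
        )

    def write_sgr(self, prefix: str | Path) -> tuple[Path, Path]:
        """One SGR file per strand (``<prefix>.top.sgr`` / ``.bottom.sgr``)."""
        top_path = Path(f"{prefix}.top.sgr")
        bottom_path = Path(f"{prefix}.bottom.sgr")
        cio.write_sgr(self.top, top_path, self.bin_size)
        cio.write_sgr(self.bottom, bottom_path, self.bin_size)
        return top_path, bottom_path

    def write_bedgraph(self, path: str | Path) -> None:
        """Two-track bedGraph; bottom-strand signal is emitted negative so
        the strands plot above and below the axis."""
        path = Path(path)
        cio.write_bedgraph(self.top, path, self.bin_size, track_name="top")
        neg = {c: -v for c, v in self.bottom.items()}
        tmp = path.with_suffix(path.suffix + ".bottom")
        cio.write_bedgraph(neg, tmp, self.bin_size, track_name="bottom")
        with open(path, "a") as out:
            out.write(tmp.read_text())
        tmp.unlink()


def stranded_coverage(
    reads: Sequence[SmallRNARead],
    total_mapped: int,
    contig_lengths: Mapping[str, int],
    bin_size: int = 1,
    mode: Literal["full", "five_prime"] = "full",
    metadata: dict | None = None,
) -> StrandedCoverageTrack:
    """Per-strand pileup normalised to reads per million mapped reads.

    ``total_mapped`` is the library's total mapped read count *before*
    length filtering, so filtering changes track mass but not the
    normaliser.  ``full`` piles up every base of each read;
    ``five_prime`` counts only the 5' end (strand-aware).
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    factor = 1e6 / total_mapped
    n_bins = {c: -(-length // bin_size) for c, length in contig_lengths.items()}
    top = {c: np.zeros(n, dtype=float) for c, n in n_bins.items()}
    bottom = {c: np.zeros(n, dtype=float) for c, n in n_bins.items()}
    for read in reads:
        target = top if read.strand == "+" else bottom
        arr = target[read.contig]
        if mode == "five_prime":
            pos = read.start if read.strand == "+" else read.end - 1
            arr[pos // bin_size] += 1.0
        elif mode == "full":
            if bin_size == 1:
                arr[read.start : read.end] += 1.0
            else:
                for b in range(read.start // bin_size, -(-read.end // bin_size)):
                    lo = max(read.start, b * bin_size)
                    hi = min(read.end, (b + 1) * bin_size)
                    arr[b] += float(hi - lo) / bin_size
        else:
            raise ValueError(f"unknown coverage mode {mode!r}")
    for arr_map in (top, bottom):
        for c in arr_map:
            arr_map[c] *= factor
    return StrandedCoverageTrack(
        top=top,
        bottom=bottom,
        normalization=factor,
        bin_size=bin_size,
        metadata=dict(metadata or {}),
    )


def compare_loss(
    track_a: StrandedCoverageTrack,
    track_b: StrandedCoverageTrack,
    region: tuple[str, int, int],
    floor_rpm: float = DEFAULT_FLOOR_RPM,
    pseudocount: float = 0.01,
) -> dict:
    """Locus-level siRNA-loss comparison between two genotypes.

    Sums RPM per strand over ``region`` in both tracks and reports the
    log2 ratio (with pseudocount) of total masses.  The *abolished* flag
    is decided on the mean per-base RPM over the region — the unit a
    genome-browser track displays, independent of locus width: abolished
    when track_b's mean signal falls below ``floor_rpm`` while track_a
    retains at least ``ABOLISHED_CONTRAST`` x ``floor_rpm`` — i.e. the
    signal was there and is now gone, not merely absent in both.
    """
    if track_a.bin_size != track_b.bin_size:
        raise ValueError("tracks must share binning")
    contig, start, end = region
    width = end - start
    if width <= 0:
        raise ValueError("empty region")
    a_top, a_bottom = track_a.region_mass(contig, start, end)
    b_top, b_bottom = track_b.region_mass(contig, start, end)
    a_mass = a_top + a_bottom
    b_mass = b_top + b_bottom
    # per-bin values average per-base counts, so bin_size * sum / width
    # is the mean per-base RPM whatever the binning
    a_mean = a_mass * track_a.bin_size / width
    b_mean = b_mass * track_b.bin_size / width
    return {
        "contig": contig,
        "start": start,
        "end": end,
        "a_top_rpm": a_top,
        "a_bottom_rpm": a_bottom,
        "b_top_rpm": b_top,
        "b_bottom_rpm": b_bottom,
        "a_total_rpm": a_mass,
        "b_total_rpm": b_mass,
        "a_mean_rpm": a_mean,
        "b_mean_rpm": b_mean,
        "log2_ratio_b_over_a": math.log2((b_mass + pseudocount) / (a_mass + pseudocount)),
        "floor_rpm": floor_rpm,
        "abolished": bool(
            b_mean < floor_rpm and a_mean >= ABOLISHED_CONTRAST * floor_rpm
        ),
    }
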