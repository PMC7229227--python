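"""Splice-junction extraction and the percent-spliced statistic.

A spliced (gapped) alignment is an ordered run of aligned blocks separated
by reference skips; each skip is a candidate intron.  For every distinct
skipped interval we count the reads split at it (the numerator) and the
reads overlapping its junction (the denominator); their ratio is the
splicing efficiency, the fraction of molecules in which the intron was
excised.

Coordinates are 0-based half-open throughout.  An intron [s, e) skips the
reference bases s .. e-1; its left boundary sits between s-1 and s, its
right boundary between e-1 and e.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

DEFAULT_MIN_OVERHANG = 4
DEFAULT_MIN_INTRON = 30
DEFAULT_MAX_INTRON = 10_000

BoundaryMode = Literal["left", "right", "either", "both"]


@dataclass(frozen=True)
class SplicedAlignment:
    """One aligned read: aligned blocks interleaved with reference skips.

    ``blocks`` is a tuple of ``(aligned_length, skipped_length)`` pairs;
    the final pair has ``skipped_length == 0``.  Equivalent to a CIGAR
    string restricted to M and N operations.
    """

    read_id: str
    contig: str
    start: int  # leftmost reference position, 0-based
    blocks: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("alignment must contain at least one block")
        if self.start < 0:
            raise ValueError("negative reference start")
        for i, (m, n) in enumerate(self.blocks):
            if m <= 0:
                raise ValueError(f"non-positive aligned length in {self.read_id}")
            terminal = i == len(self.blocks) - 1
            if terminal and n != 0:
                raise ValueError("terminal skip length must be 0")
            if not terminal and n <= 0:
                raise ValueError("internal skip length must be positive")

    @property
    def end(self) -> int:
        """One past the last aligned reference base."""
        return self.start + sum(m + n for m, n in self.blocks)

    @property
    def read_length(self) -> int:
        return sum(m for m, _ in self.blocks)

    def aligned_intervals(self) -> list[tuple[int, int]]:
        """Reference intervals covered by aligned bases, ascending."""
        out = []
        pos = self.start
        for m, n in self.blocks:
            out.append((pos, pos + m))
            pos += m + n
        return out

    def skips(self) -> list[tuple[int, int, int, int]]:
        """Skipped intervals as ``(left_anchor, start, end, right_anchor)``.

        Anchors are the aligned block lengths flanking the skip.
        """
        out = []
        pos = self.start
        for i, (m, n) in enumerate(self.blocks):
            if n > 0:
                out.append((m, pos + m, pos + m + n, self.blocks[i + 1][0]))
            pos += m + n
        return out

    def cigar(self) -> str:
        parts = []
        for m, n in self.blocks:
            parts.append(f"{m}M")
            if n:
                parts.append(f"{n}N")
        return "".join(parts)


@dataclass
class JunctionQuantification:
    """A candidate intron with its split-read and junction-overlap support."""

    contig: str
    start: int
    end: int
    strand: str = "."
    split_read_count: int = 0
    overlapping_read_count: int | None = None
    min_overhang: int = DEFAULT_MIN_OVERHANG

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty or inverted junction interval")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    @property
    def efficiency(self) -> float | None:
        """Split reads over junction-overlapping reads; None if unsupported.

        A zero denominator yields None (undefined), never 0: absence of
        overlapping reads is absence of evidence, not evidence of
        retention.
        """
        if not self.overlapping_read_count:
            return None
        return self.split_read_count / self.overlapping_read_count


def splicing_efficiency(junction: JunctionQuantification) -> float | None:
    """Fraction of junction-overlapping reads that are split at it."""
    return junction.efficiency


def extract_junctions(
    alignments: Iterable[SplicedAlignment],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_intron: int = DEFAULT_MAX_INTRON,
) -> tuple[list[JunctionQuantification], dict[str, int]]:
    """Collect distinct skipped intervals with their split-read counts.

    A read supports a junction only when it carries >= ``min_overhang``
    aligned bases on both sides of that skip; a read with k skips can
    support up to k junctions.  Skips outside [min_intron, max_intron]
    are ignored and tallied in the returned diagnostics.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    counts: Counter[tuple[str, int, int]] = Counter()
    diagnostics: Counter[str] = Counter()
    for aln in alignments:
        for left, s, e, right in aln.skips():
            length = e - s
            if not (min_intron <= length <= max_intron):
                diagnostics["skip_length_out_of_range"] += 1
                continue
            if left < min_overhang or right < min_overhang:
                diagnostics["insufficient_overhang"] += 1
                continue
            counts[(aln.contig, s, e)] += 1
    junctions = [
        JunctionQuantification(
            contig=c, start=s, end=e, split_read_count=n, min_overhang=min_overhang
        )
        for (c, s, e), n in sorted(counts.items())
    ]
    return junctions, dict(diagnostics)


def _is_split_at(
    aln: SplicedAlignment, start: int, end: int, min_overhang: int
) -> bool:
    for left, s, e, right in aln.skips():
        if s == start and e == end and left >= min_overhang and right >= min_overhang:
            return True
    return False


def _covers_boundary(aln: SplicedAlignment, boundary: int, min_overhang: int) -> bool:
    """True if one aligned block spans ``boundary`` with min_overhang on each side."""
    for s, e in aln.aligned_intervals():
        if s <= boundary - min_overhang and e >= boundary + min_overhang:
            return True
    return False


def read_overlaps_junction(
    aln: SplicedAlignment,
    junction: JunctionQuantification,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    boundary_mode: BoundaryMode = "left",
) -> bool:
    """Does this read enter the denominator of the percent-spliced statistic?

    Yes when it is split exactly at the junction, or when a contiguous
    aligned block covers the junction boundary selected by
    ``boundary_mode`` with ``min_overhang`` aligned bases on each side.

    ``left`` (default) counts the left genomic boundary only: every
    molecule then contributes reads at a single window of identical width
    whether or not the intron was excised, so the statistic is an
    unbiased binomial estimate of the per-molecule excision probability.
    ``either``/``both`` are provided for sensitivity analyses; ``either``
    deflates the statistic for introns longer than a read because a
    retained molecule offers two disjoint windows.
    """
    if aln.contig != junction.contig:
        return False
    if _is_split_at(aln, junction.start, junction.end, min_overhang):
        return True
    left = _covers_boundary(aln, junction.start, min_overhang)
    if boundary_mode == "left":
        return left
    right = _covers_boundary(aln, junction.end, min_overhang)
    if boundary_mode == "right":
        return right
    if boundary_mode == "either":
        return left or right
    if boundary_mode == "both":
        return left and right
    raise ValueError(f"unknown boundary_mode {boundary_mode!r}")


def count_overlapping_reads(
    alignments: Iterable[SplicedAlignment],
    junction: JunctionQuantification,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    boundary_mode: BoundaryMode = "left",
    contig_lengths: dict[str, int] | None = None,
) -> int:
    """Count reads overlapping a junction; each read counts once."""
    if contig_lengths is not None:
        clen = contig_lengths.get(junction.contig)
        if clen is None or junction.start < 0 or junction.end > clen:
            raise ValueError(
                f"junction {junction.contig}:{junction.start}-{junction.end} "
                "outside contig"
            )
    return sum(
        read_overlaps_junction(aln, junction, min_overhang, boundary_mode)
        for aln in alignments
    )


def quantify_junctions(
    alignments: Sequence[SplicedAlignment],
    junctions: Sequence[JunctionQuantification],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    boundary_mode: BoundaryMode = "left",
) -> list[JunctionQuantification]:
    """Fill ``overlapping_read_count`` for every junction.

    Candidate reads per junction are pre-filtered on their reference span
    with vectorised interval checks, then confirmed block by block, so
    the result is identical to scanning every read.
    """
    by_contig: dict[str, list[SplicedAlignment]] = defaultdict(list)
    for aln in alignments:
        by_contig[aln.contig].append(aln)
    spans: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, alns in by_contig.items():
        spans[contig] = (
            np.fromiter((a.start for a in alns), dtype=np.int64, count=len(alns)),
            np.fromiter((a.end for a in alns), dtype=np.int64, count=len(alns)),
        )
    out = []
    for j in junctions:
        alns = by_contig.get(j.contig, [])
        if not alns:
            out.append(replace(j, overlapping_read_count=0, min_overhang=min_overhang))
            continue
        starts, ends = spans[j.contig]
        lo = j.start - min_overhang
        hi = j.end + min_overhang
        candidate = np.nonzero((starts <= hi) & (ends >= lo))[0]
        n = sum(
            read_overlaps_junction(alns[i], j, min_overhang, boundary_mode)
            for i in candidate
        )
        out.append(replace(j, overlapping_read_count=int(n), min_overhang=min_overhang))
    return out
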