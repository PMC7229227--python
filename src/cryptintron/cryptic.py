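"""Classification of junctions as cryptic introns.

A cryptic intron is a splice junction that (i) does not match any
annotated intron, (ii) is absent from the reference (wild-type)
condition, and (iii) is inefficiently spliced — excised in strictly
less than 5% of the reads spanning its junction by default.  Such
introns surface only when RNA degradation is impaired and splicing wins
the kinetic competition in a detectable minority of molecules.
Consensus GT..AG splice sites are validated and reported, but are not
required for the cryptic verdict by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .junctions import JunctionQuantification
from .simulate import GeneModel  # type: ignore  # only for from_gene_models

logger = logging.getLogger(__name__)

DEFAULT_EFFICIENCY_THRESHOLD = 0.05
DEFAULT_MIN_DEPTH = 20
DEFAULT_MIN_REFERENCE_SUPPORT = 1

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IntronAnnotationSet:
    """Exact-coordinate lookup of annotated introns."""

    introns: frozenset[tuple[str, int, int]]
    strands: Mapping[tuple[str, int, int], str] | None = None

    @classmethod
    def from_tuples(
        cls, introns: Sequence[tuple[str, int, int, str]]
    ) -> "IntronAnnotationSet":
        keys = frozenset((c, s, e) for c, s, e, _ in introns)
        strands = {(c, s, e): strand for c, s, e, strand in introns}
        return cls(introns=keys, strands=strands)

    @classmethod
    def from_gff3(
        cls, path, known_contigs: Sequence[str] | None = None
    ) -> "IntronAnnotationSet":
        from . import io as cio

        entries = cio.read_gff3_introns(path)
        if known_contigs is not None:
            kept = []
            for entry in entries:
                if entry[0] not in known_contigs:
                    logger.warning(
                        "annotated intron on unknown contig %s ignored", entry[0]
                    )
                    continue
                kept.append(entry)
            entries = kept
        return cls.from_tuples(entries)

    @classmethod
    def from_gene_models(cls, genes: Sequence[GeneModel]) -> "IntronAnnotationSet":
        entries = [
            (g.contig, s, e, g.strand)
            for g in genes
            for (s, e), annotated in zip(g.introns, g.annotated)
            if annotated
        ]
        return cls.from_tuples(entries)

    def contains(self, contig: str, start: int, end: int, window: int = 0) -> bool:
        """Exact (contig, interval) membership; ``window`` > 0 allows a
        +/- window bp slop on each boundary independently."""
        if window == 0:
            return (contig, start, end) in self.introns
        return any(
            (contig, start + ds, end + de) in self.introns
            for ds in range(-window, window + 1)
            for de in range(-window, window + 1)
        )

    def __len__(self) -> int:
        return len(self.introns)


@dataclass(frozen=True)
class SpliceSites:
    """Donor/acceptor dinucleotides of an intron, in transcript orientation."""

    donor: str
    acceptor: str
    is_canonical: bool
    strand: str  # inferred or given; "." if undetermined


@dataclass
class CrypticIntronCall:
    """Final per-junction verdict with all contributing evidence."""

    junction: JunctionQuantification
    efficiency: float | None
    is_annotated: bool
    present_in_reference: bool
    splice_sites: SpliceSites | None
    depth_ok: bool
    is_cryptic: bool

    @property
    def is_canonical(self) -> bool | None:
        return None if self.splice_sites is None else self.splice_sites.is_canonical

    @property
    def verdict(self) -> str:
        if self.is_cryptic:
            return "cryptic"
        if self.efficiency is None or not self.depth_ok:
            return "insufficient_evidence"
        return "not_cryptic"


def subtract_annotated(
    junctions: Sequence[JunctionQuantification],
    annotation: IntronAnnotationSet,
    window: int = 0,
) -> list[bool]:
    """Flag each junction annotated iff its (contig, interval) matches an
    annotated intron exactly (or within ``window`` bp per boundary)."""
    return [
        annotation.contains(j.contig, j.start, j.end, window=window)
        for j in junctions
    ]


def subtract_reference_condition(
    test_junctions: Sequence[JunctionQuantification],
    reference_junctions: Sequence[JunctionQuantification],
    min_reference_support: int = DEFAULT_MIN_REFERENCE_SUPPORT,
) -> list[bool]:
    """Flag test junctions present in the reference (wild-type) condition.

    Present means the identical (contig, interval) was observed in the
    reference with at least ``min_reference_support`` split reads.
    """
    supported = {
        j.key for j in reference_junctions
        if j.split_read_count >= min_reference_support
    }
    return [j.key in supported for j in test_junctions]


def validate_splice_sites(
    junction: JunctionQuantification,
    sequences: Mapping[str, str],
    allow_gc: bool = False,
) -> SpliceSites:
    """Report donor/acceptor dinucleotides and whether they are consensus.

    The donor is the first two intronic bases and the acceptor the last
    two, read on the transcribed strand (reverse-complemented for minus
    strand).  With undetermined strand both orientations are tried and
    the matching one, if any, determines the reported strand.  Canonical
    means GT..AG (optionally also GC..AG).
    """
    seq = sequences.get(junction.contig)
    if seq is None:
        raise ValueError(f"no sequence for contig {junction.contig}")
    if junction.start < 0 or junction.end > len(seq) or junction.length < 4:
        raise ValueError(
            f"junction {junction.contig}:{junction.start}-{junction.end} "
            "at or beyond contig edge"
        )
    first = seq[junction.start : junction.start + 2].upper()
    last = seq[junction.end - 2 : junction.end].upper()

    def canonical(donor: str, acceptor: str) -> bool:
        return (donor, acceptor) == ("GT", "AG") or (
            allow_gc and (donor, acceptor) == ("GC", "AG")
        )

    plus = (first, last)
    minus = (_revcomp(last), _revcomp(first))
    if junction.strand == "+":
        return SpliceSites(*plus, canonical(*plus), "+")
    if junction.strand == "-":
        return SpliceSites(*minus, canonical(*minus), "-")
    # undetermined: infer from the dinucleotides themselves
    if canonical(*plus):
        return SpliceSites(*plus, True, "+")
    if canonical(*minus):
        return SpliceSites(*minus, True, "-")
    return SpliceSites(*plus, False, ".")


def classify_cryptic(
    junction: JunctionQuantification,
    is_annotated: bool,
    present_in_reference: bool,
    splice_sites: SpliceSites | None = None,
    efficiency_threshold: float = DEFAULT_EFFICIENCY_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    require_canonical: bool = False,
) -> CrypticIntronCall:
    """Apply the cryptic-intron rules to one quantified junction.

    cryptic = unannotated AND absent from reference AND efficiency
    strictly below ``efficiency_threshold`` AND junction depth at least
    ``min_depth``.  Low-depth or efficiency-undefined junctions are
    reported as insufficient evidence, never as cryptic.
    """
    efficiency = junction.efficiency
    depth_ok = (
        junction.overlapping_read_count is not None
        and junction.overlapping_read_count >= min_depth
    )
    is_cryptic = (
        not is_annotated
        and not present_in_reference
        and efficiency is not None
        and efficiency < efficiency_threshold
        and depth_ok
    )
    if require_canonical and is_cryptic:
        is_cryptic = splice_sites is not None and splice_sites.is_canonical
    return CrypticIntronCall(
        junction=junction,
        efficiency=efficiency,
        is_annotated=is_annotated,
        present_in_reference=present_in_reference,
        splice_sites=splice_sites,
        depth_ok=depth_ok,
        is_cryptic=is_cryptic,
    )


def call_cryptic_introns(
    test_junctions: Sequence[JunctionQuantification],
    reference_junctions: Sequence[JunctionQuantification],
    annotation: IntronAnnotationSet,
    sequences: Mapping[str, str] | None = None,
    efficiency_threshold: float = DEFAULT_EFFICIENCY_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_reference_support: int = DEFAULT_MIN_REFERENCE_SUPPORT,
    annotation_window: int = 0,
    require_canonical: bool = False,
    allow_gc: bool = False,
) -> list[CrypticIntronCall]:
    """Run the full rule chain over a set of quantified test junctions."""
    annotated = subtract_annotated(test_junctions, annotation, window=annotation_window)
    in_reference = subtract_reference_condition(
        test_junctions, reference_junctions, min_reference_support
    )
    calls = []
    for j, ann, ref in zip(test_junctions, annotated, in_reference):
        sites = (
            validate_splice_sites(j, sequences, allow_gc=allow_gc)
            if sequences is not None
            else None
        )
        calls.append(
            classify_cryptic(
                j,
                is_annotated=ann,
                present_in_reference=ref,
                splice_sites=sites,
                efficiency_threshold=efficiency_threshold,
                min_depth=min_depth,
                require_canonical=require_canonical,
            )
        )
    return calls
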