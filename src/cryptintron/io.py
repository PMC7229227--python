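"""Readers and writers for the plain-text genomics formats the pipeline uses.

Internal coordinates are 0-based half-open; conversion to each format's
convention (GFF3 and SGR 1-based, BED/bedGraph 0-based half-open) happens
only here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .junctions import JunctionQuantification, SplicedAlignment

# --- FASTA ---------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --- GFF3 ----------------------------------------------------------------

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def write_gff3(genes: Sequence, path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive).

    Emits gene and exon features for every gene, and intron features for
    *annotated* introns only — unannotated (cryptic) introns are absent
    from the annotation by definition.
    """
    lines = ["##gff-version 3"]
    for g in genes:
        gstart = min(s for s, _ in g.exons)
        gend = max(e for _, e in g.exons)
        lines.append(
            "\t".join(
                [g.contig, "cryptintron", "gene", str(gstart + 1), str(gend),
                 ".", g.strand, ".", f"ID={g.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(g.exons):
            lines.append(
                "\t".join(
                    [g.contig, "cryptintron", "exon", str(s + 1), str(e),
                     ".", g.strand, ".",
                     f"ID={g.gene_id}.exon{i + 1};Parent={g.gene_id}"]
                )
            )
        for i, (s, e) in enumerate(g.introns):
            if not g.annotated[i]:
                continue
            lines.append(
                "\t".join(
                    [g.contig, "cryptintron", "intron", str(s + 1), str(e),
                     ".", g.strand, ".",
                     f"ID={g.gene_id}.intron{i + 1};Parent={g.gene_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_features(path: str | Path) -> pd.DataFrame:
    """Parse a GFF3 file into a DataFrame with 0-based half-open start/end."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        rows.append(parts)
    df = pd.DataFrame(rows, columns=_GFF_COLUMNS)
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    return df


def read_gff3_introns(path: str | Path) -> list[tuple[str, int, int, str]]:
    df = read_gff3_features(path)
    introns = df[df["type"] == "intron"]
    return [
        (r.seqid, int(r.start), int(r.end), r.strand)
        for r in introns.itertuples(index=False)
    ]


# --- SAM -----------------------------------------------------------------


def _sam_header(contig_lengths: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_lengths.items()],
        }
    )


def write_sam(
    alignments: Iterable[SplicedAlignment],
    contig_lengths: Mapping[str, int],
    path: str | Path,
    sequences: Mapping[str, str] | None = None,
) -> None:
    """Write alignments as coordinate-sorted SAM text (CIGAR M/N only)."""
    header = _sam_header(contig_lengths)
    order = {c: i for i, c in enumerate(contig_lengths)}
    alns = sorted(alignments, key=lambda a: (order[a.contig], a.start, a.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alns:
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.reference_name = aln.contig
            seg.reference_start = aln.start
            seg.mapping_quality = 255
            seg.flag = 16 if aln.strand == "-" else 0
            cig = []
            for m, n in aln.blocks:
                cig.append((0, m))
                if n:
                    cig.append((3, n))
            seg.cigartuples = cig
            if sequences is not None:
                seq = "".join(
                    sequences[aln.contig][s:e] for s, e in aln.aligned_intervals()
                )
                if aln.strand == "-":
                    seq = str(Seq(seq).reverse_complement())
                seg.query_sequence = seq
            fh.write(seg)


def read_sam(path: str | Path) -> tuple[list[SplicedAlignment], dict[str, int]]:
    """Read SAM-dialect alignments; returns alignments and contig lengths.

    Only M (and =/X) and N CIGAR operations are supported, matching the
    simulator's output contract.
    """
    alignments: list[SplicedAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        contig_lengths = dict(zip(fh.references, fh.lengths))
        for seg in fh:
            if seg.is_unmapped or seg.cigartuples is None:
                continue
            blocks: list[tuple[int, int]] = []
            aligned = 0
            for op, length in seg.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    aligned += length
                elif op == 3:  # N
                    if aligned == 0:
                        raise ValueError(f"leading skip in {seg.query_name}")
                    blocks.append((aligned, length))
                    aligned = 0
                else:
                    raise ValueError(
                        f"unsupported CIGAR op {op} in {seg.query_name}"
                    )
            if aligned:
                blocks.append((aligned, 0))
            alignments.append(
                SplicedAlignment(
                    read_id=seg.query_name,
                    contig=seg.reference_name,
                    start=seg.reference_start,
                    blocks=tuple(blocks),
                    strand="-" if seg.is_reverse else "+",
                )
            )
    return alignments, contig_lengths


# --- junction tables -----------------------------------------------------


def junctions_to_frame(junctions: Sequence[JunctionQuantification]) -> pd.DataFrame:
    rows = []
    for j in junctions:
        eff = j.efficiency
        rows.append(
            {
                "contig": j.contig,
                "start": j.start,
                "end": j.end,
                "strand": j.strand,
                "split_reads": j.split_read_count,
                "overlapping_reads": j.overlapping_read_count,
                "efficiency": np.nan if eff is None else eff,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "strand", "split_reads",
            "overlapping_reads", "efficiency",
        ],
    )


def write_junction_table(
    junctions: Sequence[JunctionQuantification], path: str | Path
) -> None:
    junctions_to_frame(junctions).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_junctions_bed(
    junctions: Sequence[JunctionQuantification], path: str | Path, name: str = "junctions"
) -> None:
    """TopHat-style junctions BED: one BED12 row per junction.

    Blocks are the flanking anchors; the intron is the gap between them,
    so ``thickStart/blockSizes`` follow the junctions.bed convention.
    """
    lines = [f'track name="{name}" description="splice junctions"']
    for i, j in enumerate(junctions):
        anchor = j.min_overhang
        chrom_start = j.start - anchor
        chrom_end = j.end + anchor
        lines.append(
            "\t".join(
                [
                    j.contig, str(chrom_start), str(chrom_end), f"JUNC{i + 1:05d}",
                    str(j.split_read_count), j.strand if j.strand != "." else "+",
                    str(chrom_start), str(chrom_end), "255,0,0", "2",
                    f"{anchor},{anchor}", f"0,{j.end - chrom_start}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --- coverage tracks -----------------------------------------------------


def write_sgr(
    values_by_contig: Mapping[str, np.ndarray], path: str | Path, bin_size: int = 1
) -> None:
    """SGR: contig <tab> 1-based position <tab> value; zero bins skipped."""
    with open(path, "w") as fh:
        for contig in values_by_contig:
            vals = values_by_contig[contig]
            for i in np.nonzero(vals)[0]:
                pos = int(i) * bin_size + 1
                fh.write(f"{contig}\t{pos}\t{_fmt(vals[i])}\n")


def write_bedgraph(
    values_by_contig: Mapping[str, np.ndarray],
    path: str | Path,
    bin_size: int = 1,
    track_name: str | None = None,
) -> None:
    """bedGraph with run-length merging of equal adjacent values; zeros skipped."""
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for contig in values_by_contig:
            vals = np.asarray(values_by_contig[contig])
            if vals.size == 0:
                continue
            change = np.nonzero(np.diff(vals))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v == 0:
                    continue
                fh.write(
                    f"{contig}\t{int(s) * bin_size}\t{int(e) * bin_size}\t{_fmt(v)}\n"
                )


def read_bedgraph(
    path: str | Path, contig_lengths: Mapping[str, int], bin_size: int = 1
) -> dict[str, np.ndarray]:
    out = {
        c: np.zeros(-(-length // bin_size), dtype=float)
        for c, length in contig_lengths.items()
    }
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("track", "#")):
            continue
        contig, start, end, value = line.split("\t")
        s, e = int(start) // bin_size, int(end) // bin_size
        out[contig][s:e] = float(value)
    return out


def _fmt(v: float) -> str:
    """Stable numeric formatting so identical runs are byte-identical."""
    return f"{float(v):.6g}"


# --- BED (read intervals) ------------------------------------------------


def write_reads_bed(reads: Sequence, path: str | Path) -> None:
    lines = [
        "\t".join(
            [r.contig, str(r.start), str(r.start + r.length),
             f"smrna{i + 1:06d}", "0", r.strand]
        )
        for i, r in enumerate(reads)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_reads_bed(path: str | Path):
    from .smallrna import SmallRNARead

    reads = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("track", "#")):
            continue
        contig, start, end, _name, _score, strand = line.split("\t")[:6]
        reads.append(
            SmallRNARead(
                contig=contig,
                start=int(start),
                length=int(end) - int(start),
                strand=strand,
            )
        )
    return reads
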