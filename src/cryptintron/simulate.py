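"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the data layers of a fission-yeast style study of
lncRNA-mediated silencing:

* a toy genome carrying gene models whose introns are excised per
  molecule at programmed efficiencies — including "cryptic" introns with
  consensus splice sites that are excised in only a few percent of
  molecules and are absent from the annotation;
* 15–30 nt small-RNA reads with a controlled length distribution
  (siRNA-like 21–24 nt peak, or a broad degradation-like profile) and
  strand of origin;
* paired tagged/untagged IP coverage tracks with injected fold
  enrichment over chosen regions;
* PSM (peptide-spectrum match) count tables with a null population plus
  enriched outliers.

Everything is already-aligned: no sequencing-error or aligner model.
All randomness flows through a caller-supplied :class:`numpy.random.Generator`
(or the config seed), so a fixed seed reproduces outputs byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import CoverageTrack
from .junctions import SplicedAlignment
from .smallrna import SmallRNARead

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# siRNA-like: sharp 21-24 nt peak (Dicer products)
SIRNA_LENGTH_DIST: dict[int, float] = {21: 0.15, 22: 0.35, 23: 0.35, 24: 0.15}
# degradation-like: broad 15-30 nt profile of turnover fragments
DEGRADATION_LENGTH_DIST: dict[int, float] = {n: 1.0 / 16.0 for n in range(15, 31)}


@dataclass(frozen=True)
class ToyGenome:
    """A small in-memory genome: contig id -> uppercase ACGT string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("contig ids must be unique")
        for name, seq in self.sequences.items():
            if len(seq) < 1000:
                raise ValueError(f"contig {name} shorter than 1 kb")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} contains non-ACGT characters")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class GeneModel:
    """Exon chain on a contig; introns are the gaps between exons.

    ``splicing_efficiency[i]`` is the per-molecule probability that
    intron i is excised; ``annotated[i]`` marks whether it appears in the
    annotation (cryptic introns are planted unannotated).
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    splicing_efficiency: list[float]
    annotated: list[bool]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError("empty exon")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise ValueError("exons must be sorted and non-overlapping")
        n_introns = len(self.exons) - 1
        if len(self.splicing_efficiency) != n_introns or len(self.annotated) != n_introns:
            raise ValueError("per-intron fields must match intron count")
        for eff in self.splicing_efficiency:
            if not 0.0 <= eff <= 1.0:
                raise ValueError("splicing efficiency must lie in [0, 1]")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class GenePlan:
    """Blueprint for one planted gene."""

    splicing_efficiency: list[float] = field(default_factory=lambda: [0.9])
    annotated: list[bool] = field(default_factory=lambda: [True])
    exon_length: int = 150
    intron_length: int = 60
    strand: str = "+"
    canonical: list[bool] | None = None  # default: all canonical GT..AG

    @property
    def n_introns(self) -> int:
        return len(self.splicing_efficiency)


@dataclass
class SimulationConfig:
    """Layout and sampling parameters for the toy study."""

    seed: int = 0
    read_length: int = 50
    depth: float = 10.0  # mean read-start coverage per molecule position
    n_molecules: int = 500  # molecules per gene
    genes: list[GenePlan] = field(default_factory=lambda: [GenePlan()])
    intergenic: int = 300  # spacer between genes, bp
    min_intron_length: int = 30
    max_intron_length: int = 1000
    contig_id: str = "toy_1"

    def validate(self) -> None:
        if self.read_length < 2:
            raise ValueError("read_length too small")
        for plan in self.genes:
            if plan.intron_length < self.min_intron_length:
                raise ValueError(
                    f"intron length {plan.intron_length} < minimum "
                    f"{self.min_intron_length}"
                )
            if plan.intron_length > self.max_intron_length:
                raise ValueError("intron length exceeds maximum")
            if plan.exon_length < self.read_length:
                raise ValueError("exons must cover at least one read length")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _plant_splice_sites(
    seq: list[str], intron: tuple[int, int], strand: str, canonical: bool
) -> None:
    s, e = intron
    if canonical:
        donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
    else:
        # deliberately non-consensus on either strand (not GT..AG / CT..AC)
        donor, acceptor = ("CC", "GG")
    seq[s], seq[s + 1] = donor[0], donor[1]
    seq[e - 2], seq[e - 1] = acceptor[0], acceptor[1]


def make_toy_genome(config: SimulationConfig) -> tuple[ToyGenome, list[GeneModel]]:
    """Build a random genome with planted gene models.

    Every intron gets canonical GT..AG dinucleotides on its own strand
    unless the plan requests non-canonical sites.
    """
    config.validate()
    rng = config.rng()
    genes: list[GeneModel] = []
    cursor = max(500, config.intergenic)
    layouts = []
    for gi, plan in enumerate(config.genes):
        exons = []
        pos = cursor
        for _ in range(plan.n_introns + 1):
            exons.append((pos, pos + plan.exon_length))
            pos += plan.exon_length + plan.intron_length
        pos -= plan.intron_length  # no intron after last exon
        genes.append(
            GeneModel(
                gene_id=f"gene{gi + 1:03d}",
                contig=config.contig_id,
                strand=plan.strand,
                exons=exons,
                splicing_efficiency=list(plan.splicing_efficiency),
                annotated=list(plan.annotated),
            )
        )
        layouts.append(plan)
        cursor = pos + config.intergenic
    total = max(cursor + 500, 1000)
    seq = list(rng.choice(list("ACGT"), size=total))
    for gene, plan in zip(genes, layouts):
        canonical = plan.canonical or [True] * plan.n_introns
        for intron, canon in zip(gene.introns, canonical):
            _plant_splice_sites(seq, intron, gene.strand, canon)
    genome = ToyGenome(sequences={config.contig_id: "".join(seq)})
    return genome, genes


# --- spliced reads -------------------------------------------------------


def _molecule_segments(
    gene: GeneModel, excised: np.ndarray
) -> list[tuple[int, int]]:
    """Genomic segments of one molecule; retained introns merge exons."""
    segments: list[tuple[int, int]] = [gene.exons[0]]
    for i, exon in enumerate(gene.exons[1:]):
        if excised[i]:
            segments.append(exon)
        else:
            s, _ = segments[-1]
            segments[-1] = (s, exon[1])
    return segments


def _read_blocks(
    segments: list[tuple[int, int]], offset: int, read_length: int
) -> tuple[int, tuple[tuple[int, int], ...]]:
    """Map a molecule-coordinate read onto genomic (aligned, skip) blocks."""
    blocks: list[tuple[int, int]] = []
    start = None
    remaining = read_length
    pos = offset
    for i, (s, e) in enumerate(segments):
        seg_len = e - s
        if pos >= seg_len:
            pos -= seg_len
            continue
        take = min(seg_len - pos, remaining)
        gstart = s + pos
        if start is None:
            start = gstart
        skip = 0
        if take < remaining and i + 1 < len(segments):
            skip = segments[i + 1][0] - (gstart + take)
        blocks.append((take, skip))
        remaining -= take
        pos = 0
        if remaining == 0:
            break
    assert start is not None and remaining == 0
    if blocks and blocks[-1][1] != 0:
        blocks[-1] = (blocks[-1][0], 0)
    return start, tuple(blocks)


def simulate_spliced_reads(
    genome: ToyGenome,
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SplicedAlignment], pd.DataFrame]:
    """Sample reads from per-molecule independently spliced transcripts.

    Each molecule excises intron i with probability
    ``splicing_efficiency[i]`` (independent Bernoulli per intron).  Reads
    start uniformly along the molecule; a read crossing an excised intron
    carries a reference skip of exactly the intron length, while reads
    from retention molecules run contiguously across it.

    Returns the alignments and a per-intron ground-truth table with the
    programmed efficiency and the realised molecule counts.
    """
    if rng is None:
        rng = config.rng()
    if config.depth <= 0:
        logger.warning("zero-depth request: returning no reads")
        return [], _truth_frame(genes, {})
    reads: list[SplicedAlignment] = []
    spliced_molecules: dict[tuple[str, int], int] = {}
    for gene in genes:
        n_introns = len(gene.introns)
        excised_all = (
            rng.random((config.n_molecules, n_introns))
            < np.asarray(gene.splicing_efficiency)
        )
        for i in range(n_introns):
            spliced_molecules[(gene.gene_id, i)] = int(excised_all[:, i].sum())
        # molecule lengths and read counts are vectorised; only molecules
        # that actually yield reads pay the per-molecule mapping cost
        intron_lengths = np.asarray(
            [e - s for s, e in gene.introns], dtype=np.int64
        )
        span_length = gene.span[1] - gene.span[0]
        mol_lengths = span_length - (
            excised_all @ intron_lengths if n_introns else 0
        )
        n_pos = np.maximum(mol_lengths - config.read_length + 1, 0)
        n_reads_per_mol = rng.poisson(
            config.depth * n_pos / config.n_molecules
        )
        for mol in np.nonzero(n_reads_per_mol)[0]:
            segments = _molecule_segments(gene, excised_all[mol])
            offsets = rng.integers(0, n_pos[mol], size=n_reads_per_mol[mol])
            for ri, off in enumerate(offsets):
                start, blocks = _read_blocks(segments, int(off), config.read_length)
                reads.append(
                    SplicedAlignment(
                        read_id=f"{gene.gene_id}.m{mol}.r{ri}",
                        contig=gene.contig,
                        start=start,
                        blocks=blocks,
                        strand=gene.strand,
                    )
                )
    return reads, _truth_frame(genes, spliced_molecules, config.n_molecules)


def _truth_frame(
    genes: list[GeneModel],
    spliced_molecules: dict[tuple[str, int], int],
    n_molecules: int = 0,
) -> pd.DataFrame:
    rows = []
    for gene in genes:
        for i, (s, e) in enumerate(gene.introns):
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "intron_index": i,
                    "contig": gene.contig,
                    "start": s,
                    "end": e,
                    "strand": gene.strand,
                    "annotated": gene.annotated[i],
                    "true_efficiency": gene.splicing_efficiency[i],
                    "n_molecules": n_molecules,
                    "n_spliced_molecules": spliced_molecules.get(
                        (gene.gene_id, i), 0
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "intron_index", "contig", "start", "end", "strand",
            "annotated", "true_efficiency", "n_molecules", "n_spliced_molecules",
        ],
    )


# --- small RNAs ----------------------------------------------------------


def simulate_small_rnas(
    locus: tuple[str, int, int],
    n_reads: int,
    length_dist: dict[int, float],
    top_strand_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[list[SmallRNARead], pd.DataFrame]:
    """Draw small-RNA reads over a locus with a controlled length mix.

    Lengths follow ``length_dist`` (a probability map), strands a
    Bernoulli(top_strand_fraction) draw, and start positions are uniform
    over the locus.  Ground truth is the per-(length, strand) count table.
    """
    if not length_dist:
        raise ValueError("empty length distribution")
    probs = np.asarray(list(length_dist.values()), dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("length distribution probabilities must sum to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    contig, lo, hi = locus
    lengths_support = np.asarray(list(length_dist.keys()), dtype=int)
    if hi - lo < int(lengths_support.max()):
        raise ValueError("locus shorter than the longest read")
    lengths = rng.choice(lengths_support, size=n_reads, p=probs)
    top = rng.random(n_reads) < top_strand_fraction
    reads = []
    for i in range(n_reads):
        length = int(lengths[i])
        start = int(rng.integers(lo, hi - length + 1))
        reads.append(
            SmallRNARead(
                contig=contig,
                start=start,
                length=length,
                strand="+" if top[i] else "-",
            )
        )
    truth = (
        pd.DataFrame(
            {"length": lengths, "strand": np.where(top, "+", "-")}
        )
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["length", "strand"])
        .reset_index(drop=True)
    )
    return reads, truth


# --- RIP pair ------------------------------------------------------------


def simulate_rip_pair(
    contig_lengths: dict[str, int],
    enrichment_regions: list[tuple[str, int, int]],
    fold: float = 5.0,
    background_mean: float = 20.0,
    bin_size: int = 50,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[dict[str, CoverageTrack], dict[str, CoverageTrack], pd.DataFrame]:
    """Paired tagged/untagged coverage with injected enrichment.

    Both tracks draw Poisson background per bin; inside each enrichment
    region the tagged mean is multiplied by ``fold``.  Returns
    (tagged, untagged, ground-truth region table).
    """
    if fold < 1:
        raise ValueError("enrichment fold must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    tagged: dict[str, CoverageTrack] = {}
    untagged: dict[str, CoverageTrack] = {}
    for contig, length in contig_lengths.items():
        n_bins = -(-length // bin_size)
        mean = np.full(n_bins, background_mean, dtype=float)
        for (c, s, e) in enrichment_regions:
            if c != contig:
                continue
            if s < 0 or e > length:
                raise ValueError("enrichment region outside contig")
            mean[s // bin_size : -(-e // bin_size)] = background_mean * fold
        untagged[contig] = CoverageTrack(
            contig=contig,
            bin_size=bin_size,
            values=rng.poisson(background_mean, size=n_bins).astype(float),
            normalization="raw",
        )
        tagged[contig] = CoverageTrack(
            contig=contig,
            bin_size=bin_size,
            values=rng.poisson(mean).astype(float),
            normalization="raw",
        )
    truth = pd.DataFrame(
        [
            {"contig": c, "start": s, "end": e, "fold": fold}
            for (c, s, e) in enrichment_regions
        ],
        columns=["contig", "start", "end", "fold"],
    )
    return tagged, untagged, truth


# --- PSM tables ----------------------------------------------------------


def simulate_psm_table(
    n_proteins: int = 500,
    null_mean: float = 40.0,
    dispersion: float = 0.1,
    n_enriched: int = 10,
    enrichment_effect: float = 8.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PSM counts for a null protein population plus enriched outliers.

    Null proteins draw target and control counts i.i.d. from the same
    gamma-Poisson (negative binomial) distribution with mean
    ``null_mean`` and dispersion ``dispersion``; the first ``n_enriched``
    proteins have their target mean multiplied by ``enrichment_effect``.
    Returns (table, ground-truth labels).
    """
    if n_proteins < 50:
        raise ValueError("need at least 50 proteins")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if n_enriched < 0 or n_enriched > n_proteins:
        raise ValueError("invalid number of enriched proteins")
    if rng is None:
        rng = np.random.default_rng(seed)
    shape = 1.0 / dispersion
    enriched = np.zeros(n_proteins, dtype=bool)
    enriched[:n_enriched] = True
    target_mean = np.where(enriched, null_mean * enrichment_effect, null_mean)
    lam_t = rng.gamma(shape, target_mean * dispersion)
    lam_c = rng.gamma(shape, null_mean * dispersion, size=n_proteins)
    table = pd.DataFrame(
        {
            "protein_id": [f"P{i + 1:04d}" for i in range(n_proteins)],
            "psm_target": rng.poisson(lam_t),
            "psm_control": rng.poisson(lam_c),
        }
    )
    truth = pd.DataFrame(
        {
            "protein_id": table["protein_id"],
            "is_enriched": enriched,
            "effect": np.where(enriched, enrichment_effect, 1.0),
        }
    )
    return table, truth
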