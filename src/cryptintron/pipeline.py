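"""End-to-end runs: fixture generation, cryptic-intron calling, siRNA profiles.

Every run writes a ``manifest.json`` next to its outputs recording the
package version, the full parameter set, the seed, and SHA-256 checksums
of all inputs.  Manifests contain nothing volatile, so two runs with the
same config and seed produce byte-identical output trees; timings go to
the log only.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cryptic import (
    DEFAULT_EFFICIENCY_THRESHOLD,
    DEFAULT_MIN_DEPTH,
    DEFAULT_MIN_REFERENCE_SUPPORT,
    IntronAnnotationSet,
    call_cryptic_introns,
)
from .junctions import (
    DEFAULT_MAX_INTRON,
    DEFAULT_MIN_INTRON,
    DEFAULT_MIN_OVERHANG,
    extract_junctions,
    quantify_junctions,
)
from .simulate import (
    DEGRADATION_LENGTH_DIST,
    SIRNA_LENGTH_DIST,
    GenePlan,
    SimulationConfig,
    make_toy_genome,
    simulate_psm_table,
    simulate_rip_pair,
    simulate_small_rnas,
    simulate_spliced_reads,
)
from .smallrna import (
    DEFAULT_FLOOR_RPM,
    DEFAULT_LEN_MAX,
    DEFAULT_LEN_MIN,
    compare_loss,
    filter_by_length,
    stranded_coverage,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

# declared small-RNA library size for the fixture bundle: a typical
# small-RNA sequencing run; the fixture BEDs hold only the reads mapping
# to the simulated loci, normalisation uses the full-library total
SIRNA_LIBRARY_TOTAL = 2_000_000


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: Path, stage: str, params: dict, inputs: dict[str, str | Path]
) -> Path:
    manifest = {
        "package": "cryptintron",
        "version": __version__,
        "stage": stage,
        "parameters": params,
        "inputs": {name: _sha256(p) for name, p in sorted(inputs.items())},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["parameters"], sort_keys=True).encode()
    ).hexdigest()
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# --- cryptic-intron pipeline --------------------------------------------


@dataclass
class CrypticRunConfig:
    """Inputs and parameters for a cryptic-intron calling run."""

    test_sam: str
    reference_sam: str
    annotation_gff3: str
    genome_fasta: str
    out_dir: str
    min_overhang: int = DEFAULT_MIN_OVERHANG
    min_intron: int = DEFAULT_MIN_INTRON
    max_intron: int = DEFAULT_MAX_INTRON
    boundary_mode: str = "left"
    efficiency_threshold: float = DEFAULT_EFFICIENCY_THRESHOLD
    min_depth: int = DEFAULT_MIN_DEPTH
    min_reference_support: int = DEFAULT_MIN_REFERENCE_SUPPORT
    annotation_window: int = 0
    require_canonical: bool = False
    allow_gc: bool = False

    def validate(self) -> None:
        for name in ("test_sam", "reference_sam", "annotation_gff3", "genome_fasta"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{name}: {p}")
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        if not 0 < self.efficiency_threshold <= 1:
            raise ValueError("efficiency_threshold must be in (0, 1]")
        if self.min_depth < 0 or self.min_reference_support < 0:
            raise ValueError("depth/support thresholds must be non-negative")


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        sites = c.splice_sites
        rows.append(
            {
                "contig": c.junction.contig,
                "start": c.junction.start,
                "end": c.junction.end,
                "strand": sites.strand if sites else c.junction.strand,
                "split_reads": c.junction.split_read_count,
                "overlapping_reads": c.junction.overlapping_read_count,
                "efficiency": np.nan if c.efficiency is None else c.efficiency,
                "annotated": c.is_annotated,
                "in_reference": c.present_in_reference,
                "donor": sites.donor if sites else "NA",
                "acceptor": sites.acceptor if sites else "NA",
                "canonical": c.is_canonical,
                "depth_ok": c.depth_ok,
                "verdict": c.verdict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "strand", "split_reads",
            "overlapping_reads", "efficiency", "annotated", "in_reference",
            "donor", "acceptor", "canonical", "depth_ok", "verdict",
        ],
    )


def run_cryptic_pipeline(config: CrypticRunConfig):
    """extract -> quantify -> subtract annotated -> subtract reference -> classify.

    Writes the cryptic-intron report TSV, a BED of cryptic calls, the
    junction tables of both conditions, and a manifest.  Returns the
    list of calls.
    """
    config.validate()
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    test_alns, contig_lengths = cio.read_sam(config.test_sam)
    ref_alns, _ = cio.read_sam(config.reference_sam)
    sequences = cio.read_fasta(config.genome_fasta)
    annotation = IntronAnnotationSet.from_gff3(
        config.annotation_gff3, known_contigs=list(sequences)
    )
    test_junctions, diag = extract_junctions(
        test_alns, config.min_overhang, config.min_intron, config.max_intron
    )
    ref_junctions, _ = extract_junctions(
        ref_alns, config.min_overhang, config.min_intron, config.max_intron
    )
    test_junctions = quantify_junctions(
        test_alns, test_junctions, config.min_overhang, config.boundary_mode
    )
    calls = call_cryptic_introns(
        test_junctions,
        ref_junctions,
        annotation,
        sequences=sequences,
        efficiency_threshold=config.efficiency_threshold,
        min_depth=config.min_depth,
        min_reference_support=config.min_reference_support,
        annotation_window=config.annotation_window,
        require_canonical=config.require_canonical,
        allow_gc=config.allow_gc,
    )
    frame = calls_to_frame(calls)
    frame.to_csv(out_dir / "cryptic_report.tsv", sep="\t", index=False, na_rep="NA")
    cryptic = frame[frame["verdict"] == "cryptic"]
    bed_lines = [
        "\t".join(
            [r.contig, str(r.start), str(r.end),
             f"cryptic_intron_{i + 1}", f"{r.efficiency:.4f}",
             r.strand if r.strand in "+-" else "."]
        )
        for i, r in enumerate(cryptic.itertuples(index=False))
    ]
    (out_dir / "cryptic_calls.bed").write_text(
        "\n".join(bed_lines) + ("\n" if bed_lines else "")
    )
    cio.write_junction_table(test_junctions, out_dir / "junctions_test.tsv")
    cio.write_junction_table(ref_junctions, out_dir / "junctions_reference.tsv")
    cio.write_junctions_bed(test_junctions, out_dir / "junctions_test.bed")
    params = asdict(config)
    write_manifest(
        out_dir,
        "cryptic",
        params,
        {
            "test_sam": config.test_sam,
            "reference_sam": config.reference_sam,
            "annotation_gff3": config.annotation_gff3,
            "genome_fasta": config.genome_fasta,
        },
    )
    logger.info(
        "cryptic pipeline: %d test junctions (%s skipped), %d cryptic calls, %.2fs",
        len(test_junctions), diag, len(cryptic), time.perf_counter() - t0,
    )
    return calls


# --- siRNA profile pipeline ---------------------------------------------


@dataclass
class SirnaRunConfig:
    """Inputs and parameters for a strand-resolved siRNA profiling run."""

    reads_a_bed: str  # reference genotype (e.g. rrp6-delta)
    reads_b_bed: str  # comparison genotype (e.g. pir2-1 rrp6-delta)
    genome_fasta: str
    out_dir: str
    label_a: str = "a"
    label_b: str = "b"
    regions: list[tuple[str, int, int]] = field(default_factory=list)
    len_min: int = DEFAULT_LEN_MIN
    len_max: int = DEFAULT_LEN_MAX
    floor_rpm: float = DEFAULT_FLOOR_RPM
    bin_size: int = 1
    coverage_mode: str = "full"
    # library totals (all mapped reads, pre-filter); None = count the BED.
    # BEDs subsetted to loci of interest should declare the full totals.
    total_mapped_a: int | None = None
    total_mapped_b: int | None = None

    def validate(self) -> None:
        for name in ("reads_a_bed", "reads_b_bed", "genome_fasta"):
            if not Path(getattr(self, name)).is_file():
                raise FileNotFoundError(f"{name}: {getattr(self, name)}")
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")
        if self.floor_rpm <= 0:
            raise ValueError("floor_rpm must be positive")


def run_sirna_profile(config: SirnaRunConfig):
    """Length-filter, build per-strand RPM tracks, and flag siRNA loss."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contig_lengths = {
        c: len(s) for c, s in cio.read_fasta(config.genome_fasta).items()
    }
    tracks = {}
    for label, path, total in (
        (config.label_a, config.reads_a_bed, config.total_mapped_a),
        (config.label_b, config.reads_b_bed, config.total_mapped_b),
    ):
        reads = cio.read_reads_bed(path)
        if not reads:
            logger.warning("empty small-RNA read file for %s: %s", label, path)
        retained, histogram = filter_by_length(reads, config.len_min, config.len_max)
        track = stranded_coverage(
            retained,
            total_mapped=total if total is not None else max(len(reads), 1),
            contig_lengths=contig_lengths,
            bin_size=config.bin_size,
            mode=config.coverage_mode,
            metadata={
                "genotype": label,
                "length_window": [config.len_min, config.len_max],
            },
        )
        track.write_sgr(out_dir / f"sirna_{label}")
        track.write_bedgraph(out_dir / f"sirna_{label}.bedgraph")
        pd.DataFrame(
            sorted(histogram.items()), columns=["length", "count"]
        ).to_csv(out_dir / f"length_histogram_{label}.tsv", sep="\t", index=False)
        tracks[label] = track
    reports = [
        compare_loss(
            tracks[config.label_a], tracks[config.label_b], region,
            floor_rpm=config.floor_rpm,
        )
        for region in config.regions
    ]
    frame = pd.DataFrame(reports)
    frame.insert(0, "genotype_b", config.label_b)
    frame.insert(0, "genotype_a", config.label_a)
    frame.to_csv(out_dir / "loss_report.tsv", sep="\t", index=False)
    params = asdict(config)
    write_manifest(
        out_dir,
        "sirna",
        params,
        {
            "reads_a_bed": config.reads_a_bed,
            "reads_b_bed": config.reads_b_bed,
            "genome_fasta": config.genome_fasta,
        },
    )
    return tracks, frame


# --- fixture bundle ------------------------------------------------------


def default_simulation_config(seed: int) -> SimulationConfig:
    """The toy study layout: efficient annotated introns plus planted
    cryptic introns that splice in a few percent of molecules."""
    return SimulationConfig(
        seed=seed,
        read_length=50,
        depth=30.0,
        n_molecules=400,
        genes=[
            GenePlan(splicing_efficiency=[0.92], annotated=[True], strand="+"),
            GenePlan(splicing_efficiency=[0.95], annotated=[True], strand="-"),
            GenePlan(splicing_efficiency=[0.03], annotated=[False], strand="+"),
            GenePlan(splicing_efficiency=[0.02], annotated=[False], strand="-"),
            GenePlan(
                splicing_efficiency=[0.90, 0.025],
                annotated=[True, False],
                strand="+",
            ),
        ],
    )


def wild_type_genes(genes):
    """Reference-condition gene models: cryptic introns never splice.

    Cryptic introns surface only when degradation is impaired, so in the
    wild type their excision probability is zero; annotated introns
    splice identically in both conditions.
    """
    wt = copy.deepcopy(genes)
    for g in wt:
        g.splicing_efficiency = [
            eff if ann else 0.0
            for eff, ann in zip(g.splicing_efficiency, g.annotated)
        ]
    return wt


def control_loci(genes, n: int = 5, width: int = 200) -> list[tuple[str, int, int]]:
    """Intergenic control loci (pericentromeric-repeat stand-ins) where
    siRNA production is independent of the lncRNA locus."""
    loci = []
    for g1, g2 in zip(genes, genes[1:]):
        gap_start = g1.span[1]
        gap_end = g2.span[0]
        if gap_end - gap_start >= width + 100:
            loci.append((g1.contig, gap_start + 50, gap_start + 50 + width))
        if len(loci) == n:
            return loci
    # tail of the contig past the last gene serves as extra control space
    tail = genes[-1].span[1] + 50
    while len(loci) < n:
        loci.append((genes[-1].contig, tail, tail + width))
        tail += width + 50
    return loci


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Emit the complete synthetic dataset bundle with ground truth.

    Contents: genome FASTA, annotation GFF3, spliced-read SAM for the
    mutant and wild-type conditions, small-RNA BEDs for three genotypes,
    a tagged/untagged RIP track pair, a PSM table, per-layer truth TSVs,
    and a manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    config = default_simulation_config(seed)
    genome, genes = make_toy_genome(config)
    paths: dict[str, Path] = {}

    paths["genome"] = out_dir / "genome.fa"
    cio.write_fasta(genome.sequences, paths["genome"])
    paths["annotation"] = out_dir / "annotation.gff3"
    cio.write_gff3(genes, paths["annotation"])

    mutant_reads, mutant_truth = simulate_spliced_reads(genome, genes, config, rng=rng)
    wt_reads, wt_truth = simulate_spliced_reads(
        genome, wild_type_genes(genes), config, rng=rng
    )
    paths["reads_mutant"] = out_dir / "reads_mutant.sam"
    paths["reads_wt"] = out_dir / "reads_wt.sam"
    cio.write_sam(mutant_reads, genome.contig_lengths, paths["reads_mutant"],
                  sequences=genome.sequences)
    cio.write_sam(wt_reads, genome.contig_lengths, paths["reads_wt"],
                  sequences=genome.sequences)
    mutant_truth["condition"] = "mutant"
    wt_truth["condition"] = "wt"
    truth = pd.concat([mutant_truth, wt_truth], ignore_index=True)
    paths["intron_truth"] = out_dir / "truth_introns.tsv"
    truth.to_csv(paths["intron_truth"], sep="\t", index=False)

    # small RNAs: the lncRNA-target locus loses siRNAs in the silencing
    # mutants (what remains genome-wide is broad-length degradation
    # fragments); intergenic control loci keep siRNAs in every genotype.
    # The BEDs are subsetted to the simulated loci; the declared library
    # total reflects the whole sequencing run.
    contig = genes[0].contig
    whole_contig = (contig, 0, genome.contig_lengths[contig])
    target_gene = genes[2]
    target_locus = (target_gene.contig, *target_gene.span)
    controls = control_loci(genes)
    totals = []
    for genotype, at_target in (
        ("rrp6", "sirna"),
        ("pir2_rrp6", "degraded"),
        ("cwf10_rrp6", "degraded"),
    ):
        reads = []
        if at_target == "sirna":
            r, _ = simulate_small_rnas(
                target_locus, 2000, SIRNA_LENGTH_DIST, 0.5, rng=rng
            )
        else:
            r, _ = simulate_small_rnas(
                whole_contig, 300, DEGRADATION_LENGTH_DIST, 0.5, rng=rng
            )
        reads.extend(r)
        for locus in controls:
            r, _ = simulate_small_rnas(locus, 500, SIRNA_LENGTH_DIST, 0.5, rng=rng)
            reads.extend(r)
        totals.append(
            {"genotype": genotype, "total_mapped": SIRNA_LIBRARY_TOTAL,
             "reads_in_bed": len(reads)}
        )
        paths[f"smallrna_{genotype}"] = out_dir / f"smallrna_{genotype}.bed"
        cio.write_reads_bed(reads, paths[f"smallrna_{genotype}"])
    paths["sirna_library_stats"] = out_dir / "sirna_library_stats.tsv"
    pd.DataFrame(totals).to_csv(paths["sirna_library_stats"], sep="\t", index=False)
    loci_frame = pd.DataFrame(
        [("target", *target_locus)]
        + [(f"control_{i + 1}", *locus) for i, locus in enumerate(controls)],
        columns=["name", "contig", "start", "end"],
    )
    paths["sirna_loci"] = out_dir / "truth_sirna_loci.tsv"
    loci_frame.to_csv(paths["sirna_loci"], sep="\t", index=False)

    # RIP pair: tagged protein enriched over the lncRNA loci
    rip_regions = [
        (genes[2].contig, *genes[2].span),
        (genes[3].contig, *genes[3].span),
    ]
    tagged, untagged, rip_truth = simulate_rip_pair(
        genome.contig_lengths, rip_regions, fold=5.0, background_mean=20.0,
        bin_size=50, rng=rng,
    )
    paths["rip_tagged"] = out_dir / "rip_tagged.bedgraph"
    paths["rip_untagged"] = out_dir / "rip_untagged.bedgraph"
    cio.write_bedgraph(
        {c: t.values for c, t in tagged.items()}, paths["rip_tagged"], bin_size=50
    )
    cio.write_bedgraph(
        {c: t.values for c, t in untagged.items()}, paths["rip_untagged"], bin_size=50
    )
    paths["rip_truth"] = out_dir / "truth_rip_regions.tsv"
    rip_truth.to_csv(paths["rip_truth"], sep="\t", index=False)

    psm_table, psm_truth = simulate_psm_table(rng=rng)
    paths["psm_table"] = out_dir / "psm_table.tsv"
    psm_table.to_csv(paths["psm_table"], sep="\t", index=False)
    paths["psm_truth"] = out_dir / "truth_psm.tsv"
    psm_truth.to_csv(paths["psm_truth"], sep="\t", index=False)

    write_manifest(
        out_dir,
        "simulate",
        {"seed": seed, "config": json.loads(json.dumps(asdict(config)))},
        {name: p for name, p in paths.items()},
    )
    return paths
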