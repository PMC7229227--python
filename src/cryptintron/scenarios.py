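"""Reference study scenarios: parameterised simulations with known truth.

These compose the generator with the analysis stages into the recurring
experiments the package is validated on (and that the analysis scripts
report): binomial recovery of splicing efficiency, cryptic-intron
classification over a planted gene panel, and the siRNA / RIP / RIME
recovery designs.  Molecule counts are kept high relative to read depth
so junction-overlapping reads sample distinct molecules and the
percent-spliced statistic behaves as a binomial proportion.
"""

from __future__ import annotations

import numpy as np

from .cryptic import call_cryptic_introns, IntronAnnotationSet
from .junctions import extract_junctions, quantify_junctions
from .simulate import (
    GenePlan,
    SimulationConfig,
    make_toy_genome,
    simulate_spliced_reads,
)


def recovery_config(
    efficiency: float,
    seed: int,
    depth: float = 28.0,
    n_molecules: int = 50_000,
) -> SimulationConfig:
    """Single-intron locus tuned for binomial efficiency recovery.

    Many molecules at modest coverage keep the per-molecule junction
    read rate near 0.02, so the ~1,200 junction-overlapping reads are
    effectively independent Bernoulli(e) trials.
    """
    return SimulationConfig(
        seed=seed,
        read_length=50,
        depth=depth,
        n_molecules=n_molecules,
        genes=[
            GenePlan(
                splicing_efficiency=[efficiency],
                annotated=[False],
                exon_length=60,
                intron_length=60,
            )
        ],
    )


def estimate_efficiency(config: SimulationConfig) -> tuple[float | None, int]:
    """Simulate one locus and return (estimated efficiency, junction depth)."""
    genome, genes = make_toy_genome(config)
    reads, _ = simulate_spliced_reads(genome, genes, config)
    junctions, _ = extract_junctions(reads)
    intron = genes[0].introns[0]
    at_intron = [j for j in junctions if (j.start, j.end) == intron]
    if not at_intron:
        return None, 0
    j = quantify_junctions(reads, at_intron)[0]
    return j.efficiency, int(j.overlapping_read_count)


def efficiency_recovery_study(
    efficiencies: tuple[float, ...] = (0.01, 0.03, 0.05, 0.25, 0.5, 0.95),
    replicates_per_efficiency: int = 34,
    base_seed: int = 0,
    depth: float = 28.0,
    n_molecules: int = 50_000,
):
    """Replicated recovery of programmed efficiencies.

    Yields dicts with the programmed value, the estimate, the junction
    depth, and whether the estimate falls within three binomial standard
    errors of truth.
    """
    results = []
    for i, e in enumerate(efficiencies):
        for rep in range(replicates_per_efficiency):
            seed = base_seed + i * 1000 + rep
            est, n = estimate_efficiency(
                recovery_config(e, seed, depth=depth, n_molecules=n_molecules)
            )
            tol = 3 * np.sqrt(e * (1 - e) / n) if n else np.inf
            results.append(
                {
                    "true_efficiency": e,
                    "estimate": est,
                    "n_overlapping": n,
                    "within_3se": est is not None and abs(est - e) < tol,
                }
            )
    return results


def classification_panel_config(
    seed: int,
    n_cryptic: int = 50,
    n_annotated: int = 50,
    depth: float = 25.0,
    n_molecules: int = 2000,
) -> SimulationConfig:
    """Gene panel: planted cryptic introns (unannotated, excised in
    1–3% of molecules) interleaved with efficient annotated introns
    (90–100%)."""
    rng = np.random.default_rng(seed)
    cryptic_eff = rng.uniform(0.01, 0.03, size=n_cryptic)
    annotated_eff = rng.uniform(0.90, 1.0, size=n_annotated)
    plans = [
        GenePlan(
            splicing_efficiency=[float(eff)], annotated=[annotated],
            exon_length=60, intron_length=60,
            strand="+" if i % 4 < 2 else "-",
        )
        for i, (eff, annotated) in enumerate(
            [(e, False) for e in cryptic_eff] + [(e, True) for e in annotated_eff]
        )
    ]
    return SimulationConfig(
        seed=seed, read_length=50, depth=depth, n_molecules=n_molecules,
        genes=plans,
    )


def classification_study(seed: int, reference_depth: float = 10.0):
    """Simulate mutant and wild-type conditions over the panel and run
    the full cryptic-intron rule chain with default parameters.

    Returns (calls, expected) where ``expected`` maps each intron's
    (contig, start, end) to the verdict the plant dictates: ``cryptic``
    for unannotated mutant-specific inefficient introns, ``not_cryptic``
    for annotated efficient ones.
    """
    from .pipeline import wild_type_genes

    config = classification_panel_config(seed)
    genome, genes = make_toy_genome(config)
    rng = np.random.default_rng(seed + 1)
    mutant_reads, _ = simulate_spliced_reads(genome, genes, config, rng=rng)
    wt_config = SimulationConfig(
        seed=seed, read_length=config.read_length, depth=reference_depth,
        n_molecules=config.n_molecules, genes=config.genes,
    )
    wt_reads, _ = simulate_spliced_reads(
        genome, wild_type_genes(genes), wt_config, rng=rng
    )
    test_junctions, _ = extract_junctions(mutant_reads)
    test_junctions = quantify_junctions(mutant_reads, test_junctions)
    ref_junctions, _ = extract_junctions(wt_reads)
    annotation = IntronAnnotationSet.from_gene_models(genes)
    calls = call_cryptic_introns(
        test_junctions, ref_junctions, annotation, sequences=genome.sequences
    )
    expected = {}
    for g in genes:
        for (s, e), annotated in zip(g.introns, g.annotated):
            expected[(g.contig, s, e)] = "not_cryptic" if annotated else "cryptic"
    return calls, expected
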