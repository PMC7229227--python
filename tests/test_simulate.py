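"""The synthetic-data generator: construction rules, determinism, statistics."""

import numpy as np
import pytest

from cryptintron import io as cio
from cryptintron.simulate import (
    DEGRADATION_LENGTH_DIST,
    SIRNA_LENGTH_DIST,
    GenePlan,
    SimulationConfig,
    make_toy_genome,
    revcomp,
    simulate_psm_table,
    simulate_rip_pair,
    simulate_small_rnas,
    simulate_spliced_reads,
)


class TestMakeToyGenome:
    def test_two_genes_one_intron_each(self, tmp_path):
        config = SimulationConfig(
            genes=[GenePlan(), GenePlan(strand="-")]
        )
        genome, genes = make_toy_genome(config)
        assert len(genes) == 2
        assert sum(len(g.exons) for g in genes) == 4
        assert sum(len(g.introns) for g in genes) == 2
        cio.write_gff3(genes, tmp_path / "ann.gff3")
        feats = cio.read_gff3_features(tmp_path / "ann.gff3")
        assert (feats["type"] == "gene").sum() == 2
        assert (feats["type"] == "exon").sum() == 4
        assert (feats["type"] == "intron").sum() == 2

    def test_canonical_sites_planted_on_both_strands(self):
        config = SimulationConfig(
            genes=[GenePlan(strand="+"), GenePlan(strand="-")]
        )
        genome, genes = make_toy_genome(config)
        seq = genome.sequences[config.contig_id]
        for g in genes:
            for s, e in g.introns:
                intron = seq[s:e] if g.strand == "+" else revcomp(seq[s:e])
                assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        paths = []
        for name in ("a.fa", "b.fa"):
            genome, _ = make_toy_genome(SimulationConfig(seed=11))
            cio.write_fasta(genome.sequences, tmp_path / name)
            paths.append((tmp_path / name).read_bytes())
        assert paths[0] == paths[1]

    def test_too_short_intron_rejected(self):
        config = SimulationConfig(genes=[GenePlan(intron_length=10)])
        with pytest.raises(ValueError):
            make_toy_genome(config)


class TestSimulateSplicedReads:
    @pytest.mark.parametrize("efficiency,expect", [(0.0, 0), (1.0, "all")])
    def test_degenerate_efficiencies(self, efficiency, expect):
        config = SimulationConfig(
            seed=3, depth=8.0, n_molecules=300,
            genes=[GenePlan(splicing_efficiency=[efficiency], annotated=[True])],
        )
        genome, genes = make_toy_genome(config)
        reads, truth = simulate_spliced_reads(genome, genes, config)
        intron = genes[0].introns[0]
        split = [r for r in reads if any(
            (s, e) == intron for _, s, e, _ in r.skips()
        )]
        crossing = [
            r for r in reads
            if r.start < intron[0] and r.end > intron[1]
        ]
        if expect == 0:
            assert split == []
            assert truth["n_spliced_molecules"].iloc[0] == 0
        else:
            assert truth["n_spliced_molecules"].iloc[0] == config.n_molecules
            assert len(split) > 0
            assert len(split) == len(crossing)

    def test_split_fraction_matches_bernoulli_truth(self):
        """With efficiency e, the realised spliced-molecule count is the
        exact Bernoulli tally and the split fraction of junction-crossing
        reads tracks it within binomial error."""
        e = 0.03
        config = SimulationConfig(
            seed=5, depth=20.0, n_molecules=2000,
            genes=[GenePlan(splicing_efficiency=[e], annotated=[False])],
        )
        genome, genes = make_toy_genome(config)
        reads, truth = simulate_spliced_reads(genome, genes, config)
        # independent replay of the generator's Bernoulli stream
        replay = np.random.default_rng(config.seed).random((config.n_molecules, 1)) < e
        assert truth["n_spliced_molecules"].iloc[0] == int(replay.sum())
        intron = genes[0].introns[0]
        boundary = intron[0]
        # matched 4-base anchor windows on both sides of the boundary make
        # split and spanning reads equally likely per molecule
        split = sum(
            any((s, e_) == intron and min(l, rt) >= 4 for l, s, e_, rt in r.skips())
            for r in reads
        )
        spanning = sum(
            any(bs <= boundary - 4 and be >= boundary + 4
                for bs, be in r.aligned_intervals())
            for r in reads
        )
        n = split + spanning
        frac = split / n
        assert abs(frac - e) < 3 * np.sqrt(e * (1 - e) / n)

    def test_skip_gap_is_exactly_intron_length(self, small_dataset):
        genome, genes, reads, _ = small_dataset
        intron_lengths = {e - s for g in genes for s, e in g.introns}
        for r in reads:
            for _, s, e, _ in r.skips():
                assert e - s in intron_lengths

    def test_zero_depth_warns_and_returns_empty(self, caplog):
        config = SimulationConfig(depth=0.0)
        genome, genes = make_toy_genome(config)
        with caplog.at_level("WARNING"):
            reads, truth = simulate_spliced_reads(genome, genes, config)
        assert reads == []
        assert "zero-depth" in caplog.text

    def test_determinism(self, small_config):
        genome, genes = make_toy_genome(small_config)
        r1, t1 = simulate_spliced_reads(genome, genes, small_config)
        r2, t2 = simulate_spliced_reads(genome, genes, small_config)
        assert r1 == r2
        assert t1.equals(t2)


class TestSimulateSmallRnas:
    def test_lengths_within_support_and_strand_mix(self, rng):
        reads, truth = simulate_small_rnas(
            ("c1", 0, 2000), 1000, SIRNA_LENGTH_DIST, 1.0, rng=rng
        )
        assert {r.length for r in reads} <= set(SIRNA_LENGTH_DIST)
        assert all(r.strand == "+" for r in reads)
        assert truth["count"].sum() == 1000

    def test_empty_length_distribution_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_small_rnas(("c1", 0, 2000), 10, {}, rng=rng)

    def test_histogram_matches_multinomial_within_3_sigma(self, rng):
        n = 5000
        reads, _ = simulate_small_rnas(
            ("c1", 0, 5000), n, DEGRADATION_LENGTH_DIST, 0.5, rng=rng
        )
        counts = {}
        for r in reads:
            counts[r.length] = counts.get(r.length, 0) + 1
        for length, p in DEGRADATION_LENGTH_DIST.items():
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(length, 0) - n * p) < 3 * sigma


class TestSimulateRipPair:
    def test_fold_one_means_no_enrichment(self):
        tagged, untagged, _ = simulate_rip_pair(
            {"c1": 10000}, [("c1", 2000, 3000)], fold=1.0, seed=2
        )
        diff = tagged["c1"].values - untagged["c1"].values
        assert abs(diff.mean()) < 3 * np.sqrt(2 * 20.0 / diff.size)

    def test_planted_fold_recovered_in_region(self):
        tagged, untagged, truth = simulate_rip_pair(
            {"c1": 50000}, [("c1", 10000, 20000)], fold=5.0, seed=3
        )
        sel = slice(10000 // 50, 20000 // 50)
        ratio = tagged["c1"].values[sel].mean() / untagged["c1"].values[sel].mean()
        assert ratio == pytest.approx(5.0, rel=0.1)

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_rip_pair({"c1": 10000}, [], fold=0.5)

    def test_seed_fixed_identical_tracks(self):
        a = simulate_rip_pair({"c1": 10000}, [("c1", 0, 500)], seed=9)
        b = simulate_rip_pair({"c1": 10000}, [("c1", 0, 500)], seed=9)
        assert np.array_equal(a[0]["c1"].values, b[0]["c1"].values)
        assert np.array_equal(a[1]["c1"].values, b[1]["c1"].values)


class TestSimulatePsmTable:
    def test_all_null_median_ratio_near_zero(self):
        table, truth = simulate_psm_table(n_proteins=2000, n_enriched=0, seed=4)
        r = np.log2((table["psm_target"] + 1) / (table["psm_control"] + 1))
        assert abs(np.median(r)) < 0.1
        assert not truth["is_enriched"].any()

    def test_strong_effect_protein_has_max_ratio(self):
        hits = 0
        for seed in range(20):
            table, truth = simulate_psm_table(
                n_proteins=100, n_enriched=1, enrichment_effect=8.0, seed=seed
            )
            r = np.log2((table["psm_target"] + 1) / (table["psm_control"] + 1))
            hits += table.loc[r.idxmax(), "protein_id"] == truth.loc[
                truth["is_enriched"], "protein_id"
            ].iloc[0]
        assert hits == 20

    def test_reproducible_and_validates(self):
        a, _ = simulate_psm_table(n_proteins=50, seed=1)
        b, _ = simulate_psm_table(n_proteins=50, seed=1)
        assert a.equals(b)
        with pytest.raises(ValueError):
            simulate_psm_table(n_proteins=10)
        with pytest.raises(ValueError):
            simulate_psm_table(dispersion=0.0)
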