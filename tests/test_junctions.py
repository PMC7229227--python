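"""Junction extraction, overlap counting and the percent-spliced statistic."""

import numpy as np
import pytest

from cryptintron.junctions import (
    JunctionQuantification,
    SplicedAlignment,
    count_overlapping_reads,
    extract_junctions,
    quantify_junctions,
    read_overlaps_junction,
    splicing_efficiency,
)

from oracles import brute_force_junctions, brute_force_overlap
from conftest import random_alignments


def make_read(read_id, start, blocks, contig="c1"):
    return SplicedAlignment(read_id=read_id, contig=contig, start=start,
                            blocks=tuple(blocks))


class TestSplicedAlignment:
    def test_block_arithmetic(self):
        aln = make_read("r1", 100, [(50, 200), (50, 0)])
        assert aln.aligned_intervals() == [(100, 150), (350, 400)]
        assert aln.skips() == [(50, 150, 350, 50)]
        assert aln.end == 400
        assert aln.cigar() == "50M200N50M"

    @pytest.mark.parametrize(
        "blocks",
        [[], [(0, 10)], [(50, 5)], [(50, -1), (10, 0)], [(50, 0), (10, 0)]],
    )
    def test_invalid_blocks_rejected(self, blocks):
        with pytest.raises(ValueError):
            make_read("bad", 0, blocks)


class TestExtractJunctions:
    def test_single_split_read(self):
        juncs, diag = extract_junctions([make_read("r1", 100, [(50, 200), (50, 0)])])
        assert len(juncs) == 1
        j = juncs[0]
        assert (j.contig, j.start, j.end) == ("c1", 150, 350)
        assert j.split_read_count == 1
        assert diag == {}

    def test_short_anchor_contributes_nothing(self):
        juncs, diag = extract_junctions(
            [make_read("r1", 100, [(3, 200), (50, 0)])], min_overhang=4
        )
        assert juncs == []
        assert diag == {"insufficient_overhang": 1}

    def test_out_of_range_skip_reported_in_diagnostics(self):
        short = make_read("r1", 100, [(50, 10), (50, 0)])
        long = make_read("r2", 100, [(50, 99999), (50, 0)])
        juncs, diag = extract_junctions([short, long], min_intron=30, max_intron=10000)
        assert juncs == []
        assert diag == {"skip_length_out_of_range": 2}

    def test_multi_skip_read_counts_once_per_junction(self):
        aln = make_read("r1", 0, [(40, 100), (40, 200), (40, 0)])
        juncs, _ = extract_junctions([aln])
        assert [(j.start, j.end) for j in juncs] == [(40, 140), (180, 380)]
        assert all(j.split_read_count == 1 for j in juncs)

    def test_matches_enumeration_oracle_on_random_reads(self, rng):
        alns = random_alignments(rng, 200)
        juncs, _ = extract_junctions(alns, min_overhang=4, min_intron=30,
                                     max_intron=10000)
        expected = brute_force_junctions(alns, 4, 30, 10000)
        got = {(j.contig, j.start, j.end): j.split_read_count for j in juncs}
        assert got == expected


class TestOverlapCounting:
    def test_additive_counting(self):
        # 100 contiguous reads across the left boundary + 4 split reads
        contiguous = [
            make_read(f"c{i}", 130, [(40, 0)]) for i in range(100)
        ]
        split = [
            make_read(f"s{i}", 100, [(50, 200), (50, 0)]) for i in range(4)
        ]
        junction = JunctionQuantification("c1", 150, 350)
        n = count_overlapping_reads(contiguous + split, junction)
        assert n == 104

    def test_no_reads_near_junction(self):
        reads = [make_read("r1", 4000, [(50, 0)])]
        junction = JunctionQuantification("c1", 150, 350)
        assert count_overlapping_reads(reads, junction) == 0

    def test_junction_outside_contig_is_an_error(self):
        junction = JunctionQuantification("c1", 4990, 5100)
        with pytest.raises(ValueError):
            count_overlapping_reads([], junction, contig_lengths={"c1": 5000})

    @pytest.mark.parametrize("mode", ["left", "right", "either", "both"])
    def test_matches_per_read_oracle_in_every_mode(self, rng, mode):
        alns = random_alignments(rng, 300)
        juncs, _ = extract_junctions(alns)
        for j in juncs:
            expected = brute_force_overlap(alns, j.contig, j.start, j.end, 4, mode)
            assert count_overlapping_reads(alns, j, 4, mode) == expected

    def test_quantify_junctions_equals_naive_scan(self, rng):
        alns = random_alignments(rng, 400)
        juncs, _ = extract_junctions(alns)
        quantified = quantify_junctions(alns, juncs)
        for j in quantified:
            assert j.overlapping_read_count == count_overlapping_reads(alns, j)
            assert j.split_read_count <= j.overlapping_read_count

    def test_split_read_at_other_junction_still_counts_by_block(self):
        # read split elsewhere whose second block spans this junction's boundary
        aln = make_read("r1", 0, [(40, 100), (60, 0)])  # blocks [0,40) [140,200)
        junction = JunctionQuantification("c1", 150, 400)
        assert read_overlaps_junction(aln, junction, 4, "left")


class TestSplicingEfficiency:
    def test_worked_ratio(self):
        j = JunctionQuantification("c1", 150, 350, split_read_count=4,
                                   overlapping_read_count=104)
        assert splicing_efficiency(j) == pytest.approx(4 / 104)

    def test_all_split(self):
        j = JunctionQuantification("c1", 150, 350, split_read_count=7,
                                   overlapping_read_count=7)
        assert splicing_efficiency(j) == 1.0

    def test_zero_denominator_is_undefined_not_zero(self):
        j = JunctionQuantification("c1", 150, 350, split_read_count=0,
                                   overlapping_read_count=0)
        assert splicing_efficiency(j) is None

    def test_monotonicity_in_added_reads(self):
        """A split read never lowers efficiency; a contiguous spanning read
        never raises it."""
        j = JunctionQuantification("c1", 150, 350, split_read_count=10,
                                   overlapping_read_count=40)
        base = j.efficiency
        more_split = JunctionQuantification("c1", 150, 350, split_read_count=11,
                                            overlapping_read_count=41)
        more_contig = JunctionQuantification("c1", 150, 350, split_read_count=10,
                                             overlapping_read_count=41)
        assert more_split.efficiency >= base
        assert more_contig.efficiency <= base
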