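"""Cryptic-intron classification rules and splice-site validation."""

import numpy as np
import pytest

from cryptintron.cryptic import (
    IntronAnnotationSet,
    classify_cryptic,
    subtract_annotated,
    subtract_reference_condition,
    validate_splice_sites,
)
from cryptintron.junctions import JunctionQuantification
from cryptintron.simulate import (
    GenePlan,
    SimulationConfig,
    make_toy_genome,
    revcomp,
)


def junc(start, end, split=0, overlap=None, contig="c1", strand="."):
    return JunctionQuantification(contig, start, end, strand=strand,
                                  split_read_count=split,
                                  overlapping_read_count=overlap)


ANNOTATION = IntronAnnotationSet.from_tuples([("c1", 100, 200, "+")])


class TestSubtractAnnotated:
    def test_exact_match_is_annotated(self):
        assert subtract_annotated([junc(100, 200)], ANNOTATION) == [True]

    def test_one_bp_shift_is_unannotated(self):
        assert subtract_annotated([junc(101, 200)], ANNOTATION) == [False]
        assert subtract_annotated([junc(100, 201)], ANNOTATION) == [False]

    def test_window_option_restores_near_matches(self):
        assert subtract_annotated([junc(101, 199)], ANNOTATION, window=1) == [True]

    def test_random_set_matches_membership_oracle(self, rng):
        annotated = [
            ("c1", int(s), int(s) + int(l), "+")
            for s, l in zip(rng.integers(0, 5000, 50), rng.integers(40, 300, 50))
        ]
        annotation = IntronAnnotationSet.from_tuples(annotated)
        key_set = {(c, s, e) for c, s, e, _ in annotated}  # independent oracle
        junctions = [
            junc(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 5000, 70), rng.integers(40, 300, 70))
        ] + [junc(s, e, contig=c) for c, s, e, _ in annotated[:30]]
        flags = subtract_annotated(junctions, annotation)
        expected = [(j.contig, j.start, j.end) in key_set for j in junctions]
        assert flags == expected


class TestSubtractReference:
    def test_present_with_support(self):
        ref = [junc(100, 200, split=10)]
        assert subtract_reference_condition([junc(100, 200)], ref) == [True]

    def test_absent_from_reference(self):
        assert subtract_reference_condition([junc(100, 200)], []) == [False]

    def test_support_threshold_semantics(self):
        ref = [junc(100, 200, split=2)]
        assert subtract_reference_condition(
            [junc(100, 200)], ref, min_reference_support=3
        ) == [False]
        assert subtract_reference_condition(
            [junc(100, 200)], ref, min_reference_support=2
        ) == [True]


class TestValidateSpliceSites:
    SEQ = {"c1": ("A" * 100) + "GT" + ("C" * 56) + "AG" + ("A" * 100)}

    def test_plus_strand_canonical(self):
        sites = validate_splice_sites(junc(100, 160, strand="+"), self.SEQ)
        assert (sites.donor, sites.acceptor, sites.is_canonical) == ("GT", "AG", True)

    def test_minus_strand_canonical_from_top_strand_ct_ac(self):
        seq = {"c1": ("A" * 100) + "CT" + ("G" * 56) + "AC" + ("A" * 100)}
        sites = validate_splice_sites(junc(100, 160, strand="-"), seq)
        assert (sites.donor, sites.acceptor, sites.is_canonical) == ("GT", "AG", True)

    def test_undetermined_strand_inferred_from_dinucleotides(self):
        sites = validate_splice_sites(junc(100, 160), self.SEQ)
        assert sites.strand == "+" and sites.is_canonical

    def test_contig_edge_is_an_error(self):
        with pytest.raises(ValueError):
            validate_splice_sites(junc(0, 1000), {"c1": "ACGT" * 100})

    def test_planted_sites_all_canonical_and_shuffled_sites_not(self):
        config = SimulationConfig(
            genes=[
                GenePlan(strand="+"),
                GenePlan(strand="-"),
                GenePlan(strand="+", canonical=[False]),
                GenePlan(strand="-", canonical=[False]),
            ]
        )
        genome, genes = make_toy_genome(config)
        for gene, expect in zip(genes, [True, True, False, False]):
            for s, e in gene.introns:
                sites = validate_splice_sites(
                    junc(s, e, contig=gene.contig, strand=gene.strand),
                    genome.sequences,
                )
                assert sites.is_canonical is expect


class TestClassifyCryptic:
    def test_worked_example_just_under_threshold(self):
        call = classify_cryptic(
            junc(100, 200, split=4, overlap=104),
            is_annotated=False, present_in_reference=False,
        )
        assert call.efficiency == pytest.approx(0.03846, abs=1e-4)
        assert call.is_cryptic and call.verdict == "cryptic"

    def test_boundary_efficiency_exactly_threshold_not_cryptic(self):
        call = classify_cryptic(
            junc(100, 200, split=5, overlap=100),
            is_annotated=False, present_in_reference=False,
        )
        assert call.efficiency == 0.05
        assert not call.is_cryptic

    def test_annotated_never_cryptic_at_any_efficiency(self):
        for split in (0, 1, 4):
            call = classify_cryptic(
                junc(100, 200, split=split, overlap=100),
                is_annotated=True, present_in_reference=False,
            )
            assert not call.is_cryptic

    def test_low_depth_reported_as_insufficient_evidence(self):
        call = classify_cryptic(
            junc(100, 200, split=0, overlap=3),
            is_annotated=False, present_in_reference=False,
        )
        assert not call.is_cryptic
        assert call.verdict == "insufficient_evidence"

    def test_undefined_efficiency_is_insufficient_evidence(self):
        call = classify_cryptic(
            junc(100, 200, split=0, overlap=0),
            is_annotated=False, present_in_reference=False,
        )
        assert call.verdict == "insufficient_evidence"

    def test_threshold_monotonicity(self):
        """Raising the efficiency threshold never removes a cryptic call."""
        j = junc(100, 200, split=3, overlap=100)
        thresholds = [0.04, 0.05, 0.10, 0.5]
        calls = [
            classify_cryptic(j, False, False, efficiency_threshold=t).is_cryptic
            for t in thresholds
        ]
        assert calls == sorted(calls)

    def test_order_invariance(self, rng):
        junctions = [
            junc(int(s), int(s) + 50, split=int(k), overlap=100)
            for s, k in zip(rng.integers(0, 5000, 30), rng.integers(0, 10, 30))
        ]
        flags = [False] * 30
        forward = [
            classify_cryptic(j, a, a).is_cryptic
            for j, a in zip(junctions, flags)
        ]
        backward = [
            classify_cryptic(j, a, a).is_cryptic
            for j, a in zip(junctions[::-1], flags)
        ]
        assert forward == backward[::-1]
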