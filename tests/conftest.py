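import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cryptintron.simulate import (
    GenePlan,
    SimulationConfig,
    make_toy_genome,
    simulate_spliced_reads,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=7,
        read_length=50,
        depth=5.0,
        n_molecules=100,
        genes=[
            GenePlan(splicing_efficiency=[0.9], annotated=[True], strand="+"),
            GenePlan(splicing_efficiency=[0.03], annotated=[False], strand="-"),
        ],
    )


@pytest.fixture
def small_dataset(small_config):
    genome, genes = make_toy_genome(small_config)
    reads, truth = simulate_spliced_reads(genome, genes, small_config)
    return genome, genes, reads, truth


def random_alignments(rng, n_reads, contig="c1", contig_length=5000):
    """Random multi-skip alignments for oracle-equivalence tests.

    Anchors and skips are drawn so that short anchors (below typical
    overhang cutoffs) and out-of-range skip lengths both occur.
    """
    from cryptintron.junctions import SplicedAlignment

    out = []
    # a few recurring junction intervals so that counts aggregate
    junction_pool = [
        (int(s), int(s + l))
        for s, l in zip(
            rng.integers(200, contig_length - 600, size=8),
            rng.integers(25, 400, size=8),
        )
    ]
    for i in range(n_reads):
        n_skips = int(rng.integers(0, 3))
        blocks = []
        if n_skips == 0:
            start = int(rng.integers(0, contig_length - 120))
            blocks = [(int(rng.integers(20, 100)), 0)]
        else:
            s, e = junction_pool[int(rng.integers(0, len(junction_pool)))]
            left = int(rng.integers(1, 60))
            right = int(rng.integers(1, 60))
            start = s - left
            if start < 0:
                continue
            if n_skips == 2 and e + right + 80 + 200 < contig_length:
                second_skip = int(rng.integers(30, 150))
                third = int(rng.integers(1, 40))
                blocks = [(left, e - s), (right, second_skip), (third, 0)]
            else:
                blocks = [(left, e - s), (right, 0)]
        out.append(
            SplicedAlignment(
                read_id=f"r{i}", contig=contig, start=start, blocks=tuple(blocks)
            )
        )
    return out
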