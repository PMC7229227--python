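#!/usr/bin/env python
"""Call cryptic introns on the simulated mutant vs wild type and check
the calls against the planted truth.

A junction is cryptic when it is unannotated, absent from the wild-type
condition, covered by at least 20 junction-spanning reads, and spliced
in strictly less than 5% of them.  Expected outcome: exactly the
planted cryptic introns are called, with percent-spliced estimates near
their programmed excision probabilities; a control run of the wild type
against itself yields zero calls.
"""

import argparse
from pathlib import Path

import pandas as pd

from cryptintron.pipeline import CrypticRunConfig, run_cryptic_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixtures", type=Path,
                        default=Path("results") / "fixtures")
    parser.add_argument("--out-dir", type=Path, default=Path("results") / "cryptic")
    args = parser.parse_args()
    fx = args.fixtures

    calls = run_cryptic_pipeline(
        CrypticRunConfig(
            test_sam=str(fx / "reads_mutant.sam"),
            reference_sam=str(fx / "reads_wt.sam"),
            annotation_gff3=str(fx / "annotation.gff3"),
            genome_fasta=str(fx / "genome.fa"),
            out_dir=str(args.out_dir),
        )
    )
    null_calls = run_cryptic_pipeline(
        CrypticRunConfig(
            test_sam=str(fx / "reads_wt.sam"),
            reference_sam=str(fx / "reads_wt.sam"),
            annotation_gff3=str(fx / "annotation.gff3"),
            genome_fasta=str(fx / "genome.fa"),
            out_dir=str(args.out_dir / "self_subtraction"),
        )
    )

    truth = pd.read_csv(fx / "truth_introns.tsv", sep="\t")
    truth = truth[truth["condition"] == "mutant"]
    planted = {
        (r.contig, r.start, r.end): r.true_efficiency
        for r in truth.itertuples(index=False)
        if not r.annotated and 0 < r.true_efficiency < 0.05
    }
    called = {c.junction.key: c for c in calls if c.is_cryptic}
    print(f"{len(calls)} junctions quantified; {len(called)} called cryptic")
    for key, call in sorted(called.items()):
        true_eff = planted.get(key)
        mark = "planted" if true_eff is not None else "UNEXPECTED"
        print(
            f"  {key[0]}:{key[1]}-{key[2]}  spliced "
            f"{100 * call.efficiency:.2f}% of "
            f"{call.junction.overlapping_read_count} reads "
            f"(true {100 * (true_eff or 0):.1f}%)  [{mark}]"
        )
    missed = set(planted) - set(called)
    print(f"recall {len(set(called) & set(planted))}/{len(planted)}, "
          f"missed {sorted(missed) if missed else 'none'}")
    print(f"self-subtraction control: "
          f"{sum(c.is_cryptic for c in null_calls)} cryptic calls (expect 0)")


if __name__ == "__main__":
    main()
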