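"""Brute-force reference implementations used only as test oracles.

Each oracle expands every read into explicit per-base reference
intervals and answers by direct enumeration, deliberately sharing no
code with the package's block-walking implementations.
"""

from __future__ import annotations

from collections import Counter


def expand_read(aln):
    """(aligned intervals, skipped intervals with flanking anchor sizes)."""
    aligned = []
    skipped = []
    pos = aln.start
    pairs = list(aln.blocks)
    for idx, (m, n) in enumerate(pairs):
        aligned.append((pos, pos + m))
        if n > 0:
            left_anchor = m
            right_anchor = pairs[idx + 1][0]
            skipped.append((pos + m, pos + m + n, left_anchor, right_anchor))
        pos += m + n
    return aligned, skipped


def brute_force_junctions(alignments, min_overhang, min_intron, max_intron):
    """Junction -> split-read count by per-read enumeration."""
    counts = Counter()
    for aln in alignments:
        _, skipped = expand_read(aln)
        for s, e, left, right in skipped:
            if min_intron <= e - s <= max_intron and min(left, right) >= min_overhang:
                counts[(aln.contig, s, e)] += 1
    return dict(counts)


def brute_force_overlap(alignments, contig, start, end, min_overhang, mode="left"):
    """Denominator count by scanning every read base by base."""
    total = 0
    for aln in alignments:
        if aln.contig != contig:
            continue
        aligned, skipped = expand_read(aln)
        split_here = any(
            s == start and e == end and min(l, r) >= min_overhang
            for s, e, l, r in skipped
        )
        covered = set()
        for s, e in aligned:
            covered.update(range(s, e))

        def spans(boundary):
            # every base in the +/- overhang window must be aligned; a
            # window straddling a skip fails because skipped bases are
            # never in the covered set
            need = set(range(boundary - min_overhang, boundary + min_overhang))
            return need <= covered

        left = spans(start)
        right = spans(end)
        if mode == "left":
            hit = left
        elif mode == "right":
            hit = right
        elif mode == "either":
            hit = left or right
        elif mode == "both":
            hit = left and right
        else:
            raise ValueError(mode)
        if split_here or hit:
            total += 1
    return total


def brute_force_length_filter(reads, lo, hi):
    return [r for r in reads if lo <= r.length <= hi]
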