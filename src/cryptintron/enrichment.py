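"""IP-enrichment scoring: RIP-seq background subtraction and RIME PSM ratios.

RIP-seq enrichment is the tagged-strain coverage minus the untagged-strain
background on identically normalised tracks.  RIME enrichment scores each
protein by the log2 ratio of PSM counts in the target pulldown versus the
IgG control, with an empirical p-value taken from the observed ratio
distribution itself: the bulk of proteins in an IP table are nonspecific
binders and serve as the null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_BIN_SIZE = 50


@dataclass
class CoverageTrack:
    """Binned coverage over one contig with a normalisation label."""

    contig: str
    bin_size: int
    values: np.ndarray
    normalization: str = "raw"  # raw | RPKM | RPM

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.normalization in ("raw", "RPKM") and (self.values < 0).any():
            raise ValueError(f"{self.normalization} track must be non-negative")

    def region_mean(self, start: int, end: int) -> float:
        lo, hi = start // self.bin_size, -(-end // self.bin_size)
        return float(self.values[lo:hi].mean())


def rpkm_normalize(track: CoverageTrack, total_mapped: int) -> CoverageTrack:
    """Reads per kilobase per million mapped reads:
    count x 10^9 / (total_mapped x bin_size)."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if track.normalization != "raw":
        raise ValueError("input track must hold raw counts")
    values = track.values * 1e9 / (total_mapped * track.bin_size)
    return replace(track, values=values, normalization="RPKM")


def subtract_background(
    tagged: CoverageTrack, untagged: CoverageTrack
) -> tuple[CoverageTrack, int]:
    """Per-bin tagged minus untagged, floored at zero.

    Returns the enrichment track and the number of bins whose raw
    difference was negative (background exceeding signal).  Tracks must
    share contig, binning and normalisation.
    """
    if (
        tagged.contig != untagged.contig
        or tagged.bin_size != untagged.bin_size
        or tagged.values.size != untagged.values.size
    ):
        raise ValueError("tracks must share contig and binning")
    if tagged.normalization != untagged.normalization:
        raise ValueError("tracks must share normalization")
    diff = tagged.values - untagged.values
    n_negative = int((diff < 0).sum())
    out = replace(tagged, values=np.maximum(diff, 0.0), normalization=tagged.normalization)
    return out, n_negative


def rime_enrichment(
    psm_table: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    tail: str = "normal",
) -> pd.DataFrame:
    """Score proteins by log2 PSM ratio with empirical upper-tail p-values.

    For protein i, r_i = log2((psm_target_i + pc) / (psm_control_i + pc)).
    The null location and scale are estimated robustly (median, and MAD
    scaled by 1.4826 to estimate a standard deviation) so that enriched
    outliers do not contaminate the null fit, and each r_i is converted
    to an upper-tail p-value:

    * ``tail="normal"`` (default): standard-normal upper tail of the
      robust z-score;
    * ``tail="empirical"``: fraction of observed ratios >= r_i.

    Returns a copy of the table with ``log2_ratio`` and ``p_value``
    columns, sorted by ascending p-value.
    """
    required = {"protein_id", "psm_target", "psm_control"}
    missing = required - set(psm_table.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    if len(psm_table) < 20:
        raise ValueError("need at least 20 proteins to estimate the null")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (psm_table["psm_target"] < 0).any() or (psm_table["psm_control"] < 0).any():
        raise ValueError("PSM counts must be non-negative")
    out = psm_table.copy()
    r = np.log2(
        (out["psm_target"].to_numpy(float) + pseudocount)
        / (out["psm_control"].to_numpy(float) + pseudocount)
    )
    out["log2_ratio"] = r
    if tail == "normal":
        scale = stats.median_abs_deviation(r, scale="normal")
        if scale == 0:
            raise ValueError("all log2 ratios identical: null scale is zero")
        z = (r - np.median(r)) / scale
        out["p_value"] = stats.norm.sf(z)
    elif tail == "empirical":
        out["p_value"] = (r[:, None] <= r[None, :]).mean(axis=1)
    else:
        raise ValueError(f"unknown tail mode {tail!r}")
    out["pseudocount"] = pseudocount
    return out.sort_values(
        ["p_value", "protein_id"], kind="mergesort"
    ).reset_index(drop=True)
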