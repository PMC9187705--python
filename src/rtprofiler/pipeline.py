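"""End-to-end convenience: reads -> bins -> smoothed, normalized RT profile."""

from __future__ import annotations

import pandas as pd

from .binning import DEFAULT_READS_PER_BIN, BinReport, bin_reads
from .io import GenomeDescriptor, ReadSet
from .profile import DEFAULT_MAX_GAP, DEFAULT_P, rt_profile_from_bins


def rt_profile_from_reads(
    g1_reads: ReadSet,
    s_reads: ReadSet,
    genome: GenomeDescriptor | None = None,
    reads_per_bin: int = DEFAULT_READS_PER_BIN,
    p: float = DEFAULT_P,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[pd.DataFrame, BinReport]:
    """Run binning, smoothing and normalization; returns (profile, report)."""
    bins, report = bin_reads(g1_reads, s_reads, reads_per_bin=reads_per_bin)
    profile = rt_profile_from_bins(bins, p=p, max_gap=max_gap, genome=genome)
    return profile, report
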