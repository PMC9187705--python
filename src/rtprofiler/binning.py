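"""Variable-size genomic bins with uniform G1 coverage and S/G1 ratios.

Bins are defined so that each contains exactly ``reads_per_bin`` G1 read
starts; bin width therefore absorbs mappability, GC and copy-number
variation in the G1 baseline, leaving the S/G1 ratio sensitive only to
replication timing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ReadSet

logger = logging.getLogger(__name__)

DEFAULT_READS_PER_BIN = 200

BIN_COLUMNS = ["chrom", "start", "end", "g1_count", "s_count", "ratio", "segment_id"]


@dataclass
class BinReport:
    """Per-run accounting emitted alongside the bin table."""

    reads_per_bin: int
    bins_per_chrom: dict[str, int] = field(default_factory=dict)
    dropped_reads_per_chrom: dict[str, int] = field(default_factory=dict)
    skipped_chroms: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom.values())

    @property
    def n_dropped_reads(self) -> int:
        return sum(self.dropped_reads_per_chrom.values())

    def to_dict(self) -> dict:
        return {
            "reads_per_bin": self.reads_per_bin,
            "n_bins": self.n_bins,
            "n_dropped_reads": self.n_dropped_reads,
            "bins_per_chrom": self.bins_per_chrom,
            "dropped_reads_per_chrom": self.dropped_reads_per_chrom,
            "skipped_chroms": self.skipped_chroms,
        }


def define_bins(
    g1_reads: ReadSet, reads_per_bin: int = DEFAULT_READS_PER_BIN
) -> tuple[pd.DataFrame, BinReport]:
    """Partition each chromosome into consecutive bins of exactly
    ``reads_per_bin`` G1 read starts.

    The boundary between adjacent bins is the midpoint between the last
    read of one bin and the first read of the next (ties resolved by
    placing the boundary just after the last read). The first bin starts
    at the first read's position; the final bin ends just after its last
    read. A trailing remainder of fewer than ``reads_per_bin`` reads is
    dropped and reported; chromosomes with fewer than ``reads_per_bin``
    reads are skipped with a warning.
    """
    if reads_per_bin < 2:
        raise ValueError("reads_per_bin must be >= 2")
    report = BinReport(reads_per_bin=reads_per_bin)
    frames = []
    for chrom, pos in g1_reads.positions.items():
        n_bins = pos.size // reads_per_bin
        dropped = pos.size - n_bins * reads_per_bin
        if n_bins == 0:
            logger.warning(
                "chromosome %s has %d < %d G1 reads; skipped", chrom, pos.size, reads_per_bin
            )
            report.skipped_chroms.append(chrom)
            report.dropped_reads_per_chrom[chrom] = int(pos.size)
            continue
        lasts = pos[reads_per_bin - 1 :: reads_per_bin][:n_bins]
        firsts = pos[reads_per_bin::reads_per_bin][: n_bins - 1]
        # midpoint boundary; a tie (equal positions) puts the boundary
        # just after the last read so it stays inside its own bin;
        # boundaries are forced strictly increasing so every bin interval
        # is non-empty even when many reads share one position
        inner = np.maximum((lasts[:-1] + firsts) // 2, lasts[:-1] + 1)
        if inner.size:
            offsets = np.arange(inner.size)
            inner = np.maximum.accumulate(inner - offsets) + offsets
        starts = np.concatenate(([pos[0]], inner))
        last_end = lasts[-1] + 1 if inner.size == 0 else max(lasts[-1] + 1, inner[-1] + 1)
        ends = np.concatenate((inner, [last_end]))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "g1_count": reads_per_bin,
                }
            )
        )
        report.bins_per_chrom[chrom] = int(n_bins)
        report.dropped_reads_per_chrom[chrom] = int(dropped)
    if frames:
        bins = pd.concat(frames, ignore_index=True)
    else:
        bins = pd.DataFrame(columns=["chrom", "start", "end", "g1_count"])
    return bins, report


def count_s_reads(bins: pd.DataFrame, s_reads: ReadSet) -> pd.DataFrame:
    """Count S-phase read starts falling in each bin (half-open intervals)."""
    out = bins.copy()
    s_count = np.zeros(len(bins), dtype=np.int64)
    for chrom, sub in bins.groupby("chrom", sort=False):
        pos = s_reads.positions.get(chrom)
        if pos is None or pos.size == 0:
            continue
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"S reads on {chrom} are not sorted")
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
        s_count[sub.index] = hi - lo
    out["s_count"] = s_count
    return out


def s_over_g1(bins: pd.DataFrame) -> pd.DataFrame:
    """Library-size-normalized S/G1 ratio per bin.

    ratio_j = (s_j / sum(S)) / (g1_j / sum(G1)), with sums over all
    retained bins genome-wide; the g1-weighted mean ratio is 1 by
    construction.
    """
    total_s = int(bins["s_count"].sum())
    total_g1 = int(bins["g1_count"].sum())
    if total_s == 0:
        raise ValueError("no S reads within the binned span")
    out = bins.copy()
    out["ratio"] = (bins["s_count"] / total_s) / (bins["g1_count"] / total_g1)
    return out


def bin_reads(
    g1_reads: ReadSet,
    s_reads: ReadSet,
    reads_per_bin: int = DEFAULT_READS_PER_BIN,
) -> tuple[pd.DataFrame, BinReport]:
    """define_bins + count_s_reads + s_over_g1 in one call."""
    bins, report = define_bins(g1_reads, reads_per_bin)
    if len(bins) == 0:
        raise ValueError("no bins could be defined from the G1 reads")
    bins = count_s_reads(bins, s_reads)
    bins = s_over_g1(bins)
    return bins, report
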