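"""Relative-position centromere profiles and per-chromosome sample rankings.

Each region is divided into 100 equal-width interior bins (relative
coordinates, so regions of different lengths are comparable) plus
flanks at fixed absolute resolution; samples are ranked per chromosome
by descending median rt over the region's interior bins (earliest =
highest rt).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GenomeDescriptor, points_in_intervals

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 100
DEFAULT_FLANK = 5_000_000
DEFAULT_FLANK_BIN = 50_000


def relative_profile(
    profile: pd.DataFrame,
    regions: pd.DataFrame,
    n_bins: int = DEFAULT_N_BINS,
    flank: int = DEFAULT_FLANK,
    flank_bin: int = DEFAULT_FLANK_BIN,
    genome: GenomeDescriptor | None = None,
) -> pd.DataFrame:
    """Mean rt per relative-position bin, averaged across regions.

    Interior bin k of a region of length L spans
    ``[start + k*L/n_bins, start + (k+1)*L/n_bins)``; flank bins use
    fixed absolute width. A profile bin contributes to the relative bin
    containing its center. Indices run from ``-flank//flank_bin`` (left
    flank) through ``n_bins - 1 + flank//flank_bin`` (right flank);
    interior indices are 0..n_bins-1. Bins with no data are NaN.
    """
    if regions[["chrom", "start"]].duplicated().any():
        raise ValueError("regions must be unique")
    n_flank = flank // flank_bin
    idx_range = np.arange(-n_flank, n_bins + n_flank)
    sums = np.zeros(idx_range.size)
    counts = np.zeros(idx_range.size)
    prof_by_chrom = {c: sub for c, sub in profile.groupby("chrom", sort=False)}
    for region in regions.itertuples(index=False):
        if genome is not None:
            if region.chrom not in genome or region.end > genome.length(region.chrom):
                raise ValueError(
                    f"region {region.chrom}:{region.start}-{region.end} outside "
                    "chromosome bounds"
                )
        sub = prof_by_chrom.get(region.chrom)
        if sub is None:
            continue
        centers = sub["center"].to_numpy(dtype=float)
        rt = sub["rt"].to_numpy(dtype=float)
        L = region.end - region.start
        rel = np.full(centers.shape, np.iinfo(np.int32).min, dtype=np.int64)
        interior = (centers >= region.start) & (centers < region.end)
        rel[interior] = np.floor(
            (centers[interior] - region.start) * n_bins / L
        ).astype(np.int64)
        left = (centers >= region.start - flank) & (centers < region.start)
        rel[left] = (
            -1 - np.floor((region.start - 1 - centers[left]) / flank_bin).astype(np.int64)
        )
        right = (centers >= region.end) & (centers < region.end + flank)
        rel[right] = n_bins + np.floor(
            (centers[right] - region.end) / flank_bin
        ).astype(np.int64)
        valid = rel != np.iinfo(np.int32).min
        pos = rel[valid] + n_flank
        np.add.at(sums, pos, rt[valid])
        np.add.at(counts, pos, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"rel_bin": idx_range, "mean_rt": means, "n_values": counts.astype(int)}
    )


def rank_samples(
    profiles: dict[str, pd.DataFrame], regions: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank samples per chromosome by median rt inside the region set.

    Earliest rank (1) is the sample with the highest median rt over bins
    whose centers fall in that chromosome's region intervals (interiors
    only, no flanks). Ties are broken lexicographically by sample name
    and flagged. Chromosomes where any sample lacks centromeric bins are
    excluded and logged.

    Returns ``(rank_table, rank_histogram)``: the first has one row per
    (chromosome, sample) with the median and rank; the second counts,
    per sample, how often it took each rank.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 samples to rank")
    samples = sorted(profiles)
    chroms = sorted(regions["chrom"].unique())
    rows = []
    for chrom in chroms:
        reg = regions[regions["chrom"] == chrom]
        medians = {}
        ok = True
        for name in samples:
            prof = profiles[name]
            sub = prof[prof["chrom"] == chrom]
            inside = points_in_intervals(sub["chrom"], sub["center"].to_numpy(), reg)
            if inside.sum() == 0:
                logger.warning(
                    "sample %s has no centromeric bins on %s; chromosome excluded",
                    name, chrom,
                )
                ok = False
                break
            medians[name] = float(sub.loc[inside, "rt"].median())
        if not ok:
            continue
        # descending median; lexicographic tie-break for determinism
        ordered = sorted(samples, key=lambda s: (-medians[s], s))
        tied = len(set(medians.values())) < len(samples)
        for rank, name in enumerate(ordered, 1):
            rows.append(
                {
                    "chrom": chrom,
                    "sample": name,
                    "median_rt": medians[name],
                    "rank": rank,
                    "tied": tied,
                }
            )
    rank_table = pd.DataFrame(rows, columns=["chrom", "sample", "median_rt", "rank", "tied"])
    hist = (
        rank_table.groupby(["sample", "rank"]).size().unstack(fill_value=0)
        if len(rank_table)
        else pd.DataFrame(index=pd.Index(samples, name="sample"))
    )
    hist = hist.reindex(index=samples, fill_value=0)
    return rank_table, hist
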