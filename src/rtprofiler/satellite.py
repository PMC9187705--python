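"""Per-satellite-family replication-timing bias statistics.

Profile bins are assigned to the annotation interval covering their
center; statistics (median, IQR, fraction of early ``rt > 0`` values)
are computed per family and against a caller-supplied baseline subset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import points_in_intervals

logger = logging.getLogger(__name__)

#: families reported individually; anything else aggregates as censat_other
REPORTED_FAMILIES = ("hor", "dhor", "mon", "hsat1", "hsat2", "hsat3", "bsat", "ct")


def _check_partition(annotation: pd.DataFrame) -> None:
    for chrom, sub in annotation.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        fams = sub["family"].to_numpy()
        bad = (starts[1:] < ends[:-1]) & (fams[1:] != fams[:-1])
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"overlapping annotation intervals of different families on {chrom} "
                f"near position {starts[1:][i]}"
            )


def assign_bins_to_families(
    profile: pd.DataFrame, annotation: pd.DataFrame
) -> pd.Series:
    """Family label per profile bin, or NA when the bin center is uncovered.

    A bin belongs to the interval containing its center under half-open
    semantics. The annotation must be a partition: overlapping intervals
    of different families are rejected.
    """
    if "family" not in annotation.columns:
        raise ValueError("annotation requires a 'family' column")
    _check_partition(annotation)
    result = pd.Series(pd.NA, index=profile.index, dtype="object")
    ann_by_chrom = {
        c: sub.sort_values("start") for c, sub in annotation.groupby("chrom", sort=False)
    }
    for chrom, sub in profile.groupby("chrom", sort=False):
        ann = ann_by_chrom.get(chrom)
        if ann is None:
            continue
        starts = ann["start"].to_numpy()
        ends = ann["end"].to_numpy()
        fams = ann["family"].to_numpy()
        centers = sub["center"].to_numpy()
        idx = np.searchsorted(starts, centers, side="right") - 1
        ok = idx >= 0
        covered = np.zeros(len(sub), dtype=bool)
        covered[ok] = centers[ok] < ends[idx[ok]]
        result.loc[sub.index[covered]] = fams[idx[covered]]
    return result


def family_stats(
    assignments: pd.Series,
    profile: pd.DataFrame,
    baseline_mask: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Median / IQR / early-fraction of rt per family, plus a baseline row.

    ``baseline_mask`` selects the comparison bin subset (e.g. all
    non-centromeric bins). Families outside :data:`REPORTED_FAMILIES`
    are aggregated as ``censat_other``; families with no bins are
    omitted with a warning.
    """
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if baseline_mask.sum() == 0:
        raise ValueError("empty baseline")
    rt = profile["rt"].to_numpy(dtype=float)
    canon = assignments.map(
        lambda f: f if pd.isna(f) or f in REPORTED_FAMILIES else "censat_other"
    )
    rows = []

    def _row(label: str, values: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        return {
            "family": label,
            "n_bins": int(values.size),
            "median": float(med),
            "iqr": float(q3 - q1),
            "early_fraction": float(np.mean(values > 0)),
        }

    for fam in (*REPORTED_FAMILIES, "censat_other"):
        sel = (canon == fam).to_numpy()
        if sel.sum() == 0:
            logger.warning("family %s has no assigned bins; omitted", fam)
            continue
        rows.append(_row(fam, rt[sel]))
    rows.append(_row("baseline", rt[baseline_mask]))
    return pd.DataFrame(rows)


def newly_resolved_summary(
    profile: pd.DataFrame,
    regions: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Among early (rt > 0) bins inside ``regions``: the share assigned to
    each family (plus ``unlabeled``); shares sum to 1. No early bins is
    reported as zero counts, not an error.
    """
    inside = points_in_intervals(profile["chrom"], profile["center"].to_numpy(), regions)
    early = inside & (profile["rt"].to_numpy() > 0)
    assignments = assign_bins_to_families(profile, annotation)
    labels = assignments.where(assignments.notna(), "unlabeled")[early]
    counts = labels.value_counts()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "family": counts.index,
            "n_early_bins": counts.to_numpy(dtype=int),
            "share": (counts / total).to_numpy() if total else np.zeros(len(counts)),
        }
    ).reset_index(drop=True)
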