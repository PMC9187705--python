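"""Peak/valley calling on RT profiles and replication-dynamics statistics.

The distance between consecutive RT peaks is used as a proxy for
inter-origin distance; the averaged ascending/descending slope at each
peak is used as a proxy for replication fork speed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import peak_prominences

from .io import points_in_intervals

EXTREMA_COLUMNS = ["chrom", "position", "rt", "kind", "prominence", "segment_id"]


def _compress_plateaus(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal consecutive values to single points.

    Returns (compressed values, representative original index per run),
    the representative being the run's midpoint bin.
    """
    change = np.empty(y.size, dtype=bool)
    change[0] = True
    change[1:] = y[1:] != y[:-1]
    run_starts = np.nonzero(change)[0]
    run_ends = np.append(run_starts[1:], y.size)
    reps = (run_starts + run_ends - 1) // 2
    return y[run_starts], reps


def _enforce_alternation(ext: list[dict]) -> list[dict]:
    """Drop the shallower of any adjacent same-kind pair until the
    sequence alternates peak/valley along the segment."""
    changed = True
    while changed and len(ext) > 1:
        changed = False
        for i in range(len(ext) - 1):
            if ext[i]["kind"] == ext[i + 1]["kind"]:
                drop = i if ext[i]["prominence"] < ext[i + 1]["prominence"] else i + 1
                del ext[drop]
                changed = True
                break
    return ext


def call_extrema(profile: pd.DataFrame, min_prominence: float = 0.0) -> pd.DataFrame:
    """Discrete local maxima (peaks) and minima (valleys) of rt per segment.

    Plateaus collapse to their midpoint bin; extrema with prominence
    below ``min_prominence`` are removed, after which alternation is
    re-enforced by discarding the shallower of any adjacent same-kind
    pair. Only interior extrema are called (segment endpoints never are).
    """
    rows: list[dict] = []
    for seg, sub in profile.groupby("segment_id", sort=True):
        y = sub["rt"].to_numpy(dtype=float)
        centers = sub["center"].to_numpy()
        chrom = sub["chrom"].iloc[0]
        if y.size < 3:
            continue
        comp, reps = _compress_plateaus(y)
        if comp.size < 3:
            continue
        interior = np.arange(1, comp.size - 1)
        is_peak = (comp[interior] > comp[interior - 1]) & (comp[interior] > comp[interior + 1])
        is_valley = (comp[interior] < comp[interior - 1]) & (comp[interior] < comp[interior + 1])
        peak_idx = interior[is_peak]
        valley_idx = interior[is_valley]
        prom_peak = peak_prominences(comp, peak_idx)[0] if peak_idx.size else np.array([])
        prom_valley = peak_prominences(-comp, valley_idx)[0] if valley_idx.size else np.array([])
        ext = [
            {
                "chrom": chrom,
                "position": int(centers[reps[i]]),
                "rt": float(y[reps[i]]),
                "kind": kind,
                "prominence": float(p),
                "segment_id": seg,
                "_order": int(i),
            }
            for idx, proms, kind in (
                (peak_idx, prom_peak, "peak"),
                (valley_idx, prom_valley, "valley"),
            )
            for i, p in zip(idx, proms)
        ]
        ext.sort(key=lambda e: e["_order"])
        ext = [e for e in ext if e["prominence"] >= min_prominence]
        ext = _enforce_alternation(ext)
        for e in ext:
            del e["_order"]
        rows.extend(ext)
    return pd.DataFrame(rows, columns=EXTREMA_COLUMNS)


def inter_peak_distances(
    extrema: pd.DataFrame, regions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Distances between consecutive peaks within each segment.

    With ``regions`` given, a distance is attributed to the region set
    iff both peaks lie inside a region interval (``in_region``); pairs
    with both peaks outside are flagged ``out_region`` (spanning pairs
    are neither).
    """
    peaks = extrema[extrema["kind"] == "peak"]
    rows = []
    for seg, sub in peaks.groupby("segment_id", sort=True):
        pos = sub["position"].to_numpy()
        chrom = sub["chrom"].iloc[0]
        for a, b in zip(pos[:-1], pos[1:]):
            rows.append({"chrom": chrom, "left": int(a), "right": int(b),
                         "distance": int(b - a), "segment_id": seg})
    df = pd.DataFrame(rows, columns=["chrom", "left", "right", "distance", "segment_id"])
    if regions is not None and len(df):
        left_in = points_in_intervals(df["chrom"], df["left"].to_numpy(), regions)
        right_in = points_in_intervals(df["chrom"], df["right"].to_numpy(), regions)
        df["in_region"] = left_in & right_in
        df["out_region"] = ~left_in & ~right_in
    elif regions is not None:
        df["in_region"] = pd.Series(dtype=bool)
        df["out_region"] = pd.Series(dtype=bool)
    return df


def peak_slopes(
    profile: pd.DataFrame,
    extrema: pd.DataFrame,
    regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Averaged ascending/descending slope at each peak, in z-units per Mb.

    ascending = |rt_peak - rt_left_valley| / Mb to the left valley, and
    the descending analog; the peak's slope is their mean. Peaks missing
    a flanking valley (segment edges) use the single available side;
    peaks with no flanking valley at all are skipped.
    """
    rows = []
    for seg, sub in extrema.groupby("segment_id", sort=True):
        sub = sub.sort_values("position")
        kinds = sub["kind"].to_numpy()
        pos = sub["position"].to_numpy(dtype=float)
        rt = sub["rt"].to_numpy(dtype=float)
        chrom = sub["chrom"].iloc[0]
        for i in np.nonzero(kinds == "peak")[0]:
            sides = []
            if i > 0 and kinds[i - 1] == "valley":
                sides.append(abs(rt[i] - rt[i - 1]) / ((pos[i] - pos[i - 1]) / 1e6))
            if i + 1 < len(kinds) and kinds[i + 1] == "valley":
                sides.append(abs(rt[i] - rt[i + 1]) / ((pos[i + 1] - pos[i]) / 1e6))
            if not sides:
                continue
            rows.append({"chrom": chrom, "position": int(pos[i]),
                         "slope": float(np.mean(sides)), "segment_id": seg})
    df = pd.DataFrame(rows, columns=["chrom", "position", "slope", "segment_id"])
    if regions is not None and len(df):
        df["in_region"] = points_in_intervals(df["chrom"], df["position"].to_numpy(), regions)
    elif regions is not None:
        df["in_region"] = pd.Series(dtype=bool)
    return df


def dynamics_summary(
    profile: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    min_prominence: float = 0.0,
) -> dict:
    """Medians of inter-peak distances (Mb) and slopes (z/Mb), overall and
    split by region membership when ``regions`` is given."""
    extrema = call_extrema(profile, min_prominence=min_prominence)
    dists = inter_peak_distances(extrema, regions=regions)
    slopes = peak_slopes(profile, extrema, regions=regions)

    def _med(series: pd.Series) -> float | None:
        return float(series.median()) if len(series) else None

    out = {
        "n_peaks": int((extrema["kind"] == "peak").sum()),
        "n_valleys": int((extrema["kind"] == "valley").sum()),
        "median_inter_peak_mb": _med(dists["distance"] / 1e6),
        "median_slope_per_mb": _med(slopes["slope"]),
    }
    if regions is not None:
        out["median_inter_peak_mb_in_region"] = _med(
            dists.loc[dists["in_region"], "distance"] / 1e6
        )
        out["median_inter_peak_mb_out_region"] = _med(
            dists.loc[dists["out_region"], "distance"] / 1e6
        )
        out["median_slope_per_mb_in_region"] = _med(slopes.loc[slopes["in_region"], "slope"])
        out["median_slope_per_mb_out_region"] = _med(slopes.loc[~slopes["in_region"], "slope"])
    return out
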