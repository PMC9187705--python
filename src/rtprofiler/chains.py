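"""UCSC chain parsing, fixed-window coordinate mapping, and cross-assembly
profile correlation.

A window maps through the single highest-scoring chain overlapping it,
and only if at least ``min_match`` of its bases fall in that chain's
aligned blocks; negative-strand query coordinates are converted to
forward-strand intervals. This is deliberately simpler than full
liftOver semantics (frozen, configurable rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

DEFAULT_MIN_MATCH = 0.95


@dataclass
class Chain:
    """One chain: target (source assembly) -> query (destination assembly)."""

    score: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    sizes: np.ndarray  # aligned block sizes
    dts: np.ndarray    # gap after each block on target (last = 0)
    dqs: np.ndarray    # gap after each block on query (last = 0)

    def __post_init__(self) -> None:
        if np.any(self.sizes <= 0):
            raise ValueError(f"chain {self.chain_id}: non-positive block size")
        if self.t_strand not in "+-" or self.q_strand not in "+-":
            raise ValueError(f"chain {self.chain_id}: invalid strand")
        t_span = int(np.sum(self.sizes) + np.sum(self.dts))
        q_span = int(np.sum(self.sizes) + np.sum(self.dqs))
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: target blocks span {t_span}, "
                f"header declares {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.chain_id}: query blocks span {q_span}, "
                f"header declares {self.q_end - self.q_start}"
            )

    @property
    def t_block_starts(self) -> np.ndarray:
        return self.t_start + np.concatenate(([0], np.cumsum(self.sizes + self.dts)[:-1]))

    @property
    def q_block_starts(self) -> np.ndarray:
        """Block starts in chain-local query coordinates (strand-relative)."""
        return self.q_start + np.concatenate(([0], np.cumsum(self.sizes + self.dqs)[:-1]))


def parse_chain(path: str | Path) -> list[Chain]:
    """Parse a UCSC chain file; chains are returned ordered by descending
    score. Block arithmetic is validated against the declared spans."""
    chains: list[Chain] = []
    header: list[str] | None = None
    sizes: list[int] = []
    dts: list[int] = []
    dqs: list[int] = []

    def _flush() -> None:
        nonlocal header
        if header is None:
            return
        chains.append(
            Chain(
                score=int(header[1]),
                t_name=header[2],
                t_size=int(header[3]),
                t_strand=header[4],
                t_start=int(header[5]),
                t_end=int(header[6]),
                q_name=header[7],
                q_size=int(header[8]),
                q_strand=header[9],
                q_start=int(header[10]),
                q_end=int(header[11]),
                chain_id=header[12] if len(header) > 12 else str(len(chains)),
                sizes=np.array(sizes, dtype=np.int64),
                dts=np.array(dts, dtype=np.int64),
                dqs=np.array(dqs, dtype=np.int64),
            )
        )
        header = None
        sizes.clear()
        dts.clear()
        dqs.clear()

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                _flush()
                header = line.split()
                if len(header) < 12:
                    raise ValueError(f"{path}: malformed chain header: {line!r}")
            else:
                parts = line.split()
                sizes.append(int(parts[0]))
                if len(parts) == 3:
                    dts.append(int(parts[1]))
                    dqs.append(int(parts[2]))
                else:
                    dts.append(0)
                    dqs.append(0)
    _flush()
    chains.sort(key=lambda c: -c.score)
    return chains


def tile_windows(genome, window: int = 1000) -> pd.DataFrame:
    """Fixed-width window tiling of every chromosome (last window clipped)."""
    rows = []
    for chrom in genome.names:
        length = genome.length(chrom)
        starts = np.arange(0, length, window, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _aligned_cumulative(chain: Chain):
    """Helpers to count aligned target bases below a position and to map
    target positions to chain-local query coordinates."""
    bs = chain.t_block_starts
    be = bs + chain.sizes
    cum = np.concatenate(([0], np.cumsum(chain.sizes)))
    qs = chain.q_block_starts

    def count_below(pos: np.ndarray) -> np.ndarray:
        i = np.searchsorted(bs, pos, side="right") - 1
        out = np.zeros(pos.shape, dtype=np.int64)
        ok = i >= 0
        out[ok] = cum[i[ok]] + np.clip(pos[ok] - bs[i[ok]], 0, chain.sizes[i[ok]])
        return out

    return bs, be, qs, count_below


def map_windows(
    windows: pd.DataFrame,
    chains: list[Chain],
    min_match: float = DEFAULT_MIN_MATCH,
) -> pd.DataFrame:
    """Map fixed windows through chains (one chain per window, best score).

    Status per window: ``mapped``; ``no_chain`` (no overlapping chain);
    ``split`` (no single chain reaches ``min_match`` but chains jointly
    do); ``partial`` (insufficient aligned bases). Mapped windows get the
    forward-strand query interval spanned by their aligned bases.
    """
    n = len(windows)
    status = np.full(n, "no_chain", dtype=object)
    q_chrom = np.full(n, "", dtype=object)
    q_start = np.full(n, -1, dtype=np.int64)
    q_end = np.full(n, -1, dtype=np.int64)
    q_strand = np.full(n, "", dtype=object)
    best_score = np.full(n, -1, dtype=np.int64)
    best_aligned = np.zeros(n, dtype=np.int64)
    total_aligned = np.zeros(n, dtype=np.int64)

    win_by_chrom = {c: sub for c, sub in windows.groupby("chrom", sort=False)}
    for chain in chains:
        sub = win_by_chrom.get(chain.t_name)
        if sub is None:
            continue
        ws = sub["start"].to_numpy()
        we = sub["end"].to_numpy()
        overlaps = (we > chain.t_start) & (ws < chain.t_end)
        if not overlaps.any():
            continue
        idx = sub.index.to_numpy()[overlaps]
        ws, we = ws[overlaps], we[overlaps]
        bs, be, qs, count_below = _aligned_cumulative(chain)
        aligned = count_below(we) - count_below(ws)
        total_aligned[idx] += aligned
        better = (chain.score > best_score[idx]) & (aligned > 0)
        take = idx[better]
        if take.size == 0:
            continue
        best_score[take] = chain.score
        best_aligned[take] = aligned[better]
        wlen = we[better] - ws[better]
        ok = aligned[better] >= np.ceil(min_match * wlen).astype(np.int64)
        # first/last aligned target base inside the window -> query coords
        s_arr, e_arr = ws[better][ok], we[better][ok]
        tgt = take[ok]
        if tgt.size:
            i_s = np.searchsorted(be, s_arr, side="right")
            first = np.maximum(s_arr, bs[np.minimum(i_s, len(bs) - 1)])
            i_e = np.searchsorted(bs, e_arr, side="right") - 1
            last = np.minimum(e_arr - 1, be[i_e] - 1)
            fi = np.searchsorted(bs, first, side="right") - 1
            li = np.searchsorted(bs, last, side="right") - 1
            q_lo = qs[fi] + (first - bs[fi])
            q_hi = qs[li] + (last - bs[li]) + 1
            if chain.q_strand == "-":
                q_lo, q_hi = chain.q_size - q_hi, chain.q_size - q_lo
            status[tgt] = "mapped"
            q_chrom[tgt] = chain.q_name
            q_start[tgt] = q_lo
            q_end[tgt] = q_hi
            q_strand[tgt] = chain.q_strand
        insufficient = take[~ok]
        status[insufficient] = "partial"

    # windows no single chain satisfies but chains jointly would
    joint = (
        (status == "partial")
        & (total_aligned > best_aligned)
        & (
            total_aligned
            >= np.ceil(min_match * (windows["end"] - windows["start"]).to_numpy())
        )
    )
    status[joint] = "split"

    out = windows.copy()
    out["status"] = status
    out["q_chrom"] = q_chrom
    out["q_start"] = q_start
    out["q_end"] = q_end
    out["q_strand"] = q_strand
    return out


def mapping_fractions(window_map: pd.DataFrame) -> dict:
    n = len(window_map)
    mapped = int((window_map["status"] == "mapped").sum())
    counts = window_map["status"].value_counts().to_dict()
    return {
        "n_windows": n,
        "mapped_fraction": mapped / n if n else 0.0,
        "unmapped_fraction": (n - mapped) / n if n else 0.0,
        "status_counts": {k: int(v) for k, v in counts.items()},
    }


def _nearest_lookup(
    profile: pd.DataFrame,
    chroms: np.ndarray,
    positions: np.ndarray,
    max_gap: int,
) -> np.ndarray:
    """rt at the nearest bin center on the same chromosome (NaN beyond max_gap)."""
    out = np.full(positions.shape, np.nan)
    by_chrom = {c: sub for c, sub in profile.groupby("chrom", sort=False)}
    for chrom in np.unique(chroms):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        centers = sub["center"].to_numpy()
        order = np.argsort(centers)
        centers = centers[order]
        rt = sub["rt"].to_numpy()[order]
        sel = chroms == chrom
        pos = positions[sel]
        i = np.clip(np.searchsorted(centers, pos), 1, centers.size - 1)
        left, right = centers[i - 1], centers[i]
        nearest = np.where(pos - left <= right - pos, i - 1, i)
        if centers.size == 1:
            nearest = np.zeros(pos.shape, dtype=int)
        dist = np.abs(centers[nearest] - pos)
        vals = np.where(dist <= max_gap, rt[nearest], np.nan)
        out[sel] = vals
    return out


def profile_correlation(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    window_map: pd.DataFrame,
    max_gap: int = 100_000,
) -> dict:
    """Pearson r between two profiles over mapped windows.

    Profile A is evaluated at source-window midpoints, profile B at the
    mapped query midpoints, both by nearest-bin lookup within
    ``max_gap``. Windows unevaluable in either profile are dropped.
    """
    mapped = window_map[window_map["status"] == "mapped"]
    if len(mapped) == 0:
        raise ValueError("no mapped windows")
    mid_a = ((mapped["start"] + mapped["end"]) // 2).to_numpy()
    mid_b = ((mapped["q_start"] + mapped["q_end"]) // 2).to_numpy()
    vals_a = _nearest_lookup(profile_a, mapped["chrom"].to_numpy(), mid_a, max_gap)
    vals_b = _nearest_lookup(profile_b, mapped["q_chrom"].to_numpy(), mid_b, max_gap)
    ok = ~(np.isnan(vals_a) | np.isnan(vals_b))
    if ok.sum() < 3:
        raise ValueError("fewer than 3 paired points for correlation")
    r = float(pearsonr(vals_a[ok], vals_b[ok]).statistic)
    return {"r": r, "n": int(ok.sum())}
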