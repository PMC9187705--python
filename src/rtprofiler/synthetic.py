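"""Synthetic G1/S read generation from a known replication-kinetics landscape.

The generative model: each chromosome carries a set of replication
origins with fixed firing times (as fractions of S phase) and a constant
fork speed. A locus replicates at the earliest time any origin's fork
reaches it. S-phase cells are sampled uniformly through S-phase
progression, so the expected copy number at a locus is affine in its
replication time: ``c(x) = 2 - tau(x)``. G1 coverage is uniform up to an
optional bias curve; S coverage is proportional to ``bias * c(x)``.
Assembly gaps (e.g. rDNA placeholders) emit zero reads in both phases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import GenomeDescriptor, ReadSet, write_bedgraph

BiasCurve = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class Landscape:
    """Replication-kinetics ground truth for one chromosome.

    ``origins`` is a sequence of ``(position_bp, firing_time)`` pairs with
    firing times as fractions of S phase in ``[0, 1)``; ``fork_speed`` is
    in bp per unit S-phase fraction.
    """

    chrom_length: int
    origins: tuple[tuple[int, float], ...]
    fork_speed: float
    gaps: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be positive")
        object.__setattr__(self, "origins", tuple((int(p), float(t)) for p, t in self.origins))
        object.__setattr__(self, "gaps", tuple((int(s), int(e)) for s, e in self.gaps))
        pos = [p for p, _ in self.origins]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("origin positions must be strictly increasing")
        if any(not (0 <= p < self.chrom_length) for p in pos):
            raise ValueError("origin positions must lie within [0, chrom_length)")
        if any(not (0 <= t < 1) for _, t in self.origins):
            raise ValueError("firing times must lie in [0, 1)")
        prev_end = -1
        for s, e in self.gaps:
            if s >= e:
                raise ValueError(f"empty gap [{s}, {e})")
            if s < prev_end:
                raise ValueError("gaps must be sorted and non-overlapping")
            prev_end = e

    def to_dict(self) -> dict:
        return {
            "chrom_length": self.chrom_length,
            "origins": [[p, t] for p, t in self.origins],
            "fork_speed": self.fork_speed,
            "gaps": [[s, e] for s, e in self.gaps],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Landscape":
        return cls(
            chrom_length=d["chrom_length"],
            origins=tuple((p, t) for p, t in d["origins"]),
            fork_speed=d["fork_speed"],
            gaps=tuple((s, e) for s, e in d.get("gaps", [])),
        )


@dataclass(frozen=True)
class SimConfig:
    """Read-sampling configuration.

    ``resolution`` is the width (bp) of the piecewise-constant weight
    cells used for multinomial sampling; positions are uniform within a
    cell's mappable part.
    """

    n_reads_g1: int
    n_reads_s: int
    seed: int = 0
    bias_curve: BiasCurve | None = field(default=None, compare=False)
    resolution: int = 1000

    def __post_init__(self) -> None:
        if self.n_reads_g1 <= 0 or self.n_reads_s <= 0:
            raise ValueError("read counts must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


def timing_curve(landscape: Landscape, positions: np.ndarray | Sequence[float]) -> np.ndarray:
    """Replication time tau(x) in [0, 1] at the given positions.

    tau(x) = min over origins of (firing_time + |x - origin| / fork_speed),
    capped at 1 (loci the forks never reach within S stay unreplicated
    until the end of S).
    """
    if not landscape.origins:
        raise ValueError("no origins")
    x = np.asarray(positions, dtype=float)
    if np.any((x < 0) | (x >= landscape.chrom_length)):
        raise ValueError("positions outside [0, chrom_length)")
    tau = np.full(x.shape, np.inf)
    for pos, t in landscape.origins:
        np.minimum(tau, t + np.abs(x - pos) / landscape.fork_speed, out=tau)
    return np.minimum(tau, 1.0)


def copy_number_curve(tau: np.ndarray | Sequence[float]) -> np.ndarray:
    """Expected copy number c(x) = 2 - tau(x) under uniform sampling of S cells.

    A locus with replication time tau has been replicated in a fraction
    (1 - tau) of S-phase cells, so its expected copies per cell is
    1 + (1 - tau), ranging from 2 (earliest) down to 1 (latest).
    """
    t = np.asarray(tau, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("tau values must lie in [0, 1]")
    return 2.0 - t


def _cell_grid(landscape: Landscape, resolution: int):
    """Cell boundaries and per-cell mappable lengths for the weight grid."""
    edges = np.arange(0, landscape.chrom_length + resolution, resolution, dtype=np.int64)
    edges[-1] = landscape.chrom_length
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    lo, hi = edges[:-1], edges[1:]
    mappable = (hi - lo).astype(float)
    for gs, ge in landscape.gaps:
        overlap = np.clip(np.minimum(hi, ge) - np.maximum(lo, gs), 0, None)
        mappable -= overlap
    return lo, hi, mappable


def _cell_weights(
    landscape: Landscape, config: SimConfig, phase: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo, hi, mappable = _cell_grid(landscape, config.resolution)
    mid = (lo + hi) / 2.0
    weights = mappable.copy()
    if config.bias_curve is not None:
        bias = np.asarray(config.bias_curve(mid), dtype=float)
        if np.any(bias < 0):
            raise ValueError("bias weights must be non-negative")
        weights *= bias
    if phase == "S":
        weights *= copy_number_curve(timing_curve(landscape, mid))
    elif phase != "G1":
        raise ValueError(f"phase must be 'G1' or 'S', got {phase!r}")
    return lo, hi, weights


def _sample_chrom(
    landscape: Landscape,
    config: SimConfig,
    phase: str,
    n_reads: int,
    rng: np.random.Generator,
) -> np.ndarray:
    lo, hi, weights = _cell_weights(landscape, config, phase)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all weights zero")
    counts = rng.multinomial(n_reads, weights / total)
    nz = np.nonzero(counts)[0]
    cell_idx = np.repeat(nz, counts[nz])
    span = (hi - lo)[cell_idx]
    positions = lo[cell_idx] + np.floor(rng.random(cell_idx.size) * span).astype(np.int64)
    # reads landing inside a gap are resampled from the mappable part of
    # their cell (cell weights already exclude the gap fraction)
    for gs, ge in landscape.gaps:
        while True:
            bad = (positions >= gs) & (positions < ge)
            if not bad.any():
                break
            idx = np.nonzero(bad)[0]
            positions[idx] = (
                lo[cell_idx[idx]]
                + np.floor(rng.random(idx.size) * span[idx]).astype(np.int64)
            )
    positions.sort()
    return positions


def sample_reads(landscape: Landscape, config: SimConfig, phase: str) -> ReadSet:
    """Draw a single-chromosome ReadSet (chromosome named ``chr1``)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reads_g1 if phase == "G1" else config.n_reads_s
    positions = _sample_chrom(landscape, config, phase, n, rng)
    return ReadSet(positions={"chr1": positions}, phase=phase)


def simulate_genome(
    landscapes: dict[str, Landscape], config: SimConfig
) -> tuple[ReadSet, ReadSet]:
    """Sample G1 and S ReadSets over a multi-chromosome genome.

    Reads are allocated across chromosomes multinomially in proportion to
    each chromosome's total sampling weight, then drawn per chromosome
    with independent child seeds (deterministic under ``config.seed``).
    """
    chroms = list(landscapes)
    seq = np.random.SeedSequence(config.seed)
    alloc_rng = np.random.default_rng(seq.spawn(1)[0])
    child_seqs = seq.spawn(2 * len(chroms))
    out: dict[str, dict[str, np.ndarray]] = {"G1": {}, "S": {}}
    for pi, (phase, n_total) in enumerate(
        (("G1", config.n_reads_g1), ("S", config.n_reads_s))
    ):
        totals = np.array(
            [_cell_weights(landscapes[c], config, phase)[2].sum() for c in chroms]
        )
        if totals.sum() <= 0:
            raise ValueError("all weights zero")
        counts = alloc_rng.multinomial(n_total, totals / totals.sum())
        for ci, chrom in enumerate(chroms):
            rng = np.random.default_rng(child_seqs[pi * len(chroms) + ci])
            out[phase][chrom] = _sample_chrom(
                landscapes[chrom], config, phase, int(counts[ci]), rng
            )
    return (
        ReadSet(positions=out["G1"], phase="G1"),
        ReadSet(positions=out["S"], phase="S"),
    )


def random_landscape(
    chrom_length: int,
    n_origins: int,
    rng: np.random.Generator,
    fork_speed: float | None = None,
    firing_range: tuple[float, float] = (0.1, 0.3),
    jitter: float = 0.3,
    gaps: Sequence[tuple[int, int]] = (),
) -> Landscape:
    """Build a landscape with roughly evenly spaced, jittered origins.

    Firing times are uniform in ``firing_range``; the default fork speed
    puts the latest loci near the end of S phase without saturating.
    """
    spacing = chrom_length / n_origins
    base = (np.arange(n_origins) + 0.5) * spacing
    pos = base + rng.uniform(-jitter, jitter, n_origins) * spacing
    pos = np.clip(np.sort(pos), 0, chrom_length - 1).astype(np.int64)
    pos = np.unique(pos)
    times = rng.uniform(*firing_range, pos.size)
    if fork_speed is None:
        fork_speed = spacing / (1.0 - max(firing_range))
    return Landscape(
        chrom_length=chrom_length,
        origins=tuple(zip(pos.tolist(), times.tolist())),
        fork_speed=float(fork_speed),
        gaps=tuple(gaps),
    )


def genome_from_landscapes(landscapes: dict[str, Landscape]) -> GenomeDescriptor:
    return GenomeDescriptor.from_dict(
        {c: ls.chrom_length for c, ls in landscapes.items()}
    )


def write_truth_curves(
    landscapes: dict[str, Landscape], out_dir: str | Path, resolution: int = 1000
) -> None:
    """Write true tau(x) and c(x) as bedGraph at the given resolution."""
    out_dir = Path(out_dir)
    rows_tau, rows_c = [], []
    for chrom, ls in landscapes.items():
        edges = np.arange(0, ls.chrom_length + resolution, resolution, dtype=np.int64)
        edges[-1] = ls.chrom_length
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        mid = (edges[:-1] + edges[1:]) / 2.0
        tau = timing_curve(ls, mid)
        c = copy_number_curve(tau)
        for s, e, tv, cv in zip(edges[:-1], edges[1:], tau, c):
            rows_tau.append((chrom, int(s), int(e), tv))
            rows_c.append((chrom, int(s), int(e), cv))
    write_bedgraph(
        pd.DataFrame(rows_tau, columns=["chrom", "start", "end", "value"]),
        out_dir / "tau.bedGraph",
    )
    write_bedgraph(
        pd.DataFrame(rows_c, columns=["chrom", "start", "end", "value"]),
        out_dir / "copy_number.bedGraph",
    )


def write_landscapes_json(landscapes: dict[str, Landscape], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({c: ls.to_dict() for c, ls in landscapes.items()}, fh, indent=1)


def read_landscapes_json(path: str | Path) -> dict[str, Landscape]:
    with open(path) as fh:
        data = json.load(fh)
    return {c: Landscape.from_dict(d) for c, d in data.items()}
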