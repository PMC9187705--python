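"""Readers and writers for the text formats the pipeline touches.

All coordinates are 0-based half-open (BED-native) internally. Any
1-based external dialect is converted at the boundary, never inside
the pipeline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_AUTOSOME_RE = re.compile(r"^(chr)?([0-9]+)$", re.IGNORECASE)
_CHRX_RE = re.compile(r"^(chr)?X$", re.IGNORECASE)
_CHRY_RE = re.compile(r"^(chr)?Y$", re.IGNORECASE)


@dataclass(frozen=True)
class GenomeDescriptor:
    """Ordered chromosome names and lengths, with autosome/X/Y flags.

    Autosomes are recognized by name (``chr1``..``chr22`` or bare
    ``1``..``22``); the Y chromosome is recognized so callers can drop it.
    """

    names: tuple[str, ...]
    lengths: dict[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            if name not in self.lengths:
                raise ValueError(f"missing length for chromosome {name!r}")
            if self.lengths[name] <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def length(self, name: str) -> int:
        return self.lengths[name]

    @staticmethod
    def is_autosome(name: str) -> bool:
        m = _AUTOSOME_RE.match(name)
        return bool(m) and 1 <= int(m.group(2)) <= 22

    @staticmethod
    def is_x(name: str) -> bool:
        return bool(_CHRX_RE.match(name))

    @staticmethod
    def is_y(name: str) -> bool:
        return bool(_CHRY_RE.match(name))

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.is_autosome(n))

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeDescriptor":
        return cls(names=tuple(lengths), lengths=dict(lengths))


@dataclass
class ReadSet:
    """Sorted read start positions per chromosome, tagged with phase."""

    positions: dict[str, np.ndarray]
    phase: str | None = None

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"positions for {chrom} must be 1-D")
            if arr.size and np.any(np.diff(arr) < 0):
                raise ValueError(f"positions for {chrom} are not sorted")
            self.positions[chrom] = arr

    @property
    def n_reads(self) -> int:
        return sum(int(p.size) for p in self.positions.values())

    def chroms(self) -> list[str]:
        return list(self.positions)


def read_chrom_sizes(path: str | Path) -> GenomeDescriptor:
    """Parse a two-column ``chrom.sizes`` file."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            name, size = parts[0], int(parts[1])
            names.append(name)
            lengths[name] = size
    return GenomeDescriptor(names=tuple(names), lengths=lengths)


def write_chrom_sizes(genome: GenomeDescriptor, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome.names:
            fh.write(f"{name}\t{genome.lengths[name]}\n")


def _validate_record(
    chrom: str,
    start: int,
    end: int,
    genome: GenomeDescriptor | None,
    lineno: int,
    path: str,
    on_unknown: str,
) -> bool:
    """Return True if the record should be kept, False if skipped."""
    if start >= end:
        raise ValueError(f"{path}:{lineno}: empty interval [{start}, {end})")
    if start < 0:
        raise ValueError(f"{path}:{lineno}: negative start {start}")
    if genome is not None:
        if chrom not in genome:
            if on_unknown == "skip":
                logger.warning("%s:%d: skipping unknown chromosome %r", path, lineno, chrom)
                return False
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if end > genome.length(chrom):
            raise ValueError(
                f"{path}:{lineno}: end {end} beyond chromosome {chrom} "
                f"length {genome.length(chrom)}"
            )
    return True


def read_bed(
    path: str | Path,
    genome: GenomeDescriptor | None = None,
    on_unknown: str = "error",
) -> pd.DataFrame:
    """Read a BED3+ file into a sorted interval table.

    Columns beyond the third are kept as ``name`` (4th) when present.
    Coordinates are validated against ``genome`` when given; records on
    unknown chromosomes are skipped or rejected per ``on_unknown``.
    """
    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    n_skipped = 0
    has_name = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if not _validate_record(chrom, start, end, genome, lineno, str(path), on_unknown):
                n_skipped += 1
                continue
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            if len(parts) > 3:
                has_name = True
                names.append(parts[3])
            else:
                names.append("")
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    if has_name:
        df["name"] = names
    df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    logger.info("read %d records from %s (%d skipped)", len(df), path, n_skipped)
    df.attrs["n_skipped"] = n_skipped
    return df


def read_reads_bed(
    path: str | Path,
    genome: GenomeDescriptor | None = None,
    phase: str | None = None,
    on_unknown: str = "error",
) -> ReadSet:
    """Read aligned read start positions from BED3 into a :class:`ReadSet`."""
    df = read_bed(path, genome=genome, on_unknown=on_unknown)
    positions = {
        chrom: np.sort(sub["start"].to_numpy(dtype=np.int64))
        for chrom, sub in df.groupby("chrom", sort=True)
    }
    return ReadSet(positions=positions, phase=phase)


def write_reads_bed(reads: ReadSet, path: str | Path) -> None:
    """Write read start positions as BED3 (each read spans 1 bp)."""
    with open(path, "w") as fh:
        for chrom in reads.positions:
            for pos in reads.positions[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


# --- cenSat family parsing -------------------------------------------------

#: canonical family labels, checked in order (longer prefixes first so
#: e.g. "dhor" is not swallowed by "hor")
DEFAULT_FAMILY_PREFIXES: tuple[tuple[str, str], ...] = (
    ("dhor", "dhor"),
    ("hor", "hor"),
    ("mon", "mon"),
    ("hsat1", "hsat1"),
    ("hsat2", "hsat2"),
    ("hsat3", "hsat3"),
    ("bsat", "bsat"),
    ("gsat", "gsat"),
    ("rdna", "rDNA"),
    ("ct", "ct"),
    ("censat", "censat_other"),
)


def parse_censat_name(
    raw_name: str,
    prefixes: Sequence[tuple[str, str]] = DEFAULT_FAMILY_PREFIXES,
) -> str:
    """Map a cenSat annotation name to a canonical satellite family label.

    Matching is by case-insensitive prefix against a configurable table;
    unrecognized names fall back to ``censat_other`` with a warning.
    """
    if not raw_name:
        raise ValueError("empty annotation name")
    lowered = raw_name.lower()
    for prefix, family in prefixes:
        if lowered.startswith(prefix):
            return family
    logger.warning("unrecognized cenSat name %r -> censat_other", raw_name)
    return "censat_other"


def read_censat_bed(
    path: str | Path,
    genome: GenomeDescriptor | None = None,
    on_unknown: str = "error",
    prefixes: Sequence[tuple[str, str]] = DEFAULT_FAMILY_PREFIXES,
) -> pd.DataFrame:
    """Read a cenSat-dialect BED and attach the canonical ``family`` column."""
    df = read_bed(path, genome=genome, on_unknown=on_unknown)
    if "name" not in df.columns:
        raise ValueError(f"{path}: cenSat BED requires a name column")
    df["family"] = [parse_censat_name(n, prefixes) for n in df["name"]]
    return df


# --- bedGraph --------------------------------------------------------------

def write_bedgraph(df: pd.DataFrame, path: str | Path, value_col: str = "value") -> None:
    """Write a sorted, non-overlapping interval/value table as bedGraph.

    Values use fixed 6-decimal formatting so round trips are stable.
    """
    required = {"chrom", "start", "end", value_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        if np.any(ends[order][:-1] > starts[order][1:]):
            raise ValueError(f"overlapping bins on {chrom}")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            value = getattr(row, value_col)
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{value:.6f}\n")


def read_bedgraph(path: str | Path, value_col: str = "value") -> pd.DataFrame:
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chroms.append(parts[0])
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
            values.append(float(parts[3]))
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, value_col: values}
    )


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/abutting intervals per chromosome (bedtools-merge style)."""
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def points_in_intervals(
    chroms: Iterable[str], positions: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: is each (chrom, position) point inside the interval set?

    Intervals are merged first, so overlap in the input is harmless.
    """
    merged = merge_intervals(intervals)
    by_chrom = {c: sub for c, sub in merged.groupby("chrom", sort=False)}
    chrom_arr = np.asarray(list(chroms))
    positions = np.asarray(positions)
    mask = np.zeros(positions.shape[0], dtype=bool)
    for chrom in np.unique(chrom_arr):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        sel = chrom_arr == chrom
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, positions[sel], side="right") - 1
        ok = idx >= 0
        inside = np.zeros(sel.sum(), dtype=bool)
        inside[ok] = positions[sel][ok] < ends[idx[ok]]
        mask[sel] = inside
    return mask
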