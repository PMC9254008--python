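"""Readers and writers for the plain-text formats the package touches.

BED intervals and all tabular data are 0-based, half-open at every
interface; explicit converters are provided for 1-based coordinates as they
appear in printed tables.  TSV outputs carry ``#``-prefixed metadata lines
(parameters, seed, version) ahead of the header for provenance; readers
skip them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "read_table",
    "write_table",
    "read_reads_table",
    "load_config",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "to_one_based",
    "to_zero_based",
]

BED_COLUMNS = ("chrom", "start", "end", "name", "score")
READS_COLUMNS = ("reference", "pos5", "strand", "length", "count")


class BedParseError(ValueError):
    """A BED line failed validation; the message carries the line number."""


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a frame with chrom/start/end (+name/score).

    Comment (``#``), ``track`` and ``browser`` lines are skipped.  Raises
    :class:`BedParseError` with the offending line number on non-integer
    coordinates or empty/inverted intervals.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"line {lineno}: invalid interval [{start},{end}) "
                    "(need 0 <= start < end)"
                )
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "."
            rows.append((parts[0], start, end, name, score))
    return pd.DataFrame(rows, columns=list(BED_COLUMNS))


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write a BED frame; missing name/score columns are filled with '.'."""
    df = intervals.copy()
    for col, default in (("name", "."), ("score", ".")):
        if col not in df.columns:
            df[col] = default
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.name}\t{row.score}\n"
            )


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Minimal set of disjoint intervals covering the union, per chromosome."""
    if len(intervals) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def write_table(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    """Write a TSV with optional ``# key: value`` provenance lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (``#`` lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_reads_table(path: str | Path) -> pd.DataFrame:
    """Read a small-RNA 5'-position table and validate its columns.

    Expected columns: reference, pos5 (0-based; for minus-strand reads the
    rightmost reference base of the read), strand (+/-), length (nt), count.
    """
    df = read_table(path)
    missing = set(READS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reads table missing columns: {sorted(missing)}")
    return df[list(READS_COLUMNS)]


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def _truth_path(out_path: str | Path) -> Path:
    return Path(str(out_path) + ".truth.json")


def write_truth_sidecar(out_path: str | Path, truth: Mapping[str, object]) -> Path:
    """Write the ground-truth sidecar for a synthetic dataset."""
    path = _truth_path(out_path)
    with open(path, "w") as fh:
        json.dump(dict(truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_truth_sidecar(out_path: str | Path) -> dict:
    """Read the ground-truth sidecar written next to a synthetic dataset."""
    with open(_truth_path(out_path)) as fh:
        return json.load(fh)


def to_one_based(pos: int) -> int:
    """0-based position -> 1-based position (as printed in tables)."""
    return int(pos) + 1


def to_zero_based(pos: int) -> int:
    """1-based printed position -> 0-based internal position."""
    pos = int(pos)
    if pos < 1:
        raise ValueError("1-based positions start at 1")
    return pos - 1
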