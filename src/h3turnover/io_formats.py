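"""Readers and writers for the interval and signal formats the pipeline touches.

BED and bedGraph are read with 0-based half-open coordinates preserved
exactly as stored; malformed lines raise :class:`FormatError` carrying the
offending line number. Input may be tab- or space-delimited; all output is
tab-delimited.
"""
from __future__ import annotations

import os
from typing import List, Optional, Sequence, Union

import pandas as pd

from .core import Gene, Interval, Track


class FormatError(ValueError):
    """A malformed line in a BED/bedGraph file (1-based line number attached)."""

    def __init__(self, path, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split()


def read_intervals(path, as_genes: bool = True) -> Union[List[Gene], List[Interval]]:
    """Read a BED file into :class:`Gene` records (or plain intervals).

    Requires >= 3 columns; name/score/strand are honoured when present.
    Strand defaults to "+" when the file has no strand column. Input order
    is preserved.
    """
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(path, lineno, f"expected >=3 BED columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(path, lineno, f"non-integer coordinates {fields[1]!r}/{fields[2]!r}")
        if start >= end:
            raise FormatError(path, lineno, f"start ({start}) must be < end ({end})")
        name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
        strand = fields[5] if len(fields) > 5 else "+"
        if strand not in ("+", "-"):
            raise FormatError(path, lineno, f"unknown strand symbol {strand!r}")
        if as_genes:
            out.append(Gene(id=name, chrom=chrom, start=start, end=end, strand=strand))
        else:
            out.append(Interval(chrom=chrom, start=start, end=end, id=name))
    return out


def write_intervals(features: Sequence[Union[Gene, Interval]], path) -> None:
    """Write genes/intervals as 6-column (genes) or 4-column (intervals) BED."""
    with open(path, "w") as fh:
        for f in features:
            if isinstance(f, Gene):
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")
            else:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\n")


def read_signal(path, channel: str = "", **track_meta) -> Track:
    """Read a bedGraph file into a :class:`Track` labelled ``channel``.

    Track/browser/comment header lines are skipped; an empty file yields an
    empty track. A write/read round-trip preserves values to the printed
    precision (6 decimals).
    """
    chroms, starts, ends, values = [], [], [], []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise FormatError(path, lineno, f"expected 4 bedGraph columns, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(path, lineno, f"non-integer coordinates {fields[1]!r}/{fields[2]!r}")
        if start >= end:
            raise FormatError(path, lineno, f"start ({start}) must be < end ({end})")
        try:
            value = float(fields[3])
        except ValueError:
            raise FormatError(path, lineno, f"non-numeric value column {fields[3]!r}")
        chroms.append(fields[0])
        starts.append(start)
        ends.append(end)
        values.append(value)
    frame = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "value": values})
    if frame.empty:
        frame = pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=int),
                              "end": pd.Series(dtype=int), "value": pd.Series(dtype=float)})
    return Track(frame, label=channel, **track_meta)


def write_signal(track: Track, path, precision: int = 6) -> None:
    """Write a track as bedGraph with ``precision`` decimals."""
    with open(path, "w") as fh:
        for row in track.data.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.{precision}f}\n")


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a result table as tab-delimited text with a header row."""
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_covariate(path, id_column: Optional[str] = None,
                   value_column: Optional[str] = None) -> pd.Series:
    """Read a per-gene covariate (e.g. expression log2 fold change) table.

    Accepts any tab-delimited table; by default the first column is the
    gene id and the second the value. Returns a Series indexed by gene id.
    """
    frame = read_table(path)
    idc = id_column or frame.columns[0]
    vc = value_column or frame.columns[1]
    return frame.set_index(idc)[vc].astype(float)
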