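"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open throughout; conversion to 1-based
happens only in display code. Probe assignment everywhere uses the
integer-floor midpoint of the probe interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

TRACK_COLUMNS = ["chrom", "start", "end", "value"]


@dataclass(frozen=True)
class Gene:
    """A stranded coding-region interval.

    ``start``/``end`` are 0-based half-open genomic coordinates. The ATG
    (translation start, used as the metagene anchor and the reference for
    upstream distances) sits at ``start`` for + genes and at ``end - 1``
    for - genes.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    transcription_level: Optional[str] = None
    expression_log2fc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.id!r}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def atg(self) -> int:
        """Coordinate of the translation start (strand-aware anchor)."""
        return self.start if self.strand == "+" else self.end - 1

    def body_offset(self, midpoint: int) -> int:
        """Strand-aware distance from the 5' end for a position inside the CDS."""
        if self.strand == "+":
            return midpoint - self.start
        return (self.end - 1) - midpoint

    def upstream_distance(self, midpoint: int) -> int:
        """Strand-aware distance upstream of the ATG (positive when upstream)."""
        if self.strand == "+":
            return self.start - midpoint
        return midpoint - (self.end - 1)


@dataclass(frozen=True)
class Interval:
    """An unstranded genomic interval (ARS annotations, probes)."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval {self.id!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ProbeMeasurement:
    """A probe interval carrying one channel's signal value."""

    chrom: str
    start: int
    end: int
    value: float
    channel: str = ""

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class Track:
    """Probe-level signal for one channel: a sorted table of intervals + values.

    ``data`` has columns chrom, start, end, value. ``label`` names the
    channel (e.g. "turnover", "k36me3", "pol2"); ``genotype`` and
    ``replicate`` carry sample identity where relevant.
    """

    data: pd.DataFrame
    label: str = ""
    genotype: Optional[str] = None
    replicate: Optional[object] = None

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track is missing columns {missing}")
        self.data = (
            self.data.loc[:, TRACK_COLUMNS]
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.data["start"].to_numpy() + self.data["end"].to_numpy()) // 2)

    def with_values(self, values: np.ndarray, **meta) -> "Track":
        out = self.data.copy()
        out["value"] = np.asarray(values, dtype=float)
        kwargs = {"label": self.label, "genotype": self.genotype, "replicate": self.replicate}
        kwargs.update(meta)
        return Track(out, **kwargs)

    def same_probes(self, other: "Track") -> bool:
        a = self.data[["chrom", "start", "end"]]
        b = other.data[["chrom", "start", "end"]]
        return len(a) == len(b) and bool((a.values == b.values).all())

    def first_probe_mismatch(self, other: "Track") -> Optional[tuple]:
        """First (chrom, start, end) pair where the probe grids disagree."""
        a = self.data[["chrom", "start", "end"]].itertuples(index=False)
        b = other.data[["chrom", "start", "end"]].itertuples(index=False)
        for pa, pb in zip(a, b):
            if tuple(pa) != tuple(pb):
                return tuple(pa), tuple(pb)
        if len(self.data) != len(other.data):
            longer = self if len(self.data) > len(other.data) else other
            row = longer.data.iloc[min(len(self.data), len(other.data))]
            extra = (row["chrom"], int(row["start"]), int(row["end"]))
            return (extra, None) if longer is self else (None, extra)
        return None

    def probes(self, channel: Optional[str] = None) -> Iterator[ProbeMeasurement]:
        ch = self.label if channel is None else channel
        for row in self.data.itertuples(index=False):
            yield ProbeMeasurement(row.chrom, int(row.start), int(row.end), float(row.value), ch)


def track_from_arrays(chrom, start, end, value, **meta) -> Track:
    return Track(
        pd.DataFrame({"chrom": chrom, "start": start, "end": end, "value": value}),
        **meta,
    )


def genes_to_frame(genes: Sequence[Gene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [g.id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "length": [g.length for g in genes],
        }
    )


def check_no_overlap(genes: Sequence[Gene]) -> None:
    """Raise if any two genes on the same chromosome overlap."""
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping genes on {chrom}: {a.id!r} [{a.start},{a.end}) "
                    f"and {b.id!r} [{b.start},{b.end})"
                )
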