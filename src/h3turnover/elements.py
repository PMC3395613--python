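"""Partition probes into genomic element classes and summarize signal per class.

Classes: the first/last 500 bp of coding regions (5'/3' CDS) with mid-CDS
for the remainder; TSS for probes up to 500 bp upstream of the ATG;
Promoter for all remaining upstream probes; ARS for probes within 200 bp
of a replication origin; Null for everything else (predominantly probes
between convergently transcribed genes). Every probe maps to exactly one
class. Precedence when several definitions apply: CDS > TSS > Promoter >
ARS > Null; inside a CDS shorter than twice the end window the nearer end
wins (exact center goes 5'); a probe upstream of two divergent genes is
assigned to the nearer ATG.
"""
from __future__ import annotations

from enum import Enum
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Gene, Interval, Track, check_no_overlap


class ElementClass(Enum):
    FIVE_PRIME_CDS = "5'CDS"
    MID_CDS = "midCDS"
    THREE_PRIME_CDS = "3'CDS"
    TSS = "TSS"
    PROMOTER = "Promoter"
    ARS = "ARS"
    NULL = "Null"


CLASS_ORDER = [
    ElementClass.FIVE_PRIME_CDS,
    ElementClass.MID_CDS,
    ElementClass.THREE_PRIME_CDS,
    ElementClass.TSS,
    ElementClass.PROMOTER,
    ElementClass.ARS,
    ElementClass.NULL,
]


def _classify_in_gene(gene: Gene, midpoint: int, end_window: int) -> ElementClass:
    d5 = gene.body_offset(midpoint)
    d3 = (gene.length - 1) - d5
    if gene.length < 2 * end_window:
        return ElementClass.FIVE_PRIME_CDS if d5 <= d3 else ElementClass.THREE_PRIME_CDS
    if d5 < end_window:
        return ElementClass.FIVE_PRIME_CDS
    if d3 < end_window:
        return ElementClass.THREE_PRIME_CDS
    return ElementClass.MID_CDS


def classify_probes(
    probes: Sequence[Interval],
    genes: Sequence[Gene],
    ars_intervals: Sequence[Interval] = (),
    end_window: int = 500,
    tss_window: int = 500,
    ars_window: int = 200,
) -> List[ElementClass]:
    """Assign each probe (by its midpoint) to exactly one element class.

    Returns one class per probe, aligned with the input order. Distances
    are strand-aware: upstream of a - strand gene lies genomically
    rightward of it. Overlapping genes are an error.
    """
    check_no_overlap(genes)
    by_chrom: Dict[str, List[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: g.start)
        index[chrom] = (np.array([g.start for g in gs]), np.array([g.end for g in gs]), gs)
    ars_by_chrom: Dict[str, List[Interval]] = {}
    for a in ars_intervals:
        ars_by_chrom.setdefault(a.chrom, []).append(a)

    out: List[ElementClass] = []
    for p in probes:
        m = p.midpoint
        cls = ElementClass.NULL
        entry = index.get(p.chrom)
        left = right = None
        if entry is not None:
            starts, ends, gs = entry
            i = int(np.searchsorted(starts, m, side="right")) - 1
            if i >= 0 and m < ends[i]:
                out.append(_classify_in_gene(gs[i], m, end_window))
                continue
            left = gs[i] if i >= 0 else None
            right = gs[i + 1] if i + 1 < len(gs) else None
        # upstream assignment: nearer ATG among flanking genes facing away
        candidates = []
        if left is not None and left.strand == "-":
            candidates.append(left.upstream_distance(m))
        if right is not None and right.strand == "+":
            candidates.append(right.upstream_distance(m))
        candidates = [u for u in candidates if u > 0]
        if candidates:
            u = min(candidates)
            cls = ElementClass.TSS if u <= tss_window else ElementClass.PROMOTER
        else:
            for a in ars_by_chrom.get(p.chrom, ()):
                dist = max(a.start - m, m - (a.end - 1), 0)
                if dist <= ars_window:
                    cls = ElementClass.ARS
                    break
        out.append(cls)
    return out


def class_summary(
    classes: Sequence[ElementClass], track: Track,
    probes: Optional[Sequence[Interval]] = None,
) -> pd.DataFrame:
    """Per-class probe count, mean and SD of a track's values.

    ``classes`` must align with the probes the caller classified. Passing
    those ``probes`` makes the pairing explicit (values are looked up by
    interval, so probe order need not match the track's internal sort);
    without them, ``classes`` must align with the track's sorted rows.
    """
    if probes is not None:
        if len(classes) != len(probes):
            raise ValueError(
                f"{len(classes)} classes for {len(probes)} probes; inputs must align"
            )
        key = pd.DataFrame(
            {
                "chrom": [p.chrom for p in probes],
                "start": [p.start for p in probes],
                "end": [p.end for p in probes],
                "label": [c.value for c in classes],
            }
        )
        merged = key.merge(track.data, on=["chrom", "start", "end"], how="left")
        if merged["value"].isna().any():
            missing = merged[merged["value"].isna()].iloc[0]
            raise ValueError(
                f"track has no value for probe {missing['chrom']}:"
                f"{missing['start']}-{missing['end']}"
            )
        values = merged["value"].to_numpy()
        labels = merged["label"].to_numpy()
    else:
        if len(classes) != len(track.data):
            raise ValueError(
                f"{len(classes)} classes for {len(track.data)} probes; inputs must align"
            )
        values = track.values
        labels = np.array([c.value for c in classes])
    rows = []
    for cls in CLASS_ORDER:
        sel = labels == cls.value
        n = int(sel.sum())
        rows.append(
            {
                "element_class": cls.value,
                "n_probes": n,
                "mean": float(np.mean(values[sel])) if n else np.nan,
                "sd": float(np.std(values[sel], ddof=1)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
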