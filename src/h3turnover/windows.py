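"""Gene-end statistics versus gene length: sliding-window analyses.

Genes are ordered by length (ties broken by gene id) and a k-gene running
window of an end statistic — the mean signal over the terminal 500 bp of
the coding region — is traced per genotype. The crossover estimator reads
off the gene length at which the mutant and wild-type 3'-end series start
to diverge. Stratified variants repeat the scan within transcription
tertiles, and a generic k-gene moving average supports smoothing any
per-gene value against any covariate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Gene, Track
from .metagene import _TrackIndex

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass
class WindowSeries:
    """k-gene sliding-window means ordered by gene length.

    ``frame`` holds one row per window: ``median_length`` plus one value
    column per statistic; for N genes there are N - k + 1 windows.
    """

    frame: pd.DataFrame
    k: int

    @property
    def n_windows(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> "WindowSeries":
        return WindowSeries(self.frame[["median_length", name]].rename(columns={name: "mean"}), self.k)


def end_average(track: Track, gene: Gene, end: str, window_bp: int = 500) -> Optional[float]:
    """Mean signal over the terminal ``window_bp`` of the coding region.

    Strand-aware; genes shorter than the window use the whole CDS. Returns
    None when no probe midpoint falls in the window (the gene is then
    excluded downstream, never counted as zero).
    """
    if end not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"end must be {FIVE_PRIME!r} or {THREE_PRIME!r}, got {end!r}")
    index = track if isinstance(track, _TrackIndex) else _TrackIndex(track)
    mids, values = index.window(gene.chrom, gene.start, gene.end)
    if len(mids) == 0:
        return None
    offset = mids - gene.start if gene.strand == "+" else (gene.end - 1) - mids
    w = min(window_bp, gene.length)
    sel = offset < w if end == FIVE_PRIME else offset >= gene.length - w
    if not sel.any():
        return None
    return float(values[sel].mean())


def end_table(track: Track, genes: Sequence[Gene], end: str, window_bp: int = 500) -> pd.DataFrame:
    """Per-gene end statistics: columns id, length, value (absent genes dropped)."""
    index = _TrackIndex(track)
    rows = []
    for g in genes:
        v = end_average(index, g, end, window_bp)
        if v is not None:
            rows.append((g.id, g.length, v))
    return pd.DataFrame(rows, columns=["id", "length", "value"])


def _ordered_merge(stats_by_genotype: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    genotypes = list(stats_by_genotype)
    merged = None
    for g in genotypes:
        t = stats_by_genotype[g][["id", "length", "value"]].rename(columns={"value": f"value_{g}"})
        merged = t if merged is None else merged.merge(t.drop(columns="length"), on="id", how="inner")
    return merged.sort_values(["length", "id"], kind="stable").reset_index(drop=True)


def window_scan(stats_by_genotype: Mapping[str, pd.DataFrame], k: int = 80) -> WindowSeries:
    """Sliding (step 1) k-gene window means of an end statistic per genotype.

    Genes missing a statistic in any genotype are removed before ordering;
    ties in length break by gene id. Each window row reports the median
    gene length in the window and the per-genotype mean.
    """
    merged = _ordered_merge(stats_by_genotype)
    n = len(merged)
    if n < k:
        raise ValueError(f"only {n} genes with statistics but k={k}; use a smaller window")
    out = pd.DataFrame(
        {"median_length": merged["length"].rolling(k).median().to_numpy()[k - 1:]}
    )
    for g in stats_by_genotype:
        out[f"mean_{g}"] = merged[f"value_{g}"].rolling(k).mean().to_numpy()[k - 1:]
    return WindowSeries(out.reset_index(drop=True), k)


def default_delta_threshold(delta: np.ndarray) -> tuple:
    """(baseline, threshold) for the divergence test, from the shortest
    quartile of windows where no divergence is expected.

    The baseline is the mean between-genotype difference there — per-track
    median normalization can leave a constant genotype offset that must
    not count as divergence — and the threshold is 2 x the window SD
    around it.
    """
    n_short = max(2, math.ceil(len(delta) / 4))
    short = delta[:n_short]
    return float(np.mean(short)), 2.0 * float(np.std(short, ddof=1))


def estimate_crossover(
    series_wt: WindowSeries,
    series_mut: WindowSeries,
    delta_threshold: Optional[float] = None,
    m_consecutive: int = 5,
) -> Optional[float]:
    """Gene length at which the mutant 3'-end series departs from wild type.

    Returns the median gene length of the first window whose
    (mutant - wild type) difference exceeds ``delta_threshold`` for
    ``m_consecutive`` consecutive windows; None if it never does. Both
    series must come from the same gene ordering (identical window grids).

    When ``delta_threshold`` is None the default rule applies: the
    difference is measured relative to its shortest-quartile baseline and
    must exceed twice the baseline window SD. Because adjacent windows
    share k-1 genes, their noise is strongly correlated and short
    threshold excursions come in runs; for a detector that stays quiet on
    null data, ``m_consecutive`` should cover a full window's worth of
    genes (m = k), which the pipeline uses by default.
    """
    a, b = series_wt.frame, series_mut.frame
    if series_wt.k != series_mut.k or len(a) != len(b) or not np.allclose(
        a["median_length"], b["median_length"]
    ):
        raise ValueError("mismatched window grids; both series must share one gene ordering")
    delta = b["mean"].to_numpy() - a["mean"].to_numpy()
    if delta_threshold is None:
        baseline, delta_threshold = default_delta_threshold(delta)
        delta = delta - baseline
    exceed = delta > delta_threshold
    run = 0
    for i, e in enumerate(exceed):
        run = run + 1 if e else 0
        if run >= m_consecutive:
            first = i - m_consecutive + 1
            return float(a["median_length"].iloc[first])
    return None


def assign_tertiles(covariate: pd.Series) -> pd.Series:
    """Split genes into low/middle/high tertiles of a covariate.

    Ordering ties break by gene id, so assignment is deterministic even
    when all values are equal. Group sizes differ by at most one, larger
    groups first (9 genes -> 3/3/3).
    """
    order = covariate.reset_index()
    order.columns = ["id", "value"]
    order = order.sort_values(["value", "id"], kind="stable")
    parts = np.array_split(order["id"].to_numpy(), 3)
    labels = {}
    for name, ids in zip(("low", "middle", "high"), parts):
        for i in ids:
            labels[i] = name
    return pd.Series(labels, name="tertile")


def stratified_scan(
    stats_wt: pd.DataFrame,
    stats_mut: pd.DataFrame,
    covariate: pd.Series,
    k: int = 80,
) -> Dict[str, WindowSeries]:
    """Per-tertile k-gene window series of the (mutant - wild type) end
    statistic, with tertiles taken from a wild-type per-gene covariate
    (typically mean Pol2 enrichment, a transcription proxy)."""
    tertiles = assign_tertiles(covariate)
    merged = _ordered_merge({"wt": stats_wt, "mut": stats_mut})
    merged["delta"] = merged["value_mut"] - merged["value_wt"]
    merged = merged[merged["id"].isin(tertiles.index)]
    merged["tertile"] = merged["id"].map(tertiles)
    out: Dict[str, WindowSeries] = {}
    for name in ("low", "middle", "high"):
        sub = merged[merged["tertile"] == name]
        if len(sub) < k:
            raise ValueError(
                f"tertile {name!r} has {len(sub)} genes but k={k}; use a smaller window"
            )
        frame = pd.DataFrame(
            {
                "median_length": sub["length"].rolling(k).median().to_numpy()[k - 1:],
                "delta": sub["delta"].rolling(k).mean().to_numpy()[k - 1:],
            }
        )
        out[name] = WindowSeries(frame.reset_index(drop=True), k)
    return out


def moving_average_vs(
    x: Sequence[float],
    y: Sequence[float],
    k: int,
    ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """k-gene running mean of ``y`` with genes ordered by ``x``.

    Returns N - k + 1 rows of (x, y) window means. Ties in ``x`` break by
    ``ids`` when given, otherwise by input order (stable).
    """
    frame = pd.DataFrame({"x": np.asarray(x, dtype=float), "y": np.asarray(y, dtype=float)})
    if ids is not None:
        frame["id"] = list(ids)
        frame = frame.sort_values(["x", "id"], kind="stable")
    else:
        frame = frame.sort_values("x", kind="stable")
    n = len(frame)
    if n < k:
        raise ValueError(f"{n} points but k={k}; use a smaller window")
    return pd.DataFrame(
        {
            "x": frame["x"].rolling(k).mean().to_numpy()[k - 1:],
            "y": frame["y"].rolling(k).mean().to_numpy()[k - 1:],
        }
    ).reset_index(drop=True)
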