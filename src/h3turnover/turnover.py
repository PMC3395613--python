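"""Turn raw Flag/total channel tracks into normalized, replicate-averaged
log2 turnover values."""
from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .core import Track


def log2_turnover(flag: Track, total: Track, scale: str) -> Track:
    """Per-probe log2(Flag-H3 / total-H3).

    ``scale`` is explicit, never guessed: "linear" computes
    log2(flag) - log2(total); "log2" assumes the channels are already
    log-scale and subtracts them directly.
    """
    if scale not in ("linear", "log2"):
        raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
    mismatch = flag.first_probe_mismatch(total)
    if mismatch is not None:
        raise ValueError(f"probe set mismatch between channels: {mismatch[0]} vs {mismatch[1]}")
    if scale == "linear":
        fv, tv = flag.values, total.values
        if (fv <= 0).any() or (tv <= 0).any():
            raise ValueError("nonpositive linear signal; cannot take log2")
        values = np.log2(fv) - np.log2(tv)
    else:
        values = flag.values - total.values
    return flag.with_values(values, label="turnover")


def normalize_track(track: Track) -> Track:
    """Median-center a log2 track so its median is exactly 0.

    This is the package's location normalization for array log ratios:
    the minimal correction that removes per-sample scale offsets.
    Idempotent.
    """
    values = track.values
    if len(values) == 0:
        return track.with_values(values)
    return track.with_values(values - np.median(values))


def average_replicates(tracks: Sequence[Track]) -> Track:
    """Arithmetic per-probe mean of replicate tracks on the log2 scale."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    genotypes = {t.genotype for t in tracks}
    if len(genotypes) > 1:
        raise ValueError(f"cannot average across genotypes: {sorted(map(str, genotypes))}")
    for t in tracks[1:]:
        mismatch = first.first_probe_mismatch(t)
        if mismatch is not None:
            raise ValueError(f"probe set mismatch between replicates: {mismatch[0]} vs {mismatch[1]}")
    values = np.mean([t.values for t in tracks], axis=0)
    return first.with_values(values, replicate="averaged")
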