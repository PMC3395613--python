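"""Shared helpers for building toy tracks in tests."""
import numpy as np

from h3turnover import track_from_arrays


def make_track(probes, values, **meta):
    return track_from_arrays(
        [p.chrom for p in probes],
        [p.start for p in probes],
        [p.end for p in probes],
        np.asarray(values, dtype=float),
        **meta,
    )
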