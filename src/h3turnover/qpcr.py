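"""Ct-based ChIP enrichment arithmetic.

Enrichment of immunoprecipitated over input material from qPCR threshold
cycles, assuming perfect per-cycle doubling (efficiency 2, exposed as a
parameter): IP/Input = 2^(InputCt - IPCt). A turnover ratio divides the
enrichment of a tagged-H3 channel by that of a total-H3 channel; the same
arithmetic serves any two-epitope replacement ratio (e.g. T7/HA tag
swaps).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

CHANNELS = ("flag", "total_h3", "t7", "ha")


@dataclass(frozen=True)
class QpcrMeasurement:
    """One amplicon's input and IP threshold cycles for one channel."""

    amplicon: str
    input_ct: float
    ip_ct: float
    channel: str = "flag"

    def __post_init__(self):
        for name, ct in (("input_ct", self.input_ct), ("ip_ct", self.ip_ct)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{self.amplicon!r}: {name} must be finite and positive, got {ct}")


def ip_over_input(m: QpcrMeasurement, efficiency: float = 2.0) -> float:
    """IP/Input fraction: efficiency^(input_ct - ip_ct)."""
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    return efficiency ** (m.input_ct - m.ip_ct)


def turnover_ratio(
    numerator: QpcrMeasurement, denominator: QpcrMeasurement, efficiency: float = 2.0
) -> float:
    """Ratio of two IP/Input enrichments (e.g. Flag-H3 over total H3)."""
    return ip_over_input(numerator, efficiency) / ip_over_input(denominator, efficiency)


def plate_results(plate: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Per-row IP/Input for a plate table (amplicon, channel, input_ct, ip_ct)."""
    required = {"amplicon", "channel", "input_ct", "ip_ct"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table is missing columns {sorted(missing)}")
    out = plate.copy()
    out["ip_over_input"] = [
        ip_over_input(
            QpcrMeasurement(str(r.amplicon), float(r.input_ct), float(r.ip_ct), str(r.channel)),
            efficiency,
        )
        for r in plate.itertuples(index=False)
    ]
    return out


def plate_turnover_ratios(
    plate: pd.DataFrame,
    numerator_channel: str = "flag",
    denominator_channel: str = "total_h3",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-amplicon turnover ratio between two channels of a plate table."""
    results = plate_results(plate, efficiency)
    rows = []
    for amplicon, sub in results.groupby("amplicon", sort=False):
        num = sub[sub["channel"] == numerator_channel]
        den = sub[sub["channel"] == denominator_channel]
        if len(num) != 1 or len(den) != 1:
            raise ValueError(
                f"amplicon {amplicon!r} needs exactly one {numerator_channel!r} and one "
                f"{denominator_channel!r} row"
            )
        rows.append(
            {
                "amplicon": amplicon,
                "ratio": float(num["ip_over_input"].iloc[0] / den["ip_over_input"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)
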