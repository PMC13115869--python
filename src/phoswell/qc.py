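"""Viability (MTT) and cell-damage (LDH) quality control.

MTT viability is the background-corrected formazan absorbance (570 nm minus
655 nm reference) of a treatment, expressed as a percentage of the untreated
control mean.  Values above 100% are reported as-is — phosphate exposure can
stimulate formazan reduction — never capped.

LDH release is screened against the analyzer's detection limit (14 U/L).
Readings at or above the limit are conservatively flagged as a cytotoxicity
signal; censored "below-limit" readings are never imputed, only flagged
clean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "ViabilityRecord",
    "DamageRecord",
    "LDH_DETECTION_LIMIT_U_L",
    "LdhVerdict",
    "mtt_viability",
    "ldh_flag",
]

LDH_DETECTION_LIMIT_U_L = 14.0


@dataclass(frozen=True)
class ViabilityRecord:
    """One MTT well: absorbances at 570 nm and the 655 nm reference."""

    absorbance_570: float
    absorbance_655: float
    treatment: str
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.absorbance_570 < 0 or self.absorbance_655 < 0:
            raise ValueError("absorbances must be non-negative")

    @property
    def signal(self) -> float:
        return self.absorbance_570 - self.absorbance_655


@dataclass(frozen=True)
class DamageRecord:
    """One LDH reading in U/L; ``below_limit`` marks a censored measurement."""

    ldh_u_l: float | None = None
    below_limit: bool = False
    detection_limit_u_l: float = LDH_DETECTION_LIMIT_U_L

    def __post_init__(self) -> None:
        if self.ldh_u_l is None and not self.below_limit:
            raise ValueError("a numeric LDH value or a below-limit marker is required")
        if self.ldh_u_l is not None and self.ldh_u_l < 0:
            raise ValueError("LDH must be non-negative")


class LdhVerdict(str):
    pass


NO_CYTOTOXICITY = "no detectable cytotoxicity"
CYTOTOXICITY_SIGNAL = "cytotoxicity signal"


def mtt_viability(records: Iterable[ViabilityRecord]) -> pd.Series:
    """Percent viability per treatment relative to the untreated-control mean."""
    records = list(records)
    controls = [r for r in records if r.is_control]
    if not controls:
        raise ValueError("at least one untreated control record is required")
    control_mean = sum(r.signal for r in controls) / len(controls)
    if control_mean <= 0:
        raise ValueError(f"control signal must be positive, got mean {control_mean:g}")
    df = pd.DataFrame(
        {"treatment": [r.treatment for r in records if not r.is_control],
         "signal": [r.signal for r in records if not r.is_control]}
    )
    if df.empty:
        return pd.Series(dtype=float, name="viability_pct")
    out = df.groupby("treatment", sort=False)["signal"].mean() / control_mean * 100.0
    out.name = "viability_pct"
    return out


def ldh_flag(record: DamageRecord) -> str:
    """QC verdict for one LDH reading.

    Below the detection limit → clean; at or above it → flagged (the boundary
    reads as detectable, a deliberately conservative rule).  Censored
    below-limit markers are clean by definition.
    """
    if record.below_limit and record.ldh_u_l is None:
        return NO_CYTOTOXICITY
    assert record.ldh_u_l is not None
    if record.ldh_u_l < record.detection_limit_u_l:
        return NO_CYTOTOXICITY
    return CYTOTOXICITY_SIGNAL
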