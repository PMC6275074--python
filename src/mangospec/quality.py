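"""Derived fruit-quality quantities: titratable acidity, ripening index, damage class.

Titratable acidity converts an NaOH titration reading on a diluted juice
aliquot into mass-percent citric acid.  The ripening index

    RPI = ln(100 * firmness * TA / TSS)

summarises ripeness: firm, acid, low-sugar fruit scores high; soft, sweet,
low-acid (ripe — and, after an impact, more severely damaged) fruit scores
low.  Damage severity classes are thresholds on RPI: above 7.0 slight,
below 5.0 serious, the closed interval [5.0, 7.0] moderate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TitrationReading",
    "QualityRecord",
    "DamageThresholds",
    "titratable_acidity",
    "ripening_index",
    "damage_class",
    "records_to_frame",
    "CLASS_ORDER",
]

#: Severity labels in declared order (used for deterministic tie-breaking).
CLASS_ORDER = ("slight", "moderate", "serious")


@dataclass(frozen=True)
class TitrationReading:
    """One NaOH titration of a diluted juice aliquot.

    Defaults follow the standard protocol: 0.1 mol/L NaOH, citric-acid
    conversion factor K = 0.064 g/mmol, 10 g juice diluted to 250 mL with a
    50 mL aliquot titrated.
    """

    V: float                # NaOH volume consumed, mL
    C: float = 0.1          # NaOH concentration, mol/L
    K: float = 0.064        # grams of citric acid per mmol NaOH
    M: float = 10.0         # juice mass, g
    V0: float = 250.0       # total diluted volume, mL
    V1: float = 50.0        # titrated aliquot volume, mL

    def __post_init__(self):
        if self.V < 0:
            raise ValueError("NaOH volume must be non-negative")
        for name in ("C", "K", "M", "V0", "V1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.V1 > self.V0:
            raise ValueError("aliquot volume V1 cannot exceed total volume V0")


def titratable_acidity(reading: TitrationReading) -> float:
    """Mass-percent citric acid from a titration reading.

    TA% = C * V * K * (V0 / V1) / M * 100.  The aliquot contains V1/V0 of
    the total acid, so the measured amount is scaled back up by V0/V1.
    """
    r = reading
    return r.C * r.V * r.K * (r.V0 / r.V1) / r.M * 100.0


def ripening_index(firmness: float, ta: float, tss: float) -> float:
    """RPI = ln(100 * firmness * TA / TSS); all inputs must be positive."""
    arg = 100.0 * firmness * ta / tss if tss > 0 else -1.0
    if firmness <= 0 or ta <= 0 or tss <= 0 or arg <= 0:
        raise ValueError(
            f"RPI undefined for firmness={firmness}, ta={ta}, tss={tss}"
        )
    return math.log(arg)


@dataclass(frozen=True)
class DamageThresholds:
    """RPI cut points separating slight / moderate / serious damage."""

    slight_min: float = 7.0
    serious_max: float = 5.0

    def __post_init__(self):
        if self.serious_max >= self.slight_min:
            raise ValueError("serious_max must be below slight_min")


def damage_class(rpi: float, thresholds: DamageThresholds = DamageThresholds()) -> str:
    """Map an RPI value to its severity label.

    rpi > slight_min -> "slight"; rpi < serious_max -> "serious"; the closed
    interval in between -> "moderate".
    """
    if not np.isfinite(rpi):
        raise ValueError("RPI must be finite")
    if rpi > thresholds.slight_min:
        return "slight"
    if rpi < thresholds.serious_max:
        return "serious"
    return "moderate"


@dataclass
class QualityRecord:
    """Per-fruit quality measurements and derived indices.

    drop_height is in metres (0 marks the undamaged control group); firmness
    units (N or g) are carried as config metadata and never converted.
    """

    fruit_id: str
    drop_height: float
    day: int
    firmness: float
    tss: float
    ta: float
    chroma: float
    rpi: float | None = None
    damage: str | None = None

    def __post_init__(self):
        if self.firmness <= 0 or self.tss <= 0:
            raise ValueError(f"{self.fruit_id}: firmness and TSS must be positive")
        if self.ta < 0:
            raise ValueError(f"{self.fruit_id}: TA must be non-negative")
        if self.rpi is None and self.ta > 0:
            self.rpi = ripening_index(self.firmness, self.ta, self.tss)
        if self.damage is None:
            self.damage = (
                "control" if self.drop_height == 0 else damage_class(self.rpi)
            )


def records_to_frame(records: list[QualityRecord]) -> pd.DataFrame:
    """Tabulate quality records (one row per fruit)."""
    return pd.DataFrame([asdict(r) for r in records])
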