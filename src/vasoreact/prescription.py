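"""Isocapnic-hyperpnoea training dose prescription.

The starting dose is anchored to spirometry: tidal volume at 50% of
forced vital capacity (FVC) and a target minute ventilation (MV) of 60%
of maximal voluntary ventilation (MVV). The breath frequency follows as

    f_b = MV / (DUTY_CYCLE_FACTOR * 0.5 * FVC)

where the duty-cycle factor (1.3) corrects for the fraction of each
respiratory cycle spent moving air on the device. The workload then
rises ~15% per week, alternating which parameter (volume or frequency)
carries the increment, so the V_T * f_b product grows by exactly
1.15 per week regardless of the alternation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

from .errors import DomainError

__all__ = [
    "DUTY_CYCLE_FACTOR", "RmtPrescription", "initial_prescription",
    "progress", "schedule",
]

#: Correction for the effective duty cycle of device breathing; divides the
#: target minute ventilation when converting it to a breath frequency.
DUTY_CYCLE_FACTOR = 1.3


@dataclass(frozen=True)
class RmtPrescription:
    """One week's training dose."""

    week: int
    tidal_volume: float       # l
    breath_frequency: float   # breaths/min

    def __post_init__(self) -> None:
        if self.week < 1:
            raise DomainError("week index starts at 1")
        if self.tidal_volume <= 0 or self.breath_frequency <= 0:
            raise DomainError("volume and frequency must be positive")

    @property
    def minute_ventilation(self) -> float:
        """Air moved per minute, l/min: tidal_volume * breath_frequency."""
        return self.tidal_volume * self.breath_frequency

    @property
    def target_minute_ventilation(self) -> float:
        """Device MV setting including the duty-cycle factor (0.6*MVV at week 1)."""
        return DUTY_CYCLE_FACTOR * self.minute_ventilation


def initial_prescription(fvc: float, mvv: float) -> RmtPrescription:
    """Week-1 dose from spirometry: V_T = 0.5 FVC, MV = 0.6 MVV.

    Satisfies f_b * (1.3 * 0.5 * FVC) = 0.6 * MVV exactly.
    """
    if fvc <= 0 or mvv <= 0:
        raise DomainError("FVC and MVV must be positive")
    tidal = 0.5 * fvc
    mv_target = 0.6 * mvv
    freq = mv_target / (DUTY_CYCLE_FACTOR * tidal)
    return RmtPrescription(week=1, tidal_volume=tidal, breath_frequency=freq)


def progress(
    p: RmtPrescription, increment: float = 0.15, volume_first: bool = True
) -> RmtPrescription:
    """Advance one week, raising workload by ``increment``.

    The increment alternates between tidal volume and breath frequency;
    with ``volume_first`` the volume carries the week-2 step (even target
    weeks scale volume, odd weeks frequency). Either way the V_T * f_b
    product rises by (1 + increment) every week.
    """
    if increment <= -1:
        raise DomainError("increment must keep the workload positive")
    week = p.week + 1
    scale_volume = (week % 2 == 0) == volume_first
    if scale_volume:
        return replace(p, week=week, tidal_volume=p.tidal_volume * (1 + increment))
    return replace(p, week=week, breath_frequency=p.breath_frequency * (1 + increment))


def schedule(
    fvc: float,
    mvv: float,
    weeks: int = 8,
    increment: float = 0.15,
    volume_first: bool = True,
    adjustments: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Weekly training schedule as a DataFrame.

    ``adjustments`` optionally maps a week index to an extra multiplier
    on that week's incremented parameter (small per-subject adaptability
    corrections).
    """
    if weeks < 1:
        raise DomainError("need at least one week")
    adjustments = dict(adjustments or {})
    p = initial_prescription(fvc, mvv)
    rows = [p]
    for _ in range(weeks - 1):
        p = progress(p, increment, volume_first)
        extra = adjustments.get(p.week)
        if extra is not None:
            scale_volume = (p.week % 2 == 0) == volume_first
            if scale_volume:
                p = replace(p, tidal_volume=p.tidal_volume * extra)
            else:
                p = replace(p, breath_frequency=p.breath_frequency * extra)
        rows.append(p)
    return pd.DataFrame(
        {
            "week": [r.week for r in rows],
            "tidal_volume_l": [r.tidal_volume for r in rows],
            "breath_frequency_per_min": [r.breath_frequency for r in rows],
            "minute_ventilation_l_min": [r.minute_ventilation for r in rows],
            "target_minute_ventilation_l_min": [
                r.target_minute_ventilation for r in rows
            ],
        }
    )
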