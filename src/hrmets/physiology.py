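"""Physiological transforms: predicted HRmax, %HRR, Weir energy expenditure, METs.

All heart rates are in beats per minute (bpm), energies in kcal/min, heights in
cm. METs are dimensionless multiples of seated resting energy expenditure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "GasExchangeRecord",
    "METObservation",
    "predict_hrmax",
    "percent_hrr",
    "hr_from_percent_hrr",
    "weir_ee",
    "compute_mets",
    "resting_ee",
    "RestingEEInstabilityError",
]

# Abbreviated Weir equation (protein oxidation ignored), kcal/min per L/min.
WEIR_O2 = 3.941
WEIR_CO2 = 1.106


@dataclass(frozen=True)
class GasExchangeRecord:
    """One steady-state expired-gas summary.

    vo2, vco2 : oxygen uptake and carbon-dioxide output, L/min (STPD).
    condition : "rest_sitting" or "activity".
    duration  : measurement duration, min.
    """

    vo2: float
    vco2: float
    condition: str = "activity"
    duration: float = 5.0

    def __post_init__(self) -> None:
        if self.vo2 <= 0 or self.vco2 <= 0:
            raise ValueError("vo2 and vco2 must be positive")
        rer = self.vco2 / self.vo2
        if not (0.6 < rer < 1.3):
            raise ValueError(
                f"respiratory exchange ratio {rer:.3f} outside plausible (0.6, 1.3)"
            )


@dataclass(frozen=True)
class METObservation:
    """One subject-activity record: mean HR, %HRR, and measured METs."""

    subject_id: str
    activity_name: str
    mean_hr: float
    pct_hrr: float
    mets: float
    ee_activity: float | None = None

    def __post_init__(self) -> None:
        if self.mets <= 0:
            raise ValueError("mets must be positive")


def predict_hrmax(age: float) -> float:
    """Age-predicted maximal heart rate (Tanaka equation), bpm.

    HRmax = 208 - 0.7 * age.  Valid for adults; ages outside [18, 80] are
    rejected rather than extrapolated.
    """
    if not (18.0 <= age <= 80.0):
        raise ValueError(f"age {age} outside the validated adult range [18, 80]")
    return 208.0 - 0.7 * age


def percent_hrr(hr: float, resting_hr: float, hrmax: float) -> float:
    """Percent heart-rate reserve.

    %HRR = (HR - resting HR) / (HRmax - resting HR) * 100.  0% at seated rest,
    100% at maximal HR.  Not clamped: values slightly below 0 (HR under
    resting) or above 100 are legitimate and retained.
    """
    if hrmax <= resting_hr:
        raise ValueError("hrmax must exceed resting_hr")
    if hr <= 0:
        raise ValueError("hr must be positive")
    return (hr - resting_hr) / (hrmax - resting_hr) * 100.0


def hr_from_percent_hrr(pct_hrr: float, resting_hr: float, hrmax: float) -> float:
    """Invert %HRR back to an absolute heart rate, bpm."""
    if hrmax <= resting_hr:
        raise ValueError("hrmax must exceed resting_hr")
    return resting_hr + pct_hrr / 100.0 * (hrmax - resting_hr)


def weir_ee(gas: GasExchangeRecord) -> float:
    """Energy expenditure from gas exchange, kcal/min.

    Abbreviated Weir form: EE = 3.941 * VO2 + 1.106 * VCO2 (L/min inputs),
    ignoring the protein term.
    """
    return WEIR_O2 * gas.vo2 + WEIR_CO2 * gas.vco2


def compute_mets(ee_activity: float, ee_rest_sitting: float) -> float:
    """METs = activity EE / seated resting EE (both kcal/min)."""
    if ee_activity <= 0:
        raise ValueError("ee_activity must be positive")
    if ee_rest_sitting <= 0:
        raise ValueError("ee_rest_sitting must be positive")
    return ee_activity / ee_rest_sitting


class RestingEEInstabilityError(ValueError):
    """Raised when duplicate resting measurements disagree beyond tolerance."""


def resting_ee(replicates: Sequence[GasExchangeRecord], tolerance: float = 0.10) -> float:
    """Seated resting EE from duplicate 7-min measurements, kcal/min.

    The protocol measures resting metabolic rate at least twice and requires
    the replicates to be comparable.  Stability is accepted when the spread of
    replicate EEs relative to their mean is within ``tolerance`` (default 10%);
    otherwise :class:`RestingEEInstabilityError` is raised so the caller can
    supply a further replicate.
    """
    if len(replicates) < 2:
        raise ValueError("at least two seated resting replicates are required")
    ees = [weir_ee(g) for g in replicates]
    mean = sum(ees) / len(ees)
    spread = max(ees) - min(ees)
    if spread / mean > tolerance:
        raise RestingEEInstabilityError(
            f"resting EE replicates unstable: spread {spread:.3f} kcal/min is "
            f"{spread / mean:.1%} of the mean (tolerance {tolerance:.0%})"
        )
    return mean
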