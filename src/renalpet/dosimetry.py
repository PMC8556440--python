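"""Pediatric dosimetry extrapolation and the activity/time trade-off.

The adult effective-dose coefficient for the tracer is scaled to a
one-year-old with a conversion factor obtained as the mean adult-to-child
effective-dose ratio of six other fluorine-18 radiopharmaceuticals.  At
constant activity x time (constant expected counts), prolonging the
acquisition allows a proportional reduction of the administered activity;
the resulting pediatric PET dose and, with an optional low-dose CT, the
total effective dose complete the budget.

All intermediates are carried at full precision; rounding is applied only
at report time.  A rounded-intermediate evaluation (as the chain would be
computed from the printed, rounded values) is provided as well: both paths
agree at the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DoseModel",
    "conversion_factor",
    "pediatric_coefficient",
    "activity_reduction_factor",
    "reduced_activity",
    "dose_budget",
    "format_budget",
]

#: Adult-to-one-year-old effective-dose ratios for FDG, FDOPA,
#: fluorocholine, flutemetamol, FLT and FET.
DEFAULT_TRACER_RATIOS = (5.0, 4.0, 5.0, 4.5, 5.9, 5.1)


@dataclass(frozen=True)
class DoseModel:
    """All dosimetry constants of the budget calculation."""

    adult_coefficient: float = 0.022  # mSv/MBq
    tracer_ratios: tuple[float, ...] = DEFAULT_TRACER_RATIOS
    ct_dose: float = 0.1  # mSv, low-dose attenuation-correction CT
    reference_activity: float = 4.0  # MBq/kg at the reference protocol
    reference_duration: float = 60.0  # s per bed position, reference
    proposed_duration: float = 900.0  # s, proposed prolonged acquisition
    child_mass: float = 10.0  # kg
    n_bed_positions: int = 1  # single-bed assumption; >1 divides per-bed time

    def __post_init__(self):
        object.__setattr__(self, "tracer_ratios", tuple(self.tracer_ratios))
        if not self.tracer_ratios:
            raise ValueError("tracer_ratios must be nonempty")
        values = (
            self.adult_coefficient,
            self.reference_activity,
            self.reference_duration,
            self.proposed_duration,
            self.child_mass,
        ) + self.tracer_ratios
        if any(v <= 0 for v in values):
            raise ValueError("all dosimetry constants must be positive")
        if self.ct_dose < 0:
            raise ValueError("ct_dose must be >= 0")
        if self.n_bed_positions < 1:
            raise ValueError("n_bed_positions must be >= 1")


def conversion_factor(tracer_ratios=DEFAULT_TRACER_RATIOS) -> float:
    """Adult-to-one-year-old conversion factor: arithmetic mean of the ratios."""
    ratios = tuple(float(r) for r in tracer_ratios)
    if not ratios:
        raise ValueError("tracer_ratios must be nonempty")
    if any(r <= 0 for r in ratios):
        raise ValueError("tracer ratios must be positive")
    return sum(ratios) / len(ratios)


def pediatric_coefficient(adult_coefficient: float, factor: float) -> float:
    """Effective-dose coefficient for a one-year-old, mSv/MBq."""
    if adult_coefficient <= 0 or factor <= 0:
        raise ValueError("inputs must be positive")
    return adult_coefficient * factor


def activity_reduction_factor(
    reference_duration: float, proposed_duration: float
) -> float:
    """Allowed activity reduction at constant activity x time."""
    if reference_duration <= 0 or proposed_duration <= 0:
        raise ValueError("durations must be positive")
    return proposed_duration / reference_duration


def reduced_activity(reference_activity: float, factor: float) -> float:
    """Reduced administered activity, MBq/kg."""
    if reference_activity <= 0:
        raise ValueError("reference activity must be positive")
    if factor == 0:
        raise ValueError("reduction factor must be nonzero")
    return reference_activity / factor


def dose_budget(model: DoseModel, rounded_intermediates: bool = False) -> dict:
    """Complete pediatric dose budget.

    With ``rounded_intermediates=True`` the chain is evaluated from
    intermediates rounded to their reported precision (factor 1 dp,
    coefficient 2 dp, activity 2 dp), as a reader would recompute it from
    printed values.  Both variants agree at the reported precision.
    """
    factor = conversion_factor(model.tracer_ratios)
    coeff = pediatric_coefficient(model.adult_coefficient, factor)
    per_bed = model.proposed_duration / model.n_bed_positions
    reduction = activity_reduction_factor(model.reference_duration, per_bed)
    activity = reduced_activity(model.reference_activity, reduction)
    if rounded_intermediates:
        factor_used = round(factor, 1)
        coeff = round(pediatric_coefficient(model.adult_coefficient, factor_used), 2)
        activity = round(model.reference_activity / reduction, 2)
    injected = activity * model.child_mass
    pet_dose = injected * coeff
    return {
        "conversion_factor": factor,
        "pediatric_coefficient_msv_per_mbq": coeff,
        "activity_reduction_factor": reduction,
        "reduced_activity_mbq_per_kg": activity,
        "injected_activity_mbq": injected,
        "pet_dose_msv": pet_dose,
        "ct_dose_msv": model.ct_dose,
        "total_dose_msv": pet_dose + model.ct_dose,
        "total_dose_no_ct_msv": pet_dose,
        "rounded_intermediates": rounded_intermediates,
    }


def format_budget(budget: dict) -> str:
    """Human-readable budget at reported precision."""
    return "\n".join(
        [
            f"conversion factor (adult -> 1-year-old): {budget['conversion_factor']:.1f}",
            "pediatric dose coefficient: "
            f"{budget['pediatric_coefficient_msv_per_mbq']:.2f} mSv/MBq",
            f"activity reduction factor: {budget['activity_reduction_factor']:.0f}",
            "reduced administered activity: "
            f"{budget['reduced_activity_mbq_per_kg']:.2f} MBq/kg",
            f"injected activity: {budget['injected_activity_mbq']:.1f} MBq",
            f"PET effective dose: {budget['pet_dose_msv']:.1f} mSv",
            f"CT effective dose: {budget['ct_dose_msv']:.1f} mSv",
            f"total effective dose: {budget['total_dose_msv']:.1f} mSv",
            f"total without CT: {budget['total_dose_no_ct_msv']:.1f} mSv",
        ]
    )
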