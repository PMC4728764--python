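"""Exogenous inputs: continuous enteral nutrition and SQ insulin absorption.

Subcutaneous short-acting insulin enters the model through piecewise-linear
unit absorption shapes: an ultrashort analog (Lispro; onset 5 min, peak
30 min, duration of action 240 min) and regular insulin (onset 30 min, peak
120 min, duration 480 min).  Both shapes ride on a 0.25 residual baseline
and are identically zero outside their support.  A dose is delivered by
scaling the whole unit shape by ``dose * conversion / nominal_area`` so the
time-integral of the input equals exactly ``dose * conversion`` model
insulin units, and dose 0 is exactly the no-insulin baseline.

Continuous nutrition is a constant carbohydrate appearance rate G_in(t):
135 mg/min at goal (equivalent to 82.2 mL/h of a 1.2 kcal/mL enteral
formula), 67.5 at half goal, 0 with feeds held.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NutritionSchedule", "InsulinInjection", "AbsorptionProfile",
    "LISPRO_PROFILE", "REGULAR_PROFILE", "unit_profile",
    "lispro_unit_profile", "regular_unit_profile",
    "insulin_input", "nutrition_input",
    "GOAL_NUTRITION", "HALF_GOAL_NUTRITION", "NO_NUTRITION",
    "NUTRITION_PRESETS", "nutrition_equivalents",
    "DEFAULT_U_TO_MODEL_UNITS",
]

#: U -> model insulin units (mU) conversion for SQ boluses.  The model
#: carries a single insulin compartment, so the effective conversion is an
#: identified parameter, not the physical 1000 mU/U: 300 mU/U places the
#: fasting-Lispro hypoglycemia threshold of the borderline-clearance
#: patients at ~4 U and keeps a 6-U excursion comparable to the endogenous
#: insulin swing (docs/methods.md discusses the calibration).
DEFAULT_U_TO_MODEL_UNITS = 300.0

#: enteral formula bookkeeping: 1.2 kcal/mL, 82.2 mL/h delivers the goal
#: carbohydrate rate of 135 mg/min
_FORMULA_KCAL_PER_ML = 1.2
_FORMULA_ML_PER_H_AT_GOAL = 82.2
_GOAL_RATE_MG_PER_MIN = 135.0


@dataclass(frozen=True)
class NutritionSchedule:
    """A constant continuous-nutrition carbohydrate rate (mg/min)."""

    rate: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"nutrition rate must be >= 0, got {self.rate}")


GOAL_NUTRITION = NutritionSchedule(135.0, "goal")
HALF_GOAL_NUTRITION = NutritionSchedule(67.5, "half-goal")
NO_NUTRITION = NutritionSchedule(0.0, "none")
NUTRITION_PRESETS = {
    "goal": GOAL_NUTRITION,
    "half-goal": HALF_GOAL_NUTRITION,
    "none": NO_NUTRITION,
}


@dataclass(frozen=True)
class InsulinInjection:
    """One SQ insulin bolus: preparation, dose in U, injection time (min).

    By study protocol the injection is given at t = 0, the phase reference
    placed at a baseline glucose peak.
    """

    preparation: str
    dose: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.preparation not in ("lispro", "regular"):
            raise ValueError(f"unknown preparation {self.preparation!r}")
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0 U, got {self.dose}")


@dataclass(frozen=True)
class AbsorptionProfile:
    """A piecewise-linear unit absorption shape with compact support.

    ``nodes_t``/``nodes_v`` are the breakpoints and values; the shape is
    linear between breakpoints and identically zero outside
    ``[0, support_end]`` (the value drops from the residual 0.25 to 0 at
    the support end).  ``nominal_area`` is the exact piecewise integral of
    the unit shape.
    """

    name: str
    nodes_t: tuple[float, ...]
    nodes_v: tuple[float, ...]
    support_end: float = field(init=False)
    nominal_area: float = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.nodes_t)
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        object.__setattr__(self, "support_end", float(t[-1]))
        object.__setattr__(self, "nominal_area",
                           float(np.trapezoid(self.nodes_v, self.nodes_t)))

    def __call__(self, t_since_injection):
        t = np.asarray(t_since_injection, dtype=float)
        inside = (t >= 0.0) & (t <= self.support_end)
        v = np.interp(t, self.nodes_t, self.nodes_v)
        out = np.where(inside, v, 0.0)
        return float(out) if np.isscalar(t_since_injection) else out


# Lispro: 0.25 residual, linear rise 5 -> 30 min to the 1.25 peak, linear
# fall to the residual by 120 min, residual tail to the 240-min support end.
LISPRO_PROFILE = AbsorptionProfile(
    "lispro", (0.0, 5.0, 30.0, 120.0, 240.0), (0.25, 0.25, 1.25, 0.25, 0.25))

# Regular: onset 30 min, peak 1.25 at 120 min, two linear decay legs
# (to 0.75 at 240 min, then to the residual at the 480-min support end).
REGULAR_PROFILE = AbsorptionProfile(
    "regular", (0.0, 30.0, 120.0, 240.0, 480.0), (0.25, 0.25, 1.25, 0.75, 0.25))

_PROFILES = {"lispro": LISPRO_PROFILE, "regular": REGULAR_PROFILE}


def unit_profile(preparation: str) -> AbsorptionProfile:
    """The unit absorption shape for a preparation name."""
    return _PROFILES[preparation]


def lispro_unit_profile(t_since_injection):
    """Evaluate the Lispro unit shape (peak 1.25 at 30 min, support 240)."""
    return LISPRO_PROFILE(t_since_injection)


def regular_unit_profile(t_since_injection):
    """Evaluate the regular unit shape (peak 1.25 at 120 min, support 480)."""
    return REGULAR_PROFILE(t_since_injection)


def insulin_input(t, injection: InsulinInjection,
                  conversion: float = DEFAULT_U_TO_MODEL_UNITS):
    """Exogenous insulin rate I_in(t) in model units (mU) per minute.

    The unit shape is scaled by ``dose * conversion / nominal_area`` so its
    time-integral is exactly ``dose * conversion``; dose 0 gives the exact
    no-insulin baseline.
    """
    if conversion <= 0:
        raise ValueError(f"conversion must be > 0, got {conversion}")
    if injection.dose == 0.0:
        t = np.asarray(t, dtype=float)
        z = np.zeros_like(t)
        return float(z) if z.ndim == 0 else z
    prof = _PROFILES[injection.preparation]
    scale = injection.dose * conversion / prof.nominal_area
    return scale * prof(np.asarray(t, dtype=float) - injection.time)


def nutrition_input(t, schedule: NutritionSchedule):
    """Continuous-nutrition carbohydrate rate G_in(t) in mg/min (constant)."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, schedule.rate)
    return float(out) if out.ndim == 0 else out


def nutrition_equivalents(schedule: NutritionSchedule) -> dict[str, float]:
    """24-h bookkeeping for a nutrition rate against the enteral formula.

    Returns the formula volume rate (mL/h), daily energy (kcal/24 h) and
    daily net carbohydrate mass (g/24 h) delivered at ``schedule.rate``.
    """
    ml_per_h = _FORMULA_ML_PER_H_AT_GOAL * schedule.rate / _GOAL_RATE_MG_PER_MIN
    return {
        "ml_per_h": ml_per_h,
        "kcal_per_24h": ml_per_h * 24.0 * _FORMULA_KCAL_PER_ML,
        "carb_g_per_24h": schedule.rate * 1440.0 / 1000.0,
    }
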