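"""The two-delay glucose-insulin feedback model.

State variables are amounts: G(t) in mg over the glucose distribution
volume Vg, I(t) in mU over the plasma volume Vp.  Mass conservation gives

    dG/dt = G_in(t) + gng * f5(I(t - tau2)) * f6(G(t))
            - f2(G(t)) - beta * f3(G(t)) * f4(I(t)) - f7(G(t) - 330)
    dI/dt = I_in(t) + alpha * f1(G(t - tau1)) - d_i * I(t)

where f1 is pancreatic insulin release, f2 insulin-independent glucose
utilization, f3*f4 insulin-dependent utilization, f5 hepatic glucose
production, and f6/f7 inhibitors of hyperglycemia.  The six patient
parameters (tau1, tau2, alpha, beta, gng, d_i) scale or delay individual
arms of the feedback loop and define one virtual patient's pathophysiology.

All response functions are total on their stated domains and evaluated in
overflow-safe form (clamped exponents, power form of the f4 log-sigmoid),
so extreme states degrade gracefully to the sigmoid asymptotes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .constants import MetabolicConstants

__all__ = [
    "PatientParameters", "SystemState",
    "f1", "f2", "f3", "f4", "f5", "f6", "f7",
    "glucose_production", "glucose_utilization",
    "insulin_production", "insulin_clearance", "rhs",
]

_EXP_CLAMP = 700.0  # |x| above this saturates exp() safely below overflow


@dataclass(frozen=True)
class PatientParameters:
    """The six tunable parameters defining one virtual patient.

    alpha scales pancreatic insulin secretion (IDp when < 1), beta scales
    insulin-dependent glucose utilization (IR when < 1), gng scales hepatic
    glucose production (gluconeogenesis; 2 in stress hyperglycemia), d_i is
    the insulin clearance proportionality (1/min; raised in IC), tau1/tau2
    are the insulin- and glucose-secretion delays (min).
    """

    tau1: float
    tau2: float
    alpha: float
    beta: float
    gng: float
    d_i: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.gng < 1.0:
            raise ValueError(f"gng must be >= 1, got {self.gng}")
        if self.d_i <= 0.0:
            raise ValueError(f"d_i must be > 0, got {self.d_i}")
        if self.tau1 < 0.0 or self.tau2 < 0.0:
            raise ValueError("delays must be nonnegative")


class SystemState(NamedTuple):
    """A point (t, G, I) along a trajectory (t in min, amounts in mg / mU)."""

    t: float
    G: float
    I: float


def _sigmoid(x):
    """1 / (1 + exp(x)) with a clamped exponent."""
    return 1.0 / (1.0 + np.exp(np.clip(x, -_EXP_CLAMP, _EXP_CLAMP)))


def f1(g_delayed, c: MetabolicConstants):
    """Pancreatic insulin release (mU/min) from delayed glucose (mg)."""
    return c.Rc * _sigmoid((c.c1 - np.asarray(g_delayed) / c.Vg) / c.e1)


def f2(g, c: MetabolicConstants):
    """Insulin-independent glucose utilization (mg/min)."""
    return c.Ub * (1.0 - np.exp(np.clip(-np.asarray(g) / (c.c2 * c.Vg),
                                        -_EXP_CLAMP, 0.0)))


def f3(g, c: MetabolicConstants):
    """Linear glucose scaling; f3 = 1 at 100 mg/dL with the lineage table."""
    return np.asarray(g) / (c.c3 * c.Vg)


def f4(i, c: MetabolicConstants):
    """Insulin-dependent utilization factor (mg/min), in (Uo, Uc).

    The log-sigmoid is evaluated in power form
    ``Uo + (Uc - Uo) * z**kappa / (1 + z**kappa)`` with
    ``z = (i / c4) * (1/Vc + 1/Etc)``, which extends continuously to the
    right limit Uo at i = 0 (the raw log form is singular there).
    """
    z = (np.asarray(i, dtype=float) / c.c4) * (1.0 / c.Vc + 1.0 / c.Etc)
    with np.errstate(over="ignore"):
        zk = np.power(z, c.kappa)
    frac = np.where(np.isfinite(zk), zk / (1.0 + zk), 1.0)
    return c.Uo + (c.Uc - c.Uo) * frac


def f5(i_delayed, c: MetabolicConstants):
    """Hepatic glucose production (mg/min), suppressed by delayed insulin."""
    return c.Rg * _sigmoid(c.a5 * (np.asarray(i_delayed) / c.Vp - c.c5))


def f6(g, c: MetabolicConstants):
    """Multiplicative inhibitor of hepatic output; decreasing, = 1 at c6."""
    x = np.asarray(g) / (c.c3 * c.Vg) - c.c6
    return np.exp(np.clip(-c.gamma * x, -_EXP_CLAMP, _EXP_CLAMP))


def f7(g_shifted, c: MetabolicConstants):
    """Extra utilization between Sc and Sb engaging at severe hyperglycemia.

    The argument is the literally shifted glucose amount G - 330; the shift
    and the center c7 are fixed model constants.
    """
    x = np.asarray(g_shifted) / (c.c3 * c.Vg)
    return c.Sb + (c.Sc - c.Sb) * _sigmoid(c.delta * (x - c.c7))


def glucose_production(t, i_delayed, g, params: PatientParameters,
                       c: MetabolicConstants, g_in: float):
    """G_p = G_in + gng * f5(I(t - tau2)) * f6(G(t)), mg/min."""
    return g_in + params.gng * f5(i_delayed, c) * f6(g, c)


def glucose_utilization(g, i, params: PatientParameters, c: MetabolicConstants):
    """G_u = f2(G) + beta * f3(G) * f4(I) + f7(G - 330), mg/min."""
    return f2(g, c) + params.beta * f3(g, c) * f4(i, c) + f7(np.asarray(g) - 330.0, c)


def insulin_production(t, g_delayed, params: PatientParameters,
                       c: MetabolicConstants, i_in: float):
    """I_p = I_in + alpha * f1(G(t - tau1)), mU/min."""
    return i_in + params.alpha * f1(g_delayed, c)


def insulin_clearance(i, params: PatientParameters):
    """I_c = d_i * I, mU/min (first-order degradation)."""
    return params.d_i * np.asarray(i)


def rhs(t, g, i, g_delayed_tau1, i_delayed_tau2,
        params: PatientParameters, c: MetabolicConstants,
        g_in: float, i_in: float) -> tuple[float, float]:
    """The full balance (dG/dt, dI/dt) at one state; a pure function."""
    for name, val in (("t", t), ("g", g), ("i", i),
                      ("g_delayed_tau1", g_delayed_tau1),
                      ("i_delayed_tau2", i_delayed_tau2),
                      ("g_in", g_in), ("i_in", i_in)):
        if not np.isfinite(val):
            raise ValueError(f"rhs: non-finite argument {name} = {val!r}")
    dg = (glucose_production(t, i_delayed_tau2, g, params, c, g_in)
          - glucose_utilization(g, i, params, c))
    di = (insulin_production(t, g_delayed_tau1, params, c, i_in)
          - insulin_clearance(i, params))
    return float(dg), float(di)
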