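"""Metabolic response functions and the mass-conservation balance.

The balance terms are checked against an independent term-by-term oracle
written directly from the closed-form expressions with math.exp/math.log,
sharing no code with the implementation.
"""

import math

import numpy as np
import pytest

from glycsim import model
from glycsim.model import PatientParameters


# --- independent closed-form oracle -------------------------------------

def oracle_f(c, g, i, gd, idel):
    """All seven response values from the raw formulas."""
    f1 = c.Rc / (1 + math.exp((c.c1 - gd / c.Vg) / c.e1))
    f2 = c.Ub * (1 - math.exp(-g / (c.c2 * c.Vg)))
    f3 = g / (c.c3 * c.Vg)
    z = (i / c.c4) * (1 / c.Vc + 1 / c.Etc)
    f4 = c.Uo + (c.Uc - c.Uo) / (1 + math.exp(-c.kappa * math.log(z)))
    f5 = c.Rg / (1 + math.exp(c.a5 * (idel / c.Vp - c.c5)))
    f6 = 1.0 / math.exp(c.gamma * (g / (c.c3 * c.Vg) - c.c6))
    x7 = (g - 330.0) / (c.c3 * c.Vg)
    f7 = c.Sb + (c.Sc - c.Sb) / (1 + math.exp(c.delta * (x7 - c.c7)))
    return f1, f2, f3, f4, f5, f6, f7


def oracle_rhs(c, p, g, i, gd, idel, g_in, i_in):
    f1, f2, f3, f4, f5, f6, f7 = oracle_f(c, g, i, gd, idel)
    dg = g_in + p.gng * f5 * f6 - (f2 + p.beta * f3 * f4 + f7)
    di = i_in + p.alpha * f1 - p.d_i * i
    return dg, di


# --- pointwise values ----------------------------------------------------

def test_f1_limits_and_center(consts):
    assert model.f1(1e9, consts) == pytest.approx(consts.Rc, rel=1e-9)
    assert model.f1(0.0, consts) == pytest.approx(
        consts.Rc / (1 + math.exp(consts.c1 / consts.e1)))
    # sigmoid center: glucose amount c1*Vg gives half-maximal release
    assert model.f1(consts.c1 * consts.Vg, consts) == pytest.approx(consts.Rc / 2)


def test_f2_limits_and_scale_point(consts):
    assert model.f2(0.0, consts) == 0.0
    assert model.f2(1e9, consts) == pytest.approx(consts.Ub)
    assert model.f2(consts.c2 * consts.Vg, consts) == pytest.approx(
        consts.Ub * (1 - math.exp(-1)))


def test_f3_linear_through_origin(consts):
    assert model.f3(0.0, consts) == 0.0
    g = np.array([1.0, 2.0, 10.0]) * consts.c3 * consts.Vg
    np.testing.assert_allclose(model.f3(g, consts), [1.0, 2.0, 10.0])


def test_f4_continuous_at_zero_insulin(consts):
    # the raw log form is singular at i = 0; the implementation takes the
    # right limit Uo and must be continuous there
    assert model.f4(0.0, consts) == pytest.approx(consts.Uo)
    assert model.f4(1e-8, consts) == pytest.approx(consts.Uo, abs=1e-6)
    assert model.f4(1e12, consts) == pytest.approx(consts.Uc, rel=1e-6)


def test_f5_center_and_f6_unity_point(consts):
    assert model.f5(consts.Vp * consts.c5, consts) == pytest.approx(consts.Rg / 2)
    assert model.f6(consts.c3 * consts.Vg * consts.c6, consts) == pytest.approx(1.0)


def test_f7_bounds_and_monotonicity(consts):
    lo = model.f7(-1e9, consts)
    hi = model.f7(1e9, consts)
    assert {round(float(lo), 6), round(float(hi), 6)} == \
        {round(consts.Sb, 6), round(consts.Sc, 6)}
    x = np.linspace(-2000.0, 1e5, 1000)
    v = model.f7(x, consts)
    d = np.diff(v)
    assert np.all(d >= 0) or np.all(d <= 0)


def test_overflow_safety_over_extreme_states(consts):
    g = np.array([0.0, 1e3, 1e6, 1e12])
    i = np.array([0.0, 1e3, 1e6, 1e12])
    for fn, arg in [(model.f1, g), (model.f2, g), (model.f3, g),
                    (model.f4, i), (model.f5, i), (model.f6, g),
                    (model.f7, g - 330.0)]:
        assert np.all(np.isfinite(fn(arg, consts)))


def test_monotonicity_on_grid(consts):
    g = np.linspace(0.0, 1000.0 * consts.mg_per_dl, 1000)
    i = np.linspace(0.0, 5e4, 1000)
    assert np.all(np.diff(model.f1(g, consts)) >= 0)
    assert np.all(np.diff(model.f4(i, consts)) >= 0)
    assert np.all(np.diff(model.f5(i, consts)) <= 0)
    assert np.all(np.diff(model.f6(g, consts)) <= 0)
    assert np.all(model.f2(g, consts) <= consts.Ub)
    assert np.all(model.f5(i, consts) <= consts.Rg)


# --- balance structure ---------------------------------------------------

@pytest.fixture
def params():
    return PatientParameters(tau1=5.0, tau2=25.0, alpha=0.8, beta=0.6,
                             gng=2.0, d_i=0.17)


def test_amplitude_linearity(consts, params):
    """Scaling alpha/beta/gng by k scales exactly its own term by k."""
    g, i = 14000.0, 120.0
    k = 3.0
    p2 = PatientParameters(tau1=5, tau2=25, alpha=params.alpha,
                           beta=params.beta, gng=k * params.gng, d_i=0.17)
    hep1 = model.glucose_production(0, i, g, params, consts, 0.0)
    hep2 = model.glucose_production(0, i, g, p2, consts, 0.0)
    assert hep2 == pytest.approx(k * hep1, rel=1e-12)

    u1 = model.glucose_utilization(g, i, params, consts)
    f2 = float(model.f2(g, consts))
    f7 = float(model.f7(g - 330.0, consts))
    pb = PatientParameters(tau1=5, tau2=25, alpha=0.8, beta=params.beta / 2,
                           gng=2.0, d_i=0.17)
    u_half = model.glucose_utilization(g, i, pb, consts)
    assert (u1 - f2 - f7) == pytest.approx(2 * (u_half - f2 - f7), rel=1e-12)

    s1 = model.insulin_production(0, g, params, consts, 0.0)
    pa = PatientParameters(tau1=5, tau2=25, alpha=params.alpha / 2, beta=0.6,
                           gng=2.0, d_i=0.17)
    s_half = model.insulin_production(0, g, pa, consts, 0.0)
    assert float(s1) == pytest.approx(2 * float(s_half), rel=1e-12)


def test_clearance_proportionality(consts, params):
    assert model.insulin_clearance(0.0, params) == 0.0
    # the study's two clearance severities are strictly proportional
    p_lo = PatientParameters(tau1=5, tau2=25, alpha=.8, beta=.6, gng=2, d_i=0.17)
    p_hi = PatientParameters(tau1=5, tau2=25, alpha=.8, beta=.6, gng=2, d_i=0.25)
    i = 137.0
    ratio = model.insulin_clearance(i, p_hi) / model.insulin_clearance(i, p_lo)
    assert ratio == pytest.approx(0.25 / 0.17, rel=1e-12)


def test_rhs_matches_term_oracle_on_random_states(consts, params):
    rng = np.random.default_rng(42)
    for _ in range(100):
        g = rng.uniform(10.0, 40000.0)
        i = rng.uniform(1.0, 2000.0)
        gd = rng.uniform(10.0, 40000.0)
        idel = rng.uniform(1.0, 2000.0)
        g_in = rng.uniform(0.0, 200.0)
        i_in = rng.uniform(0.0, 50.0)
        got = model.rhs(0.0, g, i, gd, idel, params, consts, g_in, i_in)
        want = oracle_rhs(consts, params, g, i, gd, idel, g_in, i_in)
        assert got[0] == pytest.approx(want[0], abs=1e-10)
        assert got[1] == pytest.approx(want[1], abs=1e-10)


def test_rhs_balance_decomposition(consts, params):
    g, i, gd, idel = 15000.0, 130.0, 14500.0, 110.0
    dg, di = model.rhs(0.0, g, i, gd, idel, params, consts, 135.0, 2.0)
    prod = float(model.glucose_production(0.0, idel, g, params, consts, 135.0))
    util = float(model.glucose_utilization(g, i, params, consts))
    assert dg == pytest.approx(prod - util, rel=1e-14)
    sec = float(model.insulin_production(0.0, gd, params, consts, 2.0))
    clr = float(model.insulin_clearance(i, params))
    assert di == pytest.approx(sec - clr, rel=1e-14)


def test_rhs_zero_state(consts):
    p = PatientParameters(tau1=0, tau2=0, alpha=1e-12, beta=1.0, gng=1.0,
                          d_i=0.17)
    dg, di = model.rhs(0.0, 0.0, 0.0, 0.0, 0.0, p, consts, 0.0, 0.0)
    # glucose balance at the origin: hepatic term minus the f7(-330) drain
    want = float(model.glucose_production(0, 0.0, 0.0, p, consts, 0.0)) \
        - float(model.f7(-330.0, consts))
    assert dg == pytest.approx(want, rel=1e-12)
    assert di == pytest.approx(0.0, abs=1e-9)


def test_rhs_rejects_non_finite_with_argument_name(consts, params):
    with pytest.raises(ValueError, match="g_delayed_tau1"):
        model.rhs(0.0, 1.0, 1.0, float("nan"), 1.0, params, consts, 0.0, 0.0)
    with pytest.raises(ValueError, match="i_in"):
        model.rhs(0.0, 1.0, 1.0, 1.0, 1.0, params, consts, 0.0, float("inf"))


def test_patient_parameter_invariants():
    with pytest.raises(ValueError):
        PatientParameters(tau1=5, tau2=25, alpha=1.2, beta=0.8, gng=2, d_i=0.17)
    with pytest.raises(ValueError):
        PatientParameters(tau1=5, tau2=25, alpha=0.8, beta=0.0, gng=2, d_i=0.17)
    with pytest.raises(ValueError):
        PatientParameters(tau1=5, tau2=25, alpha=0.8, beta=0.8, gng=0.5, d_i=0.17)
    with pytest.raises(ValueError):
        PatientParameters(tau1=-1, tau2=25, alpha=0.8, beta=0.8, gng=2, d_i=0.17)
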