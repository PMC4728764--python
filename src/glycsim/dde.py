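"""Fixed-step integrator for the two-delay glucose-insulin system.

The system is advanced by the method of steps: a classical 4th-order
Runge-Kutta step on the non-delayed state, with delayed-state lookups
served by cubic (4-point Lagrange) interpolation of the dense solution
history on the uniform step grid.  The step size is required to be at most
a quarter of the smallest positive delay, so every delayed lookup falls in
already-computed history.  The scheme is deterministic: no randomness
anywhere, repeated runs are bit-identical.

The piecewise-linear insulin absorption profiles have corner points at 5,
30, 120, 240 and 480 min after injection; with the default 0.1-min step
and an injection time on the step grid these corners coincide with step
boundaries, so no order is lost at the kinks.

Glucose and insulin amounts are clamped at zero after each step (the model
is only meaningful on the nonnegative orthant and the clamp is inactive on
healthy trajectories).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

from . import model
from .constants import MetabolicConstants
from .inputs import (InsulinInjection, NutritionSchedule, unit_profile,
                     DEFAULT_U_TO_MODEL_UNITS)
from .metrics import GlucoseTrace, extrema_indices

__all__ = [
    "IntegrationSettings", "HistoryBuffer", "Simulation",
    "BurnInError", "IntegrationError",
    "integrate", "burn_in_to_oscillation", "steady_state_guess",
]


class IntegrationError(RuntimeError):
    """Raised when the trajectory leaves the finite domain mid-run."""


class BurnInError(RuntimeError):
    """Raised when no stable ultradian oscillation is reached in budget."""


@dataclass(frozen=True)
class IntegrationSettings:
    """Numerical settings: step (min), burn-in and measurement spans (min).

    ``output_dt`` is the dense-output sampling interval in seconds (the
    mean-glucose metric is defined on per-second samples).
    """

    step: float = 0.1
    burn_in: float = 6000.0
    measurement: float = 750.0
    output_dt: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.measurement <= 0:
            raise ValueError("measurement duration must be > 0")
        if self.output_dt <= 0:
            raise ValueError("output_dt must be > 0")

    def validate_delays(self, tau1: float, tau2: float) -> None:
        """Enforce step <= tau/4 for every positive delay."""
        for name, tau in (("tau1", tau1), ("tau2", tau2)):
            if 0.0 < tau < 4.0 * self.step:
                raise ValueError(
                    f"step {self.step} min violates the delay constraint "
                    f"step <= {name}/4 (={tau / 4.0} min)")


@dataclass(frozen=True)
class HistoryBuffer:
    """Dense uniform-grid history ending at t = 0 (the phase reference).

    ``g``/``i`` hold amounts on the grid ``t_k = (k - (n-1)) * step`` for
    k = 0..n-1, i.e. the final sample is the state at t = 0.  Queries
    inside the covered span use the same cubic interpolant as the
    integrator and reproduce stored samples exactly at the nodes.
    """

    step: float
    g: np.ndarray
    i: np.ndarray

    def __post_init__(self) -> None:
        if len(self.g) != len(self.i):
            raise ValueError("G and I histories must have equal length")
        if len(self.g) < 4:
            raise ValueError("history must hold at least 4 samples")

    @property
    def span(self) -> float:
        """Covered interval length before t = 0, in minutes."""
        return (len(self.g) - 1) * self.step

    def query(self, t: float) -> tuple[float, float]:
        """Interpolated (G, I) at time t in [-span, 0]; never extrapolates."""
        if t < -self.span - 1e-12 or t > 1e-12:
            raise ValueError(f"history query {t} outside [-{self.span}, 0]")
        n = len(self.g)
        u = t / self.step + (n - 1)
        j = int(math.floor(u + 1e-12))
        if abs(u - j) < 1e-9:
            return float(self.g[j]), float(self.i[j])
        j = min(max(j, 1), n - 3)
        s = u - j
        return (_lagrange4(self.g, j, s), _lagrange4(self.i, j, s))


def _lagrange4(y: np.ndarray, j: int, s: float) -> float:
    wm1 = -s * (s - 1.0) * (s - 2.0) / 6.0
    w0 = (s + 1.0) * (s - 1.0) * (s - 2.0) / 2.0
    w1 = -(s + 1.0) * s * (s - 2.0) / 2.0
    w2 = (s + 1.0) * s * (s - 1.0) / 6.0
    return float(wm1 * y[j - 1] + w0 * y[j] + w1 * y[j + 1] + w2 * y[j + 2])


# ---------------------------------------------------------------------------
# compiled core
# ---------------------------------------------------------------------------

_NC = 23  # number of scalars in the constants vector


def _constants_vector(c: MetabolicConstants) -> np.ndarray:
    return np.array([
        c.Rc, c.c1, c.e1, c.Vg, c.Ub, c.c2, c.c3, c.Uo, c.Uc, c.kappa,
        c.c4, c.Vc, c.Etc, c.Rg, c.c5, c.a5, c.Vp, c.gamma, c.c6,
        c.delta, c.c7, c.Sb, c.Sc,
    ], dtype=np.float64)


@njit(cache=True)
def _profile_value(prep: int, ts: float) -> float:
    # unit absorption shapes; prep: 0 none, 1 lispro, 2 regular
    if prep == 1:
        if ts < 0.0 or ts > 240.0:
            return 0.0
        if ts <= 5.0:
            return 0.25
        if ts < 30.0:
            return 0.25 + (ts - 5.0) / 25.0
        if ts < 120.0:
            return 0.25 + (120.0 - ts) / 90.0
        return 0.25
    if prep == 2:
        if ts < 0.0 or ts > 480.0:
            return 0.0
        if ts <= 30.0:
            return 0.25
        if ts < 120.0:
            return 0.25 + (ts - 30.0) / 90.0
        if ts < 240.0:
            return 1.25 - 0.5 * (ts - 120.0) / 120.0
        return 0.75 - 0.5 * (ts - 240.0) / 240.0
    return 0.0


@njit(cache=True)
def _clamped_exp(x: float) -> float:
    if x > 700.0:
        x = 700.0
    elif x < -700.0:
        x = -700.0
    return math.exp(x)


@njit(cache=True)
def _rhs_core(g: float, i: float, gd: float, idel: float, cv: np.ndarray,
              alpha: float, beta: float, gng: float, d_i: float,
              g_in: float, i_in: float) -> tuple[float, float]:
    if g < 0.0:
        g = 0.0
    if i < 0.0:
        i = 0.0
    if gd < 0.0:
        gd = 0.0
    if idel < 0.0:
        idel = 0.0
    Rc, c1, e1, Vg = cv[0], cv[1], cv[2], cv[3]
    Ub, c2, c3 = cv[4], cv[5], cv[6]
    Uo, Uc, kappa, c4, Vc, Etc = cv[7], cv[8], cv[9], cv[10], cv[11], cv[12]
    Rg, c5, a5, Vp = cv[13], cv[14], cv[15], cv[16]
    gamma, c6, delta, c7, Sb, Sc = cv[17], cv[18], cv[19], cv[20], cv[21], cv[22]

    F1 = Rc / (1.0 + _clamped_exp((c1 - gd / Vg) / e1))
    F2 = Ub * (1.0 - _clamped_exp(-g / (c2 * Vg)))
    F3 = g / (c3 * Vg)
    z = (i / c4) * (1.0 / Vc + 1.0 / Etc)
    if z <= 0.0:
        frac = 0.0
    else:
        zk = z ** kappa
        frac = zk / (1.0 + zk) if math.isfinite(zk) else 1.0
    F4 = Uo + (Uc - Uo) * frac
    F5 = Rg / (1.0 + _clamped_exp(a5 * (idel / Vp - c5)))
    F6 = _clamped_exp(-gamma * (g / (c3 * Vg) - c6))
    x7 = (g - 330.0) / (c3 * Vg)
    F7 = Sb + (Sc - Sb) / (1.0 + _clamped_exp(delta * (x7 - c7)))

    dG = g_in + gng * F5 * F6 - F2 - beta * F3 * F4 - F7
    dI = i_in + alpha * F1 - d_i * i
    return dG, dI


@njit(cache=True)
def _interp_hist(y: np.ndarray, u: float) -> float:
    # cubic Lagrange on the uniform grid; u is a continuous index
    j = int(math.floor(u + 1e-9))
    s = u - j
    if s < 1e-9:
        return y[j]
    wm1 = -s * (s - 1.0) * (s - 2.0) / 6.0
    w0 = (s + 1.0) * (s - 1.0) * (s - 2.0) / 2.0
    w1 = -(s + 1.0) * s * (s - 2.0) / 2.0
    w2 = (s + 1.0) * s * (s - 1.0) / 6.0
    return wm1 * y[j - 1] + w0 * y[j] + w1 * y[j + 1] + w2 * y[j + 2]


@njit(cache=True)
def _simulate_core(hist_g: np.ndarray, hist_i: np.ndarray, h: float,
                   n_steps: int, tau1: float, tau2: float,
                   alpha: float, beta: float, gng: float, d_i: float,
                   cv: np.ndarray, g_in: float,
                   prep: int, ins_scale: float, ins_t0: float):
    """Advance n_steps of size h from the supplied history.

    Returns (G, I, status): amount arrays over history + new steps, and
    status = -1 on success or the failing step index if the state went
    non-finite.  Time of index k is (k - (m-1)) * h with m = len(hist).
    """
    m = hist_g.shape[0]
    n = m + n_steps
    G = np.empty(n)
    I = np.empty(n)
    G[:m] = hist_g
    I[:m] = hist_i
    base = float(m - 1)
    off1 = tau1 / h
    off2 = tau2 / h
    t1z = tau1 == 0.0
    t2z = tau2 == 0.0

    for step in range(n_steps):
        k = m - 1 + step
        t = step * h
        g0 = G[k]
        i0 = I[k]

        # stage 1 (at t)
        gd = g0 if t1z else _interp_hist(G, base + step - off1)
        idl = i0 if t2z else _interp_hist(I, base + step - off2)
        iin = ins_scale * _profile_value(prep, t - ins_t0)
        k1g, k1i = _rhs_core(g0, i0, gd, idl, cv, alpha, beta, gng, d_i,
                             g_in, iin)

        # stages 2 and 3 (at t + h/2)
        um = base + step + 0.5
        iin = ins_scale * _profile_value(prep, t + 0.5 * h - ins_t0)
        ga = g0 + 0.5 * h * k1g
        ia = i0 + 0.5 * h * k1i
        gd = ga if t1z else _interp_hist(G, um - off1)
        idl = ia if t2z else _interp_hist(I, um - off2)
        k2g, k2i = _rhs_core(ga, ia, gd, idl, cv, alpha, beta, gng, d_i,
                             g_in, iin)

        gb = g0 + 0.5 * h * k2g
        ib = i0 + 0.5 * h * k2i
        gd = gb if t1z else _interp_hist(G, um - off1)
        idl = ib if t2z else _interp_hist(I, um - off2)
        k3g, k3i = _rhs_core(gb, ib, gd, idl, cv, alpha, beta, gng, d_i,
                             g_in, iin)

        # stage 4 (at t + h)
        ue = base + step + 1.0
        iin = ins_scale * _profile_value(prep, t + h - ins_t0)
        gc = g0 + h * k3g
        ic = i0 + h * k3i
        gd = gc if t1z else _interp_hist(G, ue - off1)
        idl = ic if t2z else _interp_hist(I, ue - off2)
        k4g, k4i = _rhs_core(gc, ic, gd, idl, cv, alpha, beta, gng, d_i,
                             g_in, iin)

        gn = g0 + (h / 6.0) * (k1g + 2.0 * k2g + 2.0 * k3g + k4g)
        inew = i0 + (h / 6.0) * (k1i + 2.0 * k2i + 2.0 * k3i + k4i)
        if not (math.isfinite(gn) and math.isfinite(inew)):
            return G, I, step
        G[k + 1] = gn if gn > 0.0 else 0.0
        I[k + 1] = inew if inew > 0.0 else 0.0

    return G, I, -1


# ---------------------------------------------------------------------------
# public driver layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Simulation:
    """A completed run: step-grid amounts plus the provenance needed to
    resample or continue the trajectory."""

    step: float
    n_history: int            # samples belonging to the initial history
    g: np.ndarray             # amounts (mg), full grid
    i: np.ndarray             # amounts (mU), full grid
    consts: MetabolicConstants
    meta: dict

    def times(self) -> np.ndarray:
        """Step-grid times in min; t = 0 at the start of the new segment."""
        n = len(self.g)
        return (np.arange(n) - (self.n_history - 1)) * self.step

    def glucose_trace(self, duration: float, output_dt: float = 1.0) -> GlucoseTrace:
        """Dense glucose concentration (mg/dL) on a 1-s grid over [0, duration]."""
        t_s = np.arange(0.0, duration * 60.0 + 0.5 * output_dt, output_dt)
        g_amt = _resample_cubic(self.g, self.n_history, self.step, t_s / 60.0)
        return GlucoseTrace(t_seconds=t_s,
                           g_mg_dl=g_amt / self.consts.mg_per_dl,
                           meta=dict(self.meta))

    def insulin_samples(self, duration: float, output_dt: float = 1.0) -> np.ndarray:
        """Dense insulin amounts (mU) on the same grid as glucose_trace."""
        t_s = np.arange(0.0, duration * 60.0 + 0.5 * output_dt, output_dt)
        return _resample_cubic(self.i, self.n_history, self.step, t_s / 60.0)

    def history_ending_at(self, t: float, span: float) -> HistoryBuffer:
        """Extract a history buffer covering [t - span, t] (grid-aligned t)."""
        u = t / self.step + (self.n_history - 1)
        k = int(round(u))
        if abs(u - k) > 1e-6:
            raise ValueError(f"t={t} is not on the step grid")
        n = int(round(span / self.step)) + 1
        if k - n + 1 < 0 or k >= len(self.g):
            raise ValueError("requested history exceeds simulated span")
        return HistoryBuffer(self.step, self.g[k - n + 1:k + 1].copy(),
                             self.i[k - n + 1:k + 1].copy())


def _resample_cubic(y: np.ndarray, n_history: int, h: float,
                    t_min: np.ndarray) -> np.ndarray:
    """Vectorized 4-point Lagrange resampling of a step-grid signal."""
    u = t_min / h + (n_history - 1)
    n = len(y)
    j = np.clip(np.floor(u + 1e-9).astype(np.int64), 1, n - 3)
    s = u - j
    wm1 = -s * (s - 1.0) * (s - 2.0) / 6.0
    w0 = (s + 1.0) * (s - 1.0) * (s - 2.0) / 2.0
    w1 = -(s + 1.0) * s * (s - 2.0) / 2.0
    w2 = (s + 1.0) * s * (s - 1.0) / 6.0
    return wm1 * y[j - 1] + w0 * y[j] + w1 * y[j + 1] + w2 * y[j + 2]


def steady_state_guess(params: model.PatientParameters, c: MetabolicConstants,
                       g_in: float) -> tuple[float, float]:
    """Zero-delay equilibrium amounts (G, I) used as constant initial history.

    Solves the delay-free balance with insulin slaved to glucose
    (I = alpha f1(G) / d_i) by bracketed root finding; used only to seed
    the burn-in, so any point on the balance curve suffices.
    """
    def balance(g_amt: float) -> float:
        i_amt = params.alpha * float(model.f1(g_amt, c)) / params.d_i
        dg, _ = model.rhs(0.0, g_amt, i_amt, g_amt, i_amt, params, c, g_in, 0.0)
        return dg

    lo, hi = 1.0, 100.0 * c.mg_per_dl
    # expand upward if the balance has not turned negative yet
    while balance(hi) > 0 and hi < 1e7:
        hi *= 2.0
    g_eq = brentq(balance, lo, hi, xtol=1e-6)
    i_eq = params.alpha * float(model.f1(g_eq, c)) / params.d_i
    return float(g_eq), float(i_eq)


def _history_length(settings: IntegrationSettings, tau1: float,
                    tau2: float) -> int:
    span = max(tau1, tau2, 4.0 * settings.step)
    return int(math.ceil(span / settings.step)) + 4


def integrate(params: model.PatientParameters, consts: MetabolicConstants,
              settings: IntegrationSettings, nutrition: NutritionSchedule,
              injection: InsulinInjection | None = None,
              conversion: float = DEFAULT_U_TO_MODEL_UNITS,
              history: HistoryBuffer | None = None,
              duration: float | None = None,
              meta: dict | None = None) -> Simulation:
    """Advance the system for ``duration`` min (default: measurement span).

    ``history`` supplies the state on [-max(tau), 0]; if omitted, a
    constant history at the delay-free equilibrium is used.  The optional
    ``injection`` delivers one SQ bolus through the piecewise absorption
    profile (time measured on the run's own clock).
    """
    settings.validate_delays(params.tau1, params.tau2)
    h = settings.step
    dur = settings.measurement if duration is None else duration
    n_steps = int(round(dur / h))
    if n_steps <= 0:
        raise ValueError(f"duration {dur} min yields no integration steps")

    if history is None:
        g_eq, i_eq = steady_state_guess(params, consts, nutrition.rate)
        m = _history_length(settings, params.tau1, params.tau2)
        history = HistoryBuffer(h, np.full(m, g_eq), np.full(m, i_eq))
    elif abs(history.step - h) > 1e-12:
        raise ValueError("history step does not match integration step")
    m_needed = _history_length(settings, params.tau1, params.tau2)
    if len(history.g) < m_needed:
        raise ValueError(
            f"history covers {history.span} min; needs >= "
            f"{(m_needed - 1) * h} min for the delays")

    if injection is None or injection.dose == 0.0:
        prep, scale, t0 = 0, 0.0, 0.0
    else:
        prof = unit_profile(injection.preparation)
        prep = 1 if injection.preparation == "lispro" else 2
        scale = injection.dose * conversion / prof.nominal_area
        t0 = injection.time

    G, I, status = _simulate_core(
        np.ascontiguousarray(history.g, dtype=np.float64),
        np.ascontiguousarray(history.i, dtype=np.float64),
        h, n_steps, params.tau1, params.tau2,
        params.alpha, params.beta, params.gng, params.d_i,
        _constants_vector(consts), nutrition.rate, prep, scale, t0)
    if status >= 0:
        raise IntegrationError(
            f"state became non-finite at t = {status * h:.2f} min")

    run_meta = {"nutrition": nutrition.label, "nutrition_rate": nutrition.rate,
                "step": h}
    if injection is not None:
        run_meta.update(preparation=injection.preparation, dose=injection.dose)
    else:
        run_meta.update(preparation=None, dose=0.0)
    if meta:
        run_meta.update(meta)
    return Simulation(h, len(history.g), G, I, consts, run_meta)


def burn_in_to_oscillation(params: model.PatientParameters,
                           consts: MetabolicConstants,
                           nutrition: NutritionSchedule,
                           settings: IntegrationSettings,
                           stability_tol: float = 0.5,
                           min_amplitude: float = 1.0,
                           trailing_window: float = 1000.0,
                           ) -> tuple[HistoryBuffer, dict]:
    """Run the insulin-free burn-in and re-base time at the last glucose peak.

    Integrates from a constant equilibrium history for ``settings.burn_in``
    minutes, requires the trailing window to show a stable ultradian
    oscillation (>= 3 glucose peaks with successive peak heights differing
    by less than ``stability_tol`` mg/dL and a peak-to-trough swing of at
    least ``min_amplitude`` mg/dL, so a trajectory damping to a fixed point
    is rejected rather than mistaken for a settled cycle), and returns a
    history buffer
    ending exactly at the last detected peak -- the injection time t = 0 of
    the study protocol -- plus phase diagnostics (peak value in mg/dL,
    oscillation period estimate).
    """
    if settings.burn_in <= 0:
        raise BurnInError("burn-in budget must be positive to reach the "
                          "oscillatory regime")
    # seed 2 % above the delay-free equilibrium: the equilibrium itself is
    # also a DDE fixed point, so an exact-equilibrium history would sit on
    # the unstable focus instead of spiraling out to the limit cycle
    g_eq, i_eq = steady_state_guess(params, consts, nutrition.rate)
    m = _history_length(settings, params.tau1, params.tau2)
    seed = HistoryBuffer(settings.step, np.full(m, 1.02 * g_eq),
                         np.full(m, i_eq))
    sim = integrate(params, consts, settings, nutrition, injection=None,
                    history=seed, duration=settings.burn_in)
    h = settings.step
    n_tail = min(int(round(trailing_window / h)), len(sim.g) - 1)
    tail = sim.g[-n_tail:]
    peaks, kinds = extrema_indices(tail)
    peak_idx = [p for p, kd in zip(peaks, kinds) if kd == 1]
    heights = sim.g[np.array(peak_idx, dtype=np.int64) + (len(sim.g) - n_tail)] \
        / consts.mg_per_dl if peak_idx else np.array([])
    if len(peak_idx) < 3:
        raise BurnInError(
            f"only {len(peak_idx)} glucose peaks in the trailing "
            f"{trailing_window:.0f} min; no sustained oscillation "
            f"(trailing peak heights mg/dL: {np.round(heights, 3).tolist()})")
    diffs = np.abs(np.diff(heights[-3:]))
    if np.any(diffs >= stability_tol):
        raise BurnInError(
            "oscillation not settled: successive trailing peak heights "
            f"differ by {np.round(diffs, 3).tolist()} mg/dL "
            f"(tolerance {stability_tol})")
    trough_idx = [p for p, kd in zip(peaks, kinds) if kd == -1]
    trough = (sim.g[trough_idx[-1] + (len(sim.g) - n_tail)] / consts.mg_per_dl
              if trough_idx else float(heights[-1]))
    if heights[-1] - trough < min_amplitude:
        raise BurnInError(
            f"trailing peak-to-trough swing {heights[-1] - trough:.3f} mg/dL "
            f"is below {min_amplitude}; trajectory has damped toward a "
            "fixed point, not an ultradian oscillation")

    last_peak_global = peak_idx[-1] + (len(sim.g) - n_tail)
    t_peak = (last_peak_global - (sim.n_history - 1)) * h
    span = max(params.tau1, params.tau2, 4.0 * h) + 4.0 * h
    buffer = sim.history_ending_at(t_peak, span)
    period = (np.mean(np.diff(np.array(peak_idx[-3:]) * h))
              if len(peak_idx) >= 3 else float("nan"))
    info = {"peak_mg_dl": float(heights[-1]),
            "period_min": float(period),
            "trailing_peaks_mg_dl": [float(x) for x in heights[-3:]]}
    return buffer, info
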