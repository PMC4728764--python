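"""Glycemic metrics against constructed fixtures and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from glycsim import metrics
from glycsim.metrics import (ExtremaSequence, GlycemicVariabilityUndefined,
                             ReboundUndefined, change_metrics,
                             detect_hypoglycemia, detect_rebound,
                             extrema_indices, find_extrema, gv, mgc)
from conftest import make_trace


def brute_force_extrema(v):
    """Exhaustive neighborhood scan with plateau collapse (independent oracle)."""
    out = []
    n = len(v)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left = v[i - 1]
        right = v[j + 1] if j + 1 < n else None
        if right is not None:
            if left < v[i] and right < v[i]:
                out.append(((i + j) // 2, 1))
            elif left > v[i] and right > v[i]:
                out.append(((i + j) // 2, -1))
        i = j + 1
    return out


# --- trace container -----------------------------------------------------

def test_trace_validation():
    with pytest.raises(ValueError, match="uniform"):
        metrics.GlucoseTrace(np.array([0.0, 1.0, 3.0]), np.ones(3))
    with pytest.raises(ValueError, match="start at t = 0"):
        metrics.GlucoseTrace(np.array([1.0, 2.0, 3.0]), np.ones(3))
    with pytest.raises(ValueError, match="negative"):
        make_trace([1.0, -0.5, 1.0])
    with pytest.raises(ValueError, match="non-finite"):
        make_trace([1.0, np.nan, 1.0])


# --- MGC ------------------------------------------------------------------

def test_mgc_constant_and_sinusoid():
    assert mgc(make_trace(np.full(45001, 160.0))) == 160.0
    t = np.arange(45000.0)
    tr = make_trace(150.0 + 10.0 * np.sin(2 * np.pi * t / 9000.0))
    assert mgc(tr) == pytest.approx(150.0, abs=1e-9)


def test_mgc_sawtooth_direct_summation():
    saw = np.array([100.0, 110, 120, 110, 100, 110, 120, 110, 100])
    want = sum(saw) / len(saw)   # explicit summation oracle
    assert mgc(make_trace(saw)) == pytest.approx(want, rel=1e-14)


# --- extrema detection ----------------------------------------------------

def test_monotone_trace_has_no_extrema():
    idx, kinds = extrema_indices(np.linspace(0, 10, 100))
    assert len(idx) == 0


def test_sinusoid_extrema_count_and_alternation():
    t = np.arange(0, 5000)
    v = 150 + 20 * np.sin(2 * np.pi * t / 1000.0)   # 5 full periods
    idx, kinds = extrema_indices(v)
    assert len(idx) == 10
    assert np.all(kinds[:-1] != kinds[1:])


def test_plateau_collapses_to_midpoint():
    v = np.array([0.0, 1, 2, 2, 2, 1, 0])
    idx, kinds = extrema_indices(v)
    assert list(idx) == [3] and list(kinds) == [1]
    v2 = np.array([5.0, 4, 3, 3, 4, 5])
    idx2, kinds2 = extrema_indices(v2)
    assert list(idx2) == [2] and list(kinds2) == [-1]


def test_endpoints_never_extrema():
    v = np.array([10.0, 5, 10])   # endpoints larger, interior trough only
    idx, kinds = extrema_indices(v)
    assert list(idx) == [1] and list(kinds) == [-1]


@given(st.lists(st.integers(0, 6), min_size=5, max_size=120))
@hyp_settings(max_examples=200, deadline=None)
def test_extrema_match_brute_force_scan(vals):
    v = np.array(vals, dtype=float)
    idx, kinds = extrema_indices(v)
    assert list(zip(idx, kinds)) == brute_force_extrema(v)


def test_two_frequency_fixture_matches_brute_force():
    t = np.arange(0, 30000)
    v = 150 + 15 * np.sin(2 * np.pi * t / 6000) + 5 * np.sin(2 * np.pi * t / 1100)
    idx, kinds = extrema_indices(v)
    assert list(zip(idx, kinds)) == brute_force_extrema(v)
    assert np.all(kinds[:-1] != kinds[1:])


def test_extrema_sequence_invariants_enforced():
    with pytest.raises(ValueError, match="alternate"):
        ExtremaSequence(np.array([1.0, 2.0]), np.array([5.0, 6.0]),
                        np.array([1, 1]))


# --- GV -------------------------------------------------------------------

def test_gv_undefined_on_constant_trace():
    with pytest.raises(GlycemicVariabilityUndefined):
        gv(make_trace(np.full(100, 160.0)))


def test_gv_sinusoid_equals_twice_amplitude():
    t = np.arange(0, 45000)
    tr = make_trace(150 + 12.0 * np.sin(2 * np.pi * t / 9000.0))
    assert gv(tr) == pytest.approx(24.0, rel=1e-6)


def test_gv_sawtooth_enumeration_oracle():
    saw = np.array([100.0, 120, 90, 140, 100, 130, 100])
    # interior extrema values: 120, 90, 140, 100, 130
    want = np.mean(np.abs(np.diff([120, 90, 140, 100, 130])))
    assert gv(make_trace(saw)) == pytest.approx(want, rel=1e-14)


def test_gv_invariant_under_shift_mgc_shifts_exactly():
    t = np.arange(0, 20000)
    base = 150 + 10 * np.sin(2 * np.pi * t / 4000.0)
    a, b = make_trace(base), make_trace(base + 7.5)
    assert gv(a) == pytest.approx(gv(b), rel=1e-12)
    assert mgc(b) - mgc(a) == pytest.approx(7.5, abs=1e-9)


def test_gv_scales_with_multiplicative_scaling_about_mean():
    t = np.arange(0, 20000)
    base = 150 + 10 * np.sin(2 * np.pi * t / 4000.0)
    scaled = 150 + 2.5 * (base - 150)
    assert gv(make_trace(scaled)) == pytest.approx(2.5 * gv(make_trace(base)),
                                                   rel=1e-9)


# --- change metrics and event detectors -----------------------------------

def test_change_metrics_identity_and_shift():
    t = np.arange(0, 20000)
    base = make_trace(150 + 10 * np.sin(2 * np.pi * t / 4000.0),
                      patient_id="P1", nutrition="goal")
    same = make_trace(base.g_mg_dl.copy(), patient_id="P1", nutrition="goal")
    assert change_metrics(same, base) == (0.0, 0.0)
    shifted = make_trace(base.g_mg_dl - 5.0, patient_id="P1", nutrition="goal")
    d_mgc, d_gv = change_metrics(shifted, base)
    assert d_mgc == pytest.approx(-5.0, abs=1e-9)
    assert d_gv == pytest.approx(0.0, abs=1e-9)


def test_change_metrics_rejects_provenance_mismatch():
    a = make_trace(150 + np.sin(np.arange(2000.0)), patient_id="P1",
                   nutrition="goal")
    b = make_trace(150 + np.sin(np.arange(2000.0)), patient_id="P2",
                   nutrition="goal")
    with pytest.raises(ValueError, match="provenance"):
        change_metrics(a, b)
    c = make_trace(150 + np.sin(np.arange(1000.0)), patient_id="P1",
                   nutrition="goal")
    with pytest.raises(ValueError, match="grid"):
        change_metrics(a, c)


def test_hypoglycemia_detector():
    flag, g_min = detect_hypoglycemia(make_trace(np.full(100, 160.0)))
    assert not flag and g_min == 160.0
    v = np.full(100, 160.0)
    v[40] = 59.0
    flag, g_min = detect_hypoglycemia(make_trace(v))
    assert flag and g_min == 59.0
    flag, _ = detect_hypoglycemia(make_trace(v), threshold=0.0)
    assert not flag


def test_rebound_detector_on_constructed_fixtures():
    t = np.arange(0, 30000)
    base_v = 150 + 10 * np.sin(2 * np.pi * (t + 1500) / 6000.0)  # peak at t=0
    base = make_trace(base_v, patient_id="P5", nutrition="goal")

    same = make_trace(base_v.copy(), patient_id="P5", nutrition="goal")
    assert detect_rebound(same, base) is False

    raised = base_v.copy()
    first_peak = 6000   # next interior peak of the sinusoid (period 6000 s)
    raised[first_peak - 200:first_peak + 200] += 5.0
    assert detect_rebound(make_trace(raised, patient_id="P5",
                                     nutrition="goal"), base) is True

    # shifted but not elevated first peak: the phase shift of 900 samples
    # keeps the sampled peak value exactly equal to baseline's
    shifted = 150 + 10 * np.sin(2 * np.pi * (t + 900) / 6000.0)
    assert detect_rebound(make_trace(shifted, patient_id="P5",
                                     nutrition="goal"), base) is False


def test_rebound_undefined_without_post_injection_peak():
    base = make_trace(np.linspace(160, 140, 1000), patient_id="P5",
                      nutrition="goal")
    treated = make_trace(np.linspace(160, 139, 1000), patient_id="P5",
                         nutrition="goal")
    with pytest.raises(ReboundUndefined):
        detect_rebound(treated, base)
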