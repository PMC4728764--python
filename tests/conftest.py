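"""Shared fixtures: constants, settings, the calibrated cohort and the
full dose-response study (computed once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from glycsim import load_constants
from glycsim.cohort import build_cohort, calibrate_cohort
from glycsim.dde import IntegrationSettings
from glycsim.model import PatientParameters
from glycsim.metrics import GlucoseTrace
from glycsim.study import StudyDesign, run_study


@pytest.fixture(scope="session")
def consts():
    return load_constants()


@pytest.fixture(scope="session")
def settings():
    return IntegrationSettings()


@pytest.fixture(scope="session")
def stress_params(consts):
    """Severe-IR / mild-IDp / borderline-IC patient at normal delays."""
    return PatientParameters(tau1=consts.tau1_normal, tau2=consts.tau2_normal,
                             alpha=0.8, beta=0.6, gng=2.0, d_i=0.17)


@pytest.fixture(scope="session")
def calibrated_cohort(consts, settings):
    return calibrate_cohort(build_cohort(consts), consts, settings)


@pytest.fixture(scope="session")
def full_study(calibrated_cohort, consts, settings):
    """The complete 8 x 2 x 3 x 25 factorial."""
    return run_study(calibrated_cohort, consts, StudyDesign(settings=settings))


def make_trace(values, dt=1.0, **meta) -> GlucoseTrace:
    """Helper: wrap a value array in a GlucoseTrace on a uniform grid."""
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values), dtype=float) * dt
    return GlucoseTrace(t_seconds=t, g_mg_dl=values, meta=meta)
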