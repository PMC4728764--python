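"""Glycemic endpoints: mean glucose, glucose variability, event detectors.

MGC is the arithmetic mean of per-second glucose samples over the 750-min
measurement window.  GV is the mean absolute glucose change: the average
absolute difference between consecutive local extrema (peaks/troughs) of
the noise-free simulated trace over the same window, deliberately not
normalized by time since every measurement uses an identical window.
Treated-minus-baseline differences (the patient as their own control at
dose 0) give the change-in-MGC and change-in-GV dose-response points.

Hypoglycemia is flagged when the trace minimum reaches 60 mg/dL.  Rebound
hyperglycemia is flagged when the first post-injection glucose peak
exceeds the ordinally corresponding baseline peak (the injection is given
at a shared baseline peak, so ordinal pairing is phase matching).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "GlucoseTrace", "ExtremaSequence", "DoseResponseRecord",
    "GlycemicVariabilityUndefined", "ReboundUndefined",
    "extrema_indices", "find_extrema", "mgc", "gv",
    "change_metrics", "detect_hypoglycemia", "detect_rebound",
    "HYPOGLYCEMIA_THRESHOLD",
]

#: operationalization of "glucose concentrations near 60 mg/dL"
HYPOGLYCEMIA_THRESHOLD = 60.0


class GlycemicVariabilityUndefined(ValueError):
    """Trace has fewer than two extrema; GV is undefined (not zero)."""


class ReboundUndefined(ValueError):
    """No post-injection peak exists to compare against baseline."""


@dataclass(frozen=True)
class GlucoseTrace:
    """Densely sampled glucose concentration over the measurement window.

    ``t_seconds`` is a complete uniform grid starting at 0 (the injection
    time); ``g_mg_dl`` the matching concentrations; ``meta`` carries run
    provenance (patient, dose, preparation, nutrition).
    """

    t_seconds: np.ndarray
    g_mg_dl: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_seconds, dtype=float)
        g = np.asarray(self.g_mg_dl, dtype=float)
        if t.ndim != 1 or t.shape != g.shape or len(t) < 2:
            raise ValueError("trace needs matching 1-D time/value arrays")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=0.0, atol=1e-9 * max(dt[0], 1.0)):
            raise ValueError("trace grid is not uniform")
        if t[0] != 0.0:
            raise ValueError("trace must start at t = 0")
        if not np.all(np.isfinite(g)):
            raise ValueError("trace contains non-finite glucose values")
        if np.any(g < 0.0):
            raise ValueError("trace contains negative glucose values")
        object.__setattr__(self, "t_seconds", t)
        object.__setattr__(self, "g_mg_dl", g)

    @property
    def dt(self) -> float:
        return float(self.t_seconds[1] - self.t_seconds[0])

    def __len__(self) -> int:
        return len(self.t_seconds)


@dataclass(frozen=True)
class ExtremaSequence:
    """Alternating local extrema of a trace: (time s, value mg/dL, kind).

    ``kinds`` holds +1 for peaks, -1 for troughs; kinds strictly
    alternate and times strictly increase.
    """

    times: np.ndarray
    values: np.ndarray
    kinds: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.values) == len(self.kinds)):
            raise ValueError("extrema arrays must have equal length")
        if len(self.kinds) > 1:
            if np.any(self.kinds[:-1] == self.kinds[1:]):
                raise ValueError("extrema kinds must alternate")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("extrema times must strictly increase")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[tuple[float, float, int]]:
        return iter(zip(self.times, self.values, self.kinds))

    def peaks(self) -> np.ndarray:
        """Peak values in order."""
        return self.values[self.kinds == 1]

    def peak_times(self) -> np.ndarray:
        return self.times[self.kinds == 1]


def extrema_indices(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and kinds (+1 peak / -1 trough) of interior local extrema.

    Sign changes of the discrete first difference define extrema; runs of
    exactly equal samples (possible on a dense noise-free grid) collapse to
    a single extremum at the plateau midpoint.  Endpoints are never
    extrema.
    """
    v = np.asarray(values, dtype=float)
    d = np.diff(v)
    nz = np.nonzero(d)[0]
    if len(nz) < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    s = np.sign(d[nz]).astype(np.int64)
    change = np.nonzero(s[:-1] != s[1:])[0]
    # plateau spans [nz[a] + 1, nz[a + 1]]; collapse to the midpoint
    idx = (nz[change] + 1 + nz[change + 1]) // 2
    kinds = np.where(s[change] > 0, 1, -1).astype(np.int64)
    return idx.astype(np.int64), kinds


def find_extrema(trace: GlucoseTrace) -> ExtremaSequence:
    """Alternating peak/trough sequence of a dense noise-free trace."""
    idx, kinds = extrema_indices(trace.g_mg_dl)
    return ExtremaSequence(times=trace.t_seconds[idx],
                           values=trace.g_mg_dl[idx], kinds=kinds)


def mgc(trace: GlucoseTrace) -> float:
    """Mean glucose concentration: average of the per-second samples."""
    return float(np.mean(trace.g_mg_dl))


def gv(trace: GlucoseTrace) -> float:
    """Mean absolute glucose change over consecutive extrema (mg/dL)."""
    ext = find_extrema(trace)
    if len(ext) < 2:
        raise GlycemicVariabilityUndefined(
            f"trace has {len(ext)} extrema; GV needs at least 2")
    return float(np.mean(np.abs(np.diff(ext.values))))


def _check_comparable(treated: GlucoseTrace, baseline: GlucoseTrace) -> None:
    if len(treated) != len(baseline) or treated.dt != baseline.dt:
        raise ValueError("treated and baseline traces are on different grids")
    for key in ("patient_id", "nutrition"):
        a, b = treated.meta.get(key), baseline.meta.get(key)
        if a is not None and b is not None and a != b:
            raise ValueError(
                f"provenance mismatch on {key!r}: {a!r} vs {b!r}")


def change_metrics(treated: GlucoseTrace,
                   baseline: GlucoseTrace) -> tuple[float, float]:
    """(change-in-MGC, change-in-GV): treated minus baseline, mg/dL."""
    _check_comparable(treated, baseline)
    return (mgc(treated) - mgc(baseline), gv(treated) - gv(baseline))


def detect_hypoglycemia(trace: GlucoseTrace,
                        threshold: float = HYPOGLYCEMIA_THRESHOLD,
                        ) -> tuple[bool, float]:
    """Flag a hypoglycemic episode (min G <= threshold); report the minimum."""
    g_min = float(np.min(trace.g_mg_dl))
    return g_min <= threshold, g_min


def detect_rebound(treated: GlucoseTrace, baseline: GlucoseTrace) -> bool:
    """Rebound hyperglycemia: first post-injection peak above baseline's.

    Peaks strictly after t = 0 are paired by ordinal index (the injection
    occurs at a shared baseline peak, so the first treated peak corresponds
    to the first baseline peak).
    """
    _check_comparable(treated, baseline)
    tp = find_extrema(treated)
    bp = find_extrema(baseline)
    t_peaks = tp.peaks()[tp.peak_times() > 0] if len(tp) else np.empty(0)
    b_peaks = bp.peaks()[bp.peak_times() > 0] if len(bp) else np.empty(0)
    if len(t_peaks) == 0 or len(b_peaks) == 0:
        raise ReboundUndefined("no post-injection peak in treated or baseline")
    return bool(t_peaks[0] > b_peaks[0])


@dataclass(frozen=True)
class DoseResponseRecord:
    """One experiment cell: patient x preparation x nutrition x dose."""

    patient_id: str
    preparation: str
    nutrition: str
    dose: float
    mgc: float
    gv: float
    d_mgc: float
    d_gv: float
    min_g: float
    hypoglycemia: bool
    rebound: bool
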