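"""Fixed physiological constants of the metabolic response functions.

The two-delay glucose-insulin model expresses glucose production,
utilization, insulin secretion and clearance through seven response
functions f1..f7 whose shape constants are inherited from the standard
ultradian-oscillator tabulation (Sturis/Tolic/Li-Kuang-Mason lineage).
The values live in a flat text file so a corrected table can be swapped
in without touching code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

__all__ = ["MetabolicConstants", "load_constants", "DEFAULT_CONSTANTS_FILE"]

#: names required in a constants file, in canonical order
_FIELD_NAMES = (
    "Rc", "c1", "e1", "Vg", "Ub", "c2", "c3", "Uo", "Uc", "kappa", "c4",
    "Vc", "Etc", "Rg", "c5", "a5", "Vp", "gamma", "c6", "delta", "c7",
    "Sb", "Sc", "tau1_normal", "tau2_normal",
)


@dataclass(frozen=True)
class MetabolicConstants:
    """Shape and rate constants of f1..f7 plus the two distribution volumes.

    Units: rates in mg/min (glucose) or mU/min (insulin), volumes in L,
    concentration scales in mg/L (glucose) or mU/L (insulin).  The glucose
    and insulin state variables are amounts (mg, mU); concentrations are
    obtained by dividing by Vg or Vp.  ``tau1_normal``/``tau2_normal`` are
    the normal-physiology secretion delays (min) used as the center of the
    cohort delay-calibration search.
    """

    Rc: float      # max pancreatic insulin release rate, mU/min
    c1: float      # f1 center, mg/L
    e1: float      # f1 steepness, mg/L
    Vg: float      # glucose distribution volume, L
    Ub: float      # max insulin-independent utilization, mg/min
    c2: float      # f2 scale, mg/L
    c3: float      # f3 scale, mg/L
    Uo: float      # f4 lower bound, mg/min
    Uc: float      # f4 upper bound, mg/min
    kappa: float   # f4 log-sigmoid steepness
    c4: float      # f4 insulin scale, mU/L
    Vc: float      # f4 insulin volume, L
    Etc: float     # f4 exchange-rate x time-constant product, L
    Rg: float      # max hepatic glucose release, mg/min
    c5: float      # f5 center, mU/L
    a5: float      # f5 steepness, L/mU
    Vp: float      # plasma insulin volume, L
    gamma: float   # f6 decay scale
    c6: float      # f6 centering
    delta: float   # f7 steepness
    c7: float      # f7 center (f3-scaled glucose units)
    Sb: float      # f7 high-glucose asymptote, mg/min
    Sc: float      # f7 low-glucose asymptote, mg/min
    tau1_normal: float  # min
    tau2_normal: float  # min

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"constant {f.name} is not finite: {v!r}")
        for name in ("Rc", "Vg", "Vp", "Vc", "Ub", "Rg", "e1", "c2", "c3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be strictly positive")
        if self.Uc <= self.Uo:
            raise ValueError("f4 bounds require Uc > Uo")
        if self.Sc == self.Sb:
            raise ValueError("f7 bounds require Sc != Sb")

    @property
    def mg_per_dl(self) -> float:
        """Conversion divisor: glucose amount (mg) -> concentration (mg/dL)."""
        return self.Vg * 10.0


def _default_path() -> Path:
    return Path(str(resources.files("glycsim").joinpath("data/ultradian_constants.txt")))


DEFAULT_CONSTANTS_FILE = _default_path()


def load_constants(path: str | Path | None = None) -> MetabolicConstants:
    """Parse a flat constants file into a :class:`MetabolicConstants`.

    Each non-comment line is ``name value unit [# note]``.  The parse is
    strict: unknown names, duplicates and missing names are all errors, so
    a truncated or mistyped table cannot silently change the model.
    """
    p = Path(path) if path is not None else _default_path()
    seen: dict[str, float] = {}
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(
                f"{p.name}:{lineno}: expected 'name value unit', got {raw!r}")
        name, value = parts[0], parts[1]
        if name not in _FIELD_NAMES:
            raise ValueError(f"{p.name}:{lineno}: unknown constant {name!r}")
        if name in seen:
            raise ValueError(f"{p.name}:{lineno}: duplicate constant {name!r}")
        try:
            seen[name] = float(value)
        except ValueError as exc:
            raise ValueError(
                f"{p.name}:{lineno}: bad value for {name}: {value!r}") from exc
    missing = [n for n in _FIELD_NAMES if n not in seen]
    if missing:
        raise ValueError(f"{p.name}: missing constants: {', '.join(missing)}")
    return MetabolicConstants(**seen)
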