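"""Plot glucose traces and dose-response curves (optional figures).

Produces, under results/figures/: baseline-vs-treated glucose traces for
the mild-IR and severe-IR borderline-clearance patients after 5 U of
Lispro (the rebound contrast), and the change-in-MGC / change-in-GV
dose-response curves for the borderline-IC patients at goal nutrition.
"""

import sys
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from glycsim import dde
from glycsim.cohort import cohort_from_manifest
from glycsim.constants import load_constants
from glycsim.inputs import GOAL_NUTRITION, InsulinInjection

OUT = Path(__file__).resolve().parent.parent / "results"
FIG = OUT / "figures"


def trace_pair(patient, consts, settings, dose):
    buf, _ = dde.burn_in_to_oscillation(patient.params, consts,
                                        GOAL_NUTRITION, settings)
    base = dde.integrate(patient.params, consts, settings, GOAL_NUTRITION,
                         history=buf).glucose_trace(settings.measurement)
    trt = dde.integrate(patient.params, consts, settings, GOAL_NUTRITION,
                        history=buf,
                        injection=InsulinInjection("lispro", dose),
                        ).glucose_trace(settings.measurement)
    return base, trt


def main() -> int:
    manifest = OUT / "cohort_manifest.csv"
    records = OUT / "dose_response_records.csv"
    if not (manifest.exists() and records.exists()):
        print("run analysis/01 and analysis/02 first", file=sys.stderr)
        return 1
    consts = load_constants()
    settings = dde.IntegrationSettings()
    cohort = {p.id: p for p in cohort_from_manifest(pd.read_csv(manifest))}
    FIG.mkdir(parents=True, exist_ok=True)

    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    for ax, pid, title in ((axes[0], "P1", "mild IR"),
                           (axes[1], "P5", "severe IR")):
        base, trt = trace_pair(cohort[pid], consts, settings, 5.0)
        t = base.t_seconds / 60.0
        ax.plot(t, base.g_mg_dl, lw=1, label="baseline (0 U)")
        ax.plot(t, trt.g_mg_dl, lw=1, label="5 U SQ Lispro")
        ax.set(title=f"{pid}: {title}, mild IDp, borderline IC",
               xlabel="time after injection (min)")
        ax.legend(frameon=False)
    axes[0].set_ylabel("glucose (mg/dL)")
    fig.tight_layout()
    fig.savefig(FIG / "lispro_5U_traces.png", dpi=150)

    df = pd.read_csv(records)
    sel = df[(df.nutrition == "goal")
             & df.patient_id.isin(["P1", "P3", "P5", "P7"])]
    fig, axes = plt.subplots(2, 2, figsize=(11, 7), sharex=True)
    for col, prep in enumerate(("lispro", "regular")):
        sub = sel[sel.preparation == prep]
        for pid, cell in sub.groupby("patient_id"):
            cell = cell.sort_values("dose_U")
            axes[0][col].plot(cell.dose_U, cell.d_gv, marker=".", label=pid)
            axes[1][col].plot(cell.dose_U, cell.d_mgc, marker=".", label=pid)
        axes[0][col].set_title(f"SQ {prep}, borderline IC, goal nutrition")
        axes[1][col].set_xlabel("dose (U)")
    axes[0][0].set_ylabel("change in GV (mg/dL)")
    axes[1][0].set_ylabel("change in MGC (mg/dL)")
    for ax in axes.flat:
        ax.axhline(0, color="k", lw=0.5)
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(FIG / "dose_response_borderline_ic.png", dpi=150)
    print(f"wrote figures under {FIG}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
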