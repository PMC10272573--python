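"""Longitudinal MRD assembly: clearance, molecular relapse, lead time.

A patient timeline is an ordered series of per-sample MRD readouts at
clinically anchored timepoints (diagnosis, after treatment cycle 1,
interim and final evaluation, yearly follow-up, relapse treatment).
``classify_course`` condenses the series into the clinically meaningful
flags; ``render_report`` emits the tabular report and an optional
VAF-versus-time plot with FPR and LOD guide lines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ddpcr import SampleQuant

__all__ = [
    "TimepointResult",
    "PatientTimeline",
    "CourseSummary",
    "classify_course",
    "render_report",
    "PLOT_FLOOR",
]

NOT_ASSESSED = "not_assessed"
# Zero VAF/FPR are floored to 0.001% on log-scale plots only; stored
# values are never modified.
PLOT_FLOOR = 1e-5

FOLLOWUP_PREFIX = "follow_up"


@dataclass
class TimepointResult:
    sample_id: str
    label: str  # diagnosis, post_cycle_1, interim, final, follow_up_n, ...
    day: int
    quant: SampleQuant | None = None

    @property
    def mrd_status(self) -> str:
        if self.quant is None:
            return NOT_ASSESSED
        return "positive" if self.quant.mrd_positive else "negative"


@dataclass
class PatientTimeline:
    patient_id: str
    results: list[TimepointResult]
    clinical_events: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.results = sorted(self.results, key=lambda r: r.day)
        days = [r.day for r in self.results]
        if len(set(days)) != len(days):
            raise ValueError("timepoints must have strictly increasing days")

    def find(self, label: str) -> TimepointResult | None:
        for r in self.results:
            if r.label == label:
                return r
        return None


@dataclass
class CourseSummary:
    patient_id: str
    clearance_after_cycle1: bool | str  # bool or 'not_assessed'
    ctdna_negative_at_final: bool | str
    molecular_relapse: str | None  # timepoint label
    molecular_relapse_day: int | None
    lead_time_days: int | None
    refractory: bool = False


def classify_course(timeline: PatientTimeline) -> CourseSummary:
    """Condense a timeline into course-level flags.

    * clearance_after_cycle1: diagnosis positive and post-cycle-1
      negative; 'not_assessed' when either timepoint is missing or the
      diagnosis sample was already negative (clearance is undefined
      without a detectable baseline).
    * molecular_relapse: first positive timepoint after a negative
      final evaluation; a course that never turns negative at final is
      refractory, not relapsing.
    * lead_time_days: clinical relapse day minus molecular relapse day,
      when both exist.
    """
    diagnosis = timeline.find("diagnosis")
    post_c1 = timeline.find("post_cycle_1")
    final = timeline.find("final")

    if (diagnosis is None or post_c1 is None
            or diagnosis.mrd_status == NOT_ASSESSED
            or post_c1.mrd_status == NOT_ASSESSED
            or diagnosis.mrd_status == "negative"):
        clearance = NOT_ASSESSED
    else:
        clearance = (diagnosis.mrd_status == "positive"
                     and post_c1.mrd_status == "negative")

    if final is None or final.mrd_status == NOT_ASSESSED:
        negative_at_final = NOT_ASSESSED
    else:
        negative_at_final = final.mrd_status == "negative"

    molecular_relapse = None
    relapse_day = None
    refractory = negative_at_final is False
    if negative_at_final is True:
        for r in timeline.results:
            if r.day > final.day and r.mrd_status == "positive":
                molecular_relapse = r.label
                relapse_day = r.day
                break

    lead_time = None
    clinical_relapse = timeline.clinical_events.get("relapse")
    if relapse_day is not None and clinical_relapse is not None:
        lead_time = clinical_relapse - relapse_day

    return CourseSummary(
        patient_id=timeline.patient_id,
        clearance_after_cycle1=clearance,
        ctdna_negative_at_final=negative_at_final,
        molecular_relapse=molecular_relapse,
        molecular_relapse_day=relapse_day,
        lead_time_days=lead_time,
        refractory=refractory)


def timeline_table(timeline: PatientTimeline) -> pd.DataFrame:
    """One row per timepoint x target with VAF, FPR, LOD and status."""
    rows = []
    for r in timeline.results:
        if r.quant is None:
            continue
        for tid, readout in r.quant.targets.items():
            rows.append({
                "patient_id": timeline.patient_id,
                "sample_id": r.sample_id,
                "timepoint": r.label,
                "day": r.day,
                "target": tid,
                "vaf": readout.vaf.value,
                "vaf_route": readout.vaf.route.value,
                "fpr": readout.fpr,
                "lod": r.quant.lod,
                "below_lod": readout.below_lod,
                "k_positive": readout.quant.k_positive,
                "copies_per_ml": readout.copies_per_ml_plasma,
                "target_positive": readout.positivity.positive,
                "mrd_status": r.mrd_status,
            })
    columns = ["patient_id", "sample_id", "timepoint", "day", "target",
               "vaf", "vaf_route", "fpr", "lod", "below_lod", "k_positive",
               "copies_per_ml", "target_positive", "mrd_status"]
    return pd.DataFrame(rows, columns=columns)


def render_report(
    timeline: PatientTimeline,
    outdir: str | Path,
    plot: bool = False,
) -> dict:
    """Write timeline.tsv and summary.json (and optionally a VAF plot).

    The TSV stores measured values untouched; only the plot floors zero
    VAF/FPR to 0.001% so they remain visible on the log scale.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = timeline_table(timeline)
    table.to_csv(outdir / "timeline.tsv", sep="\t", index=False)
    summary = classify_course(timeline)
    doc = {
        "patient_id": summary.patient_id,
        "clearance_after_cycle1": summary.clearance_after_cycle1,
        "ctdna_negative_at_final": summary.ctdna_negative_at_final,
        "molecular_relapse": summary.molecular_relapse,
        "molecular_relapse_day": summary.molecular_relapse_day,
        "lead_time_days": summary.lead_time_days,
        "refractory": summary.refractory,
        "n_timepoints": len(timeline.results),
    }
    (outdir / "summary.json").write_text(json.dumps(doc, indent=2) + "\n")
    if plot and not table.empty:
        _plot_timeline(timeline, table, outdir / "timeline.svg")
    return doc


def _floor(x: float) -> float:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return PLOT_FLOOR
    return max(x, PLOT_FLOOR)


def _plot_timeline(timeline: PatientTimeline, table: pd.DataFrame,
                   path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for tid, grp in table.groupby("target"):
        ax.plot(grp["day"], [_floor(v) for v in grp["vaf"]],
                marker="o", label=tid)
        ax.axhline(_floor(grp["fpr"].mean()), linestyle="--", linewidth=0.8)
    ax2 = ax.twinx()
    lod = table.drop_duplicates("day")
    ax2.plot(lod["day"], [_floor(v) for v in lod["lod"]],
             color="grey", linestyle=":", label="LOD")
    ax2.set_yscale("log")
    ax2.set_ylabel("theoretical LOD")
    ax.set_yscale("log")
    ax.set_xlabel("day")
    ax.set_ylabel("VAF")
    ax.set_title(f"{timeline.patient_id} ctDNA course")
    ax.legend(fontsize=8)
    relapse = timeline.clinical_events.get("relapse")
    if relapse is not None:
        ax.axvline(relapse, color="red", linewidth=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
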