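"""Commissioning orchestration: phantom cohorts, the three-phase validation
run, qualitative (Likert) records, and clinician-edit comparison.

The commissioning run mirrors the clinical validation flow on synthetic
cohorts: segment every case with the trained network, build a STAPLE consensus
from the simulated manual observers, score every contour (manual and auto)
against the consensus with MSD/DSC/HD95, generate a CAA-sparing synthetic plan
per contour and evaluate the dose-metric panel on the consensus CAA, then test
the contour-type effect per metric with the random-intercept mixed model. The
output tables mirror the commissioning report layout: one row per metric with
the auto mean, manual mean, manual interobserver SD (mean over patients) and
the likelihood-ratio p-value.

Everything is deterministic under a fixed seed; a repeated run produces
byte-identical report tables.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .consensus import binarize_consensus, staple
from .dosimetry import DEFAULT_PANEL, plan_metric_panel
from .errors import ValidationError
from .geometry import contour_metrics
from .interobserver_stats import (
    fit_lmm,
    lrt_contour_type,
    multiplicity_adjust,
    observer_sd_summary,
)
from .postprocess import assemble_caa
from .phantom import (
    ObserverModel,
    PhantomSpec,
    generate_dose_grid,
    generate_thorax_phantom,
    simulate_observer_contour,
)
from .preprocess import localize_heart
from .segmenter import DESK_CROP_SIZE, segment_case
from .volume_io import (
    CAA_MEMBERS,
    StructureSet,
    read_structure_set,
    read_volume,
    write_structure_set,
    write_volume,
)

#: The 1-5 qualitative contour-quality scale used at commissioning review.
LIKERT_LABELS = {
    1: "No output/software crash",
    2: "Not useful/needs contouring from scratch",
    3: "Useful/significant changes needed",
    4: "Good/minor edits only",
    5: "Very good/no changes needed",
}

#: Default simulated observer panel: three raters with small opposite
#: systematic biases and 1.5-2 mm smooth boundary noise.
DEFAULT_OBSERVERS = (
    ObserverModel(bias_mm=1.0, sd_mm=1.5),
    ObserverModel(bias_mm=-1.0, sd_mm=1.5),
    ObserverModel(bias_mm=0.0, sd_mm=2.0),
)

GEOMETRIC_METRICS = ("msd_mm", "dsc", "hd95_mm")


@dataclass(frozen=True)
class LikertRecord:
    case_id: str
    score: int
    label: str
    rater: str = ""
    timestamp: str | None = None


def record_likert(case_id: str, score: int, rater: str = "", timestamp: str | None = None) -> LikertRecord:
    """Validate a 1-5 quality score and attach its canonical label."""
    if not isinstance(score, (int, np.integer)) or isinstance(score, bool):
        raise ValidationError(f"Likert score must be an integer 1-5, got {score!r}")
    if score not in LIKERT_LABELS:
        raise ValidationError(f"Likert score must be 1-5, got {score}")
    return LikertRecord(case_id=str(case_id), score=int(score), label=LIKERT_LABELS[int(score)], rater=rater, timestamp=timestamp)


def summarize_likert(records: list[LikertRecord]) -> dict:
    """Per-score fractions (summing to 1) plus the 'Good or better' fraction (score >= 4)."""
    if not records:
        raise ValidationError("cannot summarise an empty set of Likert records")
    n = len(records)
    fractions = {s: sum(r.score == s for r in records) / n for s in LIKERT_LABELS}
    return {
        "n": n,
        "fractions": fractions,
        "good_or_better": sum(r.score >= 4 for r in records) / n,
    }


def read_likert_csv(path: str | Path) -> list[LikertRecord]:
    """Ingest clinician ratings from CSV (columns: case_id, score[, rater, timestamp])."""
    df = pd.read_csv(path)
    return [
        record_likert(
            row["case_id"],
            int(row["score"]),
            rater=str(row.get("rater", "")),
            timestamp=str(row["timestamp"]) if "timestamp" in row and pd.notna(row["timestamp"]) else None,
        )
        for _, row in df.iterrows()
    ]


def compare_edited(auto_mask: np.ndarray, edited_mask: np.ndarray, spacing) -> dict[str, float]:
    """MSD/DSC/HD95 between an auto-contour and its clinician-edited version."""
    m = contour_metrics(auto_mask, edited_mask, spacing)
    return {"msd_mm": m["msd_mm"], "dsc": m["dsc"], "hd95_mm": m["hd95_mm"]}


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def build_cohort(
    out_dir: str | Path,
    n_cases: int,
    seed: int = 0,
    spec_factory=PhantomSpec.desk,
    observers: tuple[ObserverModel, ...] = DEFAULT_OBSERVERS,
) -> Path:
    """Generate a phantom cohort with simulated manual observers on disk.

    Layout: ``case_XXX/ct.nii.gz`` plus structure-set manifests for ``truth``
    and ``obs1..obsJ`` (each observer re-draws every CAA substructure with
    their own bias/noise; their CAA is the union of their substructures).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case_streams = np.random.SeedSequence(seed).spawn(n_cases)
    for c, stream in enumerate(case_streams):
        case_dir = out_dir / f"case_{c:03d}"
        case_dir.mkdir(exist_ok=True)
        seeds = stream.generate_state(1 + len(observers) * len(CAA_MEMBERS)) % (2**31 - 1)
        spec = spec_factory(seed=int(seeds[0]))
        ct, truth = generate_thorax_phantom(spec)
        write_volume(ct, case_dir / "ct.nii.gz")
        write_structure_set(truth, case_dir)
        si = 1
        for j, obs in enumerate(observers, start=1):
            obs_set = StructureSet(grid=truth.grid, structures={}, observer=f"obs{j}")
            for name in CAA_MEMBERS:
                model = dataclasses.replace(obs, seed=int(seeds[si]))
                si += 1
                obs_set.add(name, simulate_observer_contour(truth[name], model, spec.spacing))
            obs_set.add("CAA", assemble_caa(obs_set))
            write_structure_set(obs_set, case_dir)
    return out_dir


# ---------------------------------------------------------------------------
# commissioning run
# ---------------------------------------------------------------------------


@dataclass
class CommissioningReport:
    """Bundle of the commissioning outputs (tables are pandas DataFrames)."""

    geometric_records: pd.DataFrame  # long format, feeds the mixed model
    dose_records: pd.DataFrame
    geometric_table: pd.DataFrame  # per-metric summary (report layout)
    dose_table: pd.DataFrame
    gross_failures: list[str]
    likert_summary: dict | None
    failed_stages: dict = field(default_factory=dict)
    out_dir: Path | None = None


def _summary_table(records: pd.DataFrame, metrics, adjust: bool) -> pd.DataFrame:
    rows = []
    p_values = []
    for metric in metrics:
        sub = records[records["metric"] == metric]
        auto_mean = float(sub[sub.contour_type == "auto"]["value"].mean())
        manual = sub[sub.contour_type == "manual"]
        manual_mean = float(manual.groupby("patient")["value"].mean().mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            manual_sd = observer_sd_summary(records, metric)
        full = fit_lmm(records, metric, use_type_effect=True)
        reduced = fit_lmm(records, metric, use_type_effect=False)
        lrt = lrt_contour_type(full, reduced)
        p_values.append(lrt.p_value)
        rows.append(
            {
                "metric": metric,
                "auto_mean": auto_mean,
                "manual_mean": manual_mean,
                "manual_sd_mean_over_patients": manual_sd,
                "mixed_effects_p": lrt.p_value,
            }
        )
    table = pd.DataFrame(rows)
    if adjust and len(rows) > 1:
        table["p_bonferroni"] = multiplicity_adjust(p_values, "bonferroni")
        table["p_holm"] = multiplicity_adjust(p_values, "holm")
    return table


def run_commissioning(
    cohort_dir: str | Path,
    model,
    out_dir: str | Path | None = None,
    seed: int = 0,
    crop_size=DESK_CROP_SIZE,
    panel=DEFAULT_PANEL,
    prescription_gy: float = 55.0,
    caa_limit_gy: float = 19.5,
    gross_failure_mm: float = 50.0,
) -> CommissioningReport:
    """Run the full commissioning validation over a phantom cohort.

    Per case: auto-contour -> STAPLE consensus of the manual observers ->
    geometric metrics of every contour against the consensus -> one synthetic
    CAA-sparing plan per contour, scored on the consensus CAA -> mixed-model
    contour-type tests. Stage failures are recorded per case and the run
    continues. If ``cohort_dir/likert.csv`` exists, its ratings are summarised.
    """
    cohort_dir = Path(cohort_dir)
    case_dirs = sorted(d for d in cohort_dir.iterdir() if d.is_dir() and d.name.startswith("case_"))
    if not case_dirs:
        raise ValidationError(f"no case_* directories under {cohort_dir}")
    dose_seeds = np.random.SeedSequence(seed).generate_state(len(case_dirs))

    geo_rows, dose_rows, gross_failures = [], [], []
    failed: dict[str, str] = {}
    for case_idx, case_dir in enumerate(case_dirs):
        patient = case_dir.name
        ct = read_volume(case_dir / "ct.nii.gz")
        truth = read_structure_set(case_dir / "structures_truth.json")
        observers = []
        j = 1
        while (case_dir / f"structures_obs{j}.json").exists():
            observers.append(read_structure_set(case_dir / f"structures_obs{j}.json"))
            j += 1
        if len(observers) < 2:
            failed[patient] = "fewer than 2 manual observers"
            continue

        try:
            auto = segment_case(ct, model, crop_size=crop_size)
        except Exception as exc:  # segmentation must not sink the whole run
            failed[patient] = f"segmentation: {exc}"
            continue

        # gross-failure proxy: empty CAA, or CAA centroid far from the heart
        auto_caa = auto["CAA"]
        if not auto_caa.any():
            gross_failures.append(patient)
        else:
            centre = np.asarray(localize_heart(ct), dtype=float)
            centroid = np.asarray(ndimage.center_of_mass(auto_caa))
            dist = np.linalg.norm((centroid - centre) * np.asarray(ct.spacing))
            if dist > gross_failure_mm:
                gross_failures.append(patient)

        try:
            consensus = binarize_consensus(
                staple([o["CAA"] for o in observers], spacing=ct.spacing)
            )
        except Exception as exc:
            failed[patient] = f"consensus: {exc}"
            continue

        contours = [(o.observer, "manual", o["CAA"]) for o in observers]
        contours.append(("auto", "auto", auto_caa))
        for observer, ctype, mask in contours:
            try:
                m = contour_metrics(mask, consensus, ct.spacing)
            except Exception as exc:
                failed[f"{patient}/{observer}"] = f"geometric metrics: {exc}"
                continue
            for metric in GEOMETRIC_METRICS:
                geo_rows.append(
                    {
                        "patient": patient,
                        "contour_type": ctype,
                        "observer": observer,
                        "metric": metric,
                        "value": m[metric],
                    }
                )

        # dosimetric arm: one plan per contour (same per-case dose seed so the
        # plans differ only through the CAA used for optimisation), all scored
        # on the consensus CAA
        eval_set = StructureSet(grid=truth.grid, structures={}, observer="STAPLE")
        for name in truth.names:
            if name != "CAA":
                eval_set.add(name, truth[name])
        eval_set.add("CAA", consensus)
        for observer, ctype, mask in contours:
            try:
                plan_set = StructureSet(grid=truth.grid, structures={}, observer=observer)
                for name in truth.names:
                    if name != "CAA":
                        plan_set.add(name, truth[name])
                plan_set.add("CAA", mask)
                dose = generate_dose_grid(
                    plan_set,
                    prescription_gy=prescription_gy,
                    caa_limit_gy=caa_limit_gy,
                    seed=int(dose_seeds[case_idx] % (2**31 - 1)),
                )
                table = plan_metric_panel(dose, eval_set, panel=panel, patient=patient, observer=observer)
            except Exception as exc:
                failed[f"{patient}/{observer}"] = f"dosimetry: {exc}"
                continue
            for _, row in table.iterrows():
                dose_rows.append(
                    {
                        "patient": patient,
                        "contour_type": ctype,
                        "observer": observer,
                        "metric": row["metric"],
                        "value": row["value"],
                    }
                )

    geo_records = pd.DataFrame(geo_rows)
    dose_records = pd.DataFrame(dose_rows)
    geo_table = _summary_table(geo_records, GEOMETRIC_METRICS, adjust=False)
    dose_metrics = [f"{s} {m}" for s, m in panel]
    dose_table = _summary_table(dose_records, dose_metrics, adjust=True)

    likert_summary = None
    likert_path = cohort_dir / "likert.csv"
    if likert_path.exists():
        likert_summary = summarize_likert(read_likert_csv(likert_path))

    report = CommissioningReport(
        geometric_records=geo_records,
        dose_records=dose_records,
        geometric_table=geo_table,
        dose_table=dose_table,
        gross_failures=gross_failures,
        likert_summary=likert_summary,
        failed_stages=failed,
    )
    if out_dir is not None:
        report.out_dir = write_report(report, out_dir)
    return report


def write_report(report: CommissioningReport, out_dir: str | Path) -> Path:
    """Write the report bundle (CSV tables + JSON summary) deterministically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.geometric_records.to_csv(out_dir / "geometric_metrics.csv", index=False, float_format=fmt)
    report.dose_records.to_csv(out_dir / "dose_metrics.csv", index=False, float_format=fmt)
    report.geometric_table.to_csv(out_dir / "table_geometric.csv", index=False, float_format=fmt)
    report.dose_table.to_csv(out_dir / "table_dose.csv", index=False, float_format=fmt)
    summary = {
        "n_cases": int(report.geometric_records["patient"].nunique()) if not report.geometric_records.empty else 0,
        "gross_failures": report.gross_failures,
        "failed_stages": report.failed_stages,
        "likert": report.likert_summary,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out_dir
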