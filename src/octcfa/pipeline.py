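"""End-to-end orchestration: simulate -> quantify -> call -> agree -> outcomes.

`run_pipeline` executes the whole chain for both analysis scopes
(target lesion and complete imaged segment) from a single `CohortConfig`,
producing tidy tables, machine-readable reports and a run manifest whose
exclusion accounting always reconciles. `replay_from_tables` runs the
agreement and outcome stages on externally supplied call/survival tables
with the same code path, so printed study tables can be re-analysed
without masks.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as _io
from .agreement import (
    build_contingency,
    cohen_kappa,
    diagnostic_metrics,
    percent_agreement,
)
from .calling import (
    TCFACall,
    Thresholds,
    call_patient,
    call_unit_tcfa,
    frame_excluded,
)
from .config import CohortConfig
from .frame import PlaqueMetrics
from .outcomes import (
    SurvivalRecord,
    binary_cstat,
    binary_outcome_at_2y,
    cox_univariable,
    delong_paired_test,
    kaplan_meier,
    logrank,
    records_to_frame,
)
from .quantify import quantify_frame
from .synthetic import (
    Cohort,
    Pullback,
    generate_cohort,
    generate_pullback,
    simulate_corelab_reads,
    simulate_survival,
)


@dataclass
class RunManifest:
    rng_seed: int
    config: dict
    counts: Dict[str, int] = field(default_factory=dict)
    digests: Dict[str, str] = field(default_factory=dict)
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    exclusion_log: List[dict] = field(default_factory=list)

    def reconcile(self) -> None:
        c = self.counts
        checks = [
            ("frames_total", "frames_retained", "frames_excluded"),
            ("lesions_total", "lesions_evaluable", "lesions_excluded"),
            ("pullbacks_total", "pullbacks_evaluable", "pullbacks_excluded"),
            (
                "patients_total",
                "patients_target_analysis",
                "patients_target_dropped",
            ),
            (
                "patients_total",
                "patients_segment_analysis",
                "patients_segment_dropped",
            ),
        ]
        for total, kept, dropped in checks:
            if c.get(total, 0) != c.get(kept, 0) + c.get(dropped, 0):
                raise AssertionError(
                    f"manifest does not reconcile: {total} != {kept} + {dropped}"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "rng_seed": self.rng_seed,
                "config": self.config,
                "counts": self.counts,
                "digests": self.digests,
                "stage_seconds": {
                    k: round(v, 3) for k, v in self.stage_seconds.items()
                },
                "exclusion_log": self.exclusion_log,
            },
            indent=1,
            default=str,
        )


@dataclass
class RunResult:
    manifest: RunManifest
    metrics: pd.DataFrame
    calls: pd.DataFrame
    survival: pd.DataFrame
    agreement: dict
    outcomes: dict
    truth: pd.DataFrame


def quantify_pullback_frames(
    pullback: Pullback,
    thresholds: Thresholds,
    memo: Optional[Dict[str, PlaqueMetrics]] = None,
) -> pd.DataFrame:
    """Per-frame metrics table for one pullback.

    Frame exclusion (artefact rule) is applied here; geometric
    quantification is memoised across frames that share a producer-declared
    ``geometry_key`` (identical label arrays).
    """
    if memo is None:
        memo = {}
    rows = []
    for fr in pullback.frames:
        excluded = frame_excluded(fr, thresholds)
        if excluded:
            m = PlaqueMetrics.non_analyzable(fr.frame_index)
        elif fr.geometry_key is not None and fr.geometry_key in memo:
            m = memo[fr.geometry_key]
        else:
            m = quantify_frame(fr)
            if fr.geometry_key is not None:
                memo[fr.geometry_key] = m
        rows.append(
            (
                pullback.pullback_id,
                fr.frame_index,
                m.lipid_arc_deg if m.analyzable else np.nan,
                m.min_cap_um if (m.analyzable and m.min_cap_um is not None) else np.nan,
                bool(m.analyzable) and not excluded,
                excluded,
            )
        )
    return pd.DataFrame(rows, columns=_io.METRICS_COLUMNS)


def call_units_for_pullback(
    pullback: Pullback, metrics: pd.DataFrame, thresholds: Thresholds
) -> List[TCFACall]:
    """Lesion-level calls plus the whole-pullback (complete-segment) call."""
    met = metrics.sort_values("frame_index")
    arc = met["lipid_arc_deg"].to_numpy(float)
    cap = met["min_cap_um"].to_numpy(float)
    analyzable = met["analyzable"].to_numpy(bool)
    with np.errstate(invalid="ignore"):
        # vectorised frame_qualifies: NaN cap (absent) never qualifies
        qualifies = (
            analyzable & (arc >= thresholds.arc_min_deg) & (cap < thresholds.cap_max_um)
        )
    excluded = met["excluded"].to_numpy(dtype=bool)

    calls: List[TCFACall] = []
    for les in pullback.spec.lesions:
        s, e = les.frame_span
        calls.append(
            call_unit_tcfa(
                qualifies[s:e],
                thresholds,
                scope="target_lesion",
                unit_id=les.lesion_id,
                excluded_flags=excluded[s:e],
                frame_indices=np.arange(s, e),
            )
        )
    calls.append(
        call_unit_tcfa(
            qualifies,
            thresholds,
            scope="complete_segment",
            unit_id=pullback.pullback_id,
            excluded_flags=excluded,
        )
    )
    return calls


def agreement_report(ai: np.ndarray, ref: np.ndarray) -> dict:
    table = build_contingency(ai, ref)
    agree_pos, agree_neg, overall = percent_agreement(table)
    out = {
        "n": table.n,
        "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "percent_agree_positive": 100 * agree_pos,
        "percent_agree_negative": 100 * agree_neg,
        "percent_agree_overall": 100 * overall,
    }
    try:
        kap = cohen_kappa(table)
        out.update(
            kappa=kap.kappa, kappa_se=kap.se, kappa_ci95=list(kap.ci95)
        )
    except ZeroDivisionError as exc:  # degenerate marginals at tiny n
        out.update(kappa=None, kappa_error=str(exc))
    return out


def _cox_block(sub: pd.DataFrame, exposure_col: str) -> dict:
    times = sub["time_days"].to_numpy(float)
    events = sub["event"].to_numpy(bool)
    expo = sub[exposure_col].to_numpy(bool)
    out: dict = {
        "n": int(len(sub)),
        "n_exposed": int(expo.sum()),
        "events_exposed": int(events[expo].sum()),
        "events_unexposed": int(events[~expo].sum()),
    }
    stat, p = logrank(times, events, expo)
    out["logrank_chi2"] = stat
    out["logrank_p"] = p
    cox = cox_univariable(times, events, expo)
    out["hr"] = cox.hr
    out["hr_ci95"] = list(cox.ci95)
    out["hr_p"] = cox.p
    out["converged"] = cox.converged

    records = [
        SurvivalRecord(
            patient_id=str(r.patient_id),
            time_days=float(r.time_days),
            event=bool(r.event),
            event_type=str(r.event_type) if bool(r.event) else "none",
        )
        for r in sub.itertuples()
    ]
    kept, outcome, dropped = binary_outcome_at_2y(records)
    kept_ids = {r.patient_id for r in kept}
    mask = sub["patient_id"].astype(str).isin(kept_ids).to_numpy()
    cstat, ci = binary_cstat(expo[mask], outcome)
    out["cstat"] = cstat
    out["cstat_ci95"] = list(ci)
    out["cstat_n"] = int(mask.sum())
    out["cstat_excluded_short_followup"] = dropped
    return out


def outcome_report(survival: pd.DataFrame, exposure_cols: List[str]) -> dict:
    """Cox/log-rank/KM/C-statistic block per exposure + paired DeLong tests."""
    report: dict = {"exposures": {}, "delong": {}, "km_curves": {}}
    for col in exposure_cols:
        sub = survival.dropna(subset=[col]).copy()
        sub[col] = sub[col].astype(bool)
        try:
            report["exposures"][col] = _cox_block(sub, col)
        except ValueError as exc:
            # degenerate cohort (e.g. no events at tiny n): report why
            report["exposures"][col] = {"error": str(exc), "n": int(len(sub))}
        for flag, name in ((True, "exposed"), (False, "unexposed")):
            grp = sub[sub[col] == flag]
            if len(grp) == 0:
                continue
            km = kaplan_meier(
                grp["time_days"].to_numpy(float), grp["event"].to_numpy(bool)
            )
            report["km_curves"][f"{col}:{name}"] = km.to_dict(orient="list")

    for col_a, col_b in zip(exposure_cols, exposure_cols[1:]):
        pair = survival.dropna(subset=[col_a, col_b]).copy()
        records = [
            SurvivalRecord(
                patient_id=str(r.patient_id),
                time_days=float(r.time_days),
                event=bool(r.event),
                event_type=str(r.event_type) if bool(r.event) else "none",
            )
            for r in pair.itertuples()
        ]
        kept, outcome, _ = binary_outcome_at_2y(records)
        kept_ids = {r.patient_id for r in kept}
        mask = pair["patient_id"].astype(str).isin(kept_ids).to_numpy()
        try:
            diff, z, p = delong_paired_test(
                pair[col_a].to_numpy(float)[mask],
                pair[col_b].to_numpy(float)[mask],
                outcome,
            )
            report["delong"][f"{col_a}_vs_{col_b}"] = {"diff": diff, "z": z, "p": p}
        except ValueError as exc:
            report["delong"][f"{col_a}_vs_{col_b}"] = {"error": str(exc)}

    return report


def npv_report(survival: pd.DataFrame, exposure_col: str) -> dict:
    """Negative predictive value of an exposure for the 2-year outcome."""
    sub = survival.dropna(subset=[exposure_col]).copy()
    records = [
        SurvivalRecord(
            patient_id=str(r.patient_id),
            time_days=float(r.time_days),
            event=bool(r.event),
            event_type=str(r.event_type) if bool(r.event) else "none",
        )
        for r in sub.itertuples()
    ]
    kept, outcome, _ = binary_outcome_at_2y(records)
    kept_ids = {r.patient_id for r in kept}
    mask = sub["patient_id"].astype(str).isin(kept_ids).to_numpy()
    expo = sub[exposure_col].to_numpy(bool)[mask]
    table = build_contingency(expo, outcome)
    metrics = diagnostic_metrics(table)
    npv = metrics["npv"]
    return {
        "npv_percent": 100 * npv["estimate"],
        "npv_ci95_percent": [100 * v for v in npv["ci95"]],
        "event_free_unexposed": npv["numerator"],
        "unexposed": npv["denominator"],
        "all_metrics": metrics,
    }


def run_pipeline(
    config: CohortConfig,
    thresholds: Optional[Thresholds] = None,
    outdir=None,
) -> RunResult:
    """Execute the full synthetic study for both scopes; see module docs."""
    if thresholds is None:
        thresholds = Thresholds()
    manifest = RunManifest(rng_seed=config.rng_seed, config=vars(config).copy())
    t0 = time.time()

    cohort = generate_cohort(config, thresholds)
    manifest.stage_seconds["simulate_specs"] = time.time() - t0

    # quantify + call, streaming one pullback at a time
    t0 = time.time()
    metrics_parts: List[pd.DataFrame] = []
    unit_calls: Dict[str, TCFACall] = {}
    pb_of_lesion: Dict[str, str] = {}
    for pb_id in sorted(cohort.pullbacks):
        pb = generate_pullback(cohort.pullbacks[pb_id], config)
        met = quantify_pullback_frames(pb, thresholds)
        metrics_parts.append(met)
        for call in call_units_for_pullback(pb, met, thresholds):
            unit_calls[call.unit_id] = call
            if call.scope == "target_lesion":
                pb_of_lesion[call.unit_id] = pb_id
    metrics = pd.concat(metrics_parts, ignore_index=True)
    manifest.stage_seconds["quantify_and_call"] = time.time() - t0

    # reference reads + patient aggregation
    t0 = time.time()
    corelab = simulate_corelab_reads(list(cohort.lesions.values()), config, thresholds)

    call_rows = []
    patient_rows = []
    for pat in cohort.patients:
        lesion_calls = [unit_calls[l] for l in pat.lesion_ids]
        pb_calls = [unit_calls[p] for p in pat.pullback_ids]
        ai_target = call_patient(lesion_calls)
        ai_segment = call_patient(pb_calls)
        cl_lesions = [
            corelab[l] for l in pat.lesion_ids if unit_calls[l].evaluable
        ]
        cl_target = any(cl_lesions) if cl_lesions else None
        patient_rows.append(
            (
                pat.patient_id,
                ai_target,
                cl_target,
                ai_segment,
                pat.true_tcfa_target_lesion,
                pat.true_tcfa_complete_segment,
            )
        )
        for c in lesion_calls:
            call_rows.append(
                (
                    c.scope,
                    pat.patient_id,
                    c.unit_id,
                    c.evaluable,
                    c.positive if c.evaluable else None,
                    corelab[c.unit_id],
                )
            )
        for c in pb_calls:
            call_rows.append(
                (c.scope, pat.patient_id, c.unit_id, c.evaluable,
                 c.positive if c.evaluable else None, None)
            )
    calls = pd.DataFrame(call_rows, columns=_io.CALLS_COLUMNS)
    truth = pd.DataFrame(
        patient_rows,
        columns=[
            "patient_id",
            "ai_tcfa_target",
            "cl_tcfa_target",
            "ai_tcfa_segment",
            "true_tcfa_target",
            "true_tcfa_segment",
        ],
    )
    manifest.stage_seconds["aggregate_calls"] = time.time() - t0

    # agreement (AI vs reference, lesion- and patient-level)
    t0 = time.time()
    lesion_mask = (calls["scope"] == "target_lesion") & calls["evaluable"]
    lesion_sub = calls[lesion_mask]
    agreement = {
        "lesion": agreement_report(
            lesion_sub["ai_tcfa"].to_numpy(bool),
            lesion_sub["corelab_tcfa"].to_numpy(bool),
        )
    }
    pat_sub = truth.dropna(subset=["ai_tcfa_target", "cl_tcfa_target"])
    agreement["patient"] = agreement_report(
        pat_sub["ai_tcfa_target"].to_numpy(bool),
        pat_sub["cl_tcfa_target"].to_numpy(bool),
    )
    manifest.stage_seconds["agreement"] = time.time() - t0

    # simulated follow-up driven by the planted complete-segment truth
    t0 = time.time()
    records = simulate_survival(
        [p.patient_id for p in cohort.patients],
        truth["true_tcfa_segment"].to_numpy(bool),
        config,
        exposures_target=truth["true_tcfa_target"].to_numpy(bool),
    )
    survival = records_to_frame(records)
    survival = survival.merge(
        truth[["patient_id", "ai_tcfa_target", "cl_tcfa_target", "ai_tcfa_segment"]],
        on="patient_id",
    )
    outcomes = outcome_report(
        survival, ["ai_tcfa_target", "cl_tcfa_target", "ai_tcfa_segment"]
    )
    outcomes["npv_complete_segment"] = npv_report(survival, "ai_tcfa_segment")
    manifest.stage_seconds["outcomes"] = time.time() - t0

    # manifest accounting
    n_frames = len(metrics)
    n_excluded = int(metrics["excluded"].sum())
    lesion_calls_all = [c for c in unit_calls.values() if c.scope == "target_lesion"]
    pb_calls_all = [c for c in unit_calls.values() if c.scope == "complete_segment"]
    manifest.counts.update(
        frames_total=n_frames,
        frames_excluded=n_excluded,
        frames_retained=n_frames - n_excluded,
        lesions_total=len(lesion_calls_all),
        lesions_evaluable=sum(c.evaluable for c in lesion_calls_all),
        lesions_excluded=sum(not c.evaluable for c in lesion_calls_all),
        pullbacks_total=len(pb_calls_all),
        pullbacks_evaluable=sum(c.evaluable for c in pb_calls_all),
        pullbacks_excluded=sum(not c.evaluable for c in pb_calls_all),
        patients_total=len(cohort.patients),
        patients_target_analysis=int(truth["ai_tcfa_target"].notna().sum()),
        patients_target_dropped=int(truth["ai_tcfa_target"].isna().sum()),
        patients_segment_analysis=int(truth["ai_tcfa_segment"].notna().sum()),
        patients_segment_dropped=int(truth["ai_tcfa_segment"].isna().sum()),
    )
    for c in unit_calls.values():
        if not c.evaluable:
            manifest.exclusion_log.append(
                {
                    "unit_id": c.unit_id,
                    "scope": c.scope,
                    "reason": "retained <50% of frames",
                    "n_excluded_frames": len(c.excluded_frames),
                }
            )
    manifest.reconcile()

    for name, df in (("metrics", metrics), ("calls", calls), ("survival", survival)):
        manifest.digests[name] = hashlib.sha256(
            df.to_csv(index=False).encode()
        ).hexdigest()

    result = RunResult(
        manifest=manifest,
        metrics=metrics,
        calls=calls,
        survival=survival,
        agreement=agreement,
        outcomes=outcomes,
        truth=truth,
    )
    if outdir is not None:
        _write_outputs(result, config, Path(outdir))
    return result


def _write_outputs(result: RunResult, config: CohortConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(outdir / "frame_metrics.csv", index=False)
    result.calls.to_csv(outdir / "tcfa_calls.csv", index=False)
    result.survival.to_csv(outdir / "survival.csv", index=False)
    result.truth.to_csv(outdir / "patient_truth.csv", index=False)
    (outdir / "agreement.json").write_text(json.dumps(result.agreement, indent=1))
    (outdir / "outcomes.json").write_text(
        json.dumps(result.outcomes, indent=1, default=float)
    )
    config.to_yaml(outdir / "config.yaml")
    # manifest last: its presence marks a completed run
    (outdir / "manifest.json").write_text(result.manifest.to_json())


def replay_from_tables(
    calls: pd.DataFrame, survival: Optional[pd.DataFrame] = None
) -> dict:
    """Agreement (+ optional outcome) reports from externally produced tables.

    Row order is irrelevant; the same reports as a full run are produced
    given identical intermediate tables.
    """
    _io.validate_table(calls, _io.CALLS_COLUMNS[:5], "calls")
    calls = calls.sort_values(["scope", "unit_id"]).reset_index(drop=True)
    report: dict = {"agreement": {}}
    lesion = calls[
        (calls["scope"] == "target_lesion")
        & calls["evaluable"].astype(bool)
        & calls["corelab_tcfa"].notna()
    ]
    if len(lesion):
        report["agreement"]["lesion"] = agreement_report(
            lesion["ai_tcfa"].astype(bool).to_numpy(),
            lesion["corelab_tcfa"].astype(bool).to_numpy(),
        )
    if survival is not None:
        _io.validate_table(survival, _io.SURVIVAL_COLUMNS[:4], "survival")
        survival = survival.sort_values("patient_id").reset_index(drop=True)
        exposure_cols = [
            c
            for c in ("exposure_target_lesion", "exposure_complete_segment")
            if c in survival.columns and survival[c].notna().any()
        ]
        report["outcomes"] = outcome_report(survival, exposure_cols)
    return report
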