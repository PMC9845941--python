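"""End-to-end pipeline: synthesize (or load) -> process fNIRS -> score behavior
-> fit the risk model -> group statistics -> report bundle.

Every run is deterministic under (config, seed); the JSON summary carries a
manifest (seed, config hash, package version) and a QC block (channels
rejected, catch-trial failures, subjects dropped).  A subject with a missing
or failing stream is dropped from the affected tables and logged; the pipeline
completes on the remaining subjects.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, decision, fnirs, stats, synth

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "process_fnirs_stage",
           "score_behavior_stage", "fit_decision_stage", "assemble_analysis_table"]

log = logging.getLogger("relapsekit")


@dataclass
class PipelineConfig:
    seed: int = 7
    outdir: str | Path | None = None
    cohort: synth.CohortConfig = field(default_factory=synth.default_config)
    fit: decision.FitConfig = field(default_factory=decision.FitConfig)
    artifact_criteria: fnirs.ArtifactCriteria = field(default_factory=fnirs.ArtifactCriteria)
    exclude_catch_failures: bool = True
    write_plots: bool = False


@dataclass
class PipelineResult:
    dataset: synth.SyntheticDataset
    activations: pd.DataFrame
    behavior_summary: pd.DataFrame
    fits: pd.DataFrame
    analysis_table: pd.DataFrame
    report: dict
    summary: dict
    qc: dict


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (Path, np.floating, np.integer)):
            return str(o)
        return repr(o)

    payload = asdict(cfg)
    payload.pop("outdir", None)  # where results land does not change what they are
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def process_fnirs_stage(
    recordings: dict[str, dict[str, fnirs.FnirsRecording]],
    criteria: fnirs.ArtifactCriteria | None = None,
    qc: dict | None = None,
) -> pd.DataFrame:
    """Per-subject region activations and contrasts from raw recordings."""
    rows = []
    qc = qc if qc is not None else {}
    qc.setdefault("channels_rejected", 0)
    qc.setdefault("fnirs_subjects_dropped", [])
    for sid, recs in recordings.items():
        try:
            keep, reasons = fnirs.reject_artifact_channels(recs["gonogo"], criteria)
            qc["channels_rejected"] += len(reasons)
            acts = fnirs.process_recording(recs["gonogo"], criteria=criteria,
                                           conditions=("emotional", "nonemotional"))
            if "vft" in recs:
                acts += fnirs.process_recording(recs["vft"], criteria=criteria,
                                                conditions=("vft_production",))
        except Exception as exc:  # noqa: BLE001 - fault tolerance is the contract
            log.warning("fNIRS processing failed for %s: %s; subject dropped", sid, exc)
            qc["fnirs_subjects_dropped"].append(sid)
            continue
        for a in acts:
            rows.append(dict(subject_id=a.subject_id, region=a.region, condition=a.condition,
                             integral_oxyhb=a.integral_oxyhb,
                             contrast=a.contrast_emotional_minus_neutral,
                             n_channels_used=a.n_channels_used))
    return pd.DataFrame(rows)


def score_behavior_stage(ds: synth.SyntheticDataset) -> pd.DataFrame:
    """One row per subject of go/no-go, n-back, and VFT summary measures."""
    rows = []
    for sid, grp in ds.gonogo.groupby("subject_id"):
        trials = behavior.gonogo_frame_to_trials(grp)
        scores = behavior.score_gonogo(trials)
        row: dict = {"subject_id": sid}
        emo = scores.get("emotional")
        neu = scores.get("nonemotional")
        if emo:
            row["fa_rate_emotional"] = emo.false_alarm_rate
            row["omission_rate_emotional"] = emo.omission_error_rate
            row["rt_emotional_ms"] = emo.mean_rt_correct_hits_ms
        if neu:
            row["rt_nonemotional_ms"] = neu.mean_rt_correct_hits_ms
        nb = behavior.score_nback(ds.nback[ds.nback["subject_id"] == sid])
        for load, sc in nb.items():
            row[f"nback{load}_pct"] = sc.percent_correct
            row[f"nback{load}_rt_ms"] = sc.mean_rt_ms
        row["vft_words"] = behavior.score_vft(ds.vft[ds.vft["subject_id"] == sid])
        rows.append(row)
    return pd.DataFrame(rows)


def fit_decision_stage(
    choices: pd.DataFrame, fit_config: decision.FitConfig, qc: dict | None = None
) -> pd.DataFrame:
    """Per-subject MLE fits of (lambda, gamma, tau) from the choice log."""
    qc = qc if qc is not None else {}
    qc.setdefault("fit_not_converged", [])
    qc.setdefault("catch_failures", [])
    rows = []
    for i, (sid, grp) in enumerate(choices.groupby("subject_id")):
        trials = decision.frame_to_trials(grp)
        cfg = decision.FitConfig(**{**asdict(fit_config), "seed": fit_config.seed + i})
        fit = decision.fit_mle(trials, cfg)
        if not fit.converged:
            qc["fit_not_converged"].append(sid)
        if fit.catch_accuracy is not None and fit.catch_accuracy < cfg.catch_pass_threshold:
            qc["catch_failures"].append(sid)
        rows.append(decision.fit_to_row(fit, sid))
    return pd.DataFrame(rows)


def assemble_analysis_table(
    ds: synth.SyntheticDataset,
    activations: pd.DataFrame,
    behavior_summary: pd.DataFrame,
    fits: pd.DataFrame,
    exclude_catch_failures: bool = True,
    qc: dict | None = None,
) -> pd.DataFrame:
    """Join cohort covariates with all derived measures, one row per subject."""
    table = ds.cohort.copy()
    if len(activations):
        emo = activations[activations["condition"] == "emotional"]
        contrasts = emo.pivot(index="subject_id", columns="region", values="contrast")
        contrasts.columns = [f"contrast_{c}" for c in contrasts.columns]
        table = table.merge(contrasts.reset_index(), on="subject_id", how="left")
        vft_act = activations[activations["condition"] == "vft_production"]
        if len(vft_act):
            v = vft_act.pivot(index="subject_id", columns="region", values="integral_oxyhb")
            v.columns = [f"vft_{c}" for c in v.columns]
            table = table.merge(v.reset_index(), on="subject_id", how="left")
    table = table.merge(behavior_summary, on="subject_id", how="left")
    fit_cols = fits.copy()
    if exclude_catch_failures and len(fit_cols):
        bad = fit_cols["catch_accuracy"] < decision.FitConfig().catch_pass_threshold
        if qc is not None:
            qc["subjects_excluded_catch"] = fit_cols.loc[bad, "subject_id"].tolist()
        fit_cols = fit_cols[~bad]
    table = table.merge(
        fit_cols[["subject_id", "lambda", "gamma", "tau", "catch_accuracy"]],
        on="subject_id", how="left",
    )
    return table


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    t0 = time.time()
    qc: dict = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    try:
        log.info("stage: synth (seed=%s)", config.seed)
        ds = synth.generate_dataset(config.cohort, seed=config.seed)

        log.info("stage: fnirs (%d subjects)", len(ds.recordings))
        activations = process_fnirs_stage(ds.recordings, config.artifact_criteria, qc)

        log.info("stage: behavior")
        behavior_summary = score_behavior_stage(ds)

        log.info("stage: decision-model fitting")
        fits = fit_decision_stage(ds.choices, config.fit, qc)

        log.info("stage: stats")
        table = assemble_analysis_table(ds, activations, behavior_summary, fits,
                                        config.exclude_catch_failures, qc)
        report = stats.run_group_analysis(table)

        summary = dict(report["summary"])
        summary["manifest"] = {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "package_version": __version__,
        }
        summary["qc"] = {k: v for k, v in qc.items()}
        summary["runtime_s"] = round(time.time() - t0, 2)

        if outdir:
            _write_outputs(outdir, ds, activations, behavior_summary, fits, table,
                           report, summary, config)
        return PipelineResult(ds, activations, behavior_summary, fits, table,
                              report, summary, qc)
    finally:
        if outdir:
            log.removeHandler(handler)
            handler.close()


def _write_outputs(outdir: Path, ds, activations, behavior_summary, fits, table,
                   report, summary, config) -> None:
    ds.cohort.to_csv(outdir / "cohort.csv", index=False)
    ds.truth.to_csv(outdir / "truth.csv", index=False)
    activations.to_csv(outdir / "activations.csv", index=False)
    behavior_summary.to_csv(outdir / "behavior_summary.csv", index=False)
    fits.to_csv(outdir / "fits.csv", index=False)
    table.to_csv(outdir / "analysis_table.csv", index=False)
    for name in ("demographics", "behavior", "region_contrasts", "vft_activation",
                 "risk_params", "correlations", "logistic_table"):
        if name in report and isinstance(report[name], pd.DataFrame):
            report[name].to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2,
                                                    sort_keys=True))
    (outdir / "qc.json").write_text(json.dumps(_jsonable(summary.get("qc", {})), indent=2))
    if config.write_plots:
        from . import plots
        plots.write_report_figures(table, outdir)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
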