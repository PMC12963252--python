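"""End-to-end orchestration: label -> cpSVM CV -> TC -> evaluation reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline, classify, evaluate, preprocess
from .config import RunConfig
from .errors import ParameterError
from .io import Trial, load_session

__all__ = ["run_pipeline", "prepare_trials"]


def prepare_trials(trials: list[Trial], config: RunConfig):
    """Rates, velocities and reference labels for every trial.

    Reference labels come from labels.csv when present (and not overridden);
    otherwise they are generated from cursor kinematics with the configured
    change-point parameters (per-trial overrides allowed).
    """
    prepared = []
    for tr in trials:
        rates = preprocess.estimate_firing_rates(tr.spikes, config.rate_sd_ms)
        kin = preprocess.compute_velocity(tr.kin)
        if tr.labels is not None and not config.use_truth_labels:
            ref = tr.labels
        else:
            over = config.per_trial_overrides.get(tr.trial_id, {})
            params = preprocess.LabelingParams(
                kernel_sd_ms=over.get("kernel_sd_ms", config.label_kernel_sd_ms),
                cutoff=over.get("cutoff", config.label_cutoff),
                detector_window_ms=over.get("detector_window_ms",
                                            config.detector_window_ms),
                detector_k=over.get("detector_k", config.detector_k),
            )
            ref = preprocess.generate_reference_labels(kin, params)
        n = min(rates.values.shape[0], len(ref))
        rates = preprocess.RateMatrix(rates.values[:n], rates.time_grid[:n])
        ref = preprocess.StateLabels(ref.labels[:n], ref.time_grid[:n])
        prepared.append((rates, kin, ref))
    return prepared


def _metric_rows(metrics: dict, fold: int) -> list[dict]:
    rows = []
    for state, pm in metrics.items():
        for name, value in pm.as_dict().items():
            rows.append({"fold": fold, "state": state, "metric": name,
                         "value": value})
    return rows


def run_pipeline(config: RunConfig, data, outdir) -> dict:
    """Run the full comparison and write JSON + CSV reports.

    ``data`` is a session path (CSV directory or NWB file) or a preloaded
    list of trials. Returns the report dictionary; every report embeds the
    exact configuration and seeds needed to regenerate it.
    """
    trials = data if isinstance(data, list) else load_session(data)
    if config.cv_folds > len(trials):
        raise ParameterError(
            f"cv_folds = {config.cv_folds} exceeds the {len(trials)} trials")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    prepared = prepare_trials(trials, config)
    cv_trials = [(rates, ref) for rates, _, ref in prepared]

    cv = classify.run_trialwise_cv(
        cv_trials, k=config.cv_folds, benchmark=config.benchmark,
        C=config.svm_c, eps=config.svm_eps, seed=config.seed)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    tc_params = baseline.TCParams(config.tc_threshold_x, config.tc_threshold_y,
                                  range(config.tc_sweep_min, config.tc_sweep_max + 1))
    tc_inputs = []
    for _, kin, ref in prepared:
        vx, vy = kin.vx, kin.vy
        if config.velocity_jitter_sd > 0:
            from .synthetic import jitter_velocity
            vx = jitter_velocity(vx, config.velocity_jitter_sd, rng)
            vy = jitter_velocity(vy, config.velocity_jitter_sd, rng)
        tc_inputs.append((vx, vy, ref))
    if config.tc_run_sweep:
        sweep = baseline.sweep_tc_threshold(tc_inputs, tc_params.sweep_range)
        tc_params = baseline.TCParams(sweep.threshold_x, sweep.threshold_y,
                                      tc_params.sweep_range)
    tc_preds = [baseline.tc_classify(vx, vy, tc_params) for vx, vy, _ in tc_inputs]

    rows = []
    for f, m in enumerate(cv.fold_metrics):
        rows.extend(_metric_rows(m, f))
    cpsvm_df = pd.DataFrame(rows)
    cpsvm_df.insert(0, "method", "cpsvm")

    tc_rows = []
    for t, (pred, (_, _, ref)) in enumerate(zip(tc_preds, tc_inputs)):
        _, pm_mov = evaluate.confusion_metrics(pred, ref, positive_class=1)
        _, pm_sta = evaluate.confusion_metrics(pred, ref, positive_class=0)
        tc_rows.extend(_metric_rows({"movement": pm_mov, "stationary": pm_sta}, t))
    tc_df = pd.DataFrame(tc_rows).rename(columns={"fold": "trial"})
    tc_df.insert(0, "method", "tc")

    transitions = {
        "reference": [evaluate.count_transitions(ref) for _, _, ref in prepared],
        "cpsvm": [evaluate.count_transitions(p) for p in cv.predictions],
        "tc": [evaluate.count_transitions(p) for p in tc_preds],
    }
    responsiveness = {"cpsvm": {"start_ms": [], "end_ms": []},
                      "tc": {"start_ms": [], "end_ms": []}}
    for (rates, _, ref), cp, tp in zip(prepared, cv.predictions, tc_preds):
        if evaluate.count_transitions(ref) == 0:
            continue
        for method, pred in (("cpsvm", cp), ("tc", tp)):
            summ = evaluate.summarize_trial_responsiveness(pred, ref)
            responsiveness[method]["start_ms"].append(summ["start_ms"])
            responsiveness[method]["end_ms"].append(summ["end_ms"])

    def _mean(values):
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        return float(arr.mean()) if arr.size else None

    report = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_trials": len(trials),
        "cpsvm": {
            "mean_accuracy": cv.mean_accuracy,
            "fold_metrics": [
                {state: pm.as_dict() for state, pm in m.items()}
                for m in cv.fold_metrics
            ],
        },
        "tc": {
            "threshold_x": tc_params.threshold_x,
            "threshold_y": tc_params.threshold_y,
            "mean_accuracy": _mean(
                tc_df[(tc_df.state == "movement") & (tc_df.metric == "accuracy")]
                .value),
        },
        "transitions_per_trial": {k: _mean(v) for k, v in transitions.items()},
        "responsiveness_median_ms": {
            m: {k: (float(np.nanmedian(v)) if len(v) else None)
                for k, v in d.items()}
            for m, d in responsiveness.items()
        },
    }
    pd.concat([cpsvm_df, tc_df], ignore_index=True).to_csv(
        outdir / "metrics.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
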