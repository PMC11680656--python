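"""Orchestration: simulate -> preprocess -> fit (G = 1..6) -> select -> hazard.

Each stage writes plain CSV/JSON files under a run directory and appends to
a single run manifest (file checksums, seeds, versions, timestamps), so a
completed run is reproducible bit-for-bit from its config and seed.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

import alctraj
from alctraj.synthetic import GeneratorConfig, generate_cohort, write_cohort
from alctraj.preprocess import assemble_analysis_sets
from alctraj.lcmm import (
    TrajectoryData,
    TrajectorySpec,
    fit_multistart,
    warm_start_from,
    posterior_probs,
    predict_class_trajectories,
    weighted_fit_diagnostic,
    presentation_order,
    relabel_classes,
)
from alctraj.model_select import SelectionReport, apply_selection_rules
from alctraj.hazard import HazardSpec, fit_hazard, compare_baselines

log = logging.getLogger("alctraj")


def _md5(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


class RunManifest:
    """Ordered record of one pipeline run: configs, seeds, file checksums."""

    def __init__(self, path):
        self.path = Path(path)
        self.entries: list[dict] = []

    def add(self, stage: str, **info):
        entry = {
            "stage": stage,
            "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
            **info,
        }
        self.entries.append(entry)
        self.save()
        return entry

    def add_files(self, stage: str, files: dict, **info):
        return self.add(stage, files={k: {"path": str(v), "md5": _md5(v)} for k, v in files.items()}, **info)

    def save(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps({"version": alctraj.__version__, "entries": self.entries}, indent=2))


def _load_config(config) -> GeneratorConfig:
    if isinstance(config, GeneratorConfig):
        config.validate()
        return config
    return GeneratorConfig.from_file(config)


def run_simulate(config, out_dir, seed: int | None = None) -> dict:
    """Generate a cohort from a config (path or object) and write it under ``out_dir``."""
    cfg = _load_config(config)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    intakes, subjects, truth = generate_cohort(cfg)
    paths = write_cohort(intakes, subjects, truth, out)
    manifest = RunManifest(out / "manifest.json")
    manifest.add_files("simulate", paths, seed=cfg.seed, n_subjects=cfg.n_subjects)
    log.info("simulated %d subjects, %d intake records", len(subjects), len(intakes))
    return paths


def run_full_analysis(
    config,
    out_dir,
    classes=range(1, 7),
    n_starts: int = 20,
    knots=(5, 4),
    models=("model1", "model2"),
    seed: int | None = None,
    min_share: float = 0.05,
    min_mean_posterior: float = 0.75,
) -> dict:
    """Execute every stage in order and return the key results.

    Simulates the cohort, assembles the trajectory and survival analysis
    sets with an exclusion-flow report, fits LCMMs for each candidate G
    (multistart; warm starts carried up from the previous G), applies the
    selection rules, relabels the chosen model for presentation (classes
    ordered by mean intake at age 50, so the consistently-low class is last
    and serves as hazard reference), then fits the latent-class PH model
    under Weibull and cubic M-spline baselines for each covariate set,
    choosing by AIC.  All outputs land under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out / "manifest.json")
    cfg = _load_config(config)
    if seed is not None:
        cfg = replace(cfg, seed=seed)

    # stage: simulate
    intakes, subjects, truth = generate_cohort(cfg)
    paths = write_cohort(intakes, subjects, truth, out / "data")
    manifest.add_files("simulate", paths, seed=cfg.seed, n_subjects=cfg.n_subjects)

    # stage: preprocess
    traj_subjects, surv_subjects, flow = assemble_analysis_sets(intakes, subjects)
    flow.to_json(out / "flow_report.json")
    traj_intakes = intakes[intakes["subject_id"].isin(traj_subjects["subject_id"])]
    manifest.add_files(
        "preprocess",
        {"flow_report": out / "flow_report.json"},
        flow=[{"step": s["step"], "excluded_n": s["excluded_n"], "remaining_n": s["remaining_n"]} for s in flow.steps],
    )
    log.info("trajectory set n=%d, survival set n=%d", len(traj_subjects), len(surv_subjects))

    # stage: fit LCMMs
    data = TrajectoryData.from_frame(traj_intakes)
    fits = {}
    report = SelectionReport()
    base_fit = None
    prev = None
    for G in classes:
        spec = TrajectorySpec(int(G))
        warm = [warm_start_from(prev)] if (prev is not None and prev.n_classes == G - 1) else None
        fit = fit_multistart(
            data, spec, n_starts=n_starts, warm_starts=warm, seed=cfg.seed + G,
            base_fit=base_fit,
        )
        if G == 1:
            base_fit = fit
        fits[int(G)] = fit
        post = posterior_probs(fit, data) if G >= 2 else None
        report.add_candidate(fit, post, data.n_subjects)
        fit.to_json(out / f"lcmm_fit_G{G}.json")
        log.info("G=%d loglik=%.2f", G, fit.loglik)
        prev = fit

    # stage: select
    report = apply_selection_rules(report, min_share=min_share, min_mean_posterior=min_mean_posterior)
    report.to_json(out / "selection.json")
    (out / "selection.txt").write_text(report.to_text())
    manifest.add_files("select", {"selection": out / "selection.json"}, chosen_G=report.chosen_G)

    chosen = fits[report.chosen_G]
    order = presentation_order(chosen) if chosen.n_classes > 1 else np.array([0])
    chosen = relabel_classes(chosen, order)
    chosen.to_json(out / "lcmm_fit_chosen.json")
    posteriors = posterior_probs(chosen, data)
    posteriors.to_csv(out / "posteriors.csv")

    ages = np.arange(20.0, 66.0, 1.0)
    predict_class_trajectories(chosen, ages).to_csv(out / "trajectories.csv", index=False)
    weighted_fit_diagnostic(chosen, data, np.arange(17.5, 72.6, 5.0)).to_csv(
        out / "fit_diagnostic.csv", index=False
    )
    manifest.add_files(
        "fit-lcmm",
        {
            "fit": out / "lcmm_fit_chosen.json",
            "posteriors": out / "posteriors.csv",
            "trajectories": out / "trajectories.csv",
        },
        classes=list(map(int, classes)),
        n_starts=n_starts,
    )

    # stage: hazard (survival set only)
    surv_ids = surv_subjects["subject_id"].to_numpy()
    sel = np.isin(posteriors.subject_ids, surv_ids)
    from alctraj.lcmm import PosteriorMatrix

    surv_post = PosteriorMatrix.from_probs(posteriors.probs[sel], subject_ids=posteriors.subject_ids[sel])
    hazard_results = {}
    for model in models:
        candidates = []
        specs = [HazardSpec(baseline_family="weibull", covariate_set=model)]
        specs += [HazardSpec(baseline_family="mspline", n_knots=k, covariate_set=model) for k in knots]
        for hspec in specs:
            candidates.append(fit_hazard(surv_post, surv_subjects, hspec))
        best, aic_table = compare_baselines(candidates)
        best.to_json(out / f"hazard_{model}.json")
        best.hr_table.to_csv(out / f"hr_table_{model}.csv", index=False)
        aic_table.to_csv(out / f"aic_table_{model}.csv", index=False)
        hazard_results[model] = {"fit": best, "aic_table": aic_table}
        manifest.add_files(
            "fit-hazard",
            {"fit": out / f"hazard_{model}.json", "hr_table": out / f"hr_table_{model}.csv"},
            model=model,
            chosen_baseline=str(aic_table.loc[aic_table["chosen"], "baseline"].iloc[0]),
        )
        log.info("%s: chosen baseline %s", model, aic_table.loc[aic_table["chosen"], "baseline"].iloc[0])

    return {
        "config": cfg,
        "flow": flow,
        "selection": report,
        "fits": fits,
        "chosen_fit": chosen,
        "posteriors": posteriors,
        "hazard": hazard_results,
        "out_dir": out,
    }


def make_report(run_dir) -> str:
    """Human-readable markdown summary of a completed run, cross-checked against its files."""
    run = Path(run_dir)
    required = ["flow_report.json", "selection.json", "lcmm_fit_chosen.json"]
    missing = [f for f in required if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run at {run}: missing {missing}")
    flow = json.loads((run / "flow_report.json").read_text())
    selection = json.loads((run / "selection.json").read_text())
    chosen = json.loads((run / "lcmm_fit_chosen.json").read_text())

    lines = ["# Analysis run summary", "", "## Cohort flow", ""]
    lines.append(f"- initial subjects: {flow['initial_n']}")
    for step in flow["steps"]:
        lines.append(f"- {step['step']}: excluded {step['excluded_n']}, remaining {step['remaining_n']}")
    lines += ["", "## Class-number selection", ""]
    for cand in selection["candidates"]:
        lines.append(
            f"- G={cand['G']}: loglik={cand['loglik']:.2f}, BIC={cand['BIC']:.2f}, "
            f"ICL={cand['ICL']:.2f}, smallest share={cand['smallest_class_share']:.3f}"
        )
    lines.append(f"- chosen G = {selection['chosen_G']}")
    lines += ["", "## Chosen trajectory model", ""]
    lines.append(f"- log-likelihood: {chosen['loglik']:.2f}")
    lines.append(f"- class shares: {[round(s, 3) for s in chosen['class_shares']]}")
    lines.append(f"- residual sd: {chosen['residual_sd']:.4f}")

    for model in ("model1", "model2"):
        hr_path = run / f"hr_table_{model}.csv"
        if hr_path.exists():
            hr = pd.read_csv(hr_path)
            fit = json.loads((run / f"hazard_{model}.json").read_text())
            lines += ["", f"## Hazard ratios ({model}, {fit['baseline_family']} baseline)", ""]
            for _, row in hr.iterrows():
                if row["reference"]:
                    lines.append(f"- class {int(row['class'])}: HR 1.00 (reference), "
                                 f"{row['n_women']} women / {row['n_cases']} cases")
                else:
                    lines.append(
                        f"- class {int(row['class'])}: HR {row['HR']:.2f} "
                        f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), "
                        f"{row['n_women']} women / {row['n_cases']} cases"
                    )
    text = "\n".join(lines) + "\n"
    (run / "report.md").write_text(text)
    return text
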