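"""End-to-end orchestration: simulate -> fit -> assess -> predict -> behavior.

Every stochastic stage derives its stream from the single run seed through a
fixed ``SeedSequence((seed, stage, index))`` scheme, so any stage can be
re-run in isolation and a full run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import pandas as pd
import yaml

from . import __version__
from .assessment import (
    chisq_choice_gof,
    choice_counts,
    expected_choice_counts,
    ks_rt_gof,
    plot_qp,
    quantile_probability_data,
    rm_anova_drift,
)
from .behavior import association_table, behavior_summary
from .fitting import FitConfig, fit_cohort, fits_frame, normalized_drift_rates
from .io import write_table, write_trials, write_subjects
from .prediction import (
    attach_empirical,
    holdout_evaluation,
    pair_predictions,
    predicted_vs_actual,
)
from .task import (
    PopulationConfig,
    profiles_frame,
    sample_population,
    simulate_cohort,
    STIMULUS_IDS,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 1
    n_subjects: int = 44
    population: PopulationConfig = field(default_factory=PopulationConfig)
    fitting: FitConfig = field(default_factory=FitConfig)
    n_sim_per_subject: int = 10_000  # model-based QP statistics
    ks_sim_multiplier: int = 100
    out_dir: str = "results"
    make_figure: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sim_per_subject < 1 or self.ks_sim_multiplier < 1:
            raise ValueError("all counts must be positive")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pop = PopulationConfig(**raw.pop("population", {}))
    fit = FitConfig(**raw.pop("fitting", {}))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return RunConfig(population=pop, fitting=fit, **raw)


def _stage(name: str, fn, log_entries: list):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log_entries.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
    return result


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run the full analysis; writes all tables plus a run log and summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list = []
    bundle: Dict[str, object] = {}

    profiles = _stage(
        "sample_population",
        lambda: sample_population(config.n_subjects, config.population, seed=config.seed),
        stage_log,
    )
    trials = _stage("simulate", lambda: simulate_cohort(profiles, seed=config.seed), stage_log)
    subjects = profiles_frame(profiles)
    write_trials(trials, out / "trials.csv")
    write_subjects(subjects, out / "subjects.csv")
    bundle["trials"] = trials
    bundle["subjects"] = subjects

    fits = {}
    for variant in ("drift_model", "boundary_model"):
        fits[variant] = _stage(
            f"fit_{variant}",
            lambda v=variant: fit_cohort(trials, v, config.fitting, seed=config.seed),
            stage_log,
        )
    all_fits = pd.concat([fits_frame(f) for f in fits.values()], ignore_index=True)
    write_table(all_fits, out / "fits.csv")
    bundle["fits"] = fits

    qp = _stage(
        "assess_qp",
        lambda: pd.concat(
            [
                quantile_probability_data(
                    trials,
                    fits["drift_model"],
                    n_sim_per_subject=config.n_sim_per_subject,
                    seed=config.seed,
                ),
                quantile_probability_data(
                    trials,
                    fits["boundary_model"],
                    n_sim_per_subject=config.n_sim_per_subject,
                    seed=config.seed,
                ).query("source != 'data'"),
            ],
            ignore_index=True,
        ),
        stage_log,
    )
    write_table(qp, out / "qp_table.csv")
    bundle["qp"] = qp
    if config.make_figure:
        plot_qp(qp, out / "qp_plot.png")

    gof_rows = []
    for variant in ("drift_model", "boundary_model"):
        obs = choice_counts(trials)
        exp = expected_choice_counts(fits[variant], trials)
        x2, dof, p = chisq_choice_gof(obs, exp)
        ks = ks_rt_gof(trials, fits[variant], seed=config.seed,
                       sim_multiplier=config.ks_sim_multiplier)
        row = {"variant": variant, "chisq": x2, "df": dof, "chisq_p": p}
        for sid, (d, pv) in ks.items():
            row[f"ks_D_{sid}"] = d
            row[f"ks_p_{sid}"] = pv
        gof_rows.append(row)
    gof = pd.DataFrame(gof_rows)
    write_table(gof, out / "gof.csv")
    bundle["gof"] = gof

    norm = pd.DataFrame(
        [
            {"subject_id": subject, "stimulus": sid, "value": value}
            for subject, fit in fits["drift_model"].items()
            for sid, value in normalized_drift_rates(fit).items()
        ]
    )
    anova = _stage("anova", lambda: rm_anova_drift(norm), stage_log)
    write_table(anova, out / "anova_normalized_drift.csv")
    bundle["anova"] = anova

    whole_corr = _stage(
        "predict_whole",
        lambda: predicted_vs_actual(fits["drift_model"], trials),
        stage_log,
    )
    whole_pred = attach_empirical(pair_predictions(fits["drift_model"]), trials)
    whole_pred["split"] = "whole"
    hold_corr, hold_pred = _stage(
        "holdout",
        lambda: holdout_evaluation(trials, config.fitting, seed=config.seed),
        stage_log,
    )
    write_table(pd.concat([whole_pred, hold_pred], ignore_index=True), out / "predictions.csv")
    whole_corr["split"] = "whole"
    hold_corr["split"] = "holdout"
    corr = pd.concat([whole_corr, hold_corr], ignore_index=True)
    write_table(corr, out / "correlations.csv")
    bundle["correlations"] = corr

    summary = _stage("behavior", lambda: behavior_summary(trials, subjects), stage_log)
    assoc = association_table(summary)
    write_table(summary, out / "behavior_summary.csv")
    write_table(assoc, out / "behavior_associations.csv")
    bundle["behavior"] = summary
    bundle["associations"] = assoc

    run_log = {
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "version": __version__,
        "stages": stage_log,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    (out / "summary.txt").write_text(_render_summary(bundle))
    return bundle


def _render_summary(bundle: Dict[str, object]) -> str:
    corr: pd.DataFrame = bundle["correlations"]
    gof: pd.DataFrame = bundle["gof"]
    anova: pd.DataFrame = bundle["anova"]
    assoc: pd.DataFrame = bundle["associations"]
    lines = ["Run summary", "===========", ""]
    lines.append("Predicted vs actual choice rates (Pearson r, per pair):")
    for split in ("whole", "holdout"):
        lines.append(f"  [{split}]")
        for row in corr[corr["split"] == split].itertuples(index=False):
            lines.append(f"    {row.pair}: r = {row.r:+.3f} (p = {row.p:.4g}, n = {row.n})")
    lines.append("")
    lines.append("Goodness of fit:")
    for row in gof.itertuples(index=False):
        lines.append(f"  {row.variant}: X2({row.df}) = {row.chisq:.2f}, p = {row.chisq_p:.4g}")
        for sid in STIMULUS_IDS:
            d = getattr(row, f"ks_D_{sid}")
            p = getattr(row, f"ks_p_{sid}")
            lines.append(f"    KS {sid}: D = {d:.3f}, p = {p:.4g}")
    lines.append("")
    lines.append("Risk x EV ANOVA on normalized drift rates:")
    for row in anova.itertuples(index=False):
        lines.append(
            f"  {row.effect}: F(1, {row.df2}) = {row.F:.2f}, p = {row.p:.4g}, "
            f"partial eta^2 = {row.partial_eta_sq:.3f}"
        )
    lines.append("")
    lines.append("Behavioral associations:")
    for row in assoc.itertuples(index=False):
        lines.append(f"  {row.x} vs {row.y}: r = {row.r:+.3f} (p = {row.p:.4g}, n = {row.n})")
    return "\n".join(lines) + "\n"
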