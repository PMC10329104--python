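"""End-to-end pipeline: cohort generation -> simulation -> exclusions ->
fitting -> behavioral metrics -> correlation battery -> mediation, with fully
seeded determinism and re-parseable CSV/JSON outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, CohortSpec, generate_cohort, simulate_cohort_behavior
from .fitting import fit_subject
from .io import write_trials
from .metrics import summarize_subject
from .stats import correlation_battery, mediation, render_battery
from .task import TaskConfig

log = logging.getLogger("metacontrol")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; one master seed governs all stages."""

    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    n_restarts: int = 10
    fit_pi: bool = True
    fit_rho: bool = True
    alpha_family: float = 0.05
    m_tests: int = 21
    n_boot: int = 5000
    out_dir: str = "results"
    seed: int = 0

    def to_flat(self) -> dict:
        flat: dict = {}
        for f in dataclasses.fields(TaskConfig):
            v = getattr(self.task, f.name)
            if f.name in ("transition_map", "pairs"):
                continue  # defaults only in the flat format
            flat[f"task.{f.name}"] = v
        for f in dataclasses.fields(CohortSpec):
            v = getattr(self.cohort, f.name)
            flat[f"cohort.{f.name}"] = list(v) if isinstance(v, tuple) else v
        for name in ("n_restarts", "fit_pi", "fit_rho", "alpha_family",
                     "m_tests", "n_boot", "out_dir", "seed"):
            flat[name] = getattr(self, name)
        return flat

    @classmethod
    def from_flat(cls, flat: dict) -> "RunConfig":
        task_kw, cohort_kw, top_kw = {}, {}, {}
        valid_task = {f.name for f in dataclasses.fields(TaskConfig)}
        valid_cohort = {f.name for f in dataclasses.fields(CohortSpec)}
        valid_top = {"n_restarts", "fit_pi", "fit_rho", "alpha_family",
                     "m_tests", "n_boot", "out_dir", "seed"}
        for key, value in flat.items():
            if key.startswith("task."):
                name = key[5:]
                if name not in valid_task:
                    raise ConfigError(f"unknown task key {key!r}")
                task_kw[name] = value
            elif key.startswith("cohort."):
                name = key[7:]
                if name not in valid_cohort:
                    raise ConfigError(f"unknown cohort key {key!r}")
                cohort_kw[name] = tuple(value) if name == "age_range" else value
            elif key in valid_top:
                top_kw[key] = value
            else:
                raise ConfigError(f"unknown config key {key!r}")
        try:
            return cls(task=TaskConfig(**task_kw),
                       cohort=CohortSpec(**cohort_kw), **top_kw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def save(self, path: str | Path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            flat = yaml.safe_load(fh)
        if not isinstance(flat, dict):
            raise ConfigError("config file must contain a flat mapping")
        return cls.from_flat(flat)


def run_pipeline(config: RunConfig, write_trial_csvs: bool = True) -> dict:
    """Execute every stage and write the report bundle under ``out_dir``.

    Returns a dict with the in-memory artifacts (cohort, fits table,
    summaries, battery, mediation results).  Identical configs produce
    byte-identical CSV outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    log.info("metacontrol %s | python %s | numpy %s | master seed %d",
             __version__, platform.python_version(), np.__version__,
             config.seed)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s.generate_state(1)[0]) for name, s in zip(
        ("cohort", "behavior", "fitting", "bootstrap"), ss.spawn(4))}
    log.info("stage seeds: %s", stage_seeds)

    stage = "generate_cohort"
    try:
        cohort = generate_cohort(config.cohort, seed=stage_seeds["cohort"])
        cohort.table.to_csv(out / "cohort.csv", index=False,
                            float_format="%.10g")

        stage = "simulate_cohort_behavior"
        tables = simulate_cohort_behavior(cohort, config.task,
                                          seed=stage_seeds["behavior"])
        if write_trial_csvs:
            trials_dir = out / "trials"
            trials_dir.mkdir(exist_ok=True)
            for sid, table in tables.items():
                write_trials(table, trials_dir / f"{sid}.csv")

        stage = "behavior_metrics"
        summaries = pd.DataFrame(
            [summarize_subject(t, config.task.reward_high).to_dict()
             for t in tables.values()])
        summaries.to_csv(out / "summaries.csv", index=False,
                         float_format="%.10g")

        stage = "fit_subject"
        fit_rows = []
        included = summaries.set_index("subject_id")["included"]
        for i, (sid, table) in enumerate(tables.items()):
            if not included[sid]:
                log.info("subject %s excluded (missed-trial rule)", sid)
                continue
            fit = fit_subject(table, config.task,
                              n_restarts=config.n_restarts,
                              seed=stage_seeds["fitting"] + i,
                              fit_pi=config.fit_pi, fit_rho=config.fit_rho)
            row = {"subject_id": sid}
            row.update(fit.to_dict())
            fit_rows.append(row)
        fits = pd.DataFrame(fit_rows)
        fits.to_csv(out / "fits.csv", index=False, float_format="%.10g")

        stage = "correlation_battery"
        merged = cohort.table.merge(
            fits.rename(columns={c: f"{c}_hat" for c in fits.columns
                                 if c != "subject_id"}),
            on="subject_id").merge(summaries, on="subject_id")
        merged.to_csv(out / "merged.csv", index=False, float_format="%.10g")
        battery = correlation_battery(
            merged, x_cols=["w_low_hat", "metacontrol_hat"],
            y_cols=["age", "flanker", "stroop", "wm_span",
                    "corrected_reward_rate"],
            alpha_family=config.alpha_family, m_tests=config.m_tests)
        battery.to_csv(out / "correlations.csv", index=False,
                       float_format="%.10g")
        (out / "correlations.txt").write_text(render_battery(battery) + "\n")

        stage = "mediation"
        med = {}
        for side, col in (("left", "thickness_left"),
                          ("right", "thickness_right")):
            res = mediation(merged[col], merged["flanker"],
                            merged["metacontrol_hat"], n_boot=config.n_boot,
                            seed=stage_seeds["bootstrap"])
            med[side] = res.to_dict()
        with open(out / "mediation.json", "w") as fh:
            json.dump(med, fh, indent=2, sort_keys=True)
    except Exception as exc:
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config.save(out / "config.yaml")
    log.info("pipeline complete: %d subjects, %d fitted", len(cohort.table),
             len(fits))
    return {"cohort": cohort, "tables": tables, "summaries": summaries,
            "fits": fits, "battery": battery, "mediation": med}


def _setup_logging(logfile: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    log.addHandler(logging.FileHandler(logfile, mode="w"))
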