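"""Run orchestration and reporting: simulant-classification tables,
PSE-versus-conflict predictions, and drop-in analysis of trial logs.

A :class:`RunConfig` fully specifies a run (population, generating models,
design, sizes, master seed); reports are written as CSV plus a plain-text
summary, together with a YAML snapshot of the resolved configuration so
every run is reproducible from its output directory alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import _MODEL_ORDER, classify_cohort, classify_observer
from .inference import joint_posterior, pse_estimate, sigma_posterior
from .models import Model, pse_slope
from .simulate import (
    Condition,
    ExperimentDesign,
    PopulationSpec,
    condition_data_from_trials,
    conflict_design,
    design_from_dict,
    mcs_design,
    population_from_dict,
    read_trials,
)

__all__ = ["RunConfig", "RunReport", "run_table1", "run_table2",
           "analyze_dataset", "load_config"]


@dataclass
class RunConfig:
    """Fully resolved configuration of a classification run."""

    population: PopulationSpec | int | dict = 3
    models: tuple[str, ...] = ("OPT", "WTA", "AVG")
    design: ExperimentDesign | dict | None = None
    conflict: bool = False
    n_simulants: int = 1000
    n_triplets: int = 1000
    seed: int = 0
    output_dir: str | None = None

    def resolve(self) -> "RunConfig":
        pop = population_from_dict(self.population)
        if self.design is None:
            design = conflict_design() if self.conflict else mcs_design()
        else:
            design = design_from_dict(self.design)
        has_conflict = any(c.kind == "Conflict" for c in design.conditions)
        if has_conflict != self.conflict:
            raise ValueError("config 'conflict' flag does not match the design")
        if self.n_simulants < 1 or self.n_triplets < 1:
            raise ValueError("n_simulants and n_triplets must be >= 1")
        return RunConfig(pop, tuple(Model(m).value for m in self.models),
                         design, self.conflict, int(self.n_simulants),
                         int(self.n_triplets), int(self.seed), self.output_dir)

    def to_dict(self) -> dict:
        pop = population_from_dict(self.population)
        design = (design_from_dict(self.design) if self.design is not None
                  else (conflict_design() if self.conflict else mcs_design()))
        return {
            "population": {"name": pop.name, "mean": list(pop.mean),
                           "sd": list(pop.sd)},
            "models": list(self.models),
            "design": {
                "reference_radius": design.reference_radius,
                "comparison_radii": list(design.comparison_radii),
                "trials_per_level": design.trials_per_level,
                "conditions": [c.label for c in design.conditions],
                "schedule": design.schedule,
            },
            "conflict": self.conflict,
            "n_simulants": self.n_simulants,
            "n_triplets": self.n_triplets,
            "seed": self.seed,
        }


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(
        population=raw.get("population", 3),
        models=tuple(raw.get("models", ("OPT", "WTA", "AVG"))),
        design=raw.get("design"),
        conflict=bool(raw.get("conflict", False)),
        n_simulants=int(raw.get("n_simulants", 1000)),
        n_triplets=int(raw.get("n_triplets", 1000)),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir"),
    )


@dataclass
class RunReport:
    """Everything a classification run produces, recomputable from its logs."""

    config: dict
    confusion: pd.DataFrame          # rows = assigned label, cols = generator
    observers: pd.DataFrame          # one row per simulant
    sigma_summary: pd.DataFrame      # per-condition sigma modes, mean +/- SE
    pse_table: pd.DataFrame | None = None  # conflict runs only

    def write(self, outdir) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=False)
        self.confusion.to_csv(out / "confusion.csv")
        self.observers.to_csv(out / "observers.csv", index=False)
        self.sigma_summary.to_csv(out / "sigma_summary.csv", index=False)
        if self.pse_table is not None:
            self.pse_table.to_csv(out / "pse_vs_conflict.csv", index=False)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.render())
        return out

    def render(self) -> str:
        lines = ["Simulant classification", "=" * 24, "",
                 self.confusion.to_string(), "", "Per-condition sigma summary",
                 "-" * 28, self.sigma_summary.round(3).to_string(index=False)]
        if self.pse_table is not None:
            lines += ["", "PSE shift vs conflict (observed and predicted)",
                      "-" * 46, self.pse_table.round(3).to_string(index=False)]
        lines.append("")
        return "\n".join(lines)


def _sigma_summary(observers: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cue in ("thumb", "index", "config"):
        col = observers[f"sigma_{cue}_mode"]
        rows.append({"condition": cue.capitalize(), "mean_sigma_mode": col.mean(),
                     "se": col.std(ddof=1) / np.sqrt(len(col)) if len(col) > 1 else 0.0})
    return pd.DataFrame(rows)


def _pse_table(observers: pd.DataFrame, conflicts: tuple[float, ...]) -> pd.DataFrame:
    """Mean observed PSE shift per conflict level, per generating strategy,
    with each model's predicted line evaluated at the mean estimated sigmas."""
    rows = []
    for strat, grp in observers.groupby("strategy", sort=True):
        sig = grp[["sigma_thumb_mode", "sigma_index_mode",
                   "sigma_config_mode"]].mean().to_numpy()
        for c in conflicts:
            col = grp[f"pse_{c:+g}"]
            row = {"strategy": strat, "conflict_mm": c,
                   "mean_pse_mm": col.mean(),
                   "se": col.std(ddof=1) / np.sqrt(len(col)) if len(col) > 1 else 0.0}
            for m in Model:
                row[f"pred_{m.value}"] = pse_slope(m, sig) * c
            rows.append(row)
    return pd.DataFrame(rows)


def _run_tables(config: RunConfig, conflict: bool) -> RunReport:
    cfg = config.resolve()
    if cfg.conflict != conflict:
        cfg = RunConfig(cfg.population, cfg.models, None, conflict,
                        cfg.n_simulants, cfg.n_triplets, cfg.seed,
                        cfg.output_dir).resolve()
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for m in cfg.models:
        frames.append(classify_cohort(Model(m), cfg.population, cfg.n_simulants,
                                      cfg.design, rng, cfg.n_triplets,
                                      id_prefix=m.lower(),
                                      include_pse=conflict))
    observers = pd.concat(frames, ignore_index=True)
    confusion = observers.pivot_table(index="classification", columns="strategy",
                                      aggfunc="size", fill_value=0)
    order = [m.value for m in _MODEL_ORDER]
    confusion = confusion.reindex(index=order, columns=[m for m in order
                                                        if m in confusion.columns],
                                  fill_value=0)
    confusion.columns = [f"{c} simulant" for c in confusion.columns]
    pse_table = None
    if conflict:
        conflicts = tuple(c.conflict for c in cfg.design.conditions
                          if c.kind == "Conflict")
        pse_table = _pse_table(observers, conflicts)
    report = RunReport(cfg.to_dict(), confusion, observers,
                       _sigma_summary(observers), pse_table)
    if cfg.output_dir:
        report.write(cfg.output_dir)
    return report


def run_table1(config: RunConfig) -> RunReport:
    """Non-conflict classification run: cohorts of simulants per generating
    model on the four-condition MCS design; 3x3 confusion counts."""
    return _run_tables(config, conflict=False)


def run_table2(config: RunConfig) -> RunReport:
    """Cue-conflict classification run: single-cue blocks plus the four
    conflict conditions; confusion counts plus a PSE-versus-conflict table
    with per-model prediction lines."""
    return _run_tables(config, conflict=True)


def analyze_dataset(trial_log_path, config: RunConfig | None = None) -> RunReport:
    """Analyse a CSV trial log (synthetic or empirical) end to end.

    Per observer: aggregate counts per condition, estimate single-cue sigma
    posteriors, classify via marginal likelihood on the Combined or conflict
    conditions, and (for conflict data) estimate PSE shifts.  Observers
    missing a required condition are skipped with a warning column in the
    output rather than aborting the run.
    """
    import warnings

    cfg = (config or RunConfig()).resolve() if config else None
    trials = read_trials(trial_log_path)
    per_obs = condition_data_from_trials(trials)
    strategies = trials.drop_duplicates("observer_id").set_index("observer_id")[
        "strategy"].to_dict() if "strategy" in trials.columns else {}
    n_triplets = cfg.n_triplets if cfg else 1000
    seed = cfg.seed if cfg else 0
    rng = np.random.default_rng(seed)
    rows = []
    for obs_id in sorted(per_obs):
        conds = per_obs[obs_id]
        singles = {k.lower(): conds[k] for k in ("Thumb", "Index", "Config")
                   if k in conds}
        conflict = {Condition.parse(lbl).conflict: d for lbl, d in conds.items()
                    if lbl.startswith("Conflict")}
        if len(singles) < 3 or not (conflict or "Combined" in conds):
            warnings.warn(f"observer {obs_id!r} is missing a required "
                          f"condition; skipped")
            continue
        posteriors = {cue: sigma_posterior(d) for cue, d in singles.items()}
        data = conflict if conflict else conds["Combined"]
        mp = classify_observer(posteriors, data, n_triplets, rng)
        row = {
            "observer_id": obs_id,
            "strategy": strategies.get(obs_id, ""),
            "sigma_thumb_mode": posteriors["thumb"].mode(),
            "sigma_index_mode": posteriors["index"].mode(),
            "sigma_config_mode": posteriors["config"].mode(),
            "p_OPT": mp.probs[Model.OPT], "p_WTA": mp.probs[Model.WTA],
            "p_AVG": mp.probs[Model.AVG],
            "classification": mp.classification.value, "tie_flag": mp.tie,
        }
        for c, d in sorted(conflict.items()):
            row[f"pse_{c:+g}"] = pse_estimate(joint_posterior(d))
        rows.append(row)
    observers = pd.DataFrame(rows)
    if observers.empty:
        raise ValueError("no observer in the trial log had a complete "
                         "condition set")
    confusion = observers.pivot_table(index="classification", columns="strategy",
                                      aggfunc="size", fill_value=0)
    conflicts = tuple(sorted({Condition.parse(lbl).conflict
                              for lbl in trials["condition"].unique()
                              if str(lbl).startswith("Conflict")}))
    pse_table = _pse_table(observers, conflicts) if conflicts and \
        "strategy" in observers.columns and observers["strategy"].any() else None
    cfg_dict = cfg.to_dict() if cfg else {"trial_log": str(trial_log_path)}
    report = RunReport(cfg_dict, confusion, observers,
                       _sigma_summary(observers), pse_table)
    if cfg and cfg.output_dir:
        report.write(cfg.output_dir)
    return report
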