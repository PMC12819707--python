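"""Synthetic observers and simulated 2IFC haptic size-discrimination experiments.

A *simulant* is a model observer with a fixed triplet of cue sigmas and a
fixed combination strategy.  Populations of simulants are defined by drawing
each cue sigma from a per-cue normal distribution (truncated below at
0.1 mm so that noise SDs stay positive).  Experiments present a reference
disk against comparison disks at a fixed set of radius differences (method of
constant stimuli) or under a Bayesian adaptive schedule, in four cue
conditions (Thumb, Index, Config, Combined) and optionally in cue-conflict
conditions where the reference is an oval-like object whose horizontal
half-width and edge curvature correspond to circles of different radii.

Conflict sign convention: a conflict of +c mm means the configuration cue is
centred on ``reference + c`` while both cutaneous cues are centred on
``reference - c``.  Only the reference carries a conflict; comparison disks
are always circular.

Trial logs round-trip through plain CSV (one row per trial; see
:data:`TRIAL_COLUMNS`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from scipy.special import ndtr

from .inference import (
    DEFAULT_MU_GRID,
    DEFAULT_SIGMA_GRID,
    ConditionData,
    expected_information_gain,
)
from .models import CUE_ORDER, CueSample, CueSigmas, Model, percept

__all__ = [
    "SIGMA_FLOOR",
    "PopulationSpec",
    "POPULATIONS",
    "Simulant",
    "Condition",
    "ConflictStimulus",
    "ExperimentDesign",
    "ExperimentResult",
    "TRIAL_COLUMNS",
    "STANDARD_CONDITIONS",
    "SINGLE_CUE_CONDITIONS",
    "draw_simulant",
    "draw_sigma_triplets",
    "sample_cues",
    "simulate_trial",
    "run_experiment",
    "make_conflict_stimulus",
    "mcs_design",
    "conflict_design",
    "experiment1_design",
    "experiment2_design",
    "write_trials",
    "read_trials",
    "condition_data_from_trials",
    "population_from_dict",
    "design_from_dict",
]

#: Lower truncation (mm) for sampled cue sigmas; far below any plausible
#: discrimination threshold, so the populations are minimally distorted.
SIGMA_FLOOR = 0.1


@dataclass(frozen=True)
class PopulationSpec:
    """Population of observers: per-cue sigma means and SDs (mm).

    ``mean`` and ``sd`` are (thumb, index, config) triplets; each observer's
    cue sigma is drawn from Normal(mean, sd) truncated below at
    :data:`SIGMA_FLOOR`.
    """

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        if m.shape != (3,) or s.shape != (3,):
            raise ValueError("mean and sd must be (thumb, index, config) triplets")
        if np.any(m <= 0) or np.any(s < 0):
            raise ValueError("sigma means must be positive and SDs non-negative")


#: The three study populations: one exceptional cue, similar cues, varied cues.
POPULATIONS: dict[int, PopulationSpec] = {
    1: PopulationSpec((8.0, 8.0, 2.0), (2.0, 2.0, 1.0), "population-1"),
    2: PopulationSpec((4.0, 4.0, 4.0), (0.1, 0.1, 0.1), "population-2"),
    3: PopulationSpec((7.0, 6.0, 3.0), (2.0, 3.0, 1.0), "population-3"),
}


@dataclass(frozen=True)
class Simulant:
    """A model observer: identifier, cue sigmas, and combination strategy."""

    id: str
    sigmas: CueSigmas
    strategy: Model


@dataclass(frozen=True)
class ConflictStimulus:
    """Oval-like reference whose width and curvature disagree.

    The half-width (driving the config cue) equals ``reference_radius +
    conflict`` and the curvature-equivalent radius (driving the cutaneous
    cues) equals ``reference_radius - conflict``.
    """

    reference_radius: float
    conflict: float

    def __post_init__(self) -> None:
        if not abs(self.conflict) < self.reference_radius:
            raise ValueError(
                f"|conflict| ({abs(self.conflict)}) must be smaller than the "
                f"reference radius ({self.reference_radius})"
            )

    @property
    def half_width(self) -> float:
        return self.reference_radius + self.conflict

    @property
    def curvature_radius(self) -> float:
        return self.reference_radius - self.conflict


def make_conflict_stimulus(reference_radius: float, conflict: float) -> ConflictStimulus:
    """Build a cue-conflict reference; raises on invalid geometry."""
    return ConflictStimulus(float(reference_radius), float(conflict))


@dataclass(frozen=True)
class Condition:
    """A testing condition: which cue(s) are available, and any conflict level."""

    kind: str  # "Thumb" | "Index" | "Config" | "Combined" | "Conflict"
    conflict: float = 0.0

    _KINDS = ("Thumb", "Index", "Config", "Combined", "Conflict")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.kind != "Conflict" and self.conflict != 0.0:
            raise ValueError("only Conflict conditions carry a conflict level")

    @property
    def label(self) -> str:
        if self.kind == "Conflict":
            return f"Conflict{self.conflict:+g}"
        return self.kind

    @classmethod
    def parse(cls, label: str) -> "Condition":
        if label.startswith("Conflict"):
            return cls("Conflict", float(label[len("Conflict"):]))
        return cls(label)

    @property
    def single_cue(self) -> str | None:
        return self.kind.lower() if self.kind in ("Thumb", "Index", "Config") else None


SINGLE_CUE_CONDITIONS = (Condition("Thumb"), Condition("Index"), Condition("Config"))
STANDARD_CONDITIONS = SINGLE_CUE_CONDITIONS + (Condition("Combined"),)


@dataclass(frozen=True)
class ExperimentDesign:
    """A 2IFC experiment: reference, comparison set, schedule, and conditions."""

    reference_radius: float
    comparison_radii: tuple[float, ...]
    trials_per_level: int
    conditions: tuple[Condition, ...] = STANDARD_CONDITIONS
    schedule: str = "MCS"
    block_size: int = 40

    def __post_init__(self) -> None:
        if self.trials_per_level < 1:
            raise ValueError("trials_per_level must be >= 1")
        if self.schedule not in ("MCS", "adaptive"):
            raise ValueError("schedule must be 'MCS' or 'adaptive'")
        radii = np.asarray(self.comparison_radii, dtype=float)
        if radii.size == 0 or np.unique(radii).size != radii.size:
            raise ValueError("comparison radii must be distinct and non-empty")
        if np.any(radii == self.reference_radius):
            raise ValueError("comparison radii must differ from the reference")
        for cond in self.conditions:
            if cond.kind == "Conflict":
                make_conflict_stimulus(self.reference_radius, cond.conflict)

    @property
    def deltas(self) -> np.ndarray:
        """Comparison minus reference radii (mm), sorted."""
        return np.sort(np.asarray(self.comparison_radii, dtype=float)
                       - self.reference_radius)

    @property
    def trials_per_condition(self) -> int:
        return len(self.comparison_radii) * self.trials_per_level


#: Disk set of Experiments 2/3 (reference 10 mm); delta-identical to the
#: Experiment 1 set (reference 15 mm).
_EXP23_RADII = (5.0, 8.0, 9.0, 9.5, 10.5, 11.0, 12.0, 15.0)
_EXP1_RADII = (10.0, 13.0, 14.0, 14.5, 15.5, 16.0, 17.0, 20.0)


def mcs_design(reference_radius: float = 10.0,
               comparison_radii: Sequence[float] = _EXP23_RADII,
               trials_per_level: int = 20,
               conditions: Sequence[Condition] = STANDARD_CONDITIONS) -> ExperimentDesign:
    """Method-of-constant-stimuli design: 8 levels x 20 trials by default."""
    return ExperimentDesign(float(reference_radius), tuple(comparison_radii),
                            int(trials_per_level), tuple(conditions), "MCS")


def conflict_design(conflicts: Sequence[float] = (-3.0, -2.0, 2.0, 3.0),
                    reference_radius: float = 10.0,
                    comparison_radii: Sequence[float] = _EXP23_RADII,
                    trials_per_level: int = 20) -> ExperimentDesign:
    """Cue-conflict design: three single-cue blocks plus one block per conflict level."""
    conds = SINGLE_CUE_CONDITIONS + tuple(
        Condition("Conflict", float(c)) for c in conflicts)
    return ExperimentDesign(float(reference_radius), tuple(comparison_radii),
                            int(trials_per_level), conds, "MCS")


def experiment1_design() -> ExperimentDesign:
    """Circular disks around a 15 mm reference, MCS, 8 levels x 20 trials."""
    return mcs_design(15.0, _EXP1_RADII, 20)


def experiment2_design() -> ExperimentDesign:
    """Smaller circular disks around a 10 mm reference, adaptive schedule."""
    return ExperimentDesign(10.0, _EXP23_RADII, 20, STANDARD_CONDITIONS, "adaptive")


# --- observers -------------------------------------------------------------

def draw_sigma_triplets(pop: PopulationSpec, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` (thumb, index, config) sigma triplets from a population.

    Each sigma is an independent draw from Normal(mean, sd) truncated below at
    :data:`SIGMA_FLOOR`; a zero population SD yields the mean exactly.
    """
    m = np.asarray(pop.mean, dtype=float)
    s = np.asarray(pop.sd, dtype=float)
    out = np.tile(m, (n, 1))
    for j in range(3):
        if s[j] > 0:
            a = (SIGMA_FLOOR - m[j]) / s[j]
            out[:, j] = truncnorm.rvs(a, np.inf, loc=m[j], scale=s[j],
                                      size=n, random_state=rng)
    return out


def draw_simulant(pop: PopulationSpec, strategy: Model,
                  rng: np.random.Generator, id: str = "sim-0") -> Simulant:
    """Draw one simulant from a population with the given strategy."""
    trip = draw_sigma_triplets(pop, 1, rng)[0]
    return Simulant(id, CueSigmas(*trip), Model(strategy))


def sample_cues(sigmas: CueSigmas, radius: float, conflict: float = 0.0,
                rng: np.random.Generator | None = None, size: int | None = None):
    """Draw noisy cue measurements for one stimulus presentation.

    Cutaneous cues are centred on ``radius - conflict`` and the config cue on
    ``radius + conflict`` (conflict = 0 for circular disks).  Returns a
    :class:`~cuecombo.models.CueSample` when ``size`` is None, else an array
    of shape ``(size, 3)``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng() if rng is None else rng
    means = np.array([radius - conflict, radius - conflict, radius + conflict])
    sig = sigmas.as_array() if isinstance(sigmas, CueSigmas) else np.asarray(sigmas, float)
    draws = rng.normal(means, sig, size=(size or 1, 3))
    if size is None:
        return CueSample(*draws[0])
    return draws


def _interval_percepts(sim: Simulant, cond: Condition, radii: np.ndarray,
                       conflicts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Percepts for a batch of stimulus presentations (one interval each).

    In single-cue conditions the percept is that cue's raw sample (all three
    strategies degenerate to the same single-cue observer); otherwise the
    simulant's strategy combines the three samples.
    """
    n = radii.size
    means = np.stack([radii - conflicts, radii - conflicts, radii + conflicts],
                     axis=1)
    cues = rng.normal(means, sim.sigmas.as_array()[None, :], size=(n, 3))
    cue = cond.single_cue
    if cue is not None:
        return cues[:, CUE_ORDER.index(cue)]
    return percept(sim.strategy, cues, sim.sigmas.as_array()[None, :])


def _responses(sim: Simulant, cond: Condition, deltas: np.ndarray,
               reference: float, rng: np.random.Generator) -> np.ndarray:
    """Simulate comp-judged-larger responses for a batch of trials.

    The reference carries the condition's conflict; comparisons are circular
    at ``reference + delta``.  Exact percept ties (probability zero under
    continuous noise) are broken by a fair coin.
    """
    n = deltas.size
    c = np.full(n, cond.conflict)
    p_ref = _interval_percepts(sim, cond, np.full(n, reference), c, rng)
    p_comp = _interval_percepts(sim, cond, reference + deltas, np.zeros(n), rng)
    resp = p_comp > p_ref
    ties = p_comp == p_ref
    if ties.any():
        resp[ties] = rng.random(int(ties.sum())) < 0.5
    return resp


def simulate_trial(sim: Simulant, condition, delta: float,
                   conflict: float | None = None,
                   rng: np.random.Generator | None = None,
                   reference_radius: float = 10.0) -> dict:
    """Simulate a single 2IFC trial and return a trial record (dict).

    ``condition`` may be a :class:`Condition` or its label.  ``conflict``
    overrides the condition's conflict level when given.  ``correct`` is None
    for conflict-reference trials, where "correct" is undefined.
    """
    cond = condition if isinstance(condition, Condition) else Condition.parse(condition)
    if conflict is not None and cond.kind == "Conflict":
        cond = Condition("Conflict", float(conflict))
    rng = np.random.default_rng() if rng is None else rng
    comp_first = bool(rng.random() < 0.5)  # presentation order, 0.5 each
    resp = bool(_responses(sim, cond, np.array([float(delta)]),
                           reference_radius, rng)[0])
    correct = None if cond.kind == "Conflict" else bool(resp == (delta > 0))
    return {
        "condition": cond.label,
        "conflict_mm": cond.conflict,
        "reference_mm": reference_radius,
        "comparison_mm": reference_radius + float(delta),
        "delta_mm": float(delta),
        "response_comp_larger": resp,
        "comparison_first": comp_first,
        "correct": correct,
    }


#: Mandatory trial-log columns (CSV header).
TRIAL_COLUMNS = [
    "observer_id", "strategy", "condition", "conflict_mm", "reference_mm",
    "comparison_mm", "delta_mm", "response_comp_larger", "block", "trial_index",
]


@dataclass
class ExperimentResult:
    """Outcome of one simulated experiment for one simulant."""

    simulant: Simulant
    design: ExperimentDesign
    condition_data: dict[str, ConditionData]
    trials: pd.DataFrame | None = None

    def conflict_data(self) -> dict[float, ConditionData]:
        """Map conflict level -> counts, for the Conflict conditions."""
        return {
            cond.conflict: self.condition_data[cond.label]
            for cond in self.design.conditions if cond.kind == "Conflict"
        }

    def single_cue_data(self) -> dict[str, ConditionData]:
        return {
            cond.kind.lower(): self.condition_data[cond.label]
            for cond in self.design.conditions if cond.single_cue
        }


def _run_condition_mcs(sim: Simulant, design: ExperimentDesign, cond: Condition,
                       rng: np.random.Generator):
    deltas = np.repeat(design.deltas, design.trials_per_level)
    deltas = deltas[rng.permutation(deltas.size)]
    comp_first = rng.random(deltas.size) < 0.5
    resp = _responses(sim, cond, deltas, design.reference_radius, rng)
    return deltas, resp, comp_first


def _run_condition_adaptive(sim: Simulant, design: ExperimentDesign,
                            cond: Condition, rng: np.random.Generator):
    """Greedy entropy-based adaptive schedule with the design's deltas as candidates.

    The running posterior is over sigma alone for circular-reference
    conditions and over (mu, sigma) for conflict conditions; it is updated
    trial by trial with the cumulative-normal likelihood of the observed
    response.
    """
    cand = design.deltas
    n_total = design.trials_per_condition
    if cond.kind == "Conflict":
        mu, sg = DEFAULT_MU_GRID, DEFAULT_SIGMA_GRID
        psi = ndtr((cand[:, None, None] - mu[None, :, None])
                   / (np.sqrt(2.0) * sg[None, None, :])).reshape(cand.size, -1)
        p = np.full(mu.size * sg.size, 1.0 / (mu.size * sg.size))
    else:
        sg = DEFAULT_SIGMA_GRID
        psi = ndtr(cand[:, None] / (np.sqrt(2.0) * sg[None, :]))
        p = np.full(sg.size, 1.0 / sg.size)
    deltas = np.empty(n_total)
    resp = np.empty(n_total, dtype=bool)
    comp_first = rng.random(n_total) < 0.5
    for t in range(n_total):
        gains = expected_information_gain(p, psi)
        c = int(np.argmax(np.round(gains, 12)))
        deltas[t] = cand[c]
        r = bool(_responses(sim, cond, cand[c:c + 1],
                            design.reference_radius, rng)[0])
        resp[t] = r
        p = p * (psi[c] if r else (1.0 - psi[c]))
        p /= p.sum()
    return deltas, resp, comp_first


def run_experiment(sim: Simulant, design: ExperimentDesign,
                   rng: np.random.Generator,
                   keep_trials: bool = True) -> ExperimentResult:
    """Simulate every condition of a design for one simulant.

    Conditions are run in the design's order, each on the shared ``rng``
    stream, so a fixed seed reproduces the experiment exactly.  With
    ``keep_trials`` a tidy per-trial DataFrame (columns
    :data:`TRIAL_COLUMNS` plus ``comparison_first`` and ``correct``) is
    attached to the result.
    """
    cond_data: dict[str, ConditionData] = {}
    frames = []
    for cond in design.conditions:
        if design.schedule == "adaptive":
            deltas, resp, comp_first = _run_condition_adaptive(sim, design, cond, rng)
        else:
            deltas, resp, comp_first = _run_condition_mcs(sim, design, cond, rng)
        cond_data[cond.label] = ConditionData.from_responses(deltas, resp)
        if keep_trials:
            n = deltas.size
            correct = (resp == (deltas > 0)) if cond.kind != "Conflict" else \
                np.full(n, None)
            frames.append(pd.DataFrame({
                "observer_id": sim.id,
                "strategy": sim.strategy.value,
                "condition": cond.label,
                "conflict_mm": cond.conflict,
                "reference_mm": design.reference_radius,
                "comparison_mm": design.reference_radius + deltas,
                "delta_mm": deltas,
                "response_comp_larger": resp,
                "block": np.arange(n) // design.block_size,
                "trial_index": np.arange(n),
                "comparison_first": comp_first,
                "correct": correct,
            }))
    trials = pd.concat(frames, ignore_index=True) if keep_trials else None
    return ExperimentResult(sim, design, cond_data, trials)


# --- trial-log serialisation ----------------------------------------------

def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial log as CSV with the mandatory column set first."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial log is missing required columns: {missing}")
    extra = [c for c in trials.columns if c not in TRIAL_COLUMNS]
    trials[TRIAL_COLUMNS + extra].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a CSV trial log.

    Raises ``ValueError`` naming missing header columns, and reports 1-based
    line numbers for rows with unparseable numeric fields.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(
            f"empty trial log: missing header columns {TRIAL_COLUMNS}") from None
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log header is missing columns: {missing}")
    bad_lines = []
    for col in ("conflict_mm", "reference_mm", "comparison_mm", "delta_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((np.flatnonzero(vals.isna()) + 2).tolist())
        df[col] = vals
    resp = df["response_comp_larger"].astype(str).str.strip().str.lower()
    ok = resp.isin(["true", "false", "0", "1"])
    bad_lines.extend((np.flatnonzero(~ok) + 2).tolist())
    if bad_lines:
        raise ValueError(
            f"malformed trial-log rows at line(s) {sorted(set(bad_lines))}")
    df["response_comp_larger"] = resp.isin(["true", "1"])
    return df


def condition_data_from_trials(trials: pd.DataFrame) -> dict[str, dict[str, ConditionData]]:
    """Aggregate a trial log into per-observer, per-condition counts."""
    out: dict[str, dict[str, ConditionData]] = {}
    for (obs, cond), grp in trials.groupby(["observer_id", "condition"], sort=True):
        out.setdefault(str(obs), {})[str(cond)] = ConditionData.from_responses(
            grp["delta_mm"].to_numpy(), grp["response_comp_larger"].to_numpy())
    return out


# --- config deserialisation ------------------------------------------------

def population_from_dict(spec) -> PopulationSpec:
    """Resolve a population from a name/number (1, 2, 3) or an explicit mapping
    with ``mean`` and ``sd`` triplets (thumb, index, config)."""
    if isinstance(spec, PopulationSpec):
        return spec
    if isinstance(spec, (int, str)) and str(spec).strip("population-") in {"1", "2", "3"}:
        return POPULATIONS[int(str(spec).strip("population-"))]
    return PopulationSpec(tuple(float(x) for x in spec["mean"]),
                          tuple(float(x) for x in spec["sd"]),
                          str(spec.get("name", "")))


def design_from_dict(spec: Mapping) -> ExperimentDesign:
    """Build an :class:`ExperimentDesign` from a plain mapping (e.g. YAML)."""
    if isinstance(spec, ExperimentDesign):
        return spec
    conflicts = spec.get("conflicts")
    if conflicts:
        conds = SINGLE_CUE_CONDITIONS + tuple(
            Condition("Conflict", float(c)) for c in conflicts)
    else:
        conds = tuple(Condition.parse(c) for c in spec.get(
            "conditions", [c.label for c in STANDARD_CONDITIONS]))
    return ExperimentDesign(
        float(spec.get("reference_radius", 10.0)),
        tuple(float(r) for r in spec.get("comparison_radii", _EXP23_RADII)),
        int(spec.get("trials_per_level", 20)),
        conds,
        str(spec.get("schedule", "MCS")),
    )
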