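"""Marginal-likelihood model comparison for cue-combination observers.

Each observer's three single-cue conditions yield gridded posteriors over
the cue sigmas.  Sampling one sigma per cue from those posteriors gives a
*triplet*; pushing a triplet through a model's combined-sigma (and, for
conflict data, PSE-slope) formula gives that model's predicted psychometric
parameters.  Averaging the likelihood of the Combined (or conflict)
condition data over many sampled triplets approximates the model's marginal
likelihood; with a uniform model prior, normalised marginal likelihoods are
the model posterior probabilities, and the argmax is the classification.

The same sampled triplets are used for all three models of one observer, as
each triplet is a draw from the shared single-cue posterior and serves as
input to every model formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import (
    ConditionData,
    SigmaPosterior,
    condition_log_likelihood,
    joint_posterior,
    pse_estimate,
    sample_sigmas,
    sigma_posterior,
)
from .models import CUE_ORDER, Model, combined_sigma, pse_slope
from .simulate import (
    ExperimentDesign,
    PopulationSpec,
    Simulant,
    CueSigmas,
    draw_sigma_triplets,
    run_experiment,
)

__all__ = [
    "ModelPosterior",
    "sample_triplets",
    "marginal_log_likelihood",
    "conflict_marginal_log_likelihood",
    "model_posteriors",
    "classify_observer",
    "classify_cohort",
    "classify_population",
    "confusion_table",
]

#: Classification tie-break priority.
_MODEL_ORDER = (Model.OPT, Model.WTA, Model.AVG)


@dataclass(frozen=True)
class ModelPosterior:
    """Posterior probability of each strategy for one observer."""

    probs: dict[Model, float]
    classification: Model
    tie: bool
    n_triplets: int

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError("model posterior probabilities must sum to 1")
        if self.probs[self.classification] < max(self.probs.values()) - 1e-12:
            raise ValueError("classification must attain the maximum probability")

    def bayes_factor(self, a: Model, b: Model) -> float:
        """Posterior-odds ratio of two models (equals the marginal-likelihood
        ratio under the uniform model prior)."""
        return self.probs[Model(a)] / self.probs[Model(b)]


def _posterior_triple(single_cue_posteriors) -> tuple[SigmaPosterior, ...]:
    if isinstance(single_cue_posteriors, Mapping):
        return tuple(single_cue_posteriors[c] for c in CUE_ORDER)
    triple = tuple(single_cue_posteriors)
    if len(triple) != 3:
        raise ValueError("expected three single-cue posteriors (thumb, index, config)")
    return triple


def sample_triplets(single_cue_posteriors, n_triplets: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw ``(n_triplets, 3)`` sigma triplets, one independent inverse-CDF
    draw per cue posterior (thumb, index, config order)."""
    post = _posterior_triple(single_cue_posteriors)
    return np.column_stack([sample_sigmas(p, n_triplets, rng) for p in post])


def marginal_log_likelihood(single_cue_posteriors, combined_data: ConditionData,
                            model: Model, n_triplets: int = 1000,
                            rng: np.random.Generator | None = None,
                            triplets: np.ndarray | None = None) -> float:
    """Log marginal likelihood of non-conflict Combined data under one model.

    For each sampled triplet the model's combined sigma is evaluated against
    the data (on the sqrt(2) psychometric scale); the marginal likelihood is
    the plain arithmetic mean of the per-triplet likelihoods, computed with
    log-sum-exp.
    """
    if triplets is None:
        if n_triplets < 1:
            raise ValueError("n_triplets must be >= 1")
        rng = np.random.default_rng() if rng is None else rng
        triplets = sample_triplets(single_cue_posteriors, n_triplets, rng)
    sig = combined_sigma(Model(model), triplets)
    ll = condition_log_likelihood(combined_data, np.sqrt(2.0) * np.atleast_1d(sig))
    return float(logsumexp(ll) - np.log(np.atleast_1d(sig).size))


def conflict_marginal_log_likelihood(single_cue_posteriors,
                                     conflict_data: Mapping[float, ConditionData],
                                     model: Model, n_triplets: int = 1000,
                                     rng: np.random.Generator | None = None,
                                     triplets: np.ndarray | None = None) -> float:
    """Log marginal likelihood of cue-conflict data under one model.

    Per triplet, the model predicts a (PSE shift, combined sigma) pair for
    every conflict level; the likelihood is evaluated jointly across all
    conflict conditions and then averaged over triplets.  For WTA the most
    reliable cue is re-evaluated per triplet.
    """
    if not conflict_data:
        raise ValueError("conflict_data must contain at least one conflict level")
    if triplets is None:
        if n_triplets < 1:
            raise ValueError("n_triplets must be >= 1")
        rng = np.random.default_rng() if rng is None else rng
        triplets = sample_triplets(single_cue_posteriors, n_triplets, rng)
    model = Model(model)
    sig = np.atleast_1d(combined_sigma(model, triplets))
    slope = np.atleast_1d(pse_slope(model, triplets))
    total = np.zeros(sig.size)
    for c, data in conflict_data.items():
        total += condition_log_likelihood(data, np.sqrt(2.0) * sig, slope * float(c))
    return float(logsumexp(total) - np.log(sig.size))


def model_posteriors(log_marginals: Mapping[Model, float],
                     prior: Mapping[Model, float] | None = None,
                     n_triplets: int = 0) -> ModelPosterior:
    """Normalise per-model log marginal likelihoods into a model posterior.

    The prior defaults to uniform (1/3 each).  Classification is the argmax,
    with exact ties resolved in the order OPT > WTA > AVG and flagged.
    """
    models = list(_MODEL_ORDER)
    logm = np.array([float(log_marginals[m]) for m in models])
    if prior is None:
        logp = np.zeros(3)
    else:
        pr = np.array([float(prior[m]) for m in models])
        if abs(pr.sum() - 1.0) > 1e-8 or np.any(pr < 0):
            raise ValueError("model prior must be a probability distribution")
        with np.errstate(divide="ignore"):
            logp = np.log(pr)
    score = logm + logp
    if not np.any(np.isfinite(score)):
        raise ValueError("all model marginal likelihoods are zero; "
                         "classification is degenerate")
    probs = np.exp(score - logsumexp(score))
    probs /= probs.sum()
    best = int(np.argmax(probs))  # first of ties -> OPT > WTA > AVG priority
    tie = bool(np.sum(np.isclose(probs, probs[best], rtol=0, atol=1e-12)) > 1)
    return ModelPosterior(dict(zip(models, probs.tolist())),
                          models[best], tie, n_triplets)


def classify_observer(single_cue_posteriors,
                      data,
                      n_triplets: int = 1000,
                      rng: np.random.Generator | None = None,
                      prior: Mapping[Model, float] | None = None) -> ModelPosterior:
    """Classify one observer from single-cue posteriors and combined/conflict data.

    ``data`` is either a :class:`ConditionData` (non-conflict Combined
    condition, marginal likelihood over sigma alone) or a mapping
    ``conflict level -> ConditionData`` (joint PSE/sigma marginal
    likelihood).  One shared triplet sample feeds all three models.
    """
    rng = np.random.default_rng() if rng is None else rng
    triplets = sample_triplets(single_cue_posteriors, n_triplets, rng)
    if isinstance(data, ConditionData):
        logm = {m: marginal_log_likelihood(single_cue_posteriors, data, m,
                                           triplets=triplets) for m in Model}
    else:
        logm = {m: conflict_marginal_log_likelihood(single_cue_posteriors, data,
                                                    m, triplets=triplets)
                for m in Model}
    return model_posteriors(logm, prior, n_triplets)


def _classify_one(sim: Simulant, design: ExperimentDesign, n_triplets: int,
                  rng: np.random.Generator, sigma_grid=None,
                  include_pse: bool = False) -> dict:
    """Full per-observer pipeline: simulate -> single-cue posteriors ->
    shared triplets -> per-model marginals -> classification."""
    res = run_experiment(sim, design, rng, keep_trials=False)
    posteriors = {cue: sigma_posterior(d, sigma_grid)
                  for cue, d in res.single_cue_data().items()}
    conflict = res.conflict_data()
    data = conflict if conflict else res.condition_data["Combined"]
    mp = classify_observer(posteriors, data, n_triplets, rng)
    row = {
        "observer_id": sim.id,
        "strategy": sim.strategy.value,
        "sigma_thumb_true": sim.sigmas.thumb,
        "sigma_index_true": sim.sigmas.index,
        "sigma_config_true": sim.sigmas.config,
        "sigma_thumb_mode": posteriors["thumb"].mode(),
        "sigma_index_mode": posteriors["index"].mode(),
        "sigma_config_mode": posteriors["config"].mode(),
        "p_OPT": mp.probs[Model.OPT],
        "p_WTA": mp.probs[Model.WTA],
        "p_AVG": mp.probs[Model.AVG],
        "classification": mp.classification.value,
        "tie_flag": mp.tie,
    }
    if include_pse and conflict:
        for c, d in sorted(conflict.items()):
            row[f"pse_{c:+g}"] = pse_estimate(joint_posterior(d))
    return row


def classify_cohort(strategy: Model, pop: PopulationSpec, n_simulants: int,
                    design: ExperimentDesign, rng: np.random.Generator,
                    n_triplets: int = 1000,
                    id_prefix: str | None = None,
                    include_pse: bool = False) -> pd.DataFrame:
    """Simulate and classify a cohort of simulants sharing one strategy.

    Each simulant gets an independent child RNG stream spawned from ``rng``,
    so runs are reproducible and order-independent at the observer level.
    Returns one row per observer (sigmas, model posteriors, classification).
    """
    if n_simulants < 1:
        raise ValueError("n_simulants must be >= 1")
    strategy = Model(strategy)
    prefix = id_prefix or f"{strategy.value.lower()}"
    sig = draw_sigma_triplets(pop, n_simulants, rng)
    streams = rng.spawn(n_simulants)
    rows = []
    for i in range(n_simulants):
        sim = Simulant(f"{prefix}-{i:04d}", CueSigmas(*sig[i]), strategy)
        try:
            rows.append(_classify_one(sim, design, n_triplets, streams[i],
                                      include_pse=include_pse))
        except Exception as exc:  # annotate which simulant failed
            raise RuntimeError(f"classification failed for simulant "
                               f"{sim.id!r}: {exc}") from exc
    return pd.DataFrame(rows)


def classify_population(strategy: Model, pop: PopulationSpec, n_simulants: int,
                        design: ExperimentDesign, conflict: bool,
                        rng: np.random.Generator,
                        n_triplets: int = 1000) -> dict[Model, int]:
    """Counts of assigned labels for a cohort generated by one strategy.

    ``conflict`` must match the design (present Conflict conditions iff
    True); it is validated rather than inferred silently.
    """
    has_conflict = any(c.kind == "Conflict" for c in design.conditions)
    if conflict != has_conflict:
        raise ValueError("conflict flag does not match the design's conditions")
    if not conflict and not any(c.kind == "Combined" for c in design.conditions):
        raise ValueError("non-conflict classification requires a Combined condition")
    df = classify_cohort(strategy, pop, n_simulants, design, rng, n_triplets)
    counts = df["classification"].value_counts()
    return {m: int(counts.get(m.value, 0)) for m in _MODEL_ORDER}


def confusion_table(pop: PopulationSpec, design: ExperimentDesign,
                    n_simulants: int, conflict: bool,
                    rng: np.random.Generator,
                    n_triplets: int = 1000) -> pd.DataFrame:
    """3x3 confusion table: rows = assigned label, columns = generating model.

    Mirrors the layout of the simulant-classification tables: each column is
    an independent cohort of ``n_simulants`` generated by one strategy.
    """
    cols = {}
    for m in _MODEL_ORDER:
        counts = classify_population(m, pop, n_simulants, design, conflict,
                                     rng, n_triplets)
        cols[f"{m.value} simulant"] = [counts[a] for a in _MODEL_ORDER]
    return pd.DataFrame(cols, index=[m.value for m in _MODEL_ORDER])
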