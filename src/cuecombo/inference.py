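"""Bayesian grid inference for 2IFC psychometric data.

The psychometric function is a cumulative normal of the stimulus level
``delta`` (comparison radius minus reference radius, mm):

    Psi(delta) = P(comp judged larger | delta) = Phi((delta - mu) / sigma_psy)

where ``mu`` is the PSE shift (non-zero only for cue-conflict references) and
``sigma_psy`` is the SD of the *difference* of the two interval percepts.
Because a 2IFC trial compares two independent percepts with common SD
``sigma``, ``sigma_psy = sqrt(2) * sigma``; that conversion is applied exactly
once, at likelihood evaluation, so all model predictions stay on the
single-interval scale.

Posteriors are computed on dense parameter grids with uniform priors
(``sigma``: 0.01–40.01 mm in 0.05 mm steps; ``mu``: −5 to +5 mm in 0.1 mm
steps by default) and are exact up to discretisation.  Bookkeeping note:
``k_delta`` always counts comparison-judged-larger responses (consistent with
Psi above), not correct responses; the two conventions coincide for positive
deltas and are related by ``k <-> n - k`` for negative deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import log_ndtr, logsumexp, ndtr

__all__ = [
    "ROOT2",
    "LOGLIK_FLOOR",
    "DEFAULT_SIGMA_GRID",
    "DEFAULT_MU_GRID",
    "ConditionData",
    "SigmaPosterior",
    "JointPosterior",
    "DegeneratePosteriorError",
    "psychometric_prob",
    "condition_log_likelihood",
    "condition_likelihood",
    "sigma_posterior",
    "sample_sigmas",
    "joint_posterior",
    "pse_estimate",
    "expected_information_gain",
    "select_next_stimulus",
]

ROOT2 = float(np.sqrt(2.0))

#: Floor on *max-centred* log-likelihoods when a posterior is normalised.
#: Psi has no lapse rate, so wildly wrong parameters can be penalised beyond
#: what exp() can represent; flooring the centred values (never the raw
#: ones — heavy-trial conditions legitimately have total log-likelihoods
#: below -745 everywhere) only prevents numerical underflow and never
#: changes which parameters rank highest.
LOGLIK_FLOOR = -745.0

#: sigma grid: 0.01 .. 40.01 mm in 0.05 mm steps (801 points).
DEFAULT_SIGMA_GRID = 0.01 + 0.05 * np.arange(801)
DEFAULT_SIGMA_GRID.setflags(write=False)

#: mu grid: -5 .. +5 mm in 0.1 mm steps (101 points).
DEFAULT_MU_GRID = -5.0 + 0.1 * np.arange(101)
DEFAULT_MU_GRID.setflags(write=False)


class DegeneratePosteriorError(ValueError):
    """Raised when the likelihood vanishes at every grid point."""


@dataclass(frozen=True)
class ConditionData:
    """Per-condition 2IFC counts: for each delta, (k, n).

    ``k`` is the number of comparison-judged-larger responses and ``n`` the
    number of trials at that delta.
    """

    deltas: np.ndarray
    k: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas, dtype=float)
        k = np.asarray(self.k, dtype=float)
        n = np.asarray(self.n, dtype=float)
        if not (d.shape == k.shape == n.shape and d.ndim == 1):
            raise ValueError("deltas, k, n must be 1-D arrays of equal length")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("counts must satisfy 0 <= k <= n")
        order = np.argsort(d)
        object.__setattr__(self, "deltas", d[order])
        object.__setattr__(self, "k", k[order])
        object.__setattr__(self, "n", n[order])
        for a in (self.deltas, self.k, self.n):
            a.setflags(write=False)

    @classmethod
    def from_dict(cls, counts: Mapping[float, tuple[int, int]]) -> "ConditionData":
        d = np.array(sorted(counts), dtype=float)
        k = np.array([counts[x][0] for x in d], dtype=float)
        n = np.array([counts[x][1] for x in d], dtype=float)
        return cls(d, k, n)

    @classmethod
    def from_responses(cls, deltas, responses) -> "ConditionData":
        """Aggregate per-trial (delta, comp-judged-larger) pairs into counts."""
        d = np.asarray(deltas, dtype=float)
        r = np.asarray(responses, dtype=bool)
        levels, inv = np.unique(d, return_inverse=True)
        n = np.bincount(inv, minlength=levels.size).astype(float)
        k = np.bincount(inv, weights=r.astype(float), minlength=levels.size)
        return cls(levels, k, n)

    def as_dict(self) -> dict[float, tuple[int, int]]:
        return {
            float(d): (int(k), int(n))
            for d, k, n in zip(self.deltas, self.k, self.n)
        }

    @property
    def total_trials(self) -> int:
        return int(self.n.sum())


@dataclass(frozen=True)
class SigmaPosterior:
    """Gridded posterior over a single-interval sigma (mm)."""

    grid: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if g.shape != p.shape or g.ndim != 1:
            raise ValueError("grid and p must be 1-D arrays of equal length")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("posterior mass must be non-negative and sum to 1")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "p", p)

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.p))])

    def mean(self) -> float:
        return float(self.p @ self.grid)

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.p)

    def quantile(self, q) -> np.ndarray:
        """Inverse CDF by linear interpolation over mass-bearing grid points."""
        mask = self.p > 0
        return np.interp(np.asarray(q, dtype=float),
                         np.cumsum(self.p[mask]), self.grid[mask])

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo, hi = self.quantile([(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    def entropy(self) -> float:
        p = self.p[self.p > 0]
        return float(-(p * np.log(p)).sum())

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.grid, self.p]),
                   delimiter=",", header="sigma_mm,probability", comments="")


@dataclass(frozen=True)
class JointPosterior:
    """Gridded joint posterior over (mu, sigma); ``p`` has shape (len(mu), len(sigma))."""

    mu_grid: np.ndarray
    sigma_grid: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_grid, dtype=float)
        sg = np.asarray(self.sigma_grid, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if p.shape != (mu.size, sg.size):
            raise ValueError("joint mass must have shape (len(mu), len(sigma))")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("joint mass must be non-negative and sum to 1")
        object.__setattr__(self, "mu_grid", mu)
        object.__setattr__(self, "sigma_grid", sg)
        object.__setattr__(self, "p", p)

    def mu_marginal(self) -> np.ndarray:
        return self.p.sum(axis=1)

    def sigma_marginal(self) -> np.ndarray:
        return self.p.sum(axis=0)

    def to_csv(self, path) -> None:
        """Long-format export: one (mu, sigma, probability) row per grid cell."""
        mu, sg = np.meshgrid(self.mu_grid, self.sigma_grid, indexing="ij")
        np.savetxt(path, np.column_stack([mu.ravel(), sg.ravel(), self.p.ravel()]),
                   delimiter=",", header="mu_mm,sigma_mm,probability", comments="")


def psychometric_prob(delta, sigma, mu=0.0):
    """P(comparison judged larger | delta) for a cumulative-normal psychometric
    function with PSE shift ``mu`` and psychometric SD ``sigma`` (already on
    the 2IFC difference scale)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
        raise ValueError("psychometric sigma must be finite and > 0")
    out = ndtr((np.asarray(delta, dtype=float) - mu) / sigma)
    return out if out.ndim else float(out)


def condition_log_likelihood(data: ConditionData, sigma_psy, mu=0.0) -> np.ndarray:
    """Log-likelihood of one condition's counts under (sigma_psy, mu).

    ``sigma_psy`` and ``mu`` broadcast against each other; the delta axis is
    appended internally and summed out.  Binomial coefficients are omitted
    (constant in the parameters, they cancel in every posterior and marginal
    likelihood ratio).  Computed with ``log_ndtr`` throughout, so extreme
    parameters yield large negative but finite values rather than -inf.
    """
    sigma_psy = np.asarray(sigma_psy, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(sigma_psy <= 0) or not np.all(np.isfinite(sigma_psy)):
        raise ValueError("psychometric sigma must be finite and > 0")
    z = (data.deltas - mu[..., None]) / sigma_psy[..., None]
    return (data.k * log_ndtr(z) + (data.n - data.k) * log_ndtr(-z)).sum(axis=-1)


def condition_likelihood(data: ConditionData, sigma_psy, mu=0.0):
    """Likelihood on the natural scale (exp of :func:`condition_log_likelihood`)."""
    out = np.exp(condition_log_likelihood(data, sigma_psy, mu))
    return out if np.ndim(out) else float(out)


# --- cached log-Psi tables -------------------------------------------------
# Keyed by the byte content of (deltas, grid[, mu_grid]); the tables depend
# only on the design's delta levels and the grids, so they are shared across
# every observer analysed in a session.
_SIGMA_TABLES: dict = {}
_JOINT_TABLES: dict = {}


def _sigma_tables(deltas: np.ndarray, grid: np.ndarray):
    key = (deltas.tobytes(), grid.tobytes())
    if key not in _SIGMA_TABLES:
        z = deltas[None, :] / (ROOT2 * grid[:, None])
        _SIGMA_TABLES[key] = (log_ndtr(z), log_ndtr(-z))
    return _SIGMA_TABLES[key]


def _joint_tables(deltas: np.ndarray, mu_grid: np.ndarray, grid: np.ndarray):
    key = (deltas.tobytes(), mu_grid.tobytes(), grid.tobytes())
    if key not in _JOINT_TABLES:
        z = (deltas[None, None, :] - mu_grid[:, None, None]) / (
            ROOT2 * grid[None, :, None])
        _JOINT_TABLES[key] = (log_ndtr(z), log_ndtr(-z))
    return _JOINT_TABLES[key]


def _normalise(ll: np.ndarray, what: str) -> np.ndarray:
    m = ll.max()
    if not np.isfinite(m):
        raise DegeneratePosteriorError(
            f"likelihood vanished at every grid point for {what}")
    w = np.exp(np.maximum(ll - m, LOGLIK_FLOOR))
    return w / w.sum()


def sigma_posterior(data: ConditionData, grid=None) -> SigmaPosterior:
    """Posterior over the single-interval sigma given one condition's counts.

    A uniform prior is applied on ``grid`` (default
    :data:`DEFAULT_SIGMA_GRID`); each grid sigma enters the likelihood as
    ``sqrt(2) * sigma`` on the psychometric scale.
    """
    grid = DEFAULT_SIGMA_GRID if grid is None else np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
        raise ValueError("sigma grid must be strictly increasing and positive")
    if data.total_trials == 0:
        return SigmaPosterior(grid, np.full(grid.size, 1.0 / grid.size))
    a, b = _sigma_tables(data.deltas, grid)
    ll = a @ data.k + b @ (data.n - data.k)
    return SigmaPosterior(grid, _normalise(ll, f"data {data.as_dict()!r}"))


def joint_posterior(data: ConditionData, mu_grid=None, sigma_grid=None) -> JointPosterior:
    """Joint posterior over (mu, sigma) for cue-conflict condition data.

    Uniform prior over the product grid; likelihood is the conflict
    psychometric function with ``sigma_psy = sqrt(2) * sigma``.
    """
    mu_grid = DEFAULT_MU_GRID if mu_grid is None else np.asarray(mu_grid, float)
    sigma_grid = (DEFAULT_SIGMA_GRID if sigma_grid is None
                  else np.asarray(sigma_grid, float))
    a, b = _joint_tables(data.deltas, mu_grid, sigma_grid)
    ll = a @ data.k + b @ (data.n - data.k)
    return JointPosterior(mu_grid, sigma_grid,
                          _normalise(ll, f"data {data.as_dict()!r}"))


def pse_estimate(joint: JointPosterior) -> float:
    """PSE shift estimate: mode of the mu marginal, ties broken toward the
    smallest ``|mu|`` (then toward the more negative value)."""
    marg = joint.mu_marginal()
    tied = np.flatnonzero(marg >= marg.max() * (1.0 - 1e-12))
    best = tied[np.lexsort((joint.mu_grid[tied],
                            np.abs(joint.mu_grid[tied])))[0]]
    return float(joint.mu_grid[best])


def sample_sigmas(posterior: SigmaPosterior, n_draws: int = 1000,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw sigmas from a gridded posterior by inverse-CDF sampling.

    Uniform draws on the CDF ordinate are linearly interpolated back to the
    sigma axis over the mass-bearing grid points, so the spread of draws
    reflects posterior uncertainty (a point-mass posterior yields constant
    draws).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    mask = posterior.p > 0
    cdf = np.cumsum(posterior.p[mask])
    return np.interp(rng.random(n_draws), cdf, posterior.grid[mask])


def expected_information_gain(p: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Expected entropy reduction of a gridded posterior for each candidate.

    Parameters
    ----------
    p
        Posterior mass over parameters, shape ``(P,)``.
    psi
        ``psi[c, j]`` = P(comp judged larger | candidate c, parameter j),
        shape ``(C, P)``.

    Returns
    -------
    ndarray of shape ``(C,)``: prior entropy minus the response-marginalised
    expected posterior entropy, computed exactly on the grid.
    """
    p = np.asarray(p, dtype=float)
    psi = np.asarray(psi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_prior = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
        w1 = psi * p          # unnormalised posterior after r = 1
        w0 = (1 - psi) * p    # after r = 0
        gains = np.empty(psi.shape[0])
        for c in range(psi.shape[0]):
            eh = 0.0
            for w in (w1[c], w0[c]):
                m = w.sum()
                if m > 0:
                    q = w / m
                    eh += m * float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
            gains[c] = h_prior - eh
    return gains


def select_next_stimulus(posterior, candidates: Sequence[float]) -> float:
    """Greedy adaptive stimulus choice: the candidate delta maximising the
    expected information gain about the psychometric parameters.

    ``posterior`` may be a :class:`SigmaPosterior` (mu fixed at 0) or a
    :class:`JointPosterior`.  Ties (including the zero-information point-mass
    case) resolve to the earliest candidate in the given order.
    """
    cand = np.asarray(list(candidates), dtype=float)
    if cand.size == 0:
        raise ValueError("candidate set must be non-empty")
    if isinstance(posterior, SigmaPosterior):
        p = posterior.p
        psi = ndtr(cand[:, None] / (ROOT2 * posterior.grid[None, :]))
    elif isinstance(posterior, JointPosterior):
        p = posterior.p.ravel()
        z = (cand[:, None, None] - posterior.mu_grid[None, :, None]) / (
            ROOT2 * posterior.sigma_grid[None, None, :])
        psi = ndtr(z).reshape(cand.size, -1)
    else:
        raise TypeError("posterior must be SigmaPosterior or JointPosterior")
    gains = expected_information_gain(p, psi)
    # strictly-greater scan keeps the first of any tied maxima
    return float(cand[int(np.argmax(np.round(gains, 12)))])
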