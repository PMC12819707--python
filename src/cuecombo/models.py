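"""Closed-form percept models for three-cue haptic size perception.

An observer holding a disk edge-on between thumb and index finger has three
noisy size cues: two cutaneous cues (``thumb``, ``index``, driven by skin
indentation from the disk's edge curvature) and a proprioceptive finger
``config`` cue (driven by the horizontal span between the digits).  Each cue
is modelled as a Gaussian measurement centred on the disk radius with a
per-cue, per-observer standard deviation.

Three perceptual strategies are considered:

``WTA``  (winner-take-all)
    The percept is the sample of the single most reliable cue (smallest
    sigma); the other cues are ignored.
``AVG``  (unweighted averaging)
    The percept is the arithmetic mean of the three cue samples.
``OPT``  (optimal, reliability-weighted averaging)
    The percept is the inverse-variance-weighted mean of the three samples,
    the maximum-likelihood combination of independent Gaussian cues.

All quantities are disk *radii* in millimetres.  Functions are vectorised:
sigma triplets may be given as a :class:`CueSigmas` or as an array whose last
axis has length 3 in the order ``(thumb, index, config)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Model",
    "CueSigmas",
    "CueSample",
    "ModelPrediction",
    "CUE_ORDER",
    "percept",
    "combined_sigma",
    "pse_slope",
    "conflict_pse",
    "predictions",
]

#: Canonical cue ordering used for all array representations.
CUE_ORDER = ("thumb", "index", "config")


class Model(str, enum.Enum):
    """Perceptual strategy of a model observer."""

    WTA = "WTA"
    AVG = "AVG"
    OPT = "OPT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CueSigmas:
    """Per-cue measurement standard deviations (mm), all strictly positive."""

    thumb: float
    index: float
    config: float

    def __post_init__(self) -> None:
        arr = np.array([self.thumb, self.index, self.config], dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(
                f"cue sigmas must be finite and > 0, got {tuple(arr)}"
            )

    def as_array(self) -> np.ndarray:
        """Return ``[thumb, index, config]`` as a float array."""
        return np.array([self.thumb, self.index, self.config], dtype=float)

    @property
    def best_cue(self) -> str:
        """Name of the minimum-sigma cue.

        Ties are broken with the fixed priority config > index > thumb so that
        degenerate inputs behave deterministically.
        """
        return CUE_ORDER[_best_cue_index(self.as_array())]


@dataclass(frozen=True)
class CueSample:
    """One noisy measurement per cue (mm); may be negative under large noise."""

    thumb: float
    index: float
    config: float

    def __post_init__(self) -> None:
        arr = np.array([self.thumb, self.index, self.config], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"cue samples must be finite, got {tuple(arr)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.thumb, self.index, self.config], dtype=float)


@dataclass(frozen=True)
class ModelPrediction:
    """Expected percept (mm) and across-trial percept SD (mm) for one model."""

    percept_mean: float
    percept_sigma: float


def _as_sigma_array(sigmas) -> np.ndarray:
    """Validate and convert sigmas to an array with last axis (thumb, index, config)."""
    if isinstance(sigmas, CueSigmas):
        arr = sigmas.as_array()
    else:
        arr = np.asarray(sigmas, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("sigma triplets must have last axis of length 3")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("cue sigmas must be finite and > 0")
    return arr


def _as_sample_array(cues) -> np.ndarray:
    if isinstance(cues, CueSample):
        arr = cues.as_array()
    else:
        arr = np.asarray(cues, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("cue samples must have last axis of length 3")
    if not np.all(np.isfinite(arr)):
        raise ValueError("cue samples must be finite")
    return arr


def _best_cue_index(sig: np.ndarray) -> np.ndarray:
    """Index of the minimum-sigma cue, ties broken config > index > thumb.

    Scanning the reversed order (config, index, thumb) and taking the first
    minimum implements the priority.
    """
    rev = sig[..., ::-1]  # (config, index, thumb)
    return 2 - np.argmin(rev, axis=-1)


def percept(model: Model, cues, sigmas):
    """Trial-level percept (mm) of the disk radius under one strategy.

    Parameters
    ----------
    model
        Perceptual strategy.
    cues
        A :class:`CueSample` or array ``(..., 3)`` of noisy cue measurements.
    sigmas
        A :class:`CueSigmas` or array ``(..., 3)`` of per-cue SDs.

    Returns
    -------
    float or ndarray
        WTA: the sample of the minimum-sigma cue.  AVG: the arithmetic mean
        of the three samples.  OPT: the inverse-variance-weighted mean.
    """
    x = _as_sample_array(cues)
    s = _as_sigma_array(sigmas)
    model = Model(model)
    if model is Model.AVG:
        out = x.mean(axis=-1)
    elif model is Model.OPT:
        w = 1.0 / s**2
        out = (x * w).sum(axis=-1) / w.sum(axis=-1)
    else:  # WTA
        idx = _best_cue_index(np.broadcast_to(s, x.shape))
        out = np.take_along_axis(x, idx[..., None], axis=-1)[..., 0]
    return out if out.ndim else float(out)


def combined_sigma(model: Model, sigmas):
    """Across-trial SD of the percept (mm) when the same disk is felt repeatedly.

    WTA: ``min(sigma)``.  AVG: ``sqrt(sum(sigma^2)) / 3``.  OPT:
    ``1 / sqrt(sum(1 / sigma^2))`` — never worse than the best single cue.
    """
    s = _as_sigma_array(sigmas)
    model = Model(model)
    if model is Model.AVG:
        out = np.sqrt((s**2).sum(axis=-1)) / 3.0
    elif model is Model.OPT:
        out = 1.0 / np.sqrt((1.0 / s**2).sum(axis=-1))
    else:
        out = s.min(axis=-1)
    return out if out.ndim else float(out)


def pse_slope(model: Model, sigmas):
    """Predicted PSE shift per mm of cue conflict (dimensionless).

    A conflict of +c mm shifts the config cue mean by +c and both cutaneous
    cue means by -c.  Because each percept is linear in the cue samples, the
    point of subjective equality shifts linearly in c with slope:

    * WTA: +1 when config is the most reliable cue; -1 when a cutaneous cue
      is (its mean moves opposite to the conflict).  The config-best case is
      the one of interest in this task; the cutaneous-best branch follows
      from applying the WTA percept to the shifted cue means.
    * AVG: -1/3 (two cues move with -c, one with +c).
    * OPT: ``(1/s_c^2 - 1/s_i^2 - 1/s_t^2) / (1/s_t^2 + 1/s_i^2 + 1/s_c^2)``,
      always in the open interval (-1, +1) and increasing in config
      reliability.
    """
    s = _as_sigma_array(sigmas)
    model = Model(model)
    if model is Model.AVG:
        out = np.full(s.shape[:-1], -1.0 / 3.0)
    elif model is Model.OPT:
        w = 1.0 / s**2
        out = (w[..., 2] - w[..., 1] - w[..., 0]) / w.sum(axis=-1)
    else:
        out = np.where(_best_cue_index(s) == 2, 1.0, -1.0)
    return out if np.ndim(out) else float(out)


def conflict_pse(model: Model, sigmas, conflict):
    """Expected PSE shift (mm) for a conflict reference of level ``conflict`` mm.

    Equal to ``pse_slope(model, sigmas) * conflict``: the mean percept of the
    conflict reference minus the mean percept of the circular reference.
    """
    c = np.asarray(conflict, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("conflict must be finite")
    out = pse_slope(model, sigmas) * c
    return out if np.ndim(out) else float(out)


def predictions(sigmas) -> dict[Model, ModelPrediction]:
    """Closed-form (mean percept, percept SD) of an unbiased stimulus at radius 0 shift.

    Convenience for reporting: all models are unbiased, so the mean percept
    equals the stimulus radius; only the SDs differ.
    """
    s = CueSigmas(*np.atleast_1d(_as_sigma_array(sigmas)))
    return {
        m: ModelPrediction(0.0, combined_sigma(m, s)) for m in Model
    }
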