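"""Oracle accuracy estimator: ground-truth predictions, optionally corrupted.

The oracle stands in for a trained error-prediction network wherever tests
or demos need an :class:`~accref.estogram.AccuracyPrediction` without weight
files.  Exact mode emits the one-hot true estogram and binary native mask;
controlled corruption (Gaussian blur across error categories, Bernoulli mask
flips) provides a tunable surrogate for network uncertainty.  This is test
machinery, not a claim about real network error statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .estogram import AccuracyPrediction, BinSpec, Estogram
from .metrics import true_estogram, true_mask
from .structures import ProteinModel


@dataclass(frozen=True)
class OracleConfig:
    """blur_sigma in category units (0 = exact); mask_noise = flip probability."""

    blur_sigma: float = 0.0
    mask_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0 <= self.mask_noise <= 0.5:
            raise ValueError("mask_noise must be in [0, 0.5]")


def blur_estogram(est: Estogram, sigma: float) -> Estogram:
    """Gaussian blur across the 15 categories, renormalized per pair."""
    if sigma == 0:
        return est
    probs = gaussian_filter1d(est.probs, sigma=sigma, axis=-1, mode="constant")
    probs /= probs.sum(axis=-1, keepdims=True)
    return Estogram(probs, est.bin_spec)


def corrupt_mask(mask: np.ndarray, flip_prob: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Symmetric Bernoulli flips of off-diagonal mask entries."""
    if flip_prob == 0:
        return mask
    n = mask.shape[0]
    iu = np.triu_indices(n, k=1)
    flips = rng.random(len(iu[0])) < flip_prob
    out = mask.copy()
    vals = out[iu]
    vals[flips] = 1.0 - vals[flips]
    out[iu] = vals
    out.T[iu] = vals
    return out


def oracle_predict(model: ProteinModel, native: ProteinModel,
                   config: OracleConfig | None = None,
                   bins: BinSpec | None = None) -> AccuracyPrediction:
    """Ground-truth-derived accuracy prediction with optional corruption."""
    if len(model) != len(native):
        raise ValueError("length mismatch")
    config = config or OracleConfig()
    est = true_estogram(model, native, bins)
    mask = true_mask(native)
    est = blur_estogram(est, config.blur_sigma)
    rng = np.random.default_rng(config.seed)
    mask = corrupt_mask(mask, config.mask_noise, rng)
    return AccuracyPrediction.from_estogram_mask(est, mask, provenance="oracle")


def make_oracle_predictor(native: ProteinModel,
                          config: OracleConfig | None = None):
    """Closure predictor(model) -> AccuracyPrediction bound to one native."""
    def predictor(model: ProteinModel) -> AccuracyPrediction:
        return oracle_predict(model, native, config)
    return predictor
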