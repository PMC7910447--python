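"""Ground-truth accuracy measures between a model and its native structure.

The central score is the CB local distance difference test (l-DDT): for each
residue, the fraction of native CB-CB distances below 15 A that the model
preserves within 0.5/1/2/4 A, averaged over the four cutoffs.  CA stands in
for CB at glycine.  The same machinery produces the one-hot "true" estogram
and the binary contact mask that a trained error-prediction network would
otherwise emit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estogram import (AccuracyPrediction, BinSpec, Estogram, assign_bin,
                       predicted_lddt)
from .structures import ProteinModel, cb_coords

LDDT_CUTOFFS = (0.5, 1.0, 2.0, 4.0)
INCLUSION_RADIUS = 15.0


@dataclass
class LddtProfile:
    """Per-residue l-DDT values (NaN where undefined) and their mean."""

    per_residue: np.ndarray
    global_lddt: float

    def to_dict(self) -> dict:
        vals = [None if np.isnan(v) else float(v) for v in self.per_residue]
        undefined = [int(i) for i in np.flatnonzero(np.isnan(self.per_residue))]
        return {"per_residue": vals, "global": self.global_lddt, "undefined": undefined}


def pairwise_cb_distances(model: ProteinModel) -> np.ndarray:
    xyz = cb_coords(model)
    diff = xyz[:, None, :] - xyz[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def true_mask(native: ProteinModel) -> np.ndarray:
    """Binary native contact map: CB distance strictly below 15 A, zero diagonal."""
    d = pairwise_cb_distances(native)
    mask = (d < INCLUSION_RADIUS).astype(float)
    np.fill_diagonal(mask, 0.0)
    return mask


def error_map(model: ProteinModel, native: ProteinModel) -> np.ndarray:
    """Signed per-pair CB distance error, e = d_model - d_native."""
    if len(model) != len(native):
        raise ValueError("length mismatch")
    return pairwise_cb_distances(model) - pairwise_cb_distances(native)


def true_estogram(model: ProteinModel, native: ProteinModel,
                  bins: BinSpec | None = None) -> Estogram:
    """One-hot estogram of the actual signed errors."""
    bins = bins or BinSpec()
    e = error_map(model, native)
    idx = assign_bin(e, bins)
    n = len(model)
    probs = np.zeros((n, n, bins.n_bins))
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    probs[ii, jj, idx] = 1.0
    return Estogram(probs, bins)


def cb_lddt(model: ProteinModel, native: ProteinModel,
            inclusion_radius: float = INCLUSION_RADIUS,
            min_seqsep: int = 1) -> LddtProfile:
    """CB l-DDT of the model against the native.

    Pairs enter residue i's score when |i-j| >= min_seqsep and the *native*
    CB distance is strictly below ``inclusion_radius``; the preservation
    test is inclusive (|e| <= cutoff).  Residues with no qualifying pair are
    undefined (NaN) and excluded from the global mean.
    """
    if len(model) != len(native):
        raise ValueError("length mismatch")
    n = len(model)
    d_nat = pairwise_cb_distances(native)
    e = np.abs(pairwise_cb_distances(model) - d_nat)
    seqsep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    qualify = (d_nat < inclusion_radius) & (seqsep >= max(min_seqsep, 1))
    per_res = np.full(n, np.nan)
    counts = qualify.sum(axis=1)
    ok = counts > 0
    if ok.any():
        frac = np.zeros(n)
        for c in LDDT_CUTOFFS:
            frac[ok] += ((e <= c) & qualify).sum(axis=1)[ok] / counts[ok]
        per_res[ok] = frac[ok] / len(LDDT_CUTOFFS)
    glob = float(np.nanmean(per_res)) if ok.any() else float("nan")
    return LddtProfile(per_res, glob)


def corrected_lddt(pred: AccuracyPrediction, seqsep_exclude: int = 11) -> np.ndarray:
    """l-DDT recomputed with short-range mask entries (|i-j| <= 11) zeroed.

    Raw l-DDT favours helical regions, whose short-range contacts are almost
    always preserved; excluding them gives a profile more sensitive to
    tertiary errors.  Residues left without mask weight become NaN.
    """
    n = pred.n
    seqsep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    mask = np.where(seqsep <= seqsep_exclude, 0.0, pred.mask)
    per_res, _ = predicted_lddt(pred.estogram, mask)
    return per_res


def smooth_profile(values: np.ndarray, window: int = 9) -> np.ndarray:
    """Uniform moving average; the window truncates and renormalizes at termini.

    NaN entries are excluded from each window's average.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    v = np.asarray(values, dtype=float)
    n = len(v)
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = v[lo:hi]
        seg = seg[~np.isnan(seg)]
        if len(seg):
            out[i] = seg.mean()
    return out


def oracle_prediction(model: ProteinModel, native: ProteinModel,
                      bins: BinSpec | None = None) -> AccuracyPrediction:
    """Exact AccuracyPrediction from ground truth (one-hot estogram, binary mask)."""
    est = true_estogram(model, native, bins)
    mask = true_mask(native)
    return AccuracyPrediction.from_estogram_mask(est, mask, provenance="oracle")
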