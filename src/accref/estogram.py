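"""Estogram algebra.

An *estogram* is, for every residue pair, a categorical distribution over 15
signed CB-CB distance-error bins (model minus native).  Together with a
*mask* — the (probability of the) native CB-CB distance being below 15 A —
it carries enough information to reconstruct the per-residue CB l-DDT score
without access to the native structure:

    lddt_i = 0.25 * (p0 + p1 + p2 + p3) / p4

where pk is the mask-weighted mean probability (over partners j != i) that
the absolute error is within 0.5/1/2/4 A, and p4 is the mean mask
probability.  The error cutoffs nest exactly on bin boundaries, so the
reconstruction is exact for one-hot estograms away from bin edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

#: signed-error bin boundaries (A); 15 categories including two overflow bins
DEFAULT_BOUNDARIES = np.array(
    [-20.0, -15.0, -10.0, -4.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 4.0, 10.0, 15.0, 20.0]
)

N_CATEGORIES = 15

#: category index sets whose union covers |e| <= 0.5 / 1 / 2 / 4 A (off-edge)
LDDT_CUTOFF_CATEGORIES = {
    0.5: (7,),
    1.0: (6, 7, 8),
    2.0: (5, 6, 7, 8, 9),
    4.0: (4, 5, 6, 7, 8, 9, 10),
}


@dataclass(frozen=True)
class BinSpec:
    """15-category signed-error binning.

    Interior bin centers are interval midpoints; the two overflow bins are
    assigned +/-20 A (the convention used for expected-error maps).
    Positive-side edges are half-open [lower, upper); negative-side edges
    are (lower, upper]; the central bin (-0.5, 0.5) is open at both edges.
    """

    boundaries: np.ndarray = field(default_factory=lambda: DEFAULT_BOUNDARIES.copy())

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.shape != (14,) or not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be 14 strictly ascending values")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) + 1

    @property
    def centers(self) -> np.ndarray:
        b = self.boundaries
        mids = (b[:-1] + b[1:]) / 2.0
        return np.concatenate(([b[0]], mids, [b[-1]]))


def assign_bin(error: float | np.ndarray, bins: BinSpec | None = None) -> np.ndarray:
    """Category index 0..14 of a signed error (vectorized).

    Non-negative errors use the right-closed search (so 0.5 falls in
    [0.5, 1)), negative errors the left-closed one (so -0.5 falls in
    (-1, -0.5]); overflow goes to bins 0 / 14.
    """
    bins = bins or BinSpec()
    e = np.asarray(error, dtype=float)
    if np.any(~np.isfinite(e)):
        raise ValueError("error values must be finite")
    right = np.searchsorted(bins.boundaries, e, side="right")
    left = np.searchsorted(bins.boundaries, e, side="left")
    idx = np.where(e >= 0, right, left)
    return idx if idx.shape else int(idx)


@dataclass
class Estogram:
    """n x n x 15 per-pair signed-error probability tensor."""

    probs: np.ndarray
    bin_spec: BinSpec = field(default_factory=BinSpec)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[0] != p.shape[1] or p.shape[2] != self.bin_spec.n_bins:
            raise ValueError("probs must be n x n x 15")
        if np.any(p < -1e-9):
            raise ValueError("negative probabilities")
        self.probs = p

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def validate_normalized(self, atol: float = 1e-6) -> None:
        s = self.probs.sum(axis=-1)
        if not np.allclose(s, 1.0, atol=atol):
            raise ValueError("estogram rows are not normalized")


def expected_error_map(est: Estogram) -> np.ndarray:
    """n x n expected signed error (A): probability-weighted bin centers."""
    est.validate_normalized()
    return est.probs @ est.bin_spec.centers


def p_cen(est: Estogram) -> np.ndarray:
    """Per-pair probability that |error| <= 1 A (the three central bins)."""
    return est.probs[:, :, list(LDDT_CUTOFF_CATEGORIES[1.0])].sum(axis=-1)


def p_contact(est: Estogram, d0: np.ndarray) -> np.ndarray:
    """Per-pair probability that the estimated native distance is < 10 A.

    The native-distance estimate for category i is d0 - center_i (error is
    model minus native), so mass is summed over categories with
    d0 - center_i < 10.
    """
    d0 = np.asarray(d0, dtype=float)
    if np.any(d0 < 0):
        raise ValueError("d0 must be non-negative")
    centers = est.bin_spec.centers
    # indicator[i, j, k] = 1 where d0_ij - c_k < 10
    contact = (d0[..., None] - centers[None, None, :]) < 10.0
    return (est.probs * contact).sum(axis=-1)


def symmetrize(probs: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ordered-pair outputs; idempotent."""
    return (probs + probs.transpose(1, 0, 2)) / 2.0, (mask + mask.T) / 2.0


def predicted_lddt(est: Estogram, mask: np.ndarray,
                   min_mask: float = 1e-9) -> tuple[np.ndarray, float]:
    """Per-residue CB l-DDT reconstructed from estogram + mask.

    Returns (per_residue, global); residues whose mean mask weight p4 falls
    below ``min_mask`` are undefined (NaN) and excluded from the global mean.
    """
    est.validate_normalized()
    mask = np.asarray(mask, dtype=float)
    n = est.n
    if mask.shape != (n, n):
        raise ValueError("mask shape mismatch")
    offdiag = 1.0 - np.eye(n)
    w = mask * offdiag
    denom = float(n - 1)
    p4 = w.sum(axis=1) / denom
    num = np.zeros(n)
    for cutoff in (0.5, 1.0, 2.0, 4.0):
        cat = list(LDDT_CUTOFF_CATEGORIES[cutoff])
        p_within = est.probs[:, :, cat].sum(axis=-1)
        num += (w * p_within).sum(axis=1) / denom
    per_res = np.full(n, np.nan)
    ok = p4 >= min_mask
    per_res[ok] = 0.25 * num[ok] / p4[ok]
    glob = float(np.nanmean(per_res)) if ok.any() else float("nan")
    return per_res, glob


@dataclass
class AccuracyPrediction:
    """Bundle of estogram, mask and derived l-DDT values for one model."""

    estogram: Estogram
    mask: np.ndarray
    per_residue_lddt: np.ndarray
    global_lddt: float
    provenance: str = "oracle"

    @classmethod
    def from_estogram_mask(cls, est: Estogram, mask: np.ndarray,
                           provenance: str = "oracle") -> "AccuracyPrediction":
        per_res, glob = predicted_lddt(est, mask)
        return cls(est, np.asarray(mask, dtype=float), per_res, glob, provenance)

    @property
    def n(self) -> int:
        return self.estogram.n

    def save(self, path: str) -> None:
        """HDF5 container (estogram/mask/lddt datasets) + JSON sidecar."""
        with h5py.File(path, "w") as f:
            f.create_dataset("estogram", data=self.estogram.probs.astype(np.float32))
            f.create_dataset("mask", data=self.mask.astype(np.float32))
            f.create_dataset("lddt", data=self.per_residue_lddt.astype(np.float32))
            f.attrs["global_lddt"] = self.global_lddt
        sidecar = {
            "provenance": self.provenance,
            "bin_boundaries": self.estogram.bin_spec.boundaries.tolist(),
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "AccuracyPrediction":
        with h5py.File(path, "r") as f:
            probs = f["estogram"][()].astype(float)
            mask = f["mask"][()].astype(float)
            lddt = f["lddt"][()].astype(float)
            glob = float(f.attrs["global_lddt"])
        try:
            with open(path + ".json") as fh:
                meta = json.load(fh)
            prov = meta.get("provenance", "file")
            bins = BinSpec(np.asarray(meta["bin_boundaries"]))
        except FileNotFoundError:
            prov, bins = "file", BinSpec()
        return cls(Estogram(probs, bins), mask, lddt, glob, prov)
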