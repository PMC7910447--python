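"""Pair restraints derived from accuracy predictions.

Residue pairs are classified by prediction confidence (P_cen, the estogram
probability that the absolute distance error is within 1 A):

* high confidence   (P_cen > 0.8, d0 <= 20 A): keep the current distance,
  tightly — bounded flat-bottom potential (coarse stage) or inverted
  sum-of-sigmoids well (all-atom stage) with (s, tol) = (1, 1);
* moderate          (P_cen > 0.7): same forms with (s, tol) = (2, 2);
* nonpreserving     (d0 < 40 A): free to move; the estogram itself becomes a
  log-odds distance potential (spline-interpolated), or — in iterative
  stages — a simple contact potential on pairs predicted to contact within
  10 A (P_contact > 0.8);
* excluded          (d0 >= 40 A).

An "aggressive" parameter set (w_fa = 0.2, thresholds {0.8, 0.9}) weakens the
all-atom weight and tightens the confidence classes to allow larger moves.
Restraints serialize to Rosetta-style AtomPair constraint text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.interpolate import PchipInterpolator

from .estogram import AccuracyPrediction, p_cen, p_contact
from .metrics import pairwise_cb_distances
from .structures import ProteinModel


@dataclass(frozen=True)
class RestraintParams:
    s: float = 1.0      # width (A)
    tol: float = 1.0    # tolerance (A)
    w_fa: float = 1.0   # all-atom stage weight

    def __post_init__(self) -> None:
        if self.s <= 0 or self.tol < 0 or self.w_fa < 0:
            raise ValueError("require s > 0, tol >= 0, w_fa >= 0")


@dataclass(frozen=True)
class ConfidenceThresholds:
    p_high: float = 0.8
    p_moderate: float = 0.7
    w_fa: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_moderate <= self.p_high <= 1:
            raise ValueError("require 0 <= p_moderate <= p_high <= 1")


#: default and aggressive (w_fa, {p_high, p_moderate}) parameter sets
DEFAULT_THRESHOLDS = ConfidenceThresholds(0.8, 0.7, w_fa=1.0)
AGGRESSIVE_THRESHOLDS = ConfidenceThresholds(0.9, 0.8, w_fa=0.2)

D0_CONFIDENT_MAX = 20.0
D0_SPLINE_MAX = 40.0
P_CONTACT_MIN = 0.8


class PairClass(Enum):
    HIGH = "high"
    MODERATE = "moderate"
    NONPRESERVING = "nonpreserving"
    EXCLUDED = "excluded"


def bounded_potential(d, d0, params: RestraintParams):
    """Flat-bottom bounded function: 0 within tol, quadratic over width s,
    linear beyond (continuous everywhere)."""
    d = np.asarray(d, dtype=float)
    s, tol = params.s, params.tol
    hi_quad = (np.clip(d - (d0 + tol), 0, s) / s) ** 2
    lo_quad = (np.clip((d0 - tol) - d, 0, s) / s) ** 2
    hi_lin = np.where(d > d0 + tol + s, (d - (d0 + tol + s)) / s, 0.0)
    lo_lin = np.where(d < d0 - tol - s, ((d0 - tol - s) - d) / s, 0.0)
    return hi_quad + lo_quad + hi_lin + lo_lin


def sigmoid_potential(d, d0, params: RestraintParams):
    """Inverted well from two sigmoids, symmetric about d0, bounded by w_fa."""
    d = np.asarray(d, dtype=float)
    s, tol, w = params.s, params.tol, params.w_fa
    lo = -1.0 / (1.0 + np.exp(np.clip(-5.0 * (d - d0 + tol) / s, -700, 700)))
    hi = 1.0 / (1.0 + np.exp(np.clip(-5.0 * (d - d0 - tol) / s, -700, 700)))
    return w * (lo + hi + 1.0)


def contact_potential(d):
    """Simplified contact pull: 0 below 8 A, (d-8)^2 on [8,9], linear above."""
    d = np.asarray(d, dtype=float)
    quad = np.clip(d - 8.0, 0.0, 1.0) ** 2
    lin = np.where(d > 9.0, d - 9.0, 0.0)
    return quad + lin


@dataclass
class SplinePotential:
    """Tabulated log-odds estogram potential over candidate distance.

    Knots are interpolated with a monotone cubic Hermite spline (PCHIP),
    which cannot overshoot between knots -- important because near-one-hot
    estograms produce deep isolated wells that an unconstrained cubic spline
    would surround with spurious minima.
    """

    x: np.ndarray       # knot distances (A), ascending
    y: np.ndarray       # energies at knots
    spline: PchipInterpolator = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.spline is None:
            self.spline = PchipInterpolator(self.x, self.y)

    def __call__(self, d):
        d = np.clip(np.asarray(d, dtype=float), self.x[0], self.x[-1])
        return self.spline(d)

    def derivative(self, d):
        d = np.asarray(d, dtype=float)
        inside = (d > self.x[0]) & (d < self.x[-1])
        return np.where(inside, self.spline(np.clip(d, self.x[0], self.x[-1]), 1), 0.0)

    def argmin(self, resolution: float = 0.05) -> float:
        grid = np.arange(self.x[0], self.x[-1] + resolution, resolution)
        return float(grid[np.argmin(self(grid))])


def estogram_spline_potential(probs: np.ndarray, d0: float,
                              bin_centers: np.ndarray,
                              background: np.ndarray | None = None,
                              floor: float = 1e-4) -> SplinePotential:
    """Log-odds distance potential from one pair's estogram.

    A candidate distance d corresponds to error e = d0 - d_native, i.e. the
    native-distance estimate for error-category i is d0 - center_i; the
    energy there is -log(P_i / P_bg).  Knots at the mapped bin centers are
    cubic-spline interpolated and clamped outside the tabulated range.
    Background defaults to uniform.
    """
    if d0 >= D0_SPLINE_MAX:
        raise ValueError("spline potential not applicable for d0 >= 40 A")
    probs = np.asarray(probs, dtype=float)
    k = len(probs)
    bg = np.full(k, 1.0 / k) if background is None else np.asarray(background, dtype=float)
    energies = -np.log(np.maximum(probs, floor) / np.maximum(bg, floor))
    # distance knots: d = d0 - center, ascending => reverse category order
    x = d0 - bin_centers[::-1]
    y = energies[::-1]
    keep = x > 0.0
    if keep.sum() < 4:
        raise ValueError("too few positive-distance knots")
    return SplinePotential(np.ascontiguousarray(x[keep]),
                           np.ascontiguousarray(y[keep]))


def recompute_background(predictions: list[AccuracyPrediction],
                         models: list[ProteinModel],
                         seqsep_edges: tuple = (6, 12, 24),
                         d0_edges: tuple = (8.0, 16.0, 24.0)) -> dict:
    """Mean estogram per (sequence-separation, d0) stratum over a decoy set.

    Desk-scale analogue of collecting background statistics from a large
    decoy collection; the returned table maps stratum index pairs to
    15-vectors usable as the ``background`` of the spline potential.
    """
    table: dict[tuple[int, int], np.ndarray] = {}
    counts: dict[tuple[int, int], int] = {}
    for pred, model in zip(predictions, models):
        n = pred.n
        d0 = pairwise_cb_distances(model)
        seqsep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        sbin = np.digitize(seqsep, seqsep_edges)
        dbin = np.digitize(d0, d0_edges)
        for i in range(n):
            for j in range(i + 1, n):
                key = (int(sbin[i, j]), int(dbin[i, j]))
                table.setdefault(key, np.zeros(pred.estogram.probs.shape[-1]))
                table[key] += pred.estogram.probs[i, j]
                counts[key] = counts.get(key, 0) + 1
    return {k: v / counts[k] for k, v in table.items()}


def classify_pairs(pred: AccuracyPrediction, d0: np.ndarray,
                   thresholds: ConfidenceThresholds = DEFAULT_THRESHOLDS
                   ) -> np.ndarray:
    """n x n array of PairClass values (diagonal excluded)."""
    pc = p_cen(pred.estogram)
    n = pred.n
    out = np.full((n, n), PairClass.EXCLUDED, dtype=object)
    confident = d0 <= D0_CONFIDENT_MAX
    out[(pc > thresholds.p_moderate) & confident] = PairClass.MODERATE
    out[(pc > thresholds.p_high) & confident] = PairClass.HIGH
    is_np = (out == PairClass.EXCLUDED) & (d0 < D0_SPLINE_MAX)
    out[is_np] = PairClass.NONPRESERVING
    np.fill_diagonal(out, PairClass.EXCLUDED)
    return out


@dataclass
class Restraint:
    i: int
    j: int
    atom_i: str
    atom_j: str
    form: str               # bounded | sigmoid | spline | contact
    d0: float
    params: RestraintParams | None = None
    spline: SplinePotential | None = None

    def energy(self, d):
        if self.form == "bounded":
            return bounded_potential(d, self.d0, self.params)
        if self.form == "sigmoid":
            return sigmoid_potential(d, self.d0, self.params)
        if self.form == "contact":
            return contact_potential(d)
        return self.spline(d)

    def gradient(self, d, eps: float = 1e-5):
        if self.form == "spline":
            return self.spline.derivative(d)
        return (self.energy(np.asarray(d) + eps) - self.energy(np.asarray(d) - eps)) / (2 * eps)


@dataclass
class RestraintSet:
    entries: list[Restraint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def total_energy(self, cb_xyz: np.ndarray) -> float:
        if not self.entries:
            return 0.0
        ii = np.array([r.i for r in self.entries])
        jj = np.array([r.j for r in self.entries])
        d = np.linalg.norm(cb_xyz[ii] - cb_xyz[jj], axis=1)
        return float(sum(r.energy(di) for r, di in zip(self.entries, d)))


def _pair_atoms(model: ProteinModel, i: int, j: int) -> tuple[str, str]:
    ai = "CA" if model.residues[i].aa == "G" else "CB"
    aj = "CA" if model.residues[j].aa == "G" else "CB"
    return ai, aj


def build_restraints(pred: AccuracyPrediction, model: ProteinModel,
                     stage: str = "coarse", mode: str = "default",
                     iterative: bool = False,
                     background: dict | None = None) -> RestraintSet:
    """Convert a prediction into a typed restraint set for one model.

    stage: "coarse" (bounded wells) or "fullatom" (sigmoid wells) for
    confident pairs.  Nonpreserving pairs get the estogram spline potential
    at diversification, replaced in ``iterative`` stages by the simplified
    contact potential on pairs with P_contact > 0.8.
    """
    if stage not in ("coarse", "fullatom"):
        raise ValueError("stage must be coarse or fullatom")
    thresholds = AGGRESSIVE_THRESHOLDS if mode == "aggressive" else DEFAULT_THRESHOLDS
    d0 = pairwise_cb_distances(model)
    classes = classify_pairs(pred, d0, thresholds)
    pcont = p_contact(pred.estogram, d0) if iterative else None
    centers = pred.estogram.bin_spec.centers
    out = RestraintSet()
    n = pred.n
    for i in range(n):
        for j in range(i + 1, n):
            cls = classes[i, j]
            if cls == PairClass.EXCLUDED:
                continue
            ai, aj = _pair_atoms(model, i, j)
            if cls in (PairClass.HIGH, PairClass.MODERATE):
                st = 1.0 if cls == PairClass.HIGH else 2.0
                params = RestraintParams(s=st, tol=st, w_fa=thresholds.w_fa)
                form = "bounded" if stage == "coarse" else "sigmoid"
                out.entries.append(Restraint(i, j, ai, aj, form,
                                             float(d0[i, j]), params=params))
            else:  # nonpreserving
                if iterative:
                    if pcont[i, j] > P_CONTACT_MIN:
                        out.entries.append(Restraint(i, j, ai, aj, "contact",
                                                     float(d0[i, j])))
                else:
                    spl = estogram_spline_potential(
                        pred.estogram.probs[i, j], float(d0[i, j]), centers)
                    out.entries.append(Restraint(i, j, ai, aj, "spline",
                                                 float(d0[i, j]), spline=spl))
    return out


def ema_pair_weights(per_residue_scores: np.ndarray, lam: float = 1.4,
                     percentile_cap: float = 70.0) -> np.ndarray:
    """Pair weights from residue-wise external EMA scores.

    P_ij = exp(-lam/L_i) * exp(-lam/L_j), normalized by the value at the
    given percentile and capped at 1.0.
    """
    scores = np.asarray(per_residue_scores, dtype=float)
    if np.any(scores <= 0):
        raise ValueError("per-residue scores must be positive")
    p = np.exp(-lam / scores)
    pij = np.outer(p, p)
    iu = np.triu_indices(len(scores), k=1)
    ref = np.percentile(pij[iu], percentile_cap)
    out = np.minimum(pij / ref, 1.0)
    np.fill_diagonal(out, 0.0)
    return out


# --- Rosetta constraint-file dialect -------------------------------------

def write_cst(rs: RestraintSet, path: str) -> None:
    """Serialize to Rosetta-style AtomPair constraint text (1-based residues).

    bounded -> BOUNDED lb ub sd 0.5 tag; sigmoid -> SUMFUNC encoding the two
    sigmoids and the offset; contact -> CONTACT marker with d0; spline ->
    SPLINE with inline knot table.
    """
    with open(path, "w") as f:
        for r in rs.entries:
            head = f"AtomPair {r.atom_i} {r.i + 1} {r.atom_j} {r.j + 1}"
            if r.form == "bounded":
                lb, ub = r.d0 - r.params.tol, r.d0 + r.params.tol
                f.write(f"{head} BOUNDED {lb:.3f} {ub:.3f} {r.params.s:.3f} 0.5 acc\n")
            elif r.form == "sigmoid":
                p = r.params
                f.write(f"{head} SUMFUNC SIGMOID {r.d0:.3f} {p.tol:.3f} "
                        f"{p.s:.3f} {p.w_fa:.3f}\n")
            elif r.form == "contact":
                f.write(f"{head} CONTACT {r.d0:.3f}\n")
            else:
                knots = " ".join(f"{x:.4f}:{y:.6f}" for x, y in zip(r.spline.x, r.spline.y))
                f.write(f"{head} SPLINE {r.d0:.3f} {knots}\n")


def read_cst(path: str) -> RestraintSet:
    """Parse the dialect written by :func:`write_cst` (round-trip support)."""
    rs = RestraintSet()
    with open(path) as f:
        for line in f:
            tok = line.split()
            if not tok or tok[0] != "AtomPair":
                continue
            ai, i, aj, j, func = tok[1], int(tok[2]) - 1, tok[3], int(tok[4]) - 1, tok[5]
            if func == "BOUNDED":
                lb, ub, sd = float(tok[6]), float(tok[7]), float(tok[8])
                d0, tol = (lb + ub) / 2, (ub - lb) / 2
                rs.entries.append(Restraint(i, j, ai, aj, "bounded", d0,
                                            params=RestraintParams(sd, tol)))
            elif func == "SUMFUNC":
                d0, tol, s, w = (float(t) for t in tok[7:11])
                rs.entries.append(Restraint(i, j, ai, aj, "sigmoid", d0,
                                            params=RestraintParams(s, tol, w)))
            elif func == "CONTACT":
                rs.entries.append(Restraint(i, j, ai, aj, "contact", float(tok[6])))
            elif func == "SPLINE":
                d0 = float(tok[6])
                pts = [p.split(":") for p in tok[7:]]
                x = np.array([float(p[0]) for p in pts])
                y = np.array([float(p[1]) for p in pts])
                rs.entries.append(Restraint(i, j, ai, aj, "spline", d0,
                                            spline=SplinePotential(x, y)))
    return rs
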