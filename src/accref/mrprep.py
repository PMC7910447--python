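"""Molecular-replacement preparation from predicted accuracy.

Residue-wise predicted CB l-DDT is converted to an estimated coordinate
error u_i = 1.5 * exp(4 * (0.7 - lddt_i)) (A) and then to an isotropic
B-factor B_i = 8 pi^2 u_i^2 / 3 (A^2), written into the PDB B column of the
search model.  Terminal residues that do not pack against the rest of the
chain are trimmed before MR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import ProteinModel, write_pdb


@dataclass(frozen=True)
class MrParams:
    u_scale: float = 1.5        # A
    u_rate: float = 4.0
    u_ref_lddt: float = 0.7
    contact_cutoff: float = 4.5  # A, heavy-atom "direct interaction"
    min_seqsep: int = 4

    def __post_init__(self) -> None:
        if self.u_scale <= 0 or self.contact_cutoff <= 0:
            raise ValueError("scales must be positive")


def position_error(lddt: np.ndarray | float, params: MrParams = MrParams()) -> np.ndarray:
    """Estimated positional error u_i (A) from predicted per-residue l-DDT."""
    lddt = np.asarray(lddt, dtype=float)
    if np.any((lddt < 0) | (lddt > 1)):
        raise ValueError("l-DDT values must be in [0, 1]")
    return params.u_scale * np.exp(params.u_rate * (params.u_ref_lddt - lddt))


def bfactor(u: np.ndarray | float) -> np.ndarray:
    """Isotropic B-factor (A^2) from positional error u (A): 8 pi^2 u^2 / 3."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("u must be non-negative")
    return 8.0 * np.pi ** 2 * u ** 2 / 3.0


def _residue_interacts(model: ProteinModel, idx: int, params: MrParams) -> bool:
    res = model.residues[idx]
    xyz_i = np.array(list(res.atoms.values()))
    for j, other in enumerate(model.residues):
        if abs(j - idx) < params.min_seqsep:
            continue
        xyz_j = np.array(list(other.atoms.values()))
        d = np.linalg.norm(xyz_i[:, None, :] - xyz_j[None, :, :], axis=-1)
        if d.min() < params.contact_cutoff:
            return True
    return False


def trim_termini(model: ProteinModel, params: MrParams = MrParams()) -> ProteinModel:
    """Iteratively drop non-interacting terminal residues (both ends).

    A residue "directly interacts" when any heavy-atom pair to a residue at
    least ``min_seqsep`` apart in sequence is within ``contact_cutoff``.
    Trimming stops at the first interacting residue on each end; it is
    idempotent.  Raises if the whole chain would be removed.
    """
    if len(model) < 3:
        raise ValueError("model too short to trim")
    lo, hi = 0, len(model)  # half-open window of retained residues

    def window_model() -> ProteinModel:
        return ProteinModel(model.chain_id, model.residues[lo:hi], model.source_path)

    while hi - lo >= 3:
        m = window_model()
        if not _residue_interacts(m, 0, params):
            lo += 1
            continue
        if not _residue_interacts(m, len(m) - 1, params):
            hi -= 1
            continue
        break
    if hi - lo < 3:
        raise ValueError("trimming would remove the entire model")
    return window_model()


def prepare_mr_model(model: ProteinModel, per_residue_lddt: np.ndarray,
                     out_pdb: str, params: MrParams = MrParams()) -> dict:
    """Trim termini, assign accuracy-derived B-factors, write the PDB.

    Returns a JSON-ready report of u_i and B_i for the retained residues.
    """
    lddt = np.asarray(per_residue_lddt, dtype=float)
    if len(lddt) != len(model):
        raise ValueError("l-DDT length mismatch")
    trimmed = trim_termini(model, params)
    retained = {id(r) for r in trimmed.residues}
    keep = [i for i, r in enumerate(model.residues) if id(r) in retained]
    u = position_error(np.nan_to_num(lddt[keep], nan=0.0), params)
    b = bfactor(u)
    write_pdb(trimmed, out_pdb, bfactors=b)
    return {
        "retained": keep,
        "u": u.tolist(),
        "bfactor": b.tolist(),
    }
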