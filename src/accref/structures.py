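"""Structure data model, PDB I/O and geometric primitives.

A :class:`ProteinModel` is a single-chain, ordered list of residues with at
least the backbone N/CA/C atoms per residue.  All accuracy metrics and
restraint builders in this package act on this container.  Distance-based
quantities use the CB atom, falling back to CA for glycine (which has no CB)
or when CB is absent from a stripped model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io

logger = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class EmptyStructureError(ValueError):
    """Raised when a PDB file yields no complete residue."""


@dataclass
class Residue:
    """One amino-acid residue: one-letter code, atom map, original numbering."""

    aa: str
    atoms: dict[str, np.ndarray]
    pdb_number: int

    def __post_init__(self) -> None:
        for name, xyz in self.atoms.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError(f"atom {name}: non-finite or malformed coordinates")
            self.atoms[name] = xyz

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))


@dataclass
class ProteinModel:
    """Ordered single-chain protein model.

    Residues are internally indexed 0..n-1; original PDB numbering is kept
    as per-residue metadata only.
    """

    chain_id: str
    residues: list[Residue]
    source_path: str | None = None

    def __post_init__(self) -> None:
        for i, r in enumerate(self.residues):
            if not r.has_backbone():
                raise ValueError(f"residue {i} is missing backbone atoms")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues])

    def copy(self) -> "ProteinModel":
        return ProteinModel(
            chain_id=self.chain_id,
            residues=[
                Residue(r.aa, {k: v.copy() for k, v in r.atoms.items()}, r.pdb_number)
                for r in self.residues
            ],
            source_path=self.source_path,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinModel":
        """Return a rigid-transformed copy (x -> R x + t)."""
        out = self.copy()
        for r in out.residues:
            for k in r.atoms:
                r.atoms[k] = rotation @ r.atoms[k] + translation
        return out


def cb_coords(model: ProteinModel) -> np.ndarray:
    """n x 3 array of CB coordinates; CA is used for GLY or when CB is absent."""
    rows = []
    for i, r in enumerate(model.residues):
        if r.aa == "G" or "CB" not in r.atoms:
            if r.aa != "G" and "CB" not in r.atoms:
                logger.warning("residue %d (%s): CB absent, substituting CA", i, r.aa)
            rows.append(r.atoms["CA"])
        else:
            rows.append(r.atoms["CB"])
    return np.array(rows)


def read_pdb(path: str, chain: str | None = None) -> ProteinModel:
    """Read a single chain from a PDB file.

    Altloc conflicts are resolved by highest occupancy (ties toward 'A', the
    biotite default). Residues lacking any of N/CA/C are dropped with a
    warning. Insertion codes are rejected.
    """
    pdb_file = pdb_io.PDBFile.read(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        atoms = pdb_file.get_structure(model=1, altloc="occupancy", extra_fields=["b_factor"])
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if chain is None:
        chains = np.unique(atoms.chain_id)
        if len(chains) == 0:
            raise EmptyStructureError(f"{path}: no amino-acid ATOM records")
        chain = str(chains[0])
    atoms = atoms[atoms.chain_id == chain]
    if np.any(atoms.ins_code != ""):
        raise ValueError(f"{path}: insertion codes are not supported")

    residues: list[Residue] = []
    for res_id in np.unique(atoms.res_id):
        sel = atoms[atoms.res_id == res_id]
        res_name = str(sel.res_name[0])
        aa = _THREE_TO_ONE.get(res_name)
        if aa is None:
            continue
        atom_map = {str(n): sel.coord[k] for k, n in enumerate(sel.atom_name)}
        if not all(a in atom_map for a in ("N", "CA", "C")):
            logger.warning("%s chain %s residue %d: incomplete backbone, dropped",
                           path, chain, int(res_id))
            continue
        residues.append(Residue(aa, atom_map, int(res_id)))
    if not residues:
        raise EmptyStructureError(f"{path} chain {chain}: zero complete residues")
    return ProteinModel(chain_id=chain, residues=residues, source_path=path)


def write_pdb(model: ProteinModel, path: str, bfactors: np.ndarray | None = None) -> None:
    """Write the model as ATOM/TER/END records (occupancy 1.00).

    ``bfactors`` is an optional per-residue vector written into the B column
    of every atom of that residue; default 0.00.
    """
    names, elements, coords, res_ids, res_names, bcol = [], [], [], [], [], []
    for i, r in enumerate(model.residues):
        b = 0.0 if bfactors is None else float(bfactors[i])
        for name, xyz in r.atoms.items():
            names.append(name)
            elements.append(name.strip()[0])
            coords.append(xyz)
            res_ids.append(r.pdb_number)
            res_names.append(_ONE_TO_THREE[r.aa])
            bcol.append(b)
    arr = struc.AtomArray(len(names))
    arr.coord = np.array(coords)
    arr.atom_name = np.array(names)
    arr.element = np.array(elements)
    arr.res_id = np.array(res_ids)
    arr.res_name = np.array(res_names)
    arr.chain_id = np.full(len(names), model.chain_id)
    arr.hetero = np.zeros(len(names), dtype=bool)
    arr.set_annotation("occupancy", np.ones(len(names)))
    arr.set_annotation("b_factor", np.array(bcol))
    f = pdb_io.PDBFile()
    f.set_structure(arr)
    f.write(path)


@dataclass
class Superposition:
    """Least-squares rigid superposition result (proper rotation only)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Optimal proper rotation + translation mapping mobile onto target."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be n x 3 with equal n")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (mobile - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_t - rot @ mu_m
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def ca_rmsd(model: ProteinModel, reference: ProteinModel) -> float:
    """CA RMSD after optimal superposition."""
    if len(model) != len(reference):
        raise ValueError("length mismatch")
    return kabsch_superpose(model.ca_coords(), reference.ca_coords()).rmsd


_GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)


def _refine_fraction(mobile: np.ndarray, target: np.ndarray,
                     seed_idx: np.ndarray, cutoff: float,
                     max_iter: int = 10) -> float:
    """Iteratively re-superpose on the within-cutoff subset; return fraction."""
    idx = seed_idx
    best = 0.0
    for _ in range(max_iter):
        if len(idx) < 3:
            break
        sup = kabsch_superpose(mobile[idx], target[idx])
        d = np.linalg.norm(sup.apply(mobile) - target, axis=1)
        new_idx = np.flatnonzero(d <= cutoff)
        best = max(best, len(new_idx) / len(mobile))
        if len(new_idx) == len(idx) and np.array_equal(new_idx, idx):
            break
        if len(new_idx) < 3:
            break
        idx = new_idx
    return best


def gdt_ts(model: ProteinModel, native: ProteinModel,
           window_lengths: tuple[int, ...] = (3, 5, 7)) -> float:
    """GDT-TS in [0, 100]: mean over 1/2/4/8 A cutoffs of the best CA fraction.

    Superpositions are seeded from every contiguous CA window of the given
    lengths plus the full-length fit, each iteratively trimmed to the
    cutoff's within-distance subset; the per-cutoff maximum is taken.  This
    deterministic seed-window search approximates the exhaustive GDT
    superposition search.
    """
    if len(model) != len(native):
        raise ValueError("length mismatch")
    mob = model.ca_coords()
    tgt = native.ca_coords()
    n = len(mob)
    seeds = [np.arange(n)]
    for w in window_lengths:
        if w > n:
            continue
        for start in range(n - w + 1):
            seeds.append(np.arange(start, start + w))
    fractions = {c: 0.0 for c in _GDT_CUTOFFS}
    for seed in seeds:
        for c in _GDT_CUTOFFS:
            fractions[c] = max(fractions[c], _refine_fraction(mob, tgt, seed, c))
    return 100.0 * float(np.mean([fractions[c] for c in _GDT_CUTOFFS]))


def s_score(model: ProteinModel, reference: ProteinModel, d0: float = 5.0) -> float:
    """S-score = (1/n) sum 1/(1+(d_i/d0)^2) over CA deviations after Kabsch fit."""
    if len(model) != len(reference):
        raise ValueError("length mismatch")
    mob = model.ca_coords()
    tgt = reference.ca_coords()
    sup = kabsch_superpose(mob, tgt)
    d = np.linalg.norm(sup.apply(mob) - tgt, axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
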