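"""Input featurization: rotation-invariant voxel grids, 1D and 2D features.

Every residue gets a local orthonormal frame from its backbone N/CA/C atoms;
heavy atoms in a cube around the CA are splatted into an occupancy grid in
that frame, which makes the representation exactly invariant to global rigid
motions of the model.  Per-residue (1D) features cover sequence identity,
physicochemical properties, backbone torsions and a torsion-derived
secondary-structure state; per-pair (2D) features cover the CB distance map,
inter-residue orientation angles and sequence separation.  Externally
computed pair channels (e.g. predicted distance distributions or sequence
embeddings) can be appended verbatim; slots for per-residue energy terms are
reserved and zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import pairwise_cb_distances
from .structures import ProteinModel, Residue, cb_coords

# Meiler et al. 7-descriptor amino-acid parameterization
# (steric, polarizability, volume, hydrophobicity, isoelectric, helix-p, sheet-p)
MEILER = {
    "A": (1.28, 0.05, 1.00, 0.31, 6.11, 0.42, 0.23),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07, 0.13, 0.15),
    "V": (3.67, 0.14, 3.00, 1.22, 6.02, 0.27, 0.49),
    "L": (2.59, 0.19, 4.00, 1.70, 6.04, 0.39, 0.31),
    "I": (4.19, 0.19, 4.00, 1.80, 6.04, 0.30, 0.45),
    "F": (2.94, 0.29, 5.89, 1.79, 5.67, 0.30, 0.38),
    "Y": (2.94, 0.30, 6.47, 0.96, 5.66, 0.25, 0.41),
    "W": (3.21, 0.41, 8.08, 2.25, 5.94, 0.32, 0.42),
    "T": (3.03, 0.11, 2.60, 0.26, 5.60, 0.21, 0.36),
    "S": (1.31, 0.06, 1.60, -0.04, 5.70, 0.20, 0.28),
    "R": (2.34, 0.29, 6.13, -1.01, 10.74, 0.36, 0.25),
    "K": (1.89, 0.22, 4.77, -0.99, 9.99, 0.32, 0.27),
    "H": (2.99, 0.23, 4.66, 0.13, 7.69, 0.27, 0.30),
    "D": (1.60, 0.11, 2.78, -0.77, 2.95, 0.25, 0.20),
    "E": (1.56, 0.15, 3.78, -0.64, 3.09, 0.42, 0.21),
    "N": (1.60, 0.13, 2.95, -0.60, 6.52, 0.21, 0.22),
    "Q": (1.56, 0.18, 3.95, -0.22, 5.65, 0.36, 0.25),
    "M": (2.35, 0.22, 4.43, 1.23, 5.71, 0.38, 0.32),
    "P": (2.67, 0.00, 2.72, 0.72, 6.80, 0.13, 0.34),
    "C": (1.77, 0.13, 2.43, 1.54, 6.35, 0.17, 0.41),
}

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

ELEMENT_CHANNELS = {"C": 0, "N": 1, "O": 2, "S": 3}


@dataclass(frozen=True)
class VoxelConfig:
    """Occupancy grid geometry: G^3 voxels, 4 element channels + own-residue flag."""

    grid_size: int = 24
    spacing: float = 1.0
    n_channels: int = 5

    @property
    def half_extent(self) -> float:
        return (self.grid_size - 1) / 2.0 * self.spacing


@dataclass
class FeatureBundle:
    """All network inputs for one model: voxels + 1D and 2D feature tensors."""

    f1: np.ndarray          # n x F1
    f2: np.ndarray          # n x n x F2
    voxels: np.ndarray      # n x G x G x G x C
    n: int


def local_frame(residue: Residue) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal frame (origin at CA; x along CA->N; right-handed).

    Returns (origin, 3x3 matrix with rows = x/y/z axes).
    """
    n, ca, c = residue.atoms["N"], residue.atoms["CA"], residue.atoms["C"]
    x = n - ca
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise ValueError("degenerate frame: N coincides with CA")
    x = x / nx
    v = c - ca
    z = np.cross(x, v)
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        raise ValueError("degenerate frame: collinear N/CA/C")
    z = z / nz
    y = np.cross(z, x)
    return ca, np.stack([x, y, z])


def voxelize(model: ProteinModel, center_residue: int,
             config: VoxelConfig | None = None) -> np.ndarray:
    """G x G x G x C occupancy grid around one residue, in its local frame.

    Heavy atoms inside the cube are splatted by trilinear interpolation into
    their element channel; atoms of the center residue are additionally
    splatted into the own-residue flag channel.
    """
    config = config or VoxelConfig()
    origin, axes = local_frame(model.residues[center_residue])
    g, sp = config.grid_size, config.spacing
    grid = np.zeros((g, g, g, config.n_channels))
    offset = (g - 1) / 2.0

    coords, channels, own_flags = [], [], []
    for ri, res in enumerate(model.residues):
        for name, xyz in res.atoms.items():
            ch = ELEMENT_CHANNELS.get(name.strip()[0])
            if ch is None:
                continue
            coords.append(xyz)
            channels.append(ch)
            own_flags.append(ri == center_residue)
    coords = np.asarray(coords)
    channels = np.asarray(channels)
    own_flags = np.asarray(own_flags)

    local = (coords - origin) @ axes.T
    fidx = local / sp + offset
    i0 = np.floor(fidx).astype(int)
    frac = fidx - i0
    keep = np.all(i0 >= -1, axis=1) & np.all(i0 < g, axis=1)
    i0, frac = i0[keep], frac[keep]
    channels, own_flags = channels[keep], own_flags[keep]
    for corner in range(8):
        d = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = i0 + d
        ok = np.all((idx >= 0) & (idx < g), axis=1)
        if not ok.any():
            continue
        w = np.prod(np.where(d[None, :] == 1, frac[ok], 1.0 - frac[ok]), axis=1)
        np.add.at(grid, (idx[ok, 0], idx[ok, 1], idx[ok, 2], channels[ok]), w)
        ow = ok & own_flags
        if ow.any():
            wo = np.prod(np.where(d[None, :] == 1, frac[ow], 1.0 - frac[ow]), axis=1)
            np.add.at(grid, (idx[ow, 0], idx[ow, 1], idx[ow, 2],
                             np.full(ow.sum(), 4)), wo)
    return grid


def voxelize_all(model: ProteinModel, config: VoxelConfig | None = None) -> np.ndarray:
    config = config or VoxelConfig()
    return np.stack([voxelize(model, i, config) for i in range(len(model))])


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.arctan2(y, x))


def _angle(p0, p1, p2) -> float:
    a, b = p0 - p1, p2 - p1
    cosv = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(cosv, -1, 1)))


def backbone_torsions(model: ProteinModel) -> np.ndarray:
    """n x 3 phi/psi/omega in radians; NaN where undefined (termini)."""
    n = len(model)
    out = np.full((n, 3), np.nan)
    res = model.residues
    for i in range(n):
        if i > 0:
            out[i, 0] = _dihedral(res[i - 1].atoms["C"], res[i].atoms["N"],
                                  res[i].atoms["CA"], res[i].atoms["C"])
        if i < n - 1:
            out[i, 1] = _dihedral(res[i].atoms["N"], res[i].atoms["CA"],
                                  res[i].atoms["C"], res[i + 1].atoms["N"])
            out[i, 2] = _dihedral(res[i].atoms["CA"], res[i].atoms["C"],
                                  res[i + 1].atoms["N"], res[i + 1].atoms["CA"])
    return out


def secondary_structure(model: ProteinModel) -> np.ndarray:
    """3-state SS one-hot (helix/strand/coil) from phi/psi torsion windows.

    Rules: helix for phi in (-120, -30) and psi in (-80, 0); strand for
    phi in (-180, -60) and psi in (60, 180) or below -150; coil otherwise
    (including undefined termini).
    """
    tor = np.rad2deg(backbone_torsions(model))
    n = len(model)
    one_hot = np.zeros((n, 3))
    for i in range(n):
        phi, psi = tor[i, 0], tor[i, 1]
        if np.isnan(phi) or np.isnan(psi):
            one_hot[i, 2] = 1.0
        elif -120 < phi < -30 and -80 < psi < 0:
            one_hot[i, 0] = 1.0
        elif -180 <= phi < -60 and (psi > 60 or psi < -150):
            one_hot[i, 1] = 1.0
        else:
            one_hot[i, 2] = 1.0
    return one_hot


N_ENERGY_1D = 1  # reserved zero-filled slot for intraresidue energy terms


def residue_features(model: ProteinModel,
                     energy_terms: np.ndarray | None = None) -> np.ndarray:
    """n x F1 per-residue features.

    Layout: aa one-hot (20) | 7 physicochemical descriptors | sin/cos of
    phi/psi/omega (6) | torsion presence flags (3) | SS one-hot (3) |
    intraresidue-energy slot (zero unless provided).
    """
    n = len(model)
    onehot = np.zeros((n, 20))
    phys = np.zeros((n, 7))
    for i, r in enumerate(model.residues):
        onehot[i, AA_ORDER.index(r.aa)] = 1.0
        phys[i] = MEILER[r.aa]
    tor = backbone_torsions(model)
    present = (~np.isnan(tor)).astype(float)
    tor0 = np.nan_to_num(tor)
    trig = np.concatenate([np.sin(tor0), np.cos(tor0)], axis=1) * np.tile(present, 2)
    ss = secondary_structure(model)
    if energy_terms is None:
        energy_terms = np.zeros((n, N_ENERGY_1D))
    return np.concatenate([onehot, phys, trig, present, ss, energy_terms], axis=1)


def orientation_features(model: ProteinModel) -> np.ndarray:
    """n x n x 7 inter-residue orientation angles as sin/cos + validity flag.

    Angles follow the trRosetta convention: omega dihedral
    (CA_i-CB_i-CB_j-CA_j, symmetric), theta dihedral (N_i-CA_i-CB_i-CB_j,
    asymmetric), phi angle (CA_i-CB_i-CB_j, asymmetric).  Pairs where either
    residue lacks a real CB (GLY) are flagged invalid (flag 0, angles 0).
    """
    n = len(model)
    out = np.zeros((n, n, 7))
    has_cb = [r.aa != "G" and "CB" in r.atoms for r in model.residues]
    res = model.residues
    for i in range(n):
        for j in range(n):
            if i == j or not (has_cb[i] and has_cb[j]):
                continue
            cai, cbi = res[i].atoms["CA"], res[i].atoms["CB"]
            caj, cbj = res[j].atoms["CA"], res[j].atoms["CB"]
            omega = _dihedral(cai, cbi, cbj, caj)
            theta = _dihedral(res[i].atoms["N"], cai, cbi, cbj)
            phi = _angle(cai, cbi, cbj)
            out[i, j] = [np.sin(omega), np.cos(omega),
                         np.sin(theta), np.cos(theta),
                         np.sin(phi), np.cos(phi), 1.0]
    return out


def pair_features(model: ProteinModel,
                  extra_channels: np.ndarray | None = None,
                  energy_terms: np.ndarray | None = None) -> np.ndarray:
    """n x n x F2 pair features.

    Layout: CB distance (1) | orientations + flag (7) | log sequence
    separation (1) | inter-residue-energy slot (1, zero unless provided) |
    optional external channels appended verbatim.
    """
    n = len(model)
    # distances scaled to unit-order magnitude for network conditioning
    dist = pairwise_cb_distances(model)[..., None] / 10.0
    orient = orientation_features(model)
    seqsep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    logsep = np.log1p(seqsep)[..., None]
    if energy_terms is None:
        energy_terms = np.zeros((n, n, 1))
    blocks = [dist, orient, logsep, energy_terms]
    if extra_channels is not None:
        extra = np.asarray(extra_channels, dtype=float)
        if extra.shape[:2] != (n, n):
            raise ValueError("external pair channels must be n x n x K")
        if extra.ndim == 2:
            extra = extra[..., None]
        blocks.append(extra)
    return np.concatenate(blocks, axis=2)


def tile_and_merge(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Tile 1D features along both pair axes and concatenate with 2D features.

    Entry (i, j) is [f1_i | f1_j | f2_ij]; output width 2*F1 + F2.
    """
    if f1.shape[0] != f2.shape[0] or f2.shape[0] != f2.shape[1]:
        raise ValueError("residue-count mismatch between 1D and 2D features")
    n = f1.shape[0]
    row_i = np.broadcast_to(f1[:, None, :], (n, n, f1.shape[1]))
    row_j = np.broadcast_to(f1[None, :, :], (n, n, f1.shape[1]))
    return np.concatenate([row_i, row_j, f2], axis=2)


def featurize(model: ProteinModel, voxel_config: VoxelConfig | None = None,
              extra_pair_channels: np.ndarray | None = None) -> FeatureBundle:
    """Full input featurization of a model."""
    return FeatureBundle(
        f1=residue_features(model),
        f2=pair_features(model, extra_channels=extra_pair_channels),
        voxels=voxelize_all(model, voxel_config),
        n=len(model),
    )
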