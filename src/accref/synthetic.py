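"""Synthetic native structures and decoys at controllable accuracy.

Toy natives are built from ideal backbone geometry (fixed bond lengths and
angles, canonical phi/psi per topology) with CB placed by the standard
tetrahedral construction.  Decoys are produced by perturbing backbone
torsions inside randomly placed segments and rebuilding coordinates, which
emulates decoy sets whose quality spans roughly 50-90 GDT-TS: larger torsion
noise gives lower l-DDT/GDT-TS.  Local geometry stays ideal, so restraint
energies remain well defined on every decoy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import cb_lddt
from .structures import ProteinModel, Residue, gdt_ts

# ideal backbone geometry (A / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
OMEGA = 180.0

TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
}

_DEFAULT_AAS = "ADLKEIVRNFMQSTWYHCP"  # no GLY: every residue carries a CB


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position of the next atom given the three previous ones."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -length * np.cos(angle),
        length * np.sin(angle) * np.cos(torsion),
        length * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_from_backbone(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral CB construction (|CB-CA| ~ 1.53 A)."""
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec + ca


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   sequence: str, chain_id: str = "A") -> ProteinModel:
    """Build an ideal-geometry chain from per-residue phi/psi torsions.

    phi[0] and psi[-1] are ignored (undefined at termini).
    """
    n_res = len(sequence)
    if len(phi) != n_res or len(psi) != n_res:
        raise ValueError("torsion arrays must match sequence length")
    coords = []  # flat list of (N, CA, C) triples
    # seed residue laid out in a plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords.append((n0, ca0, c0))
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[-1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, B_C_N, A_CA_C_N, psi[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, B_N_CA, A_C_N_CA, OMEGA)
        c_i = _place_atom(c_prev, n_i, ca_i, B_CA_C, A_N_CA_C, phi[i])
        coords.append((n_i, ca_i, c_i))
    residues = []
    for i, (n_i, ca_i, c_i) in enumerate(coords):
        atoms = {"N": n_i, "CA": ca_i, "C": c_i}
        # carbonyl O in the peptide plane (or trans extension at the C-terminus)
        if i + 1 < n_res:
            n_next = coords[i + 1][0]
            atoms["O"] = _place_atom(n_next, ca_i, c_i, B_C_O, 120.8, 180.0)
        else:
            atoms["O"] = c_i + (c_i - ca_i) / np.linalg.norm(c_i - ca_i) * B_C_O
        aa = sequence[i]
        if aa != "G":
            atoms["CB"] = _cb_from_backbone(n_i, ca_i, c_i)
        residues.append(Residue(aa, atoms, pdb_number=i + 1))
    return ProteinModel(chain_id=chain_id, residues=residues)


@dataclass
class DecoySpec:
    """Parameters of a toy native and its perturbation family."""

    n_residues: int = 60
    topology: str = "helix_bundle"  # helix_bundle | sheet_like | coil
    sigma_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 20:
            raise ValueError("n_residues must be >= 20")
        if self.sigma_deg < 0:
            raise ValueError("sigma must be >= 0")
        if self.topology not in ("helix_bundle", "sheet_like", "coil"):
            raise ValueError(f"unknown topology {self.topology!r}")


def _native_torsions(spec: DecoySpec) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    phi = np.empty(n)
    psi = np.empty(n)
    if spec.topology == "coil":
        phi[:] = rng.uniform(-150, -60, n)
        psi[:] = rng.uniform(-60, 150, n)
        return phi, psi
    if spec.topology == "helix_bundle":
        seg_tor, n_seg = TORSIONS["helix"], max(2, n // 25)
    else:  # sheet_like
        seg_tor, n_seg = TORSIONS["strand"], max(2, n // 15)
    loop_len = 4
    seg_len = (n - (n_seg - 1) * loop_len) // n_seg
    phi[:], psi[:] = seg_tor
    pos = seg_len
    for _ in range(n_seg - 1):
        lo, hi = pos, min(pos + loop_len, n)
        # turn torsions chosen to reverse the chain direction
        phi[lo:hi] = rng.uniform(-100, -60, hi - lo)
        psi[lo:hi] = rng.uniform(-40, 40, hi - lo)
        pos = hi + seg_len
    return phi, psi


def make_native(spec: DecoySpec) -> ProteinModel:
    """Deterministic ideal-geometry toy native for the given spec."""
    phi, psi = _native_torsions(spec)
    seq = "".join(_DEFAULT_AAS[i % len(_DEFAULT_AAS)] for i in range(spec.n_residues))
    return build_backbone(phi, psi, seq)


def perturb_torsions(phi: np.ndarray, psi: np.ndarray, sigma_deg: float,
                     rng: np.random.Generator,
                     segment_fraction: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian torsion noise confined to 1-3 random contiguous segments."""
    n = len(phi)
    phi, psi = phi.copy(), psi.copy()
    if sigma_deg == 0:
        return phi, psi
    n_seg = int(rng.integers(1, 4))
    total = max(2, int(round(segment_fraction * n)))
    lengths = np.maximum(2, rng.multinomial(total, np.ones(n_seg) / n_seg))
    for seg_len in lengths:
        start = int(rng.integers(0, max(1, n - seg_len)))
        sl = slice(start, start + seg_len)
        phi[sl] += rng.normal(0, sigma_deg, seg_len)
        psi[sl] += rng.normal(0, sigma_deg, seg_len)
    return phi, psi


def make_decoys(native: ProteinModel, count: int,
                magnitudes: float | list[float], seed: int = 0,
                spec: DecoySpec | None = None,
                with_gdt: bool = False) -> list[tuple[ProteinModel, dict]]:
    """Seeded decoys of a toy native with their true accuracy metrics.

    ``magnitudes`` is a torsion-noise sigma in degrees (scalar, or one per
    decoy).  Magnitude 0 reproduces the native exactly.  Each decoy is
    returned with {"lddt": global CB l-DDT, "gdt_ts": optional}.
    """
    mags = np.broadcast_to(np.asarray(magnitudes, dtype=float), (count,))
    if np.any(mags < 0):
        raise ValueError("magnitudes must be >= 0")
    if spec is None:
        spec = DecoySpec(n_residues=len(native))
    phi0, psi0 = _native_torsions(spec)
    rng = np.random.default_rng(seed)
    out = []
    for k in range(count):
        if mags[k] == 0:
            decoy = native.copy()
        else:
            phi, psi = perturb_torsions(phi0, psi0, mags[k], rng)
            decoy = build_backbone(phi, psi, native.sequence)
        info = {"lddt": cb_lddt(decoy, native).global_lddt, "magnitude": float(mags[k])}
        if with_gdt:
            info["gdt_ts"] = gdt_ts(decoy, native)
        out.append((decoy, info))
    return out


def make_stratified_decoys(native: ProteinModel, per_bin: int = 3,
                           bins: tuple[float, ...] = (50, 60, 70, 80, 90),
                           seed: int = 0, max_tries: int = 400,
                           spec: DecoySpec | None = None) -> list[tuple[ProteinModel, dict]]:
    """Decoys stratified into GDT-TS bins [b, b+10) for b in ``bins``.

    Mirrors, at desk scale, decoy collection stratified over the 50-90
    GDT-TS range; each returned decoy carries its bin label.
    """
    if spec is None:
        spec = DecoySpec(n_residues=len(native))
    phi0, psi0 = _native_torsions(spec)
    rng = np.random.default_rng(seed)
    want = {b: per_bin for b in bins}
    out = []
    tries = 0
    while any(v > 0 for v in want.values()) and tries < max_tries:
        tries += 1
        sigma = rng.uniform(2.0, 60.0)
        phi, psi = perturb_torsions(phi0, psi0, sigma, rng)
        decoy = build_backbone(phi, psi, native.sequence)
        g = gdt_ts(decoy, native)
        for b in bins:
            if b <= g < b + 10 and want[b] > 0:
                want[b] -= 1
                out.append((decoy, {"gdt_ts": g, "bin": b,
                                    "lddt": cb_lddt(decoy, native).global_lddt}))
                break
    return out
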