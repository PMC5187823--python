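"""Backbone geometry engine.

Dihedral computation, internal-coordinate (NeRF) atom placement,
Kabsch–Sander hydrogen-bond detection, least-squares superposition,
iterative ensemble averaging and RMSD. Everything downstream
(secondary-structure assignment, fibril metrics, the 3₁-helix detector)
is built on these primitives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError, InputError, NumericalError
from .structures import ATOM_INDEX, BackboneStructure, ConformerEnsemble

# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle(s) in degrees, in (-180, 180].

    Accepts single points or stacked (m, 3) arrays. Raises
    :class:`GeometryError` when three consecutive atoms are collinear
    (the angle is then undefined).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    n1n = np.linalg.norm(n1, axis=-1)
    n2n = np.linalg.norm(n2, axis=-1)
    if np.any(n1n < 1e-9) or np.any(n2n < 1e-9) or np.any(b2n < 1e-9):
        raise GeometryError("dihedral undefined: collinear or coincident atoms")
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * (b2 / b2n[..., None]), axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return ang


def compute_dihedrals(structure: BackboneStructure) -> list[np.ndarray]:
    """Per-chain (n, 3) arrays of (phi, psi, omega) in degrees.

    phi(0), psi(last) and omega(0) are undefined and returned as NaN.
    omega(i) is the peptide-bond dihedral CA(i-1)–C(i-1)–N(i)–CA(i)
    preceding residue i.
    """
    out = []
    for chain in structure.chains:
        n = len(chain)
        angles = np.full((n, 3), np.nan)
        N = chain.atom("N")
        CA = chain.atom("CA")
        C = chain.atom("C")
        if n >= 2:
            angles[1:, 0] = dihedral(C[:-1], N[1:], CA[1:], C[1:])      # phi
            angles[:-1, 1] = dihedral(N[:-1], CA[:-1], C[:-1], N[1:])   # psi
            angles[1:, 2] = dihedral(CA[:-1], C[:-1], N[1:], CA[1:])    # omega
        out.append(angles)
    return out


# ---------------------------------------------------------------------------
# Internal-coordinate placement (NeRF)
# ---------------------------------------------------------------------------

def nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom D given A–B–C, |CD|, angle(B,C,D) and dihedral(A,B,C,D)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-9:
        raise GeometryError("NeRF frame undefined: A, B, C collinear")
    n /= n_norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference."""

    rotation: np.ndarray     # (3, 3), proper
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Kabsch least-squares superposition with a proper rotation.

    Returns the transform x -> R x + t minimising the RMSD of
    ``mobile`` to ``reference`` over rigid motions.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise GeometryError("selections differ in atom count")
    if mobile.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    spread = np.linalg.svd(x, compute_uv=False)
    if spread[1] < 1e-8:  # absolute, in Å: second principal extent vanishes
        raise GeometryError("superposition selection is collinear")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    fitted = x @ rot.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return SuperpositionResult(rot, trans, rmsd)


def average_structure(
    ensemble: ConformerEnsemble,
    atoms: tuple[str, ...] = ("N", "CA", "C", "O"),
    resnum_range: tuple[int, int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Converged mean coordinates after iterative superposition.

    Repeatedly superposes every frame on the current mean and recomputes
    it until the mean moves by less than ``tol`` Å (max-norm).
    """
    if ensemble.n_frames < 2:
        raise InputError("averaging needs at least 2 frames")
    sel = [f.coord_array(atoms, resnum_range) for f in ensemble.frames]
    mean = sel[0].copy()
    for _ in range(max_iter):
        fitted = np.stack([superpose(s, mean).apply(s) for s in sel])
        new_mean = fitted.mean(axis=0)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < tol:
            return mean
    raise NumericalError(
        f"average structure did not converge in {max_iter} iterations "
        f"(last shift {shift:.2e} Å)"
    )


def ensemble_rmsd(
    ensemble: ConformerEnsemble,
    reference: np.ndarray,
    atoms: tuple[str, ...] = ("N", "CA", "C", "O"),
    resnum_range: tuple[int, int] | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-frame post-fit RMSD to a reference, with mean and population sd."""
    values = []
    for frame in ensemble.frames:
        coords = frame.coord_array(atoms, resnum_range)
        values.append(superpose(coords, reference).rmsd)
    values = np.asarray(values)
    return values, float(values.mean()), float(values.std())


# ---------------------------------------------------------------------------
# Hydrogen bonds (Kabsch–Sander energy + geometric gates)
# ---------------------------------------------------------------------------

#: Kabsch–Sander electrostatic prefactor q1*q2*f in kcal·Å/mol.
KS_PREFACTOR = 0.084 * 332.0
#: Energy threshold for a bond, kcal/mol.
KS_ENERGY_CUTOFF = -0.5
#: Geometric gates of the strict criterion.
MAX_HO_DISTANCE = 2.5   # Å
MIN_NHO_ANGLE = 120.0   # degrees


@dataclass
class HBond:
    """A backbone N–H···O=C hydrogen bond."""

    donor: tuple[int, int]      # (chain index, residue number)
    acceptor: tuple[int, int]
    h_o_distance: float
    n_o_distance: float
    energy: float
    pattern_offset: int | None  # donor - acceptor residue separation; None inter-chain


def kabsch_sander_energy(
    n_pos: np.ndarray, h_pos: np.ndarray, c_pos: np.ndarray, o_pos: np.ndarray
) -> np.ndarray:
    """Electrostatic H-bond energy E = f·q1·q2·(1/rON + 1/rCH − 1/rOH − 1/rCN)."""
    r_on = np.linalg.norm(n_pos - o_pos, axis=-1)
    r_ch = np.linalg.norm(h_pos - c_pos, axis=-1)
    r_oh = np.linalg.norm(h_pos - o_pos, axis=-1)
    r_cn = np.linalg.norm(n_pos - c_pos, axis=-1)
    return KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def detect_hbonds(
    structure: BackboneStructure,
    criterion: str = "energy",
    max_no_distance: float = 5.2,
    best_per_donor: bool = True,
) -> list[HBond]:
    """Backbone hydrogen bonds under the strict (energy) or geometric rule.

    ``energy``: Kabsch–Sander energy ≤ −0.5 kcal/mol AND H···O ≤ 2.5 Å AND
    N–H···O angle ≥ 120° — the "strict" conjunction. ``geometric`` drops the
    energy gate. Intra-chain pairs with |i−j| < 2 are excluded; at most the
    best bond per donor is kept (bifurcation is not resolved further).
    """
    if criterion not in ("energy", "geometric"):
        raise InputError(f"unknown criterion {criterion!r}")
    # gather donors (residues with H) and acceptors (residues with O and C)
    donors = []   # (chain_idx, res_idx, N, H)
    acceptors = []  # (chain_idx, res_idx, C, O)
    for ci, chain in enumerate(structure.chains):
        N = chain.atom("N")
        H = chain.atom("H")
        C = chain.atom("C")
        O = chain.atom("O")
        for ri in range(len(chain)):
            if not np.isnan(H[ri]).any() and not np.isnan(N[ri]).any():
                donors.append((ci, ri, N[ri], H[ri]))
            if not np.isnan(C[ri]).any() and not np.isnan(O[ri]).any():
                acceptors.append((ci, ri, C[ri], O[ri]))
    if not donors or not acceptors:
        return []
    d_n = np.array([d[2] for d in donors])
    d_h = np.array([d[3] for d in donors])
    a_c = np.array([a[2] for a in acceptors])
    a_o = np.array([a[3] for a in acceptors])

    r_no = np.linalg.norm(d_n[:, None, :] - a_o[None, :, :], axis=-1)
    candidate = r_no <= max_no_distance
    # exclude self and sequence-adjacent intra-chain pairs
    for di, (dci, dri, _, _) in enumerate(donors):
        for ai in np.nonzero(candidate[di])[0]:
            aci, ari, _, _ = acceptors[ai]
            if dci == aci and abs(dri - ari) < 2:
                candidate[di, ai] = False

    bonds: list[HBond] = []
    for di in range(len(donors)):
        ai_cand = np.nonzero(candidate[di])[0]
        if ai_cand.size == 0:
            continue
        n_pos, h_pos = d_n[di], d_h[di]
        accepted = []
        for ai in ai_cand:
            c_pos, o_pos = a_c[ai], a_o[ai]
            r_oh = float(np.linalg.norm(h_pos - o_pos))
            if r_oh > MAX_HO_DISTANCE:
                continue
            v1 = n_pos - h_pos
            v2 = o_pos - h_pos
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle < MIN_NHO_ANGLE:
                continue
            energy = float(kabsch_sander_energy(n_pos, h_pos, c_pos, o_pos))
            if criterion == "energy" and energy > KS_ENERGY_CUTOFF:
                continue
            accepted.append((ai, r_oh, energy))
        if not accepted:
            continue
        if best_per_donor:
            key = (lambda t: t[2]) if criterion == "energy" else (lambda t: t[1])
            accepted = [min(accepted, key=key)]
        for ai, r_oh, energy in accepted:
            dci, dri = donors[di][0], donors[di][1]
            aci, ari = acceptors[ai][0], acceptors[ai][1]
            d_chain = structure.chains[dci]
            a_chain = structure.chains[aci]
            offset = (
                int(d_chain.resnums[dri] - a_chain.resnums[ari]) if dci == aci else None
            )
            bonds.append(HBond(
                donor=(dci, int(d_chain.resnums[dri])),
                acceptor=(aci, int(a_chain.resnums[ari])),
                h_o_distance=r_oh,
                n_o_distance=float(r_no[di, ai]),
                energy=energy,
                pattern_offset=offset,
            ))
    return bonds
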