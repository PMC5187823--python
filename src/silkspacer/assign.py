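"""Secondary-structure assignment.

Per-frame assignment of α-helix (H), 3₁₀-helix (G, with handedness),
β-sheet/bridge (E/B), β-turn (T, Thornton types I, I′, II, II′, IV) and
coil (C) from backbone hydrogen bonds and dihedrals, in the
Kabsch–Sander tradition. Type-III turns — geometrically one turn of
3₁₀-helix — are never reported as turns; windows matching the type-III
canon are merged into the 3₁₀ class, and left-handed 3₁₀ segments
(mirror-image dihedrals near (70°, 25°)) are tracked explicitly because
they are unusually common in the Gly-rich silk spacer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ClassificationError, InputError
from .geometry import HBond, compute_dihedrals, detect_hbonds
from .structures import BackboneStructure, ConformerEnsemble

# Canonical central dihedrals (phi2, psi2, phi3, psi3) of β-turn types.
TURN_CANON = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
    "III": (-60.0, -30.0, -60.0, -30.0),
    "III'": (60.0, 30.0, 60.0, 30.0),
}
TURN_WINDOW = 30.0        # degrees; every angle
TURN_WINDOW_SLACK = 45.0  # degrees; at most one angle
TURN_CA_CUTOFF = 7.0      # Å between CA(i) and CA(i+3)

def _angdiff(a: float, b: float) -> float:
    """Absolute angular difference in degrees, wrapped to [0, 180]."""
    d = abs(a - b) % 360.0
    return 360.0 - d if d > 180.0 else d


def classify_turn(phi2: float, psi2: float, phi3: float, psi3: float) -> str:
    """Thornton turn type of the two central residues of a 4-residue window.

    Returns one of I, I', II, II', IV — or "III" to signal a window that
    matches the type-III canon (equivalent to one 3₁₀-helix turn) and
    must therefore be treated as 3₁₀, not as a turn.
    """
    angles = (phi2, psi2, phi3, psi3)
    if any(a is None or not np.isfinite(a) for a in angles):
        raise ClassificationError("turn classification needs four finite angles")
    best = None
    for name, canon in TURN_CANON.items():
        devs = sorted(_angdiff(a, c) for a, c in zip(angles, canon))
        if devs[-1] > TURN_WINDOW_SLACK or devs[-2] > TURN_WINDOW:
            continue
        score = sum(devs)
        if best is None or score < best[0]:
            best = (score, name)
    if best is None:
        return "IV"
    name = best[1]
    return "III" if name in ("III", "III'") else name


def helix_handedness(phis: np.ndarray) -> tuple[str, bool]:
    """Handedness of a helical segment from its phi angles.

    Returns (handedness, ambiguous): right for median phi < 0, left for
    median phi > 0; the ambiguity flag is set when the segment mixes
    phi signs and |median| < 10°.
    """
    phis = np.asarray([p for p in phis if np.isfinite(p)], dtype=float)
    if phis.size == 0:
        raise InputError("handedness needs at least one defined phi")
    med = float(np.median(phis))
    mixed = (phis > 0).any() and (phis < 0).any()
    ambiguous = mixed and abs(med) < 10.0
    return ("left" if med > 0 else "right"), ambiguous


def ramachandran_basin(phi: float, psi: float) -> str:
    """Rectangular basin label: I, II, III, their primes, or "other".

    Basin I holds β-sheet/β-turn dihedrals, II the turn/3₁-helix/coil
    region, III the 3₁₀/α helical region; primed basins are the point
    reflections through the origin (left-handed mirrors).
    """
    if not (np.isfinite(phi) and np.isfinite(psi)):
        return "other"
    if -180 <= phi < -100 and 100 < psi <= 180:
        return "I"
    if -100 <= phi <= -55 and 120 <= psi <= 170:
        return "II"
    if -110 <= phi <= -40 and -60 <= psi <= 10:
        return "III"
    if 100 < phi <= 180 and -180 <= psi < -100:
        return "I'"
    if 55 <= phi <= 100 and -170 <= psi <= -120:
        return "II'"
    if 40 <= phi <= 110 and -10 <= psi <= 60:
        return "III'"
    return "other"


@dataclass
class TurnRecord:
    chain: int
    start_resnum: int   # residue i of the i..i+3 window
    turn_type: str      # I, I', II, II', IV


@dataclass
class HelixSegment:
    chain: int
    start_resnum: int
    length: int
    handedness: str
    ambiguous: bool


@dataclass
class SSAssignment:
    """Per-residue secondary structure for one frame."""

    labels: list[np.ndarray]        # per chain, array of single chars
    turns: list[TurnRecord]
    g_segments: list[HelixSegment]  # 3₁₀ segments with handedness
    basins: list[list[str]]         # per chain, per residue
    dihedrals: list[np.ndarray]     # per chain (n, 3) phi/psi/omega

    def chain_string(self, chain: int) -> str:
        return "".join(self.labels[chain])


def assign_frame(
    structure: BackboneStructure, hbonds: list[HBond] | None = None
) -> SSAssignment:
    """Assign secondary structure to one frame.

    Rules, applied with priority H > G > E > B > T > C:

    * H — two consecutive i→i+4 bonds mark residues i+1..i+4;
    * G — two consecutive i→i+3 bonds mark i+1..i+3, or a 4-residue
      window (i→i+3 bond, or Cα(i)–Cα(i+3) < 7 Å) whose central
      dihedrals match the type-III turn canon;
    * E/B — Kabsch–Sander parallel/antiparallel bridges; ladders of ≥ 2
      consecutive bridges become E, isolated bridges B;
    * T — remaining turn windows, typed by the Thornton canon (I, I′,
      II, II′, else IV).
    """
    if hbonds is None:
        hbonds = detect_hbonds(structure, criterion="energy")
    dihedrals = compute_dihedrals(structure)
    n_chains = structure.n_chains
    sizes = [len(c) for c in structure.chains]
    resnum_to_idx = [
        {int(rn): i for i, rn in enumerate(c.resnums)} for c in structure.chains
    ]

    # donor -> acceptor bonds by (chain, residue index)
    bond_set: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for b in hbonds:
        d = (b.donor[0], resnum_to_idx[b.donor[0]][b.donor[1]])
        a = (b.acceptor[0], resnum_to_idx[b.acceptor[0]][b.acceptor[1]])
        if d == a:
            raise InputError("self-bonded residue in hydrogen bond list")
        bond_set.add((d, a))

    def turn_bond(c: int, i: int, k: int) -> bool:
        """Intra-chain bond acceptor i <- donor i+k."""
        return ((c, i + k), (c, i)) in bond_set

    h_mask = [np.zeros(n, dtype=bool) for n in sizes]
    g_mask = [np.zeros(n, dtype=bool) for n in sizes]
    e_mask = [np.zeros(n, dtype=bool) for n in sizes]
    b_mask = [np.zeros(n, dtype=bool) for n in sizes]

    # --- helices -----------------------------------------------------------
    for c in range(n_chains):
        n = sizes[c]
        for i in range(n - 5):
            if turn_bond(c, i, 4) and turn_bond(c, i + 1, 4):
                h_mask[c][i + 1:i + 5] = True
        for i in range(n - 4):
            if turn_bond(c, i, 3) and turn_bond(c, i + 1, 3):
                g_mask[c][i + 1:i + 4] = True

    # --- turn windows: type III -> G, others deferred to T -----------------
    turn_windows: list[tuple[int, int, str]] = []  # (chain, start index, type)
    for c in range(n_chains):
        chain = structure.chains[c]
        ca = chain.atom("CA")
        dih = dihedrals[c]
        for i in range(sizes[c] - 3):
            has_bond = turn_bond(c, i, 3)
            ca_close = float(np.linalg.norm(ca[i + 3] - ca[i])) < TURN_CA_CUTOFF
            if not (has_bond or ca_close):
                continue
            central = (dih[i + 1, 0], dih[i + 1, 1], dih[i + 2, 0], dih[i + 2, 1])
            if not all(np.isfinite(a) for a in central):
                continue
            ttype = classify_turn(*central)
            if ttype == "III":
                # merge into 3₁₀: mark the window residues whose own
                # dihedrals sit in the (hand-consistent) 3₁₀ region
                sign = -1.0 if central[0] < 0 else 1.0
                for j in range(i, i + 4):
                    phi, psi = dih[j, 0], dih[j, 1]
                    if not (np.isfinite(phi) and np.isfinite(psi)):
                        continue
                    if (
                        _angdiff(phi, sign * 60.0) <= TURN_WINDOW_SLACK
                        and _angdiff(psi, sign * 30.0) <= TURN_WINDOW_SLACK
                    ):
                        g_mask[c][j] = True
            else:
                turn_windows.append((c, i, ttype))

    # --- bridges and ladders ----------------------------------------------
    bridges = _find_bridges(bond_set, sizes)
    ladder = set()
    for (p, q) in bridges:
        neighbors = [
            ((p[0], p[1] + 1), (q[0], q[1] + 1)),
            ((p[0], p[1] - 1), (q[0], q[1] - 1)),
            ((p[0], p[1] + 1), (q[0], q[1] - 1)),
            ((p[0], p[1] - 1), (q[0], q[1] + 1)),
        ]
        if any(_norm_pair(a, b) in bridges for a, b in neighbors):
            ladder.add((p, q))
    for (p, q) in bridges:
        mask = e_mask if (p, q) in ladder else b_mask
        mask[p[0]][p[1]] = True
        mask[q[0]][q[1]] = True

    # helix segments must span >= 3 residues; shorter G runs are turn-like
    for c in range(n_chains):
        i = 0
        n = sizes[c]
        while i < n:
            if not g_mask[c][i]:
                i += 1
                continue
            j = i
            while j < n and g_mask[c][j]:
                j += 1
            if j - i < 3 and not (h_mask[c][i:j].any()):
                g_mask[c][i:j] = False
            i = j

    # --- priority resolution ----------------------------------------------
    labels = [np.full(n, "C", dtype="<U1") for n in sizes]
    for c in range(n_chains):
        labels[c][b_mask[c]] = "B"
        labels[c][e_mask[c]] = "E"
        labels[c][g_mask[c]] = "G"
        labels[c][h_mask[c]] = "H"

    # turns last: only windows whose central residues are not H/G/E
    turns: list[TurnRecord] = []
    for c, i, ttype in turn_windows:
        if any(labels[c][j] in ("H", "G", "E") for j in (i + 1, i + 2)):
            continue
        turns.append(TurnRecord(c, int(structure.chains[c].resnums[i]), ttype))
        for j in range(i, i + 4):
            if labels[c][j] == "C":
                labels[c][j] = "T"

    # --- G segments with handedness ----------------------------------------
    g_segments: list[HelixSegment] = []
    for c in range(n_chains):
        chain = structure.chains[c]
        i = 0
        n = sizes[c]
        while i < n:
            if labels[c][i] != "G":
                i += 1
                continue
            j = i
            while j < n and labels[c][j] == "G":
                j += 1
            phis = dihedrals[c][i:j, 0]
            hand, amb = helix_handedness(phis)
            g_segments.append(HelixSegment(
                c, int(chain.resnums[i]), j - i, hand, amb
            ))
            i = j

    basins = [
        [ramachandran_basin(d[0], d[1]) for d in dihedrals[c]]
        for c in range(n_chains)
    ]
    return SSAssignment(labels, turns, g_segments, basins, dihedrals)


def _norm_pair(p: tuple[int, int], q: tuple[int, int]):
    return (p, q) if p <= q else (q, p)


def _find_bridges(bond_set, sizes) -> set:
    """Kabsch–Sander parallel/antiparallel bridge pairs from H-bonds.

    Bridge residues i, j (|i−j| ≥ 3 within a chain, or any inter-chain
    pair) satisfy one of the four bond patterns; candidates are
    enumerated from the bonds themselves.
    """
    def hb(a, b):  # donor a -> acceptor b
        return (a, b) in bond_set

    def valid(p):
        c, i = p
        return 0 <= i < sizes[c]

    candidates = set()
    for (d, a) in bond_set:
        # parallel: Hb(i-1, j) & Hb(j, i+1)  -> from first bond: i = d[1]+1 (same chain as d), j = a
        candidates.add(_norm_pair((d[0], d[1] + 1), a))
        candidates.add(_norm_pair((d[0], d[1] - 1), a))
        # antiparallel: Hb(i, j) & Hb(j, i)
        candidates.add(_norm_pair(d, a))
        # antiparallel: Hb(i-1, j+1) & Hb(j-1, i+1)
        candidates.add(_norm_pair((d[0], d[1] + 1), (a[0], a[1] - 1)))
        candidates.add(_norm_pair((d[0], d[1] - 1), (a[0], a[1] + 1)))

    bridges = set()
    for (p, q) in candidates:
        if not (valid(p) and valid(q)) or p == q:
            continue
        if p[0] == q[0] and abs(p[1] - q[1]) < 3:
            continue
        (ci, i), (cj, j) = p, q
        para = (
            (hb((ci, i - 1), (cj, j)) and hb((cj, j), (ci, i + 1)))
            or (hb((cj, j - 1), (ci, i)) and hb((ci, i), (cj, j + 1)))
        )
        anti = (
            (hb(p, q) and hb(q, p))
            or (hb((ci, i - 1), (cj, j + 1)) and hb((cj, j - 1), (ci, i + 1)))
        )
        if para or anti:
            bridges.add((p, q))
    return bridges


# ---------------------------------------------------------------------------
# Ensemble fractions
# ---------------------------------------------------------------------------

#: Classes reported in fraction tables; bridges (B) and π-helices are
#: computed internally but not reported.
REPORTED_CLASSES = {"G": "310_helix", "T": "beta_turn", "C": "coil",
                    "E": "beta_sheet", "H": "alpha_helix"}


@dataclass
class SSFractions:
    """Pooled percentages of region residue-frames per reported class."""

    percent: dict[str, float]
    region: tuple[int, int]
    n_residue_frames: int = 0
    by_handedness: dict[str, float] = field(default_factory=dict)


def assign_ensemble(ensemble: ConformerEnsemble) -> list[SSAssignment]:
    return [assign_frame(frame) for frame in ensemble.frames]


def region_fractions(
    assignments: list[SSAssignment],
    ensemble: ConformerEnsemble,
    region: tuple[int, int],
) -> SSFractions:
    """Percentage of region residue-frames in each reported class.

    Pools residues across frames: 100 × (residue-frames with label ℓ in
    the region) / (region residues × frames).
    """
    lo, hi = region
    counts = {name: 0 for name in REPORTED_CLASSES.values()}
    hand_counts = {"left": 0, "right": 0}
    total = 0
    topo = ensemble.topology
    for assignment in assignments:
        for c, chain in enumerate(topo.chains):
            in_region = (chain.resnums >= lo) & (chain.resnums <= hi)
            idx = np.nonzero(in_region)[0]
            total += idx.size
            for i in idx:
                lab = assignment.labels[c][i]
                if lab in REPORTED_CLASSES:
                    counts[REPORTED_CLASSES[lab]] += 1
        for seg in assignment.g_segments:
            resnums = topo.chains[seg.chain].resnums
            start = seg.start_resnum
            for rn in range(start, start + seg.length):
                if lo <= rn <= hi and not seg.ambiguous:
                    hand_counts[seg.handedness] += 1
    if total == 0:
        raise InputError(f"region {region} contains no residues")
    percent = {k: 100.0 * v / total for k, v in counts.items()}
    hand = {k: 100.0 * v / total for k, v in hand_counts.items()}
    return SSFractions(percent, region, total, hand)
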