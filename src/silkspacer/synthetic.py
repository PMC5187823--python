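"""Synthetic conformer generation.

The MD ensembles this package analyses come from temperature
replica-exchange simulations of MaSp1 mini-fibrils; no trajectories are
deposited, so this module generates stand-in ensembles with controlled
ground truth: chains built from ideal internal coordinates, mini-fibrils
assembled as planes of antiparallel β-strands, and a stochastic sampler
that places the disordered spacer residues in named conformational
states (β, polyglycine-II 3₁, right/left 3₁₀, α, turn, coil) with
prescribed occupancies and Gaussian dihedral noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, ConstructionError, InputError
from .geometry import compute_dihedrals, nerf_place, superpose
from .structures import AA3, ATOM_INDEX, BackboneStructure, Chain, ConformerEnsemble

# ---------------------------------------------------------------------------
# Ideal backbone geometry (Engh–Huber-like)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneGeometry:
    """Fixed internal-coordinate parameters, lengths in Å, angles in degrees."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    n_h: float = 1.00
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8


IDEAL_GEOMETRY = BackboneGeometry()

#: MaSp1 consensus fragment, residues 71–121.
MASP1_SEQUENCE = (
    "GQGAGAAAAAAGGAGQGGYGGLGSQGAGRGGLGGQGAGAAAAAAAGGAGQG"
)
MASP1_FIRST_RESNUM = 71
#: Disordered Gly-rich spacer between the two poly(Ala) blocks.
SPACER_RANGE = (82, 107)
POLYA1_RANGE = (71, 81)
POLYA2_RANGE = (108, 121)


# ---------------------------------------------------------------------------
# Chain construction from dihedrals (NeRF)
# ---------------------------------------------------------------------------

def build_backbone(
    sequence: str,
    dihedrals: np.ndarray,
    geometry: BackboneGeometry = IDEAL_GEOMETRY,
    first_resnum: int = 1,
) -> BackboneStructure:
    """Build a single chain from per-residue (phi, psi, omega) in degrees.

    ``dihedrals`` has shape (n, 3). phi of the first residue and psi of
    the last may be NaN (they do not enter the construction); omega
    defaults to 180° where NaN. Recomputing dihedrals from the returned
    coordinates reproduces the inputs to well below 1e-6°.
    """
    dihedrals = np.asarray(dihedrals, dtype=float)
    n = len(sequence)
    if dihedrals.shape != (n, 3):
        raise InputError(
            f"need one (phi, psi, omega) triple per residue: got "
            f"{dihedrals.shape} for {n} residues"
        )
    for code in sequence:
        if code not in AA3:
            raise InputError(f"unknown residue code {code!r}")
    interior = dihedrals.copy()
    interior[0, 0] = np.nan   # phi(0) unused
    interior[-1, 1] = np.nan  # psi(last) unused
    used = np.concatenate([interior[1:, 0], interior[:-1, 1], interior[1:, 2]])
    if not np.all(np.isfinite(used[~np.isnan(used)])):
        raise InputError("non-finite dihedral angle")
    if np.isnan(interior[1:, 0]).any() or np.isnan(interior[:-1, 1]).any():
        raise InputError("interior phi/psi may not be missing")
    omega = np.where(np.isnan(interior[:, 2]), 180.0, interior[:, 2])

    g = geometry
    coords = np.full((n, 5, 3), np.nan)
    iN, iCA, iC, iO, iH = (ATOM_INDEX[a] for a in ("N", "CA", "C", "O", "H"))
    # first residue in a canonical frame
    coords[0, iN] = [0.0, 0.0, 0.0]
    coords[0, iCA] = [g.n_ca, 0.0, 0.0]
    theta = math.radians(g.ang_n_ca_c)
    coords[0, iC] = coords[0, iCA] + g.ca_c * np.array(
        [-math.cos(theta), math.sin(theta), 0.0]
    )
    for i in range(1, n):
        psi_prev = interior[i - 1, 1]
        coords[i, iN] = nerf_place(
            coords[i - 1, iN], coords[i - 1, iCA], coords[i - 1, iC],
            g.c_n, g.ang_ca_c_n, psi_prev,
        )
        coords[i, iCA] = nerf_place(
            coords[i - 1, iCA], coords[i - 1, iC], coords[i, iN],
            g.n_ca, g.ang_c_n_ca, omega[i],
        )
        coords[i, iC] = nerf_place(
            coords[i - 1, iC], coords[i, iN], coords[i, iCA],
            g.ca_c, g.ang_n_ca_c, interior[i, 0],
        )
    # carbonyl O: in the peptide plane, anti to the next N
    for i in range(n):
        psi = interior[i, 1] if i < n - 1 else 180.0
        coords[i, iO] = nerf_place(
            coords[i, iN], coords[i, iCA], coords[i, iC],
            g.c_o, g.ang_ca_c_o, psi - 180.0,
        )
    # amide H: external bisector of C(i-1)–N–CA, in the peptide plane
    for i in range(1, n):
        u1 = coords[i - 1, iC] - coords[i, iN]
        u2 = coords[i, iCA] - coords[i, iN]
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        coords[i, iH] = coords[i, iN] - g.n_h * bis / np.linalg.norm(bis)

    resnums = np.arange(first_resnum, first_resnum + n)
    return BackboneStructure([Chain(sequence, resnums, coords)])


def uniform_dihedrals(n: int, phi: float, psi: float, omega: float = 180.0) -> np.ndarray:
    """(n, 3) dihedral array with every residue at the same (phi, psi, omega)."""
    d = np.tile([phi, psi, omega], (n, 1)).astype(float)
    d[0, 0] = np.nan
    d[-1, 1] = np.nan
    return d


# ---------------------------------------------------------------------------
# Mini-fibril assembly
# ---------------------------------------------------------------------------

@dataclass
class FibrilSpec:
    """Strand packing of a mini-fibril.

    Strands run antiparallel within each plane; planes stack either
    parallel (AP system) or antiparallel (AA system).
    """

    n_planes: int = 3
    n_strands_per_plane: int = 5
    between_plane_orientation: str = "parallel"   # "parallel" (AP) | "antiparallel" (AA)
    inter_strand_spacing: float = 4.8  # Å, within a plane
    inter_plane_spacing: float = 5.3   # Å, between stacked planes

    def __post_init__(self) -> None:
        if self.n_planes < 1 or self.n_strands_per_plane < 1:
            raise InputError("fibril needs at least 1 plane and 1 strand")
        if self.between_plane_orientation not in ("parallel", "antiparallel"):
            raise InputError(
                f"unknown orientation {self.between_plane_orientation!r}"
            )

    def strand_direction(self, plane: int, strand: int) -> int:
        """+1 / −1 direction flag of a strand (N→C along +axis or −axis)."""
        flip = (-1) ** strand
        if self.between_plane_orientation == "antiparallel":
            flip *= (-1) ** plane
        return flip


#: Extended β template used for fibril strands.
EXTENDED_BETA = (-135.0, 135.0)


def build_fibril(
    spec: FibrilSpec,
    strand_sequence: str = MASP1_SEQUENCE,
    strand_dihedrals: np.ndarray | None = None,
    first_resnum: int = MASP1_FIRST_RESNUM,
    geometry: BackboneGeometry = IDEAL_GEOMETRY,
    min_clearance: float = 2.0,
) -> BackboneStructure:
    """Assemble a mini-fibril of identical strands on a rectangular grid.

    Each strand is built (extended β by default), centred, and rotated
    into a canonical frame: long axis along x, mean alternating carbonyl
    direction along y. Strands are copied to lattice positions
    y = strand·spacing (the hydrogen-bond direction within a sheet
    plane), z = plane·spacing (the sheet stacking direction). Alternate
    strands within a plane are flipped 180° about z (antiparallel
    packing), with the axial register of flipped strands chosen by a
    deterministic scan that maximises inter-strand hydrogen bonds.
    Raises :class:`ConstructionError` on steric clash (< ``min_clearance``
    Å between atoms of different chains).
    """
    from .geometry import detect_hbonds  # local import: geometry imports nothing back

    n = len(strand_sequence)
    if strand_dihedrals is None:
        strand_dihedrals = uniform_dihedrals(n, *EXTENDED_BETA)
    template = build_backbone(strand_sequence, strand_dihedrals, geometry, first_resnum)
    chain = template.chains[0]
    ca = chain.atom("CA")
    centroid = ca.mean(axis=0)
    coords = chain.coords - centroid
    # principal axis of the strand -> x, oriented N→C
    flat = ca - centroid
    _, _, vt = np.linalg.svd(flat, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    # alternating carbonyl direction -> y (this is where sheet H-bonds form)
    co = chain.atom("O") - chain.atom("C")
    signs = np.array([(-1.0) ** i for i in range(n)])
    v = (co * signs[:, None]).mean(axis=0)
    v -= np.dot(v, axis) * axis
    v /= np.linalg.norm(v)
    rot = np.stack([axis, v, np.cross(axis, v)])
    coords = coords @ rot.T
    flip = np.diag([-1.0, -1.0, 1.0])  # 180° about z

    # register of antiparallel neighbours: scan the axial offset of the
    # flipped strand for maximal inter-strand H-bonding, then clearance
    register = 0.0
    if spec.n_strands_per_plane > 1 or (
        spec.n_planes > 1 and spec.between_plane_orientation == "antiparallel"
    ):
        best = None
        for dx in np.arange(-4.0, 4.01, 0.25):
            partner = coords @ flip.T + np.array(
                [dx, spec.inter_strand_spacing, 0.0]
            )
            pair = BackboneStructure([
                Chain(strand_sequence, chain.resnums.copy(), coords),
                Chain(strand_sequence, chain.resnums.copy(), partner),
            ])
            n_bonds = sum(
                b.donor[0] != b.acceptor[0] for b in detect_hbonds(pair)
            )
            a = coords[:, :4, :].reshape(-1, 3)
            bpts = partner[:, :4, :].reshape(-1, 3)
            clearance = float(np.sqrt(
                ((a[:, None, :] - bpts[None, :, :]) ** 2).sum(-1).min()
            ))
            key = (n_bonds, clearance)
            if best is None or key > best[0]:
                best = (key, float(dx))
        register = best[1]

    chains = []
    for plane in range(spec.n_planes):
        for strand in range(spec.n_strands_per_plane):
            c = coords.copy()
            offset = np.array([
                0.0,
                strand * spec.inter_strand_spacing,
                plane * spec.inter_plane_spacing,
            ])
            if spec.strand_direction(plane, strand) < 0:
                c = c @ flip.T
                offset[0] += register
            chains.append(Chain(strand_sequence, chain.resnums.copy(), c + offset))

    fibril = BackboneStructure(chains)
    _check_clashes(fibril, min_clearance)
    return fibril


def _check_clashes(structure: BackboneStructure, min_clearance: float) -> None:
    heavy = [c.coords[:, :4, :].reshape(-1, 3) for c in structure.chains]
    for i in range(len(heavy)):
        for j in range(i + 1, len(heavy)):
            d2 = np.sum((heavy[i][:, None, :] - heavy[j][None, :, :]) ** 2, axis=-1)
            dmin = math.sqrt(float(d2.min()))
            if dmin < min_clearance:
                raise ConstructionError(
                    f"chains {i} and {j} clash: minimum inter-atom distance "
                    f"{dmin:.2f} Å < {min_clearance} Å (increase spacing)"
                )


# ---------------------------------------------------------------------------
# Conformational state library
# ---------------------------------------------------------------------------

#: Ramachandran rectangles coil residues may occupy (basins I, II and their
#: mirrors; the helical basin is deliberately excluded — it belongs to the
#: explicit helical states).
COIL_BASINS = (
    (-180.0, -100.0, 100.0, 180.0),   # basin I
    (-100.0, -55.0, 120.0, 170.0),    # basin II
    (100.0, 180.0, -180.0, -100.0),   # basin I'
    (55.0, 100.0, -170.0, -120.0),    # basin II'
)


@dataclass
class ConformationalState:
    """One named (phi, psi) state with Gaussian spread and occupancy.

    ``centers`` lists the (phi, psi) centre for each residue of a run;
    one entry means every residue of the run uses the same centre.
    ``run_length`` is the natural contiguous extent of the state
    (3 for the helical states, matching the observation that silk
    3₁- and 3₁₀-helices are three residues long; 1 for point states).
    ``uniform_basins`` replaces Gaussian sampling with a uniform draw
    over Ramachandran rectangles (used by the coil state).
    """

    label: str
    centers: tuple[tuple[float, float], ...]
    sigma: float = 10.0
    occupancy: float = 0.0
    run_length: int = 1
    uniform_basins: tuple[tuple[float, float, float, float], ...] | None = None

    def sample(self, rng: np.random.Generator, position: int) -> tuple[float, float]:
        if self.uniform_basins is not None:
            areas = np.array([
                (hi_p - lo_p) * (hi_s - lo_s)
                for lo_p, hi_p, lo_s, hi_s in self.uniform_basins
            ], dtype=float)
            k = rng.choice(len(areas), p=areas / areas.sum())
            lo_p, hi_p, lo_s, hi_s = self.uniform_basins[k]
            return float(rng.uniform(lo_p, hi_p)), float(rng.uniform(lo_s, hi_s))
        phi_c, psi_c = self.centers[min(position, len(self.centers) - 1)]
        phi = _wrap_angle(phi_c + rng.normal(0.0, self.sigma))
        psi = _wrap_angle(psi_c + rng.normal(0.0, self.sigma))
        return phi, psi


def _wrap_angle(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass
class StateLibrary:
    """Named conformational states with occupancies summing to 1."""

    states: list[ConformationalState]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise InputError("state labels must be unique")
        for s in self.states:
            if not 0.0 <= s.occupancy <= 1.0:
                raise InputError(f"occupancy of {s.label!r} outside [0, 1]")
            if s.sigma < 0:
                raise InputError(f"negative sigma for {s.label!r}")
        total = sum(s.occupancy for s in self.states)
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"occupancies sum to {total}, not 1")

    def __getitem__(self, label: str) -> ConformationalState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]


def default_state(label: str, occupancy: float, sigma: float = 10.0) -> ConformationalState:
    """A state from the built-in catalogue with the given occupancy."""
    catalogue: dict[str, ConformationalState] = {
        "beta": ConformationalState("beta", ((-135.0, 135.0),), sigma, run_length=1),
        "pgii": ConformationalState("pgii", ((-90.0, 150.0),), sigma, run_length=3),
        "310R": ConformationalState("310R", ((-70.0, -25.0),), sigma, run_length=3),
        "310L": ConformationalState("310L", ((70.0, 25.0),), sigma, run_length=3),
        "alpha": ConformationalState("alpha", ((-57.0, -47.0),), sigma, run_length=6),
        "turn": ConformationalState(
            "turn", ((-60.0, -30.0), (-90.0, 0.0)), sigma, run_length=2
        ),
        "coil": ConformationalState(
            "coil", ((0.0, 0.0),), sigma, run_length=1, uniform_basins=COIL_BASINS
        ),
    }
    if label not in catalogue:
        raise InputError(f"unknown state {label!r}; known: {sorted(catalogue)}")
    state = catalogue[label]
    state.occupancy = occupancy
    return state


def make_library(occupancies: dict[str, float], sigma: float = 10.0) -> StateLibrary:
    """Library from a {state label: occupancy} mapping using catalogue centres."""
    return StateLibrary([default_state(k, v, sigma) for k, v in occupancies.items()])


# ---------------------------------------------------------------------------
# Ensemble sampling
# ---------------------------------------------------------------------------

def sample_ensemble(
    template: BackboneStructure,
    library: StateLibrary,
    region: tuple[int, int] = SPACER_RANGE,
    n_frames: int = 100,
    seed: int | None = None,
    mode: str = "segment",
    geometry: BackboneGeometry = IDEAL_GEOMETRY,
    temperature: float = 300.0,
) -> ConformerEnsemble:
    """Generate a stochastic conformer ensemble over a residue region.

    Per frame, region residues of every chain are assigned conformational
    states and their dihedrals redrawn; residues outside the region keep
    the template dihedrals. Each chain is rebuilt from internal
    coordinates and re-anchored by superposing its leading non-region
    segment (or its first three residues) onto the template, so the
    first poly(Ala) block stays in the fibril frame while downstream
    geometry responds to the spacer.

    ``mode="segment"`` (default) draws contiguous runs: a run's state is
    chosen with probability proportional to occupancy / run_length and
    extends over the state's natural run length, which leaves each
    residue's marginal state probability equal to the library occupancy
    while producing helical segments long enough to hydrogen-bond.
    ``mode="independent"`` assigns every residue independently.
    """
    if mode not in ("segment", "independent"):
        raise InputError(f"unknown sampling mode {mode!r}")
    if n_frames < 1:
        raise InputError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = region
    template_dihedrals = compute_dihedrals(template)
    for chain in template.chains:
        in_region = (chain.resnums >= lo) & (chain.resnums <= hi)
        if not in_region.any():
            raise InputError(f"region {region} outside chain numbering")

    occ = np.array([s.occupancy for s in library.states])
    run_w = np.array([s.occupancy / s.run_length for s in library.states])

    frames: list[BackboneStructure] = []
    labels_per_frame: list[list[list[str | None]]] = []
    for _ in range(n_frames):
        new_chains = []
        frame_labels = []
        for ci, chain in enumerate(template.chains):
            n = len(chain)
            dih = template_dihedrals[ci].copy()
            in_region = (chain.resnums >= lo) & (chain.resnums <= hi)
            region_idx = np.nonzero(in_region)[0]
            labels: list[str | None] = [None] * n

            if mode == "independent":
                for ri in region_idx:
                    k = rng.choice(len(library.states), p=occ)
                    state = library.states[k]
                    labels[ri] = state.label
                    dih[ri, 0], dih[ri, 1] = state.sample(rng, 0)
            else:
                p = 0
                w = run_w / run_w.sum()
                while p < len(region_idx):
                    k = rng.choice(len(library.states), p=w)
                    state = library.states[k]
                    run = min(state.run_length, len(region_idx) - p)
                    for j in range(run):
                        ri = region_idx[p + j]
                        labels[ri] = state.label
                        dih[ri, 0], dih[ri, 1] = state.sample(rng, j)
                    p += run
            # terminal angles stay undefined
            dih[0, 0] = np.nan
            dih[-1, 1] = np.nan
            rebuilt = build_backbone(
                chain.sequence, dih, geometry, int(chain.resnums[0])
            ).chains[0]
            # re-anchor on the leading non-region residues (>= 3 residues)
            anchor = np.nonzero(chain.resnums < lo)[0]
            if anchor.size < 3:
                anchor = np.arange(min(3, n))
            mob = rebuilt.coords[anchor][:, :4, :].reshape(-1, 3)
            ref = chain.coords[anchor][:, :4, :].reshape(-1, 3)
            fit = superpose(mob, ref)
            rebuilt = Chain(
                rebuilt.sequence,
                rebuilt.resnums,
                rebuilt.coords @ fit.rotation.T + fit.translation,
            )
            new_chains.append(rebuilt)
            frame_labels.append(labels)
        frames.append(BackboneStructure(new_chains))
        labels_per_frame.append(frame_labels)

    return ConformerEnsemble(
        frames=frames,
        state_labels=labels_per_frame,
        temperature=temperature,
        seed=seed,
        meta={"region": region, "mode": mode, "states": library.labels},
    )


def ground_truth_fraction(ensemble: ConformerEnsemble, label: str,
                          region: tuple[int, int] | None = None) -> float:
    """Fraction of region residue-frames the generator placed in ``label``."""
    if ensemble.state_labels is None:
        raise InputError("ensemble carries no generator labels")
    lo, hi = region if region is not None else ensemble.meta.get("region", (None, None))
    hit = total = 0
    for frame_labels, frame in zip(ensemble.state_labels, ensemble.frames):
        for chain_labels, chain in zip(frame_labels, frame.chains):
            for lab, resnum in zip(chain_labels, chain.resnums):
                if lab is None:
                    continue
                if lo is not None and not (lo <= resnum <= hi):
                    continue
                total += 1
                hit += lab == label
    if total == 0:
        raise InputError("no labelled residues in region")
    return hit / total


# ---------------------------------------------------------------------------
# Replica-temperature ladders
# ---------------------------------------------------------------------------

#: Common replica temperatures (K) shared by the AP and AA systems.
COMMON_TEMPERATURES = (
    300, 302, 304, 307, 309, 311, 313, 315, 317, 319, 322, 324, 326, 329,
    333, 334.5, 336, 339, 341, 343, 345, 347, 350, 352, 355, 357, 359, 361,
    363, 365, 367, 369, 371, 373, 375, 377, 380,
)
#: System-specific additions.
AP_EXTRA_TEMPERATURES = (305.5, 320, 327.5, 331, 337, 348.5, 353)
AA_EXTRA_TEMPERATURES = (305.5, 321, 327.5, 331, 337.5, 353.5, 378.5)


@dataclass
class ReplicaLadder:
    """Sorted replica temperatures for one fibril system."""

    temperatures: tuple[float, ...]
    system: str  # "AP" | "AA"

    def __len__(self) -> int:
        return len(self.temperatures)


def parse_replica_ladder(
    config: dict | None = None, system: str = "AP"
) -> ReplicaLadder:
    """Merge common and system-specific temperature lists into a ladder.

    ``config`` may carry keys ``common`` and ``ap_extra`` / ``aa_extra``;
    omitted keys fall back to the packaged lists. Duplicate temperatures
    and an empty merged list are configuration errors.
    """
    system = system.upper()
    if system not in ("AP", "AA"):
        raise ConfigError(f"unknown system {system!r}")
    config = config or {}
    common = list(config.get("common", COMMON_TEMPERATURES))
    extra_key = "ap_extra" if system == "AP" else "aa_extra"
    default_extra = AP_EXTRA_TEMPERATURES if system == "AP" else AA_EXTRA_TEMPERATURES
    extra = list(config.get(extra_key, default_extra if "common" not in config else ()))
    merged = [float(t) for t in common + extra]
    if not merged:
        raise ConfigError("empty temperature ladder")
    if len(set(merged)) != len(merged):
        dupes = sorted({t for t in merged if merged.count(t) > 1})
        raise ConfigError(f"duplicate temperatures in ladder: {dupes}")
    merged.sort()
    if any(b <= a for a, b in zip(merged, merged[1:])):
        raise ConfigError("ladder not strictly increasing after merge")
    return ReplicaLadder(tuple(merged), system)
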