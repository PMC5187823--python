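"""Backbone structure containers and multi-model PDB I/O.

The package works exclusively with protein backbones: per residue the
atoms N, CA, C, O and the amide H (absent on chain-initial residues).
Coordinates are stored as a dense ``(n_residues, 5, 3)`` array per chain
with NaN marking absent atoms, which keeps every downstream geometric
operation vectorisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .exceptions import FormatError, InputError

#: Backbone atom order used throughout the package.
BACKBONE_ATOMS = ("N", "CA", "C", "O", "H")
ATOM_INDEX = {name: i for i, name in enumerate(BACKBONE_ATOMS)}

# One-letter -> three-letter residue codes (standard amino acids).
AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


@dataclass
class Chain:
    """One polypeptide chain: sequence, residue numbers and backbone coords."""

    sequence: str
    resnums: np.ndarray          # (n,) int
    coords: np.ndarray           # (n, 5, 3) float, NaN = atom absent

    def __post_init__(self) -> None:
        self.resnums = np.asarray(self.resnums, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.sequence)
        if self.resnums.shape != (n,) or self.coords.shape != (n, 5, 3):
            raise InputError(
                f"chain shape mismatch: {n} residues, resnums "
                f"{self.resnums.shape}, coords {self.coords.shape}"
            )
        for code in self.sequence:
            if code not in AA3:
                raise InputError(f"unknown residue code {code!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def atom(self, name: str) -> np.ndarray:
        """Coordinates of one backbone atom type, shape (n, 3)."""
        return self.coords[:, ATOM_INDEX[name], :]

    def resnum_index(self, resnum: int) -> int:
        idx = np.nonzero(self.resnums == resnum)[0]
        if idx.size != 1:
            raise InputError(f"residue number {resnum} not unique in chain")
        return int(idx[0])


@dataclass
class BackboneStructure:
    """An ordered collection of chains sharing one coordinate frame."""

    chains: list[Chain]

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def coord_array(
        self,
        atoms: tuple[str, ...] = ("N", "CA", "C", "O"),
        resnum_range: tuple[int, int] | None = None,
        chain_indices: list[int] | None = None,
    ) -> np.ndarray:
        """Flattened (m, 3) coordinate selection in stable chain/residue order.

        ``resnum_range`` is an inclusive ``(lo, hi)`` residue-number window;
        atoms that are absent (NaN) are dropped, so the selection mask is a
        pure function of topology and applies identically to every frame of
        an ensemble.
        """
        chain_indices = (
            list(range(self.n_chains)) if chain_indices is None else chain_indices
        )
        atom_idx = [ATOM_INDEX[a] for a in atoms]
        parts = []
        for ci in chain_indices:
            chain = self.chains[ci]
            mask = np.ones(len(chain), dtype=bool)
            if resnum_range is not None:
                lo, hi = resnum_range
                mask &= (chain.resnums >= lo) & (chain.resnums <= hi)
            sel = chain.coords[mask][:, atom_idx, :].reshape(-1, 3)
            parts.append(sel)
        coords = np.concatenate(parts, axis=0) if parts else np.empty((0, 3))
        return coords[~np.isnan(coords).any(axis=1)]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        new_chains = []
        for chain in self.chains:
            coords = chain.coords @ rotation.T + translation
            new_chains.append(Chain(chain.sequence, chain.resnums.copy(), coords))
        return BackboneStructure(new_chains)

    def same_topology(self, other: "BackboneStructure") -> bool:
        if self.n_chains != other.n_chains:
            return False
        for a, b in zip(self.chains, other.chains):
            if a.sequence != b.sequence or not np.array_equal(a.resnums, b.resnums):
                return False
        return True


@dataclass
class ConformerEnsemble:
    """Frames of one topology, optionally with generator ground-truth labels.

    ``state_labels[f][c]`` is a list (len = chain length) of state names for
    frame ``f``, chain ``c``; None for ensembles read from file.
    """

    frames: list[BackboneStructure]
    state_labels: list[list[list[str | None]]] | None = None
    temperature: float = 300.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise InputError("ensemble must contain at least one frame")
        first = self.frames[0]
        for frame in self.frames[1:]:
            if not frame.same_topology(first):
                raise FormatError("ensemble frames differ in topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def topology(self) -> BackboneStructure:
        return self.frames[0]


# ---------------------------------------------------------------------------
# PDB I/O (multi-model, via biotite)
# ---------------------------------------------------------------------------

def _to_atom_array(structure: BackboneStructure) -> AtomArray:
    records = []
    for ci, chain in enumerate(structure.chains):
        cid = _CHAIN_IDS[ci % len(_CHAIN_IDS)]
        for ri in range(len(chain)):
            for atom_name in BACKBONE_ATOMS:
                xyz = chain.coords[ri, ATOM_INDEX[atom_name]]
                if np.isnan(xyz).any():
                    continue
                records.append((cid, int(chain.resnums[ri]),
                                AA3[chain.sequence[ri]], atom_name, xyz))
    arr = AtomArray(len(records))
    for i, (cid, resnum, resname, atom_name, xyz) in enumerate(records):
        arr.chain_id[i] = cid
        arr.res_id[i] = resnum
        arr.res_name[i] = resname
        arr.atom_name[i] = atom_name
        arr.element[i] = atom_name[0]
        arr.coord[i] = xyz
    arr.hetero[:] = False
    arr.set_annotation("occupancy", np.ones(len(records)))
    arr.set_annotation("b_factor", np.zeros(len(records)))
    return arr


def write_ensemble_pdb(ensemble: ConformerEnsemble, path: str) -> None:
    """Write all frames as a multi-model PDB (MODEL/ENDMDL records)."""
    template = _to_atom_array(ensemble.topology)
    stack = AtomArrayStack(ensemble.n_frames, template.array_length())
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    for fi, frame in enumerate(ensemble.frames):
        stack.coord[fi] = _to_atom_array(frame).coord
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def write_structure_pdb(structure: BackboneStructure, path: str) -> None:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    pdb.write(path)


def _chains_from_atom_array(arr: AtomArray) -> list[Chain]:
    chains: list[Chain] = []
    for cid in np.unique(arr.chain_id):
        sub = arr[arr.chain_id == cid]
        resnums = []
        seq = []
        coords = []
        for resnum in sorted(set(int(r) for r in sub.res_id)):
            res = sub[sub.res_id == resnum]
            resname = str(res.res_name[0])
            if resname not in AA1:
                continue
            block = np.full((5, 3), np.nan)
            for ai, atom_name in enumerate(BACKBONE_ATOMS):
                hit = res[res.atom_name == atom_name]
                if hit.array_length() > 0:
                    block[ai] = hit.coord[0]
            if np.isnan(block[:4]).any():
                # mandatory backbone atom absent: skip the residue
                continue
            resnums.append(resnum)
            seq.append(AA1[resname])
            coords.append(block)
        if seq:
            chains.append(Chain("".join(seq), np.array(resnums), np.array(coords)))
    return chains


def read_ensemble_pdb(path: str, synthesize_h: bool = True) -> ConformerEnsemble:
    """Read a multi-model PDB into an ensemble.

    Amide hydrogens absent from the file are rebuilt from the standard
    in-plane placement so hydrogen-bond detection always has them.
    Raises :class:`FormatError` when models disagree in atom count.
    """
    pdb = PDBFile.read(path)
    n_models = pdb.get_model_count()
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise FormatError(f"inconsistent models in {path}: {exc}") from exc
    if isinstance(stack, AtomArray):
        stack = AtomArrayStack(1, stack.array_length())
    frames = []
    for mi in range(n_models):
        arr = pdb.get_structure(model=mi + 1)
        chains = _chains_from_atom_array(arr)
        structure = BackboneStructure(chains)
        if synthesize_h:
            _fill_missing_amide_h(structure)
        frames.append(structure)
    return ConformerEnsemble(frames)


def _fill_missing_amide_h(structure: BackboneStructure) -> None:
    """Place missing amide hydrogens on the external C(i-1)–N–CA bisector."""
    h = ATOM_INDEX["H"]
    for chain in structure.chains:
        for ri in range(1, len(chain)):
            if not np.isnan(chain.coords[ri, h]).any():
                continue
            n_pos = chain.coords[ri, ATOM_INDEX["N"]]
            c_prev = chain.coords[ri - 1, ATOM_INDEX["C"]]
            ca = chain.coords[ri, ATOM_INDEX["CA"]]
            u1 = c_prev - n_pos
            u2 = ca - n_pos
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            bis = u1 + u2
            chain.coords[ri, h] = n_pos - 1.00 * bis / np.linalg.norm(bis)
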