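"""Fibril-level geometry: bending between the poly(Ala) crystal blocks
and region-resolved RMSD.

The mini-fibril has two nanocrystalline poly(Ala) β-sheet blocks joined
by the disordered spacer; the spacer's flexibility lets the fibril bend.
Bending is measured as the angle between the principal axes of the two
blocks and decomposed into in-plane (within the sheet plane) and
out-of-plane (along the sheet stacking direction) components, anchored
to the first block's sheet frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError, InputError
from .geometry import average_structure, ensemble_rmsd, superpose
from .structures import BackboneStructure, ConformerEnsemble


@dataclass
class RegionSpec:
    """Named residue ranges of one strand (inclusive bounds)."""

    polya1: tuple[int, int] = (71, 81)
    spacer: tuple[int, int] = (82, 107)
    polya2: tuple[int, int] = (108, 121)

    def __post_init__(self) -> None:
        ranges = [self.polya1, self.spacer, self.polya2]
        for lo, hi in ranges:
            if lo > hi:
                raise InputError(f"empty region ({lo}, {hi})")
        for (a, b), (c, d) in zip(ranges, ranges[1:]):
            if b >= c:
                raise InputError("regions must be disjoint and ordered")

    def named(self) -> dict[str, tuple[int, int]]:
        return {"polyA1": self.polya1, "spacer": self.spacer, "polyA2": self.polya2}


def block_frame(
    structure: BackboneStructure, block: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed orthonormal frame (axis, in_plane, normal) of a block.

    axis   — first principal component of the block's Cα cloud, oriented
             N→C along the first chain;
    normal — third principal component (the sheet stacking direction);
    in_plane = normal × axis completes the frame.
    """
    ca = structure.coord_array(atoms=("CA",), resnum_range=block)
    if ca.shape[0] < 4:
        raise GeometryError("block frame needs at least 4 CA atoms")
    centred = ca - ca.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-6:
        raise GeometryError("degenerate (collinear) block")
    axis, normal = vt[0], vt[2]
    # orient axis N->C along the first chain's block residues
    chain = structure.chains[0]
    mask = (chain.resnums >= block[0]) & (chain.resnums <= block[1])
    ca0 = chain.atom("CA")[mask]
    if ca0.shape[0] >= 2 and np.dot(axis, ca0[-1] - ca0[0]) < 0:
        axis = -axis
    in_plane = np.cross(normal, axis)
    if np.dot(np.cross(axis, in_plane), normal) < 0:
        normal = -normal
        in_plane = np.cross(normal, axis)
    return axis, in_plane, normal


@dataclass
class BendingResult:
    """Per-frame bending angles (degrees) with summary statistics."""

    total: np.ndarray
    in_plane: np.ndarray
    out_of_plane: np.ndarray

    def summary(self) -> dict[str, tuple[float, float]]:
        return {
            "total": (float(self.total.mean()), float(self.total.std())),
            "in_plane": (float(self.in_plane.mean()), float(self.in_plane.std())),
            "out_of_plane": (
                float(self.out_of_plane.mean()), float(self.out_of_plane.std())
            ),
        }


def bending_angles(
    ensemble: ConformerEnsemble, regions: RegionSpec | None = None
) -> BendingResult:
    """Bending between the two poly(Ala) blocks, decomposed per frame.

    total        — angle between the two block axes;
    out_of_plane — |asin| of the second axis' component along the first
                   block's sheet normal;
    in_plane     — angle between the first axis and the second axis
                   projected onto the first block's sheet plane.
    """
    regions = regions or RegionSpec()
    totals, in_planes, out_planes = [], [], []
    for frame in ensemble.frames:
        axis1, _, normal1 = block_frame(frame, regions.polya1)
        axis2, _, _ = block_frame(frame, regions.polya2)
        cos_total = np.clip(np.dot(axis1, axis2), -1.0, 1.0)
        totals.append(np.degrees(np.arccos(cos_total)))
        z = np.clip(np.dot(axis2, normal1), -1.0, 1.0)
        out_planes.append(abs(np.degrees(np.arcsin(z))))
        proj = axis2 - z * normal1
        norm = np.linalg.norm(proj)
        if norm < 1e-9:
            in_planes.append(0.0)
        else:
            cos_ip = np.clip(np.dot(axis1, proj / norm), -1.0, 1.0)
            in_planes.append(np.degrees(np.arccos(cos_ip)))
    return BendingResult(
        np.asarray(totals), np.asarray(in_planes), np.asarray(out_planes)
    )


def region_rmsd_report(
    ensemble: ConformerEnsemble,
    regions: RegionSpec | None = None,
    reference: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Backbone RMSD mean ± sd per region, against the ensemble average.

    Frames are superposed on the FULL backbone before measuring each
    region, so region values express mobility relative to the global
    fibril frame; the reference is the converged iterative mean unless
    supplied.
    """
    regions = regions or RegionSpec()
    atoms = ("N", "CA", "C", "O")
    if reference is None:
        reference = average_structure(ensemble, atoms=atoms)

    # build per-region row masks of the full backbone selection
    topo = ensemble.topology
    rows = []
    for chain in topo.chains:
        for ri in range(len(chain)):
            for a in range(4):
                if not np.isnan(chain.coords[ri, a]).any():
                    rows.append(int(chain.resnums[ri]))
    rows = np.asarray(rows)

    report: dict[str, tuple[float, float]] = {}
    per_frame: dict[str, list[float]] = {name: [] for name in regions.named()}
    per_frame["overall"] = []
    for frame in ensemble.frames:
        coords = frame.coord_array(atoms=atoms)
        fit = superpose(coords, reference)
        fitted = fit.apply(coords)
        sq = np.sum((fitted - reference) ** 2, axis=1)
        per_frame["overall"].append(float(np.sqrt(sq.mean())))
        for name, (lo, hi) in regions.named().items():
            mask = (rows >= lo) & (rows <= hi)
            per_frame[name].append(float(np.sqrt(sq[mask].mean())))
    for name, values in per_frame.items():
        arr = np.asarray(values)
        report[name] = (float(arr.mean()), float(arr.std()))
    return report


def overall_rmsd(
    ensemble: ConformerEnsemble, reference: np.ndarray | None = None
) -> tuple[np.ndarray, float, float]:
    """Full-backbone per-frame RMSD against the ensemble average."""
    atoms = ("N", "CA", "C", "O")
    if reference is None:
        reference = average_structure(ensemble, atoms=atoms)
    return ensemble_rmsd(ensemble, reference, atoms=atoms)
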