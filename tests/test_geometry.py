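"""Geometric engine: dihedrals, H-bonds, superposition, averaging."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from silkspacer.exceptions import GeometryError
from silkspacer.geometry import (
    HBond,
    average_structure,
    detect_hbonds,
    dihedral,
    ensemble_rmsd,
    kabsch_sander_energy,
    superpose,
)
from silkspacer.structures import ConformerEnsemble
from silkspacer.synthetic import build_backbone, uniform_dihedrals
from tests.conftest import random_dihedrals


def oracle_dihedral(p0, p1, p2, p3):
    """Independent dihedral formula: atan2 on explicit plane normals."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(b2 / np.linalg.norm(b2), n1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def oracle_ks_energy(n, h, c, o):
    """Scalar Kabsch–Sander electrostatic energy, written independently."""
    def d(a, b):
        return math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))
    return 0.084 * 332.0 * (1 / d(o, n) + 1 / d(c, h) - 1 / d(o, h) - 1 / d(c, n))


class TestDihedral:
    def test_matches_independent_oracle_on_random_points(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                got = float(dihedral(*pts))
            except GeometryError:
                continue
            want = oracle_dihedral(*pts)
            if want <= -180.0:
                want += 360.0
            assert got == pytest.approx(want, abs=1e-9)

    def test_collinear_atoms_are_rejected(self):
        pts = [np.array([float(i), 0.0, 0.0]) for i in range(4)]
        with pytest.raises(GeometryError):
            dihedral(*pts)

    def test_range_half_open(self):
        # a planar trans arrangement gives exactly +180, never -180
        p = [np.array(v, float) for v in
             [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]]]
        assert float(dihedral(*p)) == 180.0


class TestHBonds:
    def test_alpha_helix_donates_i_to_i4_only(self):
        s = build_backbone("A" * 12, uniform_dihedrals(12, -57.0, -47.0))
        bonds = detect_hbonds(s)
        offsets = {b.pattern_offset for b in bonds}
        assert offsets == {4}
        donors = {b.donor[1] for b in bonds}
        # every interior residue past the first turn donates to i-4
        assert donors == set(range(5, 13))

    def test_extended_strand_has_no_intra_chain_bonds(self):
        s = build_backbone("A" * 10, uniform_dihedrals(10, 180.0, 180.0))
        assert detect_hbonds(s) == []

    def test_310_helix_forms_i_to_i3_bonds(self):
        s = build_backbone("A" * 10, uniform_dihedrals(10, -70.0, -25.0))
        bonds = detect_hbonds(s)
        assert bonds and all(b.pattern_offset == 3 for b in bonds)
        assert all(b.h_o_distance <= 2.5 for b in bonds)

    def test_energy_matches_scalar_oracle(self, rng):
        for _ in range(100):
            n, h, c, o = rng.normal(size=(4, 3)) * 2 + 5
            got = float(kabsch_sander_energy(n, h, c, o))
            assert got == pytest.approx(oracle_ks_energy(n, h, c, o), abs=1e-9)

    def test_detection_invariant_under_rigid_transforms(self, rng):
        s = build_backbone("A" * 10, uniform_dihedrals(10, -70.0, -25.0))
        ref = [(b.donor, b.acceptor, round(b.h_o_distance, 9))
               for b in detect_hbonds(s)]
        rot = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        moved = s.transformed(rot, np.array([10.0, -4.0, 2.0]))
        got = [(b.donor, b.acceptor, round(b.h_o_distance, 9))
               for b in detect_hbonds(moved)]
        assert got == ref

    def test_matches_exhaustive_pairwise_evaluation(self):
        """Strict-criterion bonds equal a literal re-evaluation of every
        donor/acceptor pair (best-energy bond kept per donor)."""
        s = build_backbone("A" * 12, uniform_dihedrals(12, -57.0, -47.0))
        chain = s.chains[0]
        N, H, C, O = (chain.atom(a) for a in ("N", "CA", "C", "O"))
        H = chain.atom("H")
        C, O = chain.atom("C"), chain.atom("O")
        expected = {}
        for di in range(1, 12):  # donors (have H)
            best = None
            for ai in range(12):
                if abs(di - ai) < 2:
                    continue
                e = oracle_ks_energy(N[di], H[di], C[ai], O[ai])
                d_oh = float(np.linalg.norm(H[di] - O[ai]))
                v1, v2 = N[di] - H[di], O[ai] - H[di]
                ang = math.degrees(math.acos(
                    np.clip(np.dot(v1, v2)
                            / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
                ))
                if e <= -0.5 and d_oh <= 2.5 and ang >= 120.0:
                    if best is None or e < best[1]:
                        best = (ai, e)
            if best is not None:
                expected[di + 1] = best[0] + 1  # residue numbers
        got = {b.donor[1]: b.acceptor[1] for b in detect_hbonds(s)}
        assert got == expected


class TestSuperpose:
    def test_identity_on_equal_inputs(self, rng):
        x = rng.normal(size=(20, 3))
        res = superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_rigid_copy(self, rng):
        x = rng.normal(size=(15, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ rot.T + np.array([3.0, -1.0, 7.0])
        assert superpose(y, x).rmsd == pytest.approx(0.0, abs=1e-9)

    def test_proper_rotation_even_for_reflected_clouds(self, rng):
        x = rng.normal(size=(10, 3))
        y = x.copy()
        y[:, 2] *= -1  # mirror image: optimal orthogonal map is improper
        res = superpose(y, x)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_fitted_rmsd_never_exceeds_unfitted(self, rng):
        for _ in range(50):
            x = rng.normal(size=(12, 3)) * 4
            y = x + rng.normal(size=(12, 3))
            unfitted = float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
            assert superpose(x, y).rmsd <= unfitted + 1e-12

    def test_matches_independent_kabsch_oracle(self, rng):
        for _ in range(20):
            ref = rng.normal(size=(10, 3)) * 3
            mob = ref + rng.normal(size=(10, 3)) * 0.7
            got = superpose(mob, ref).rmsd
            _, want = Rotation.align_vectors(
                ref - ref.mean(0), mob - mob.mean(0)
            )
            # align_vectors rssd -> rmsd
            assert got == pytest.approx(want / math.sqrt(10), abs=1e-9)

    def test_degenerate_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            superpose(line, line)
        with pytest.raises(GeometryError):
            superpose(line[:2], line[:2])


class TestAverageAndRMSD:
    def _ensemble_of(self, frames):
        return ConformerEnsemble(frames=frames)

    def test_identical_frames_average_to_the_frame(self, masp1_strand):
        ens = self._ensemble_of([masp1_strand, masp1_strand])
        mean = average_structure(ens)
        assert np.allclose(mean, masp1_strand.coord_array(), atol=1e-9)

    def test_average_invariant_under_rigid_pretransforms(self, masp1_strand, rng):
        frames = []
        for _ in range(4):
            rot = Rotation.random(rng=np.random.default_rng(int(rng.integers(1e6)))).as_matrix()
            frames.append(masp1_strand.transformed(rot, rng.normal(size=3) * 5))
        mean_a = average_structure(self._ensemble_of(frames))
        mean_b = average_structure(self._ensemble_of([masp1_strand] * 2))
        assert superpose(mean_a, mean_b).rmsd == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_perturbation_cancels(self, masp1_strand, rng):
        # displacement field orthogonal to rigid modes (zero net shift
        # and zero net torque), so +delta and -delta average back to the
        # template under superposition-based averaging
        coords = masp1_strand.chains[0].coords
        flat = coords.reshape(-1, 3)
        valid = ~np.isnan(flat).any(axis=1)
        delta = rng.normal(size=flat.shape) * 0.002
        delta[~valid] = 0.0
        delta[valid] -= delta[valid].mean(axis=0)
        r = np.zeros_like(flat)
        r[valid] = flat[valid] - flat[valid].mean(axis=0)
        for k in range(3):  # project out infinitesimal rotations
            b = np.cross(np.eye(3)[k], r).ravel()
            b /= np.linalg.norm(b)
            delta = (delta.ravel() - (delta.ravel() @ b) * b).reshape(flat.shape)
        delta = delta.reshape(coords.shape)
        plus = masp1_strand.transformed(np.eye(3), np.zeros(3))
        minus = masp1_strand.transformed(np.eye(3), np.zeros(3))
        plus.chains[0].coords = coords + delta
        minus.chains[0].coords = coords - delta
        mean = average_structure(self._ensemble_of([plus, minus]))
        assert superpose(
            mean, masp1_strand.coord_array()
        ).rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rmsd_zero_for_reference_frames(self, masp1_strand):
        ens = self._ensemble_of([masp1_strand, masp1_strand])
        values, mean, sd = ensemble_rmsd(ens, masp1_strand.coord_array())
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)
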