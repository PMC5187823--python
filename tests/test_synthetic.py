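"""Synthetic generator: chain building, fibril assembly, sampling, ladders."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from silkspacer.exceptions import ConfigError, ConstructionError, InputError
from silkspacer.geometry import compute_dihedrals, superpose
from silkspacer.synthetic import (
    AA_EXTRA_TEMPERATURES,
    COMMON_TEMPERATURES,
    IDEAL_GEOMETRY,
    MASP1_SEQUENCE,
    FibrilSpec,
    build_backbone,
    build_fibril,
    ground_truth_fraction,
    make_library,
    parse_replica_ladder,
    sample_ensemble,
    uniform_dihedrals,
)
from tests.conftest import random_dihedrals


def oracle_chain_ca(dihedrals):
    """Independent poly-Ala CA trace built by serial rotation matrices.

    Walks the backbone N->CA->C->N'... composing explicit axis-angle
    rotations (scipy) instead of the NeRF local frame, as a cross-check.
    """
    g = IDEAL_GEOMETRY
    bonds = {0: g.c_n, 1: g.n_ca, 2: g.ca_c}      # bond ending at N, CA, C
    angles = {0: g.ang_ca_c_n, 1: g.ang_c_n_ca, 2: g.ang_n_ca_c}
    n = len(dihedrals)
    tor = {}
    for i in range(n):
        phi, psi, omega = dihedrals[i]
        tor[3 * i] = phi if np.isfinite(phi) else 0.0        # places C(i)
        tor[3 * i + 1] = psi if np.isfinite(psi) else 0.0    # places N(i+1)
        tor[3 * i + 2] = omega if np.isfinite(omega) else 180.0  # places CA(i)
    pts = [np.zeros(3), np.array([g.n_ca, 0.0, 0.0])]
    d0 = Rotation.from_rotvec(
        np.radians(180 - g.ang_n_ca_c) * np.array([0.0, 0.0, 1.0])
    ).apply([1.0, 0.0, 0.0])
    pts.append(pts[-1] + g.ca_c * d0)
    for k in range(3, 3 * n):
        m = k % 3
        t = tor[k + 1] if m == 1 else tor[k - 2]
        prev = pts[-1] - pts[-2]
        prev /= np.linalg.norm(prev)
        nrm = np.cross(pts[-2] - pts[-3], pts[-1] - pts[-2])
        nrm /= np.linalg.norm(nrm)
        d = Rotation.from_rotvec(np.radians(180 - angles[m]) * nrm).apply(prev)
        d = Rotation.from_rotvec(np.radians(t) * prev).apply(d)
        pts.append(pts[-1] + bonds[m] * d)
    return np.array(pts)[1::3]  # CA atoms


class TestBuildBackbone:
    def test_pgii_chain_round_trips_exactly(self):
        d = uniform_dihedrals(30, -90.0, 150.0)
        s = build_backbone("AGG" * 10, d)
        back = compute_dihedrals(s)[0]
        assert np.nanmax(np.abs(back - d)) < 1e-6

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_round_trip_property_over_random_specs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        d = random_dihedrals(rng, n)
        s = build_backbone("A" * n, d)
        back = compute_dihedrals(s)[0]
        assert np.nanmax(np.abs(back - d)) < 1e-6

    def test_masp1_sequence_has_51_residues(self, masp1_strand):
        printed = "GQGAGAAAAA-AGGAGQGGYG-GLGSQGAGRG-GLGGQGAGAA-AAAAAGGAGQ-G"
        assert MASP1_SEQUENCE == printed.replace("-", "")
        assert len(masp1_strand.chains[0]) == 51
        assert masp1_strand.chains[0].resnums[0] == 71
        assert masp1_strand.chains[0].resnums[-1] == 121

    def test_alpha_helix_rise_matches_independent_construction(self):
        d = uniform_dihedrals(12, -57.0, -47.0)
        s = build_backbone("A" * 12, d)
        ca = s.chains[0].atom("CA")
        rise = np.linalg.norm(ca[-1] - ca[0]) / 11
        assert rise == pytest.approx(1.5, abs=0.1)
        oracle = oracle_chain_ca(d)
        assert superpose(ca, oracle).rmsd == pytest.approx(0.0, abs=1e-6)

    def test_bonded_geometry_within_ideal_tolerances(self, masp1_strand):
        c = masp1_strand.chains[0]
        n_ca = np.linalg.norm(c.atom("CA") - c.atom("N"), axis=1)
        ca_c = np.linalg.norm(c.atom("C") - c.atom("CA"), axis=1)
        c_n = np.linalg.norm(c.atom("N")[1:] - c.atom("C")[:-1], axis=1)
        assert np.allclose(n_ca, 1.458, atol=1e-6)
        assert np.allclose(ca_c, 1.525, atol=1e-6)
        assert np.allclose(c_n, 1.329, atol=1e-6)

    def test_unknown_residue_code_rejected(self):
        with pytest.raises(InputError):
            build_backbone("AXZ", uniform_dihedrals(3, -90, 150))

    def test_non_finite_angle_rejected(self):
        d = uniform_dihedrals(5, -90, 150)
        d[2, 0] = np.inf
        with pytest.raises(InputError):
            build_backbone("A" * 5, d)


class TestBuildFibril:
    def test_ap_fibril_has_15_chains(self):
        fib = build_fibril(FibrilSpec())
        assert fib.n_chains == 15
        assert all(c.sequence == MASP1_SEQUENCE for c in fib.chains)

    def test_single_strand_spec_equals_plain_build(self, masp1_strand):
        fib = build_fibril(FibrilSpec(1, 1))
        assert fib.n_chains == 1
        # identical up to the canonical rigid placement
        assert superpose(
            fib.coord_array(), masp1_strand.coord_array()
        ).rmsd == pytest.approx(0.0, abs=1e-6)

    def test_neighbour_strands_are_antiparallel(self):
        fib = build_fibril(
            FibrilSpec(1, 2), "A" * 10, uniform_dihedrals(10, -135, 135),
            first_resnum=1,
        )
        d0 = fib.chains[0].atom("CA")[-1] - fib.chains[0].atom("CA")[0]
        d1 = fib.chains[1].atom("CA")[-1] - fib.chains[1].atom("CA")[0]
        assert np.dot(d0, d1) < 0

    def test_orientation_pattern_follows_spec(self):
        ap = FibrilSpec(3, 5, "parallel")
        aa = FibrilSpec(3, 5, "antiparallel")
        assert ap.strand_direction(0, 0) == ap.strand_direction(1, 0)
        assert aa.strand_direction(0, 0) == -aa.strand_direction(1, 0)
        assert ap.strand_direction(0, 0) == -ap.strand_direction(0, 1)

    def test_too_small_spacing_raises_construction_error(self):
        with pytest.raises(ConstructionError):
            build_fibril(
                FibrilSpec(1, 2, inter_strand_spacing=1.0),
                "A" * 10, uniform_dihedrals(10, -135, 135), first_resnum=1,
            )


class TestSampleEnsemble:
    def test_zero_sigma_single_state_is_exact(self, masp1_strand):
        lib = make_library({"pgii": 1.0}, sigma=0.0)
        ens = sample_ensemble(masp1_strand, lib, n_frames=3, seed=0)
        for frame in ens.frames:
            d = compute_dihedrals(frame)[0]
            idx = (frame.chains[0].resnums >= 82) & (frame.chains[0].resnums <= 107)
            assert np.allclose(d[idx, 0], -90.0, atol=1e-6)
            assert np.allclose(d[idx, 1], 150.0, atol=1e-6)

    def test_identical_seed_is_bitwise_reproducible(self, masp1_strand):
        lib = make_library({"310R": 0.3, "coil": 0.7}, sigma=8.0)
        a = sample_ensemble(masp1_strand, lib, n_frames=5, seed=77)
        b = sample_ensemble(masp1_strand, lib, n_frames=5, seed=77)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(
                fa.chains[0].coords, fb.chains[0].coords, equal_nan=True
            )
        assert a.state_labels == b.state_labels

    def test_independent_mode_matches_binomial_occupancy(self, masp1_strand):
        p = 0.2
        n_frames = 500
        lib = make_library({"pgii": p, "coil": 1 - p}, sigma=5.0)
        ens = sample_ensemble(
            masp1_strand, lib, n_frames=n_frames, seed=3, mode="independent"
        )
        frac = ground_truth_fraction(ens, "pgii")
        n = n_frames * 26
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_segment_mode_preserves_marginal_occupancy(self, masp1_strand):
        p = 0.2
        lib = make_library({"310R": p, "coil": 1 - p}, sigma=5.0)
        ens = sample_ensemble(masp1_strand, lib, n_frames=500, seed=3)
        frac = ground_truth_fraction(ens, "310R")
        # run length 3 inflates the variance threefold (design effect)
        n_eff = 500 * 26 / 3
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n_eff)

    def test_310_state_mean_phi_near_minus70(self, masp1_strand):
        lib = make_library({"310R": 1.0}, sigma=10.0)
        ens = sample_ensemble(masp1_strand, lib, n_frames=50, seed=4)
        phis = []
        for frame, labels in zip(ens.frames, ens.state_labels):
            d = compute_dihedrals(frame)[0]
            for i, lab in enumerate(labels[0]):
                if lab == "310R" and np.isfinite(d[i, 0]):
                    phis.append(d[i, 0])
        se = 10.0 / np.sqrt(len(phis))
        assert abs(np.mean(phis) - (-70.0)) < 3 * se

    def test_bad_occupancies_rejected(self, masp1_strand):
        with pytest.raises(InputError):
            make_library({"pgii": 0.5, "coil": 0.6})

    def test_region_outside_numbering_rejected(self, masp1_strand):
        lib = make_library({"coil": 1.0})
        with pytest.raises(InputError):
            sample_ensemble(masp1_strand, lib, region=(300, 320), n_frames=1)


class TestReplicaLadder:
    def test_packaged_ap_and_aa_ladders_have_44_temperatures(self):
        assert len(parse_replica_ladder(system="AP")) == 44
        assert len(parse_replica_ladder(system="AA")) == 44

    def test_common_list_alone_has_37(self):
        ladder = parse_replica_ladder({"common": list(COMMON_TEMPERATURES)}, "AP")
        assert len(ladder) == 37
        assert ladder.temperatures[0] == 300.0
        assert ladder.temperatures[-1] == 380.0

    def test_ladder_strictly_increasing(self):
        t = parse_replica_ladder(system="AA").temperatures
        assert all(b > a for a, b in zip(t, t[1:]))

    def test_empty_list_is_config_error(self):
        with pytest.raises(ConfigError):
            parse_replica_ladder({"common": []}, "AP")

    def test_duplicate_temperature_is_config_error(self):
        cfg = {"common": list(COMMON_TEMPERATURES),
               "ap_extra": [300.0]}
        with pytest.raises(ConfigError):
            parse_replica_ladder(cfg, "AP")
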