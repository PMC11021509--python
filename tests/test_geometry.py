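"""Rg, block averaging, Kabsch superposition, average structure, RMSF."""

import numpy as np
import pytest

from dnajconf import (
    Structure,
    Trajectory,
    average_structure,
    block_average,
    disorder_fraction,
    kabsch_superpose,
    radius_of_gyration,
    rg_series,
    rmsf,
)
from dnajconf.errors import DnajconfError
from dnajconf.geometry import ATOMIC_MASSES, apply_transform

from conftest import kabsch_oracle, random_rigid_transform, random_structure


def _cloud(rng, n=100, elements=("C", "N", "O", "S")):
    return Structure(
        serials=np.arange(1, n + 1),
        names=["CA"] * n,
        elements=list(rng.choice(elements, size=n)),
        residue_indices=1 + np.arange(n) // 4,
        residue_codes=["A"] * n,
        coords=rng.normal(0, 10, size=(n, 3)),
    )


class TestRadiusOfGyration:
    def test_point_mass_is_zero(self):
        s = random_structure(np.random.default_rng(0), 1)
        assert radius_of_gyration(s) == pytest.approx(0.0, abs=1e-9)

    def test_two_equal_masses_two_angstrom_apart(self):
        s = Structure([1, 2], ["CA", "CA"], ["C", "C"], [1, 2], ["A", "A"],
                      np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert radius_of_gyration(s) == pytest.approx(1.0, abs=1e-12)

    def test_unit_square_of_carbons(self):
        coords = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        s = Structure([1, 2, 3, 4], ["CA"] * 4, ["C"] * 4, [1, 2, 3, 4],
                      ["A"] * 4, coords)
        assert radius_of_gyration(s) == pytest.approx(np.sqrt(2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = _cloud(rng)
        masses = np.array([ATOMIC_MASSES[e] for e in s.elements])
        com = (masses[:, None] * s.coords).sum(0) / masses.sum()
        expected = np.sqrt(
            float(sum(m * ((x - com) ** 2).sum() for m, x in zip(masses, s.coords)))
            / masses.sum()
        )
        assert radius_of_gyration(s) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = _cloud(rng)
        R, t = random_rigid_transform(rng)
        moved = apply_transform(s, R, t)
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(s), rel=1e-9
        )

    def test_against_mdanalysis(self):
        """Cross-check the mass-weighted Rg against MDAnalysis."""
        mda = pytest.importorskip("MDAnalysis")
        rng = np.random.default_rng(42)
        s = _cloud(rng, n=60)
        u = mda.Universe.empty(60, trajectory=True)
        u.atoms.positions = s.coords.astype(np.float32)
        u.add_TopologyAttr("masses", [ATOMIC_MASSES[e] for e in s.elements])
        assert radius_of_gyration(s) == pytest.approx(
            float(u.atoms.radius_of_gyration()), rel=1e-5
        )

    def test_empty_structure_rejected(self):
        s = Structure([], [], [], [], [], np.zeros((0, 3)))
        with pytest.raises(DnajconfError):
            radius_of_gyration(s)


class TestBlockAverage:
    def test_pairwise_blocks(self):
        np.testing.assert_allclose(block_average([1, 2, 3, 4], 2), [1.5, 3.5])

    def test_block_one_is_identity(self):
        x = [0.5, 1.5, -2.0]
        np.testing.assert_allclose(block_average(x, 1), x)

    def test_trailing_partial_block(self):
        np.testing.assert_allclose(block_average([1, 2, 3], 2), [1.5, 3.0])

    @pytest.mark.parametrize("block", [1, 2, 5, 10])
    def test_mean_preserved_on_divisible_lengths(self, block):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        assert block_average(x, block).mean() == pytest.approx(x.mean(), rel=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(DnajconfError, match="empty"):
            block_average([], 2)


def _backbone_structure(rng, n_res=20):
    atoms_per = 4
    coords = rng.normal(0, 8, size=(n_res * atoms_per, 3))
    return Structure(
        serials=np.arange(1, n_res * atoms_per + 1),
        names=["N", "CA", "C", "O"] * n_res,
        elements=["N", "C", "C", "O"] * n_res,
        residue_indices=np.repeat(np.arange(1, n_res + 1), atoms_per),
        residue_codes=["A"] * (n_res * atoms_per),
        coords=coords,
    )


class TestKabsch:
    def test_identical_structures(self):
        rng = np.random.default_rng(1)
        s = _backbone_structure(rng)
        R, t, rmsd = kabsch_superpose(s, s)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-8)

    def test_recovers_known_rotation_translation(self):
        rng = np.random.default_rng(2)
        s = _backbone_structure(rng)
        theta = np.pi / 2
        R_true = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        t_true = np.array([5.0, -3.0, 12.0])
        moved = apply_transform(s, R_true, t_true)
        R, t, rmsd = kabsch_superpose(s, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, R_true, atol=1e-8)
        np.testing.assert_allclose(t, t_true, atol=1e-7)

    def test_mirror_image_keeps_proper_rotation(self):
        rng = np.random.default_rng(3)
        s = _backbone_structure(rng)
        mirrored = s.with_coords(s.coords * np.array([-1.0, 1.0, 1.0]))
        R, t, rmsd = kabsch_superpose(s, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1
        # matches the independent SVD-with-sign-correction oracle
        R_o, t_o = kabsch_oracle(s.coords, mirrored.coords)
        aligned = s.coords @ R_o.T + t_o
        expected = np.sqrt(((aligned - mirrored.coords) ** 2).sum(1).mean())
        assert rmsd == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = _backbone_structure(rng)
        b = a.with_coords(a.coords + rng.normal(0, 1.0, a.coords.shape))
        R, t, rmsd = kabsch_superpose(a, b)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        R_o, t_o = kabsch_oracle(a.coords, b.coords)
        aligned = a.coords @ R_o.T + t_o
        expected = np.sqrt(((aligned - b.coords) ** 2).sum(1).mean())
        assert rmsd == pytest.approx(expected, rel=1e-9)
        # superposition never increases the RMSD
        raw = np.sqrt(((a.coords - b.coords) ** 2).sum(1).mean())
        assert rmsd <= raw + 1e-12

    def test_too_few_atoms_rejected(self):
        s = Structure([1, 2], ["CA", "CA"], ["C", "C"], [1, 2], ["A", "A"],
                      np.array([[0.0, 0, 0], [3.8, 0, 0]]))
        with pytest.raises(DnajconfError, match="at least 3"):
            kabsch_superpose(s, s, selection={"CA"})

    def test_collinear_selection_rejected(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        s = Structure([1, 2, 3, 4], ["CA"] * 4, ["C"] * 4, [1, 2, 3, 4],
                      ["A"] * 4, coords)
        with pytest.raises(DnajconfError, match="collinear"):
            kabsch_superpose(s, s, selection={"CA"})


class TestAverageStructure:
    def test_static_trajectory(self):
        rng = np.random.default_rng(4)
        s = _backbone_structure(rng)
        avg = average_structure(Trajectory([s, s, s]))
        np.testing.assert_allclose(avg.coords, s.coords, atol=1e-9)

    def test_single_frame(self):
        rng = np.random.default_rng(5)
        s = _backbone_structure(rng)
        avg = average_structure(Trajectory([s]))
        np.testing.assert_allclose(avg.coords, s.coords, atol=1e-9)

    def test_rigid_transform_frames_average_to_original(self):
        rng = np.random.default_rng(6)
        s = _backbone_structure(rng)
        frames = [s]
        for _ in range(3):
            R, t = random_rigid_transform(rng)
            frames.append(apply_transform(s, R, t))
        avg = average_structure(Trajectory(frames))
        _, _, rmsd = kabsch_superpose(avg, s)
        assert rmsd == pytest.approx(0.0, abs=1e-6)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        rng = np.random.default_rng(7)
        s = _backbone_structure(rng)
        profile = rmsf(Trajectory([s, s, s]), reference=s)
        np.testing.assert_allclose(profile.values, 0.0, atol=1e-12)

    def test_rigid_transform_frames_are_zero(self):
        rng = np.random.default_rng(8)
        s = _backbone_structure(rng)
        frames = [s]
        for _ in range(4):
            R, t = random_rigid_transform(rng)
            frames.append(apply_transform(s, R, t))
        profile = rmsf(Trajectory(frames), reference=s)
        np.testing.assert_allclose(profile.values, 0.0, atol=1e-8)

    def test_single_displaced_atom_gives_half_displacement(self):
        # many atoms spread widely, so superposition stays ~identity
        rng = np.random.default_rng(9)
        s = _backbone_structure(rng, n_res=60)
        d = 0.5
        coords2 = s.coords.copy()
        coords2[5] += [d, 0.0, 0.0]  # a CA of residue 2
        traj = Trajectory([s, s.with_coords(coords2)])
        profile = rmsf(traj, reference=s)
        # residue 2 holds 4 backbone atoms; only one moved: residue RMSF
        # is the RMS over atoms of per-atom values (d/2 for the moved one)
        assert profile.value_at(2) == pytest.approx((d / 2) / 2, abs=0.01)
        assert profile.value_at(40) == pytest.approx(0.0, abs=0.01)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(10)
        base = _backbone_structure(rng, n_res=15)
        frames = [
            base.with_coords(base.coords + rng.normal(0, 0.3, base.coords.shape))
            for _ in range(6)
        ]
        traj = Trajectory(frames)
        profile = rmsf(traj, reference=base)
        # oracle: same definition, from scratch with the oracle Kabsch
        sel = np.array([n in {"N", "CA", "C", "O"} for n in base.names])
        aligned = []
        for f in frames:
            R, t = kabsch_oracle(f.coords[sel], base.coords[sel])
            aligned.append(f.coords[sel] @ R.T + t)
        aligned = np.array(aligned)
        mean_pos = aligned.mean(0)
        msd = ((aligned - mean_pos) ** 2).sum(2).mean(0)
        res = base.residue_indices[sel]
        for r in np.unique(res):
            expected = np.sqrt(msd[res == r].mean())
            assert profile.value_at(int(r)) == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_frame_permutation(self):
        rng = np.random.default_rng(11)
        base = _backbone_structure(rng, n_res=10)
        frames = [
            base.with_coords(base.coords + rng.normal(0, 0.2, base.coords.shape))
            for _ in range(5)
        ]
        p1 = rmsf(Trajectory(frames), reference=base)
        p2 = rmsf(Trajectory(frames[::-1]), reference=base)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-12)


class TestDisorderFraction:
    def test_all_helix_is_ordered(self):
        assert disorder_fraction("HHHHH") == (1.0, 0.0)

    def test_coil_and_turn_are_disordered(self):
        assert disorder_fraction("CCTTC") == (0.0, 1.0)

    def test_mixed_fractions(self):
        ordered, disordered = disorder_fraction("HCHCT")
        assert ordered == pytest.approx(0.4)
        assert disordered == pytest.approx(0.6)

    def test_region_slicing(self):
        ordered, _ = disorder_fraction("HHCC", region=(3, 4), first_residue=1)
        assert ordered == 0.0

    def test_unknown_letter_rejected(self):
        with pytest.raises(DnajconfError, match="unknown"):
            disorder_fraction("HHXH")


class TestRgSeries:
    def test_ordering_of_synthetic_states(self, small_trajectory):
        """Compactness ordering closed < open < extended, as designed."""
        rg = rg_series(small_trajectory)
        closed, open_, ext = rg[:3].mean(), rg[3:6].mean(), rg[6:].mean()
        assert closed < open_ < ext
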