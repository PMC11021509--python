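"""Contact detection, persistence maps, profiles and the G/F boundary."""

import numpy as np
import pytest

from dnajconf import (
    ContactProfile1D,
    Trajectory,
    contact_profile,
    frame_contacts,
    gf_boundary,
    interdomain_count,
    pair_frequency,
    persistence_map,
)
from dnajconf.contacts import ContactSet
from dnajconf.errors import ContactError

from conftest import naive_contacts, random_structure, structure_from_points


class TestFrameContacts:
    def test_pair_within_cutoff_detected(self):
        s = structure_from_points({10: (0, 0, 0), 20: (3.9, 0, 0)})
        assert (10, 20) in frame_contacts(s).pairs

    def test_cutoff_is_inclusive(self):
        s = structure_from_points({10: (0, 0, 0), 20: (4.0, 0, 0)})
        assert (10, 20) in frame_contacts(s).pairs
        s = structure_from_points({10: (0, 0, 0), 20: (4.0001, 0, 0)})
        assert (10, 20) not in frame_contacts(s).pairs

    def test_sequence_neighbours_excluded(self):
        # residues i+1 .. i+3 never count, however close
        s = structure_from_points({10: (0, 0, 0), 12: (3.0, 0, 0)})
        assert len(frame_contacts(s).pairs) == 0
        s = structure_from_points({10: (0, 0, 0), 14: (3.0, 0, 0)})
        assert (10, 14) in frame_contacts(s).pairs

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, n_atoms=int(rng.integers(100, 300)))
        assert frame_contacts(s).pairs == naive_contacts(s)

    def test_empty_structure_rejected(self):
        s = structure_from_points({})
        with pytest.raises(ContactError, match="empty"):
            frame_contacts(s)

    def test_hydrogens_rejected(self):
        s = structure_from_points({1: (0, 0, 0), 5: (3, 0, 0)}, element="H")
        with pytest.raises(ContactError, match="hydrogen"):
            frame_contacts(s)


def _two_residue_frames(distances):
    """Frames of two single-atom residues (10, 20) at given separations."""
    return Trajectory(
        [structure_from_points({10: (0, 0, 0), 20: (d, 0, 0)}) for d in distances]
    )


class TestPersistenceMap:
    def test_quarter_occupancy(self):
        traj = _two_residue_frames([3.0, 10.0, 10.0, 10.0])
        assert persistence_map(traj).entry(10, 20) == 25.0

    def test_full_occupancy(self):
        traj = _two_residue_frames([3.0, 3.5, 2.0])
        assert persistence_map(traj).entry(10, 20) == 100.0

    def test_equals_mean_of_frame_indicators(self):
        rng = np.random.default_rng(7)
        frames = [random_structure(rng, 90) for _ in range(10)]
        traj = Trajectory(frames)
        pmap = persistence_map(traj)
        # recompute via an explicit frame_contacts loop
        residues = list(traj[0].residue_numbers())
        idx = {r: k for k, r in enumerate(residues)}
        expected = np.zeros((len(residues), len(residues)))
        for frame in frames:
            for i, j in naive_contacts(frame):
                expected[idx[i], idx[j]] += 1
                expected[idx[j], idx[i]] += 1
        np.testing.assert_allclose(pmap.values, 100.0 * expected / 10)

    def test_symmetric_with_zero_band(self, small_trajectory):
        pmap = persistence_map(small_trajectory)
        np.testing.assert_array_equal(pmap.values, pmap.values.T)
        res = pmap.residues
        for k, i in enumerate(res):
            near = np.abs(res - i) <= 3
            assert np.all(pmap.values[k, near] == 0.0)

    def test_invariant_under_frame_reordering(self):
        rng = np.random.default_rng(11)
        frames = [random_structure(rng, 60) for _ in range(6)]
        fwd = persistence_map(Trajectory(frames))
        rev = persistence_map(Trajectory(frames[::-1]))
        np.testing.assert_array_equal(fwd.values, rev.values)


class TestInterdomainCount:
    GF1 = (75, 108)
    CTD = (189, 241)

    def test_enumeration_example(self):
        cs = ContactSet(0, frozenset({(80, 200), (80, 210), (15, 120)}))
        assert interdomain_count(cs, self.GF1, self.CTD) == 2

    def test_empty_set(self):
        assert interdomain_count(ContactSet(0, frozenset()), self.GF1, self.CTD) == 0

    def test_overlapping_regions_rejected(self):
        cs = ContactSet(0, frozenset())
        with pytest.raises(ContactError, match="overlap"):
            interdomain_count(cs, (1, 100), (50, 150))

    def test_matches_set_comprehension_oracle(self):
        rng = np.random.default_rng(3)
        pairs = set()
        while len(pairs) < 200:
            i, j = sorted(rng.integers(1, 242, size=2))
            if j - i >= 4:
                pairs.add((int(i), int(j)))
        cs = ContactSet(0, frozenset(pairs))
        a, b = (75, 131), (132, 188)
        expected = len(
            {p for p in pairs
             if (a[0] <= p[0] <= a[1] and b[0] <= p[1] <= b[1])
             or (b[0] <= p[0] <= b[1] and a[0] <= p[1] <= a[1])}
        )
        assert interdomain_count(cs, a, b) == expected


class TestContactProfile:
    FOCAL = (109, 131)
    PARTNER = (132, 188)

    def test_single_frame_count(self):
        frame = structure_from_points(
            {120: (0, 0, 0), 150: (3, 0, 0), 160: (0, 3, 0), 170: (20, 20, 20)}
        )
        prof = contact_profile(Trajectory([frame]), self.FOCAL, self.PARTNER)
        assert prof.value_at(120) == 2.0

    def test_mean_over_frames(self):
        near = structure_from_points({120: (0, 0, 0), 150: (3, 0, 0), 160: (0, 3, 0)})
        far = structure_from_points({120: (0, 0, 0), 150: (30, 0, 0), 160: (0, 30, 0)})
        prof = contact_profile(Trajectory([near, far]), self.FOCAL, self.PARTNER)
        assert prof.value_at(120) == 1.0

    def test_matches_per_frame_recount(self, small_trajectory, scheme):
        focal, partner = scheme.gf(), scheme.region("ST")
        prof = contact_profile(small_trajectory, focal, partner)
        totals = {r: 0 for r in range(focal[0], focal[1] + 1)}
        for frame in small_trajectory:
            for i, j in naive_contacts(frame):
                if focal[0] <= i <= focal[1] and partner[0] <= j <= partner[1]:
                    totals[i] += 1
                if focal[0] <= j <= focal[1] and partner[0] <= i <= partner[1]:
                    totals[j] += 1
        expected = np.array(
            [totals[r] for r in range(focal[0], focal[1] + 1)], dtype=float
        ) / small_trajectory.n_frames
        np.testing.assert_allclose(prof.values, expected)


def _profile(gf, values):
    return ContactProfile1D(
        residues=np.arange(gf[0], gf[1] + 1), values=np.asarray(values, float)
    )


class TestGfBoundary:
    GF = (75, 131)

    def test_idealized_split_recovered(self):
        n = self.GF[1] - self.GF[0] + 1
        pj = [1.0 if r <= 108 else 0.0 for r in range(75, 132)]
        pst = [1.0 if r >= 109 else 0.0 for r in range(75, 132)]
        assert gf_boundary(_profile(self.GF, pj), _profile(self.GF, pst), self.GF) == 109

    def test_swapped_profiles_degenerate_with_warning(self):
        pj = [0.0 if r <= 108 else 1.0 for r in range(75, 132)]
        pst = [1.0 if r <= 108 else 0.0 for r in range(75, 132)]
        with pytest.warns(UserWarning, match="degenerated"):
            b = gf_boundary(_profile(self.GF, pj), _profile(self.GF, pst), self.GF)
        assert b == self.GF[0]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_split_scan(self, seed):
        rng = np.random.default_rng(seed)
        pj = rng.uniform(0, 2, size=57)
        pst = rng.uniform(0, 2, size=57)
        best, best_val = None, -1.0
        for b in range(75, 133):
            val = pj[: b - 75].sum() + pst[b - 75 :].sum()
            if val > best_val + 1e-12:
                best, best_val = b, val
        got = gf_boundary(_profile(self.GF, pj), _profile(self.GF, pst), self.GF)
        assert got == best

    def test_flat_zero_profiles_rejected(self):
        zero = _profile(self.GF, np.zeros(57))
        with pytest.raises(ContactError, match="no boundary signal"):
            gf_boundary(zero, zero, self.GF)


class TestPairFrequency:
    def test_three_of_four_frames(self):
        traj = _two_residue_frames([3.0, 3.5, 2.0, 9.0])
        assert pair_frequency(traj, 10, 20) == 75.0

    def test_never_in_contact(self):
        traj = _two_residue_frames([9.0, 9.0])
        assert pair_frequency(traj, 10, 20) == 0.0

    def test_excluded_band_rejected(self):
        traj = _two_residue_frames([3.0])
        with pytest.raises(ContactError, match="excluded"):
            pair_frequency(traj, 10, 12)

    def test_equals_persistence_map_entry(self, small_trajectory):
        pmap = persistence_map(small_trajectory)
        for i, j in [(31, 104), (21, 125), (80, 200)]:
            assert pair_frequency(small_trajectory, i, j) == pmap.entry(i, j)
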