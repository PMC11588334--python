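"""Superposition: Kabsch oracle checks, residue mapping, profiles, symmetry."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from osmokit.structio import Structure
from osmokit.superpose import (DisplacementProfile, ResidueMapping,
                               apply_crystal_symmetry, displacement_profile,
                               find_hinge, kabsch, map_residues, rmsd_selection)

from conftest import ca_only_structure, random_rotation


def brute_force_min_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: minimize rmsd over rotation vectors + translation."""

    def cost(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        d = a @ rot.T + x[3:] - b
        return float((d ** 2).sum())

    best = np.inf
    rng = np.random.default_rng(0)
    for _ in range(24):
        x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.normal(0, 5, 3)])
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        best = min(best, res.fun)
    return float(np.sqrt(best / len(a)))


class TestKabsch:
    def test_identity(self, rng):
        a = rng.normal(size=(10, 3))
        res = kabsch(a, a)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered(self, rng):
        a = rng.normal(size=(12, 3)) * 5
        rot = random_rotation(rng)
        b = a @ rot.T + np.array([1.0, -2.0, 3.0])
        res = kabsch(a, b)
        assert res.rmsd < 1e-8
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_four_point_oracle(self):
        """Displaced-point rmsd matches an independent numerical minimizer."""
        a = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], dtype=float)
        b = a.copy()
        b[3] += [1.0, -0.5, 0.8]
        expected = brute_force_min_rmsd(a, b)
        assert kabsch(a, b).rmsd == pytest.approx(expected, abs=1e-6)

    def test_symmetry_and_invariance(self, rng):
        a = rng.normal(size=(8, 3)) * 4
        b = a + rng.normal(size=(8, 3)) * 0.5
        r_ab, r_ba = kabsch(a, b).rmsd, kabsch(b, a).rmsd
        assert r_ab == pytest.approx(r_ba, abs=1e-8)
        rot = random_rotation(rng)
        b_moved = b @ rot.T + np.array([4.0, 5.0, -6.0])
        assert kabsch(a, b_moved).rmsd == pytest.approx(r_ab, abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            kabsch(line, line)

    def test_no_reflection(self):
        a = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]], dtype=float)
        b = a.copy()
        b[:, 2] *= -1  # mirror image
        res = kabsch(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        assert res.rmsd > 0.5  # a proper rotation cannot null a reflection


class TestMapResidues:
    def test_identity_mapping(self):
        seq = [(i + 10, c) for i, c in enumerate("ACDEFGHIKL")]
        m = map_residues(seq, seq)
        assert m.source == "identity" and len(m.pairs) == 10
        assert m.pairs[0] == (10, 10)

    def test_deletion_skips_gap(self):
        # b = a with residues 5 and 6 deleted: 8 aligned pairs remain
        a = [(i + 1, c) for i, c in enumerate("ACDEFGHIKL")]
        b = [(n, c) for n, c in a if n not in (5, 6)]
        m = map_residues(a, b)
        expected = tuple((n, n) for n, _ in a if n not in (5, 6))
        assert m.pairs == expected and len(m.pairs) == 8

    def test_homolog_mapping_offset_numbering(self):
        # same fold, different numbering and one substitution: E40 <-> E28-like
        a = [(i + 30, c) for i, c in enumerate("WKEQVAELRSTW")]
        b = [(i + 4, c) for i, c in enumerate("WKDQVAELRSTW")]
        m = map_residues(a, b)
        assert m.source == "alignment"
        assert m.b_for_a(36) == 10  # L opposite L despite offset numbering
        assert len(m.pairs) == 12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            map_residues([], [(1, "A")])

    def test_monotonic_invariant_enforced(self):
        with pytest.raises(ValueError):
            ResidueMapping(((2, 1), (1, 2)), "identity")


class TestRmsdSelection:
    def make_pair(self):
        rng = np.random.default_rng(3)
        core = rng.normal(size=(12, 3)) * 4
        loop = rng.normal(size=(5, 3)) * 4 + 10
        a = np.vstack([core, loop])
        b = a.copy()
        b[12:] += [2.0, 0.0, 0.0]  # loop rigidly shifted 2 A
        return ca_only_structure(a, "a"), ca_only_structure(b, "b")

    def test_self_comparison_zero(self):
        s, _ = self.make_pair()
        m = ResidueMapping.identity(range(1, 18))
        assert rmsd_selection(s, s, m, "A", "A").rmsd == pytest.approx(0, abs=1e-12)

    def test_core_fit_loop_rmsd_matches_direct_computation(self):
        s_a, s_b = self.make_pair()
        m = ResidueMapping.identity(range(1, 18))
        core, loop = set(range(1, 13)), set(range(13, 18))
        res = rmsd_selection(s_a, s_b, m, "A", "A", selection=loop, fit_on=core)
        # core superposes exactly -> transform is identity -> loop rmsd is 2 A
        assert res.rmsd == pytest.approx(2.0, abs=1e-9)
        # and the fit_on rmsd equals plain kabsch over those pairs
        res_core = rmsd_selection(s_a, s_b, m, "A", "A", selection=core)
        assert res_core.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        s_a, s_b = self.make_pair()
        m = ResidueMapping.identity(range(1, 18))
        with pytest.raises(ValueError):
            rmsd_selection(s_a, s_b, m, "A", "A", fit_on={1, 2})


class TestDisplacementProfile:
    def test_self_profile_is_zero(self):
        rng = np.random.default_rng(5)
        s = ca_only_structure(rng.normal(size=(20, 3)) * 5, "x")
        m = ResidueMapping.identity(range(1, 21))
        prof = displacement_profile(s, s, m, "A", "A")
        assert np.all(prof.displacements == pytest.approx(0, abs=1e-12))

    def test_hinge_rotation_peaks_in_moved_helix(self):
        """10-degree hinge rotation: displacements match direct per-atom oracle."""
        rng = np.random.default_rng(8)
        coords = np.cumsum(rng.normal(0, 1.5, size=(30, 3)), axis=0)
        hinge = 18
        rot = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        moved = coords.copy()
        pivot = coords[hinge]
        moved[hinge:] = (coords[hinge:] - pivot) @ rot.T + pivot
        s_a = ca_only_structure(coords, "a")
        s_b = ca_only_structure(moved, "b")
        m = ResidueMapping.identity(range(1, 31))
        anchor = set(range(1, hinge + 1))
        prof = displacement_profile(s_a, s_b, m, "A", "A", anchor=anchor)
        # anchor superposes exactly, so displacements are the raw distances
        expected = np.linalg.norm(moved - coords, axis=1)
        assert prof.displacements == pytest.approx(expected, abs=1e-9)
        assert prof.peak()[0] > hinge

    def test_changepoint_recovers_planted_hinge(self):
        """A rigidly shifted C-terminal block starts at the recovered changepoint."""
        rng = np.random.default_rng(9)
        coords = np.cumsum(rng.normal(0, 1.5, size=(30, 3)), axis=0)
        hinge = 17
        moved = coords.copy()
        moved[hinge:] += [2.5, 0.0, 0.0]
        s_a = ca_only_structure(coords, "a")
        s_b = ca_only_structure(moved, "b")
        m = ResidueMapping.identity(range(1, 31))
        prof = displacement_profile(s_a, s_b, m, "A", "A",
                                    anchor=set(range(1, hinge + 1)))
        assert abs(find_hinge(prof) - (hinge + 1)) <= 1


class TestCrystalSymmetry:
    def p21_structure(self):
        rng = np.random.default_rng(11)
        s = ca_only_structure(rng.uniform(2, 8, size=(5, 3)), "xtal")
        s.spacegroup = "P 1 21 1"
        s.cell = (10.0, 20.0, 30.0, 90.0, 90.0, 90.0)
        return s

    @staticmethod
    def coords(s: Structure) -> np.ndarray:
        return np.array([r.atoms[0].pos for r in s.chains["A"]])

    def test_identity_operator(self):
        s = self.p21_structure()
        s2 = apply_crystal_symmetry(s, 0, (0, 0, 0))
        assert np.allclose(self.coords(s2), self.coords(s), atol=1e-10)

    def test_screw_applied_twice_is_lattice_translation(self):
        """Group closure: the 2_1 screw squared is a pure b-axis translation."""
        s = self.p21_structure()
        once = apply_crystal_symmetry(s, 1, (0, 0, 0))
        twice = apply_crystal_symmetry(once, 1, (0, 0, 0))
        shifted = apply_crystal_symmetry(s, 0, (0, 1, 0))
        assert np.allclose(self.coords(twice), self.coords(shifted), atol=1e-8)

    def test_unknown_spacegroup_rejected(self):
        s = self.p21_structure()
        s.spacegroup = ""
        with pytest.raises(ValueError):
            apply_crystal_symmetry(s, 1)
        s.spacegroup = "P 1 21 1"
        with pytest.raises(IndexError):
            apply_crystal_symmetry(s, 5)
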