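"""Conserved-water detection: projection, clustering, matching, networks."""

import numpy as np
import pytest

from osmokit.structio import Atom, Residue, Structure
from osmokit.synthdata import EnsembleSpec, make_ensemble
from osmokit.watermap import (WaterSite, build_network, cluster_waters,
                              conservation_between, project_waters,
                              site_environment)

from conftest import add_waters, ca_only_structure, random_rotation


def site(sid, num, pos):
    return WaterSite(sid, ("W", num), np.asarray(pos, dtype=float))


class TestProjectWaters:
    def test_reference_waters_unchanged(self, rng):
        s = ca_only_structure(rng.normal(size=(10, 3)) * 5, "ref")
        add_waters(s, rng.normal(size=(4, 3)) * 5)
        sites = project_waters([s], s)
        got = np.array([w.pos_ref for w in sites])
        expected = np.array([w.water_o.pos for w in s.waters])
        assert np.allclose(got, expected)

    def test_rigidly_moved_copy_projects_back(self, rng):
        coords = rng.normal(size=(12, 3)) * 5
        wpos = rng.normal(size=(5, 3)) * 5
        ref = add_waters(ca_only_structure(coords, "ref"), wpos)
        rot = random_rotation(rng)
        trans = np.array([7.0, -3.0, 11.0])
        moved = add_waters(ca_only_structure(coords @ rot.T + trans, "mov"),
                           wpos @ rot.T + trans)
        sites = project_waters([moved], ref)
        got = np.array([w.pos_ref for w in sites])
        assert np.allclose(got, wpos, atol=1e-6)

    def test_occupancy_and_bfactor_filters(self, rng):
        s = ca_only_structure(rng.normal(size=(10, 3)) * 5, "ref")
        s.waters = [
            Residue("W", 1, "HOH", [Atom("O", "O", [0, 0, 0], 1.0, 20.0)]),
            Residue("W", 2, "HOH", [Atom("O", "O", [1, 0, 0], 0.3, 20.0)]),  # low occ
            Residue("W", 3, "HOH", [Atom("O", "O", [2, 0, 0], 1.0, 95.0)]),  # high B
        ]
        sites = project_waters([s], s)
        assert [w.water_id for w in sites] == [("W", 1)]


class TestClusterWaters:
    def test_two_structures_one_cluster(self):
        sites = [site("s1", 1, [0, 0, 0]), site("s2", 1, [0.3, 0, 0])]
        clusters = cluster_waters(sites, 2.0, n_structures=2)
        assert len(clusters) == 1
        assert clusters[0].conservation == 1.0

    def test_same_structure_never_merges(self):
        sites = [site("s1", 1, [0, 0, 0]), site("s1", 2, [0.3, 0, 0])]
        clusters = cluster_waters(sites, 2.0, n_structures=1)
        assert len(clusters) == 2

    def test_partition_property(self, rng):
        sites = [site(f"s{i % 4}", i, rng.normal(size=3) * 6) for i in range(40)]
        clusters = cluster_waters(sites, 2.2, n_structures=4)
        assert sum(len(c.members) for c in clusters) == 40
        keys = sorted(m.key() for c in clusters for m in c.members)
        assert keys == sorted(s.key() for s in sites)

    def test_permutation_invariance(self, rng):
        sites = [site(f"s{i % 3}", i, rng.normal(size=3) * 4) for i in range(30)]
        ref = cluster_waters(sites, 2.2, n_structures=3)
        perm = [sites[i] for i in rng.permutation(30)]
        got = cluster_waters(perm, 2.2, n_structures=3)
        as_sets = lambda cl: sorted(tuple(sorted(m.key() for m in c.members)) for c in cl)
        assert as_sets(ref) == as_sets(got)

    def test_members_within_cutoff_of_centroid(self, rng):
        sites = [site(f"s{i % 5}", i, rng.normal(size=3) * 3) for i in range(50)]
        cutoff = 2.0
        for c in cluster_waters(sites, cutoff, n_structures=5):
            for m in c.members:
                assert np.linalg.norm(m.pos_ref - c.centroid) <= cutoff + 1e-9

    def test_planted_sites_recovered(self):
        structures, truth = make_ensemble(EnsembleSpec(seed=3))
        sites = project_waters(structures, structures[0])
        clusters = cluster_waters(sites, 2.2, len(structures))
        truth_members = {
            frozenset((sid, (w[0], w[1])) for sid, w in entry["members"].items())
            for entry in truth["sites"]
        }
        predicted = {
            frozenset((m.structure_id, m.water_id) for m in c.members)
            for c in clusters if c.conservation >= 0.8
        }
        recovered = sum(1 for t in truth_members if t in predicted)
        assert recovered >= 0.95 * len(truth_members)
        assert len(predicted) <= len(truth_members) / 0.95


class TestConservationBetween:
    def test_identical_lists_fully_retained(self, rng):
        pts = rng.normal(size=(6, 3)) * 5
        n, flags = conservation_between(pts, pts, 2.2)
        assert n == 6 and all(flags)

    def test_empty_other_side(self, rng):
        n, flags = conservation_between(rng.normal(size=(3, 3)), [], 2.2)
        assert n == 0 and flags == [False] * 3

    def test_symmetric_retained_count(self, rng):
        p = rng.normal(size=(8, 3)) * 4
        q = rng.normal(size=(6, 3)) * 4
        n_pq, _ = conservation_between(p, q, 2.5)
        n_qp, _ = conservation_between(q, p, 2.5)
        assert n_pq == n_qp

    def test_optimal_beats_greedy_pathology(self):
        # P1 close to Q1 but P2 only matches Q1: optimal assignment keeps both
        p = [[0.0, 0, 0], [1.0, 0, 0]]
        q = [[0.4, 0, 0], [-0.9, 0, 0]]
        n_opt, _ = conservation_between(p, q, 1.0)
        assert n_opt == 2
        n_greedy, _ = conservation_between(p, q, 1.0, greedy=True)
        assert n_greedy <= n_opt


class TestBuildNetwork:
    def make_clusters(self, positions):
        sites = [site("s1", i, p) for i, p in enumerate(positions)]
        return cluster_waters(sites, 0.1, n_structures=1)

    def test_collinear_chain_single_component(self):
        nets = build_network(self.make_clusters([[0, 0, 0], [2.8, 0, 0], [5.6, 0, 0]]), 3.4)
        assert len(nets) == 1
        assert len(nets[0]) == 3 and len(nets[0].edges) == 2

    def test_distant_triplets_split(self):
        pos = [[0, 0, 0], [2.8, 0, 0], [5.6, 0, 0],
               [20, 0, 0], [22.8, 0, 0], [25.6, 0, 0]]
        nets = build_network(self.make_clusters(pos), 3.4)
        assert [len(n) for n in nets] == [3, 3]
        assert {n.component_id for n in nets} == {0, 1}

    def test_every_cluster_in_exactly_one_component(self, rng):
        pos = rng.normal(size=(25, 3)) * 6
        clusters = self.make_clusters(pos)
        nets = build_network(clusters, 3.4)
        assert sum(len(n) for n in nets) == len(clusters)


class TestSiteEnvironment:
    def test_far_centroid_empty(self, rng):
        s = ca_only_structure(rng.normal(size=(5, 3)), "x")
        assert site_environment(np.array([100.0, 100, 100]), s, 3.5) == []

    def test_asp_carboxylate_contact_listed_first(self):
        s = Structure(id="toy")
        s.chains["A"] = [
            Residue("A", 1, "ASP", [Atom("CA", "C", [0, 0, 0]),
                                    Atom("OD1", "O", [2.9, 0, 0])]),
            Residue("A", 2, "LYS", [Atom("CA", "C", [5, 5, 5]),
                                    Atom("NZ", "N", [3.4, 0.5, 0])]),
        ]
        contacts = site_environment(np.zeros(3), s, 3.5)
        assert [r.name for r, _ in contacts] == ["ASP", "LYS"]
        assert contacts[0][1] == pytest.approx(2.9)
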