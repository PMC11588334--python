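"""Conserved-water mapping across superposed crystal structures.

Crystallographic waters that recur at the same position in independently
determined structures mark genuine hydration sites rather than lattice
noise.  The workflow implemented here:

1. :func:`project_waters` — superpose each structure onto a common reference
   (anchored on a chosen residue set, e.g. the N-terminal domain) and carry
   every retained water oxygen into the reference frame;
2. :func:`cluster_waters` — greedy agglomerative clustering of the pooled
   sites, with the constraint that a cluster holds at most one water per
   structure; a cluster's conservation is the fraction of structures that
   contribute a member;
3. :func:`build_network` — hydrogen-bond graph on cluster centroids
   (O-O distance cutoff) whose connected components are the conserved water
   networks; the two largest in unphosphorylated WNK1 are known as CWN1
   (active site, between the Catalytic and Activation Loops) and CWN2
   (dimer interface);
4. :func:`conservation_between` — optimal one-to-one matching of one
   structure's sites against another's, to count how many waters of a
   network are retained in a second structure or state.

Defaults: ``match_cutoff`` 2.2 A (separates hydration sites while
tolerating lattice-to-lattice drift), ``hbond_cutoff`` 3.4 A (upper bound of
water-water hydrogen bonds), waters with occupancy < 0.5 or B > 80 A^2
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .structio import Residue, Structure
from .superpose import ResidueMapping, kabsch
from .structio import select_ca

DEFAULT_MATCH_CUTOFF = 2.2
DEFAULT_HBOND_CUTOFF = 3.4
DEFAULT_MIN_OCC = 0.5
DEFAULT_MAX_B = 80.0

__all__ = [
    "WaterSite",
    "ConservedWaterCluster",
    "WaterNetwork",
    "project_waters",
    "cluster_waters",
    "conservation_between",
    "build_network",
    "site_environment",
]


@dataclass(frozen=True)
class WaterSite:
    """One water oxygen, carried into the common reference frame."""

    structure_id: str
    water_id: tuple[str, int]  # (chain, seqnum)
    pos_ref: np.ndarray

    def key(self) -> tuple:
        return (self.structure_id, *self.water_id)


@dataclass
class ConservedWaterCluster:
    """A matched water position: at most one member site per structure."""

    members: list[WaterSite]
    n_structures: int

    @property
    def centroid(self) -> np.ndarray:
        return np.mean([m.pos_ref for m in self.members], axis=0)

    @property
    def conservation(self) -> float:
        return len(self.members) / self.n_structures

    def member_for(self, structure_id: str) -> WaterSite | None:
        for m in self.members:
            if m.structure_id == structure_id:
                return m
        return None


@dataclass
class WaterNetwork:
    """A connected component of the centroid hydrogen-bond graph."""

    clusters: list[ConservedWaterCluster]
    edges: list[tuple[int, int]] = field(default_factory=list)  # indices into clusters
    component_id: int = 0

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.clusters])


def _retained_waters(s: Structure, min_occupancy: float, max_bfactor: float) -> list[Residue]:
    out = []
    for w in s.waters:
        o = w.water_o
        if o is None:
            continue
        if o.occupancy < min_occupancy or o.bfactor > max_bfactor:
            continue
        out.append(w)
    return out


def project_waters(structures: Sequence[Structure], ref: Structure,
                   anchors: dict[str, set[int]] | None = None,
                   chain_map: dict[str, tuple[str, str]] | None = None,
                   mappings: dict[str, ResidueMapping] | None = None,
                   min_occupancy: float = DEFAULT_MIN_OCC,
                   max_bfactor: float = DEFAULT_MAX_B) -> list[WaterSite]:
    """Superpose each structure onto ``ref`` and project its water oxygens.

    ``anchors`` gives the per-structure seqnum set (in that structure's own
    numbering) used for the anchoring superposition; ``None`` anchors on all
    common residues.  ``chain_map`` names the (structure chain, ref chain)
    used for anchoring, defaulting to the first chain of each.  ``mappings``
    supplies cross-isoform residue mappings keyed by structure id (identity
    numbering assumed when absent).
    """
    sites: list[WaterSite] = []
    ref_ca_by_chain = {ch: dict(select_ca(ref, ch)) for ch in ref.chains}
    for s in structures:
        if s.id == ref.id:
            rot, trans = np.eye(3), np.zeros(3)
        else:
            ch_s, ch_r = (chain_map or {}).get(
                s.id, (next(iter(s.chains)), next(iter(ref.chains))))
            ca_s = dict(select_ca(s, ch_s))
            ca_r = ref_ca_by_chain[ch_r]
            mapping = (mappings or {}).get(s.id)
            if mapping is None:
                common = sorted(set(ca_s) & set(ca_r))
                pairs = [(n, n) for n in common]
            else:
                pairs = [(a, b) for a, b in mapping.pairs if a in ca_s and b in ca_r]
            anchor = (anchors or {}).get(s.id)
            if anchor is not None:
                pairs = [(a, b) for a, b in pairs if a in anchor]
            if len(pairs) < 3:
                raise ValueError(f"{s.id}: anchor yields fewer than 3 C-alpha pairs onto {ref.id}")
            a = np.array([ca_s[p[0]] for p in pairs])
            b = np.array([ca_r[p[1]] for p in pairs])
            fit = kabsch(a, b)
            rot, trans = fit.rotation, fit.translation
        for w in _retained_waters(s, min_occupancy, max_bfactor):
            o = w.water_o
            sites.append(WaterSite(s.id, (w.chain_id, w.seqnum), rot @ o.pos + trans))
    return sites


def cluster_waters(sites: Sequence[WaterSite], match_cutoff: float = DEFAULT_MATCH_CUTOFF,
                   n_structures: int | None = None) -> list[ConservedWaterCluster]:
    """Greedy agglomerative clustering of projected water sites.

    Repeatedly merges the two clusters whose centroids are closest, subject
    to (i) centroid distance <= ``match_cutoff``, (ii) the merged cluster
    keeps at most one member per structure, and (iii) every member stays
    within ``match_cutoff`` of the merged centroid.  Ties are broken by
    distance and then lexicographically on member identity, so the result
    does not depend on input order.  Every site ends up in exactly one
    cluster (singletons allowed).
    """
    sites = sorted(sites, key=lambda s: s.key())
    if n_structures is None:
        n_structures = len({s.structure_id for s in sites}) or 1
    clusters: list[list[WaterSite]] = [[s] for s in sites]
    if not clusters:
        return []

    def centroid(c: list[WaterSite]) -> np.ndarray:
        return np.mean([m.pos_ref for m in c], axis=0)

    def can_merge(ci: list[WaterSite], cj: list[WaterSite]) -> bool:
        ids_i = {m.structure_id for m in ci}
        if any(m.structure_id in ids_i for m in cj):
            return False
        merged = ci + cj
        cen = centroid(merged)
        return all(np.linalg.norm(m.pos_ref - cen) <= match_cutoff for m in merged)

    while True:
        cents = np.array([centroid(c) for c in clusters])
        d = cdist(cents, cents)
        np.fill_diagonal(d, np.inf)
        # candidate merges sorted by (distance, identity of smallest member keys)
        ii, jj = np.where(d <= match_cutoff)
        cand = sorted(
            ((d[i, j], min(clusters[i][0].key(), clusters[j][0].key()),
              max(clusters[i][0].key(), clusters[j][0].key()), i, j)
             for i, j in zip(ii.tolist(), jj.tolist()) if i < j)
        )
        merged_any = False
        for _, _, _, i, j in cand:
            if can_merge(clusters[i], clusters[j]):
                merged = sorted(clusters[i] + clusters[j], key=lambda m: m.key())
                clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
                clusters.append(merged)
                merged_any = True
                break  # recompute distances after every merge
        if not merged_any:
            break
    clusters.sort(key=lambda c: (-len(c), c[0].key()))
    return [ConservedWaterCluster(c, n_structures) for c in clusters]


def conservation_between(sites_p: Sequence[WaterSite] | Sequence[np.ndarray],
                         sites_q: Sequence[WaterSite] | Sequence[np.ndarray],
                         match_cutoff: float = DEFAULT_MATCH_CUTOFF,
                         greedy: bool = False) -> tuple[int, list[bool]]:
    """How many of the P sites have a matching Q site within ``match_cutoff``.

    Uses optimal one-to-one assignment (minimum total distance, pairs beyond
    the cutoff forbidden), which makes retention counts reproducible;
    ``greedy=True`` instead matches closest-pair-first.  Returns the
    retained count and a per-P-site retained flag.
    """

    def pos(x):
        return x.pos_ref if isinstance(x, WaterSite) else np.asarray(x, dtype=float)

    p = np.array([pos(s) for s in sites_p]).reshape(-1, 3)
    q = np.array([pos(s) for s in sites_q]).reshape(-1, 3)
    flags = [False] * len(p)
    if len(p) == 0 or len(q) == 0:
        return 0, flags
    d = cdist(p, q)
    if greedy:
        used_q: set[int] = set()
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for i, j in order:
            if d[i, j] > match_cutoff:
                break
            if not flags[i] and j not in used_q:
                flags[i] = True
                used_q.add(int(j))
    else:
        big = match_cutoff * 1e6 + 1e6
        cost = np.where(d <= match_cutoff, d, big)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if d[i, j] <= match_cutoff:
                flags[i] = True
    return sum(flags), flags


def build_network(clusters: Sequence[ConservedWaterCluster],
                  hbond_cutoff: float = DEFAULT_HBOND_CUTOFF) -> list[WaterNetwork]:
    """Connected components of the centroid O-O hydrogen-bond graph.

    Returns networks largest-first (size = number of member clusters; ties
    broken by centroid for determinism).
    """
    clusters = list(clusters)
    if not clusters:
        return []
    cents = np.array([c.centroid for c in clusters])
    d = cdist(cents, cents)
    g = nx.Graph()
    g.add_nodes_from(range(len(clusters)))
    ii, jj = np.where((d <= hbond_cutoff) & (d > 0))
    g.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i < j)
    comps = sorted(nx.connected_components(g),
                   key=lambda c: (-len(c), tuple(np.round(cents[sorted(c)[0]], 3))))
    out = []
    for k, comp in enumerate(comps):
        idx = sorted(comp)
        remap = {old: new for new, old in enumerate(idx)}
        edges = [(remap[i], remap[j]) for i, j in g.edges if i in comp and j in comp]
        out.append(WaterNetwork([clusters[i] for i in idx],
                                [(min(e), max(e)) for e in edges], k))
    return out


_POLAR = frozenset({"N", "O", "S"})


def site_environment(centroid: np.ndarray, s: Structure,
                     contact_cutoff: float = 3.5) -> list[tuple[Residue, float]]:
    """Residues with a polar heavy atom within ``contact_cutoff`` of a site.

    Returns (residue, minimum polar-atom distance) sorted by distance —
    the local protein cage of a hydration site, e.g. the cluster of charged
    Activation-Loop/Catalytic-Loop residues around the active-site network.
    """
    centroid = np.asarray(centroid, dtype=float)
    out = []
    for residues in s.chains.values():
        for r in residues:
            dists = [float(np.linalg.norm(a.pos - centroid))
                     for a in r.atoms if a.element in _POLAR]
            if dists and min(dists) <= contact_cutoff:
                out.append((r, min(dists)))
    out.sort(key=lambda t: t[1])
    return out
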