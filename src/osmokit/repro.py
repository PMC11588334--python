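"""End-to-end comparisons of the deposited WNK kinase-domain structures.

These routines run the published structural analyses when a local directory
with the relevant PDB entries is available:

* ``6CN9`` — unphosphorylated WNK1/SA, the asymmetric dimer (chains A, B);
* ``5DRB`` — an independent uWNK1 structure used for water conservation;
* ``9D3F`` — WNK1/SA soaked in PEG400 (monomeric asymmetric unit, P2_1);
* ``9D7Q`` — WNK3/SA/E314A.

Files are looked up as ``<dir>/<id>.cif`` or ``<dir>/<id>.pdb`` (case
insensitive on the id).  Nothing here downloads anything: supply the files.

Residue-window defaults (author numbering, configurable):

* WNK1 Activation Loop 371-400 (spanning the phosphoacceptors S378/S382 and
  E388), WNK3 Activation Loop 297-326 (S304/S308, E314) — the segments
  excluded from "Activation Loops excluded" comparisons;
* N-terminal-domain anchor: start of the kinase domain through the end of
  beta-5 (WNK1 194-310 by default).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .structio import Structure, read_structure, select_ca
from .superpose import (ResidueMapping, apply_crystal_symmetry, kabsch,
                        map_residues, rmsd_selection)
from .watermap import (build_network, cluster_waters, conservation_between,
                       project_waters, site_environment)

WNK1_ACTIVATION_LOOP = (371, 400)
WNK3_ACTIVATION_LOOP = (297, 326)
WNK1_NTERM_ANCHOR = (194, 310)

__all__ = ["load_entry", "reproduce_structural_comparisons", "reproduce_water_conservation"]


def load_entry(directory: str | Path, pdb_id: str) -> Structure:
    """Load ``<dir>/<id>.{cif,pdb}``; FileNotFoundError when absent."""
    directory = Path(directory)
    for name in (pdb_id.upper(), pdb_id.lower()):
        for ext in (".cif", ".pdb", ".ent"):
            p = directory / f"{name}{ext}"
            if p.exists():
                s = read_structure(p)
                s.id = pdb_id.upper()
                return s
    raise FileNotFoundError(
        f"no coordinate file for {pdb_id} under {directory} "
        f"(expected {pdb_id.upper()}.cif or .pdb)")


def _self_mapping(s_a: Structure, ch_a: str, s_b: Structure, ch_b: str) -> ResidueMapping:
    return map_residues(s_a.sequence(ch_a), s_b.sequence(ch_b))


def _first_chain(s: Structure) -> str:
    return next(iter(s.chains))


def _range_set(lo_hi: tuple[int, int]) -> set[int]:
    return set(range(lo_hi[0], lo_hi[1] + 1))


def dimer_on_dimer_rmsd(monomer: Structure, dimer: Structure,
                        op_index: int = 1,
                        lattice_shifts=((0, 0, 0), (0, 1, 0), (0, -1, 0),
                                        (1, 0, 0), (-1, 0, 0),
                                        (0, 0, 1), (0, 0, -1))) -> float:
    """r.m.s.d. between a deposited dimer and monomer + crystal-symmetry mate.

    The monomeric asymmetric unit is expanded by a symmetry operator (the
    2_1 screw for a P2_1 form); every lattice shift and both chain-pairing
    assignments (A<->A/B<->B vs A<->B/B<->A) are tried, and the lowest
    all-common-C-alpha r.m.s.d. is returned, since the deposited origin
    choice is not recoverable from text.
    """
    ch_m = _first_chain(monomer)
    chains_d = list(dimer.chains)
    if len(chains_d) < 2:
        raise ValueError(f"{dimer.id}: expected a two-chain dimer")
    best = np.inf
    for shift in lattice_shifts:
        mate = apply_crystal_symmetry(monomer, op_index, shift)
        for ca_pair in ((chains_d[0], chains_d[1]), (chains_d[1], chains_d[0])):
            coords_m, coords_d = [], []
            for sub, ch_d in zip((monomer, mate), ca_pair):
                mapping = _self_mapping(sub, ch_m, dimer, ch_d)
                ca_a = dict(select_ca(sub, ch_m))
                ca_b = dict(select_ca(dimer, ch_d))
                for na, nb in mapping.pairs:
                    if na in ca_a and nb in ca_b:
                        coords_m.append(ca_a[na])
                        coords_d.append(ca_b[nb])
            if len(coords_m) < 3:
                continue
            fit = kabsch(np.array(coords_m), np.array(coords_d))
            best = min(best, fit.rmsd)
    return float(best)


def reproduce_structural_comparisons(directory: str | Path) -> dict:
    """The r.m.s.d. panel of the PEG400 / activating-mutant comparison.

    Returns a dict with keys ``dimer_rmsd`` (6CN9 dimer vs the two 9D3F
    subunits), ``monomer_vs_chainA`` / ``monomer_vs_chainB`` (9D3F vs the
    two 6CN9 subunits) and ``e314a_vs_peg400`` / ``e314a_vs_6cn9``
    (9D7Q vs 9D3F and 6CN9, Activation Loops excluded).
    """
    s6cn9 = load_entry(directory, "6CN9")
    s9d3f = load_entry(directory, "9D3F")
    s9d7q = load_entry(directory, "9D7Q")

    ch_m = _first_chain(s9d3f)
    chains_6 = list(s6cn9.chains)
    out: dict[str, float] = {}

    out["dimer_rmsd"] = dimer_on_dimer_rmsd(s9d3f, s6cn9)

    for label, ch in zip(("monomer_vs_chainA", "monomer_vs_chainB"), chains_6[:2]):
        mapping = _self_mapping(s9d3f, ch_m, s6cn9, ch)
        out[label] = rmsd_selection(s9d3f, s6cn9, mapping, ch_m, ch).rmsd

    al1 = _range_set(WNK1_ACTIVATION_LOOP)
    al3 = _range_set(WNK3_ACTIVATION_LOOP)
    ch_q = _first_chain(s9d7q)

    def rmsd_excl_al(s_a, ch_a, excl_a, s_b, ch_b, excl_b):
        mapping = _self_mapping(s_a, ch_a, s_b, ch_b)
        keep = {a for a, b in mapping.pairs if a not in excl_a and b not in excl_b}
        return rmsd_selection(s_a, s_b, mapping, ch_a, ch_b, selection=keep).rmsd

    out["e314a_vs_peg400"] = rmsd_excl_al(s9d7q, ch_q, al3, s9d3f, ch_m, al1)
    out["e314a_vs_6cn9"] = rmsd_excl_al(s9d7q, ch_q, al3, s6cn9, chains_6[0], al1)
    return out


def reproduce_water_conservation(directory: str | Path,
                                 match_cutoff: float = 2.2,
                                 hbond_cutoff: float = 3.4) -> dict:
    """Conserved-water-network census of 6CN9 vs 5DRB and 9D3F.

    Labels networks by region: CWN1 is the largest hydrogen-bonded component
    whose sites contact both Catalytic-Loop and Activation-Loop residues;
    CWN2 is the largest component contacting both subunits of the dimer.
    Returns member counts and retention counts in 5DRB / 9D3F.
    """
    s6cn9 = load_entry(directory, "6CN9")
    s5drb = load_entry(directory, "5DRB")
    s9d3f = load_entry(directory, "9D3F")

    anchor = _range_set(WNK1_NTERM_ANCHOR)
    ref_chain = _first_chain(s6cn9)
    structures = [s6cn9, s5drb, s9d3f]
    anchors = {s.id: anchor for s in structures}
    chain_map = {s.id: (_first_chain(s), ref_chain) for s in structures}
    sites = project_waters(structures, s6cn9, anchors=anchors, chain_map=chain_map)

    by_struct = {s.id: [w for w in sites if w.structure_id == s.id] for s in structures}
    clusters = cluster_waters(by_struct["6CN9"], match_cutoff, n_structures=1)
    networks = build_network(clusters, hbond_cutoff)

    cl_res = _range_set((344, 358))  # WNK1 Catalytic Loop neighborhood
    al_res = _range_set(WNK1_ACTIVATION_LOOP)

    def contacts(net, residue_set, chain_ids=None):
        hits = set()
        for c in net.clusters:
            for res, _d in site_environment(c.centroid, s6cn9, 4.0):
                if chain_ids is not None and res.chain_id in chain_ids:
                    hits.add(res.chain_id)
                if res.seqnum in residue_set:
                    hits.add(res.seqnum)
        return hits

    cwn1 = cwn2 = None
    chains_6 = set(s6cn9.chains)
    for net in networks:
        if cwn1 is None and contacts(net, cl_res) and contacts(net, al_res):
            cwn1 = net
        touched = contacts(net, set(), chain_ids=chains_6) & chains_6
        if cwn2 is None and len(touched) >= 2 and net is not cwn1:
            cwn2 = net
        if cwn1 is not None and cwn2 is not None:
            break

    out: dict[str, int] = {}
    if cwn1 is not None:
        p_sites = [c.members[0] for c in cwn1.clusters]
        out["cwn1_size"] = len(p_sites)
        out["cwn1_retained_5drb"], _ = conservation_between(
            p_sites, by_struct["5DRB"], match_cutoff)
        out["cwn1_retained_9d3f"], _ = conservation_between(
            p_sites, by_struct["9D3F"], match_cutoff)
    if cwn2 is not None:
        p_sites = [c.members[0] for c in cwn2.clusters]
        out["cwn2_size"] = len(p_sites)
        out["cwn2_retained_5drb"], _ = conservation_between(
            p_sites, by_struct["5DRB"], match_cutoff)
    return out
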