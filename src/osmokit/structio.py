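"""Reading and representing crystal structures.

Thin domain model on top of gemmi: a :class:`Structure` keeps polymer chains
(ordered residues with their atoms) separate from crystallographic water
molecules, because every downstream analysis treats the two differently —
superposition and displacement profiles run on C-alpha atoms of the polymer,
while conserved-water mapping runs on water oxygens.

Conventions (fixed across the package):

* author residue numbering is authoritative (structure papers cite author
  numbers such as E388 / E314);
* only the blank or ``'A'`` alternate-location conformer is kept;
* only the first model of a multi-model file is read;
* hydrogens are dropped; water geometry always means the oxygen position.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "read_structure",
    "select_ca",
    "write_table",
    "write_structure",
]


@dataclass
class Atom:
    """A single atom: label, element, position (A), occupancy, B-factor."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0 + 1e-9):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """A residue (or one water molecule) of a given chain."""

    chain_id: str
    seqnum: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def water_o(self) -> Atom | None:
        """The oxygen of a water residue (None for non-water)."""
        if not self.is_water:
            return None
        for a in self.atoms:
            if a.element == "O":
                return a
        return None


@dataclass
class Structure:
    """A crystal structure: chains of polymer residues plus waters.

    ``chains`` maps chain id to an ordered residue list; ``waters`` collects
    all water residues regardless of the chain they were deposited under
    (each keeps its ``chain_id``/``seqnum`` identity).
    """

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    waters: list[Residue] = field(default_factory=list)
    spacegroup: str = ""
    cell: tuple[float, float, float, float, float, float] | None = None

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"structure {self.id!r} has no chain {chain_id!r} "
                           f"(chains: {sorted(self.chains)})")
        return self.chains[chain_id]

    def residue(self, chain_id: str, seqnum: int) -> Residue | None:
        for r in self.chain(chain_id):
            if r.seqnum == seqnum:
                return r
        return None

    def sequence(self, chain_id: str) -> list[tuple[int, str]]:
        """(seqnum, one-letter code) per residue; 'X' for non-standard."""
        out = []
        for r in self.chain(chain_id):
            info = gemmi.find_tabulated_residue(r.name)
            one = info.one_letter_code.upper() if info else "x"
            out.append((r.seqnum, one if one.isalpha() else "X"))
        return out

    @property
    def n_atoms(self) -> int:
        n = sum(len(r.atoms) for ch in self.chains.values() for r in ch)
        return n + sum(len(w.atoms) for w in self.waters)

    def copy(self) -> "Structure":
        import copy as _copy

        return _copy.deepcopy(self)


def _keep_altloc(altloc: str, policy: str) -> bool:
    if policy == "first":
        return altloc in ("", "A", "\0")
    if policy == "all":
        return True
    raise ValueError(f"unknown altloc policy {policy!r}")


def read_structure(path: str | Path, format: str = "auto", altloc: str = "first") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (by extension/content).
    altloc:
        ``"first"`` keeps blank/'A' conformers only (default); ``"all"``
        keeps everything.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "auto":
            st = gemmi.read_structure(str(path))
        elif format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise IOError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models parsed")

    out = Structure(id=st.name or path.stem,
                    spacegroup=st.spacegroup_hm or "",
                    cell=(st.cell.a, st.cell.b, st.cell.c,
                          st.cell.alpha, st.cell.beta, st.cell.gamma)
                    if st.cell.a > 1.0 else None)

    model = st[0]  # first model only
    for chain in model:
        for res in chain:
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]),
                     min(a.occ, 1.0), a.b_iso, a.altloc.strip("\0"))
                for a in res
                if _keep_altloc(a.altloc.strip("\0"), altloc) and not a.is_hydrogen()
            ]
            if not atoms:
                continue
            residue = Residue(chain.name, res.seqid.num, res.name, atoms)
            if residue.is_water:
                out.waters.append(residue)
            else:
                out.chains.setdefault(chain.name, []).append(residue)

    if out.n_atoms == 0:
        raise ValueError(f"{path}: no atoms parsed")
    return out


def select_ca(s: Structure, chain: str, seq_range: tuple[int, int] | None = None,
              ) -> list[tuple[int, np.ndarray]]:
    """Ordered (seqnum, CA position) for residues of ``chain`` in ``seq_range``.

    Residues without a C-alpha (waters, ligands, partially modelled
    residues) are skipped.  ``seq_range`` is an inclusive (lo, hi) interval
    of author seqnums; ``None`` selects the whole chain.
    """
    lo, hi = (-math.inf, math.inf) if seq_range is None else seq_range
    out = []
    for r in s.chain(chain):
        if not (lo <= r.seqnum <= hi):
            continue
        ca = r.ca
        if ca is not None:
            out.append((r.seqnum, ca.pos.copy()))
    out.sort(key=lambda t: t[0])
    return out


def write_table(rows: Sequence[dict], path: str | Path, format: str = "csv") -> None:
    """Write homogeneous record dicts as CSV (header always emitted) or JSON."""
    path = Path(path)
    rows = list(rows)
    if rows:
        keys = list(rows[0].keys())
        for r in rows[1:]:
            if list(r.keys()) != keys:
                raise ValueError("rows do not share a schema")
    else:
        keys = []
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(rows)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown table format {format!r}")


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    if s.spacegroup:
        st.spacegroup_hm = s.spacegroup
    if s.cell is not None:
        st.cell = gemmi.UnitCell(*s.cell)
    model = gemmi.Model("1")

    def add(chain_name: str, residues: Iterable[Residue]) -> None:
        chain = gemmi.Chain(chain_name)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.seqnum, " ")
            if r.is_water:
                res.het_flag = "H"
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.pos)
                atom.occ = a.occupancy
                atom.b_iso = a.bfactor
                if a.altloc:
                    atom.altloc = a.altloc
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)

    for chain_id, residues in s.chains.items():
        add(chain_id, residues)
    by_chain: dict[str, list[Residue]] = {}
    for w in s.waters:
        by_chain.setdefault(w.chain_id, []).append(w)
    for chain_id, ws in by_chain.items():
        add(chain_id if chain_id not in s.chains else chain_id + "w", ws)
    st.add_model(model)
    return st


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as PDB-format text (used by the synthetic generator)."""
    st = _to_gemmi(s)
    st.setup_entities()
    st.write_pdb(str(path))
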