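"""Shared fixtures: tiny hand-built structures and PDB text."""

from __future__ import annotations

import numpy as np
import pytest

from osmokit.structio import Atom, Residue, Structure

MINI_PDB = """\
CRYST1   20.000   30.000   40.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       2.000   2.500   3.500  1.00 10.00           C
ATOM      3  C   ALA A   1       3.000   3.000   4.000  1.00 10.00           C
ATOM      4  N   GLY A   2       4.000   3.500   4.500  1.00 11.00           N
ATOM      5  CA  GLY A   2       5.000   4.000   5.000  1.00 11.00           C
ATOM      6  CA ASER A   3       6.000   4.500   5.500  0.60 12.00           C
ATOM      7  CA BSER A   3       6.400   4.900   5.900  0.40 12.00           C
HETATM    8  O   HOH S   1      10.000  10.000  10.000  1.00 20.00           O
HETATM    9  O   HOH S   2      12.000  10.000  10.000  1.00 25.00           O
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return p


def ca_only_structure(coords: np.ndarray, structure_id: str = "toy",
                      chain_id: str = "A", start: int = 1) -> Structure:
    """C-alpha-trace structure from an N x 3 array."""
    s = Structure(id=structure_id)
    s.chains[chain_id] = [
        Residue(chain_id, start + i, "ALA", [Atom("CA", "C", c)])
        for i, c in enumerate(np.asarray(coords, dtype=float))
    ]
    return s


def add_waters(s: Structure, positions: np.ndarray, chain_id: str = "W") -> Structure:
    for i, p in enumerate(np.asarray(positions, dtype=float), start=1):
        s.waters.append(Residue(chain_id, i, "HOH", [Atom("O", "O", p)]))
    return s


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(42)
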