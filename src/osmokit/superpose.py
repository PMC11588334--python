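"""Rigid-body superposition and per-residue displacement profiles.

Everything here works on C-alpha atoms by default: backbone-level
comparisons are the convention for reporting r.m.s.d. between kinase-domain
structures, and they keep cross-isoform comparisons well defined once
residues have been mapped by sequence alignment.

The workhorse is the Kabsch algorithm (least-squares rigid superposition via
SVD with reflection correction).  On top of it sit

* :func:`rmsd_selection` — superpose on one residue set (``fit_on``) and
  report r.m.s.d. over another (``selection``), supporting "local" fits such
  as superposing N-terminal domains only;
* :func:`displacement_profile` — per-residue C-alpha displacement after an
  anchored superposition, the quantity plotted against sequence to localize
  conformational change (Activation Loop, helix C, ...);
* :func:`apply_crystal_symmetry` — regenerate a symmetry mate so that a
  monomeric asymmetric unit can be compared against a deposited dimer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structio import Structure, select_ca

__all__ = [
    "ResidueMapping",
    "SuperpositionResult",
    "DisplacementProfile",
    "map_residues",
    "kabsch",
    "rmsd_selection",
    "displacement_profile",
    "apply_crystal_symmetry",
]


@dataclass(frozen=True)
class ResidueMapping:
    """Ordered (seqnum_a, seqnum_b) residue correspondence between two chains."""

    pairs: tuple[tuple[int, int], ...]
    source: str  # "identity" | "alignment"

    def __post_init__(self) -> None:
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if sorted(set(a)) != a or sorted(set(b)) != b:
            raise ValueError("mapping pairs must be strictly increasing in both columns")

    def b_for_a(self, seqnum_a: int) -> int | None:
        for a, b in self.pairs:
            if a == seqnum_a:
                return b
        return None

    @classmethod
    def identity(cls, seqnums: Iterable[int]) -> "ResidueMapping":
        return cls(tuple((n, n) for n in seqnums), "identity")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform b ~ R a + t, with its r.m.s.d."""

    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector, A
    rmsd: float
    n_pairs: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class DisplacementProfile:
    """Per-residue C-alpha displacement (A) after an anchored superposition."""

    entries: tuple[tuple[int, float], ...]  # (seqnum in frame of structure a, A)
    anchor: str

    @property
    def seqnums(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries])

    @property
    def displacements(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries])

    def peak(self) -> tuple[int, float]:
        i = int(np.argmax(self.displacements))
        return self.entries[i]


def map_residues(seq_a: Sequence[tuple[int, str]], seq_b: Sequence[tuple[int, str]],
                 open_gap: float = -11.0, extend_gap: float = -1.0,
                 matrix: str = "BLOSUM62") -> ResidueMapping:
    """Map residue numbers of chain a onto chain b.

    ``seq_a``/``seq_b`` are (seqnum, one-letter) lists as produced by
    :meth:`Structure.sequence`.  Identical sequences over a shared numbering
    map by identity; otherwise a global pairwise alignment with affine gap
    penalties is computed and every residue-to-residue (non-gap) column
    becomes a pair.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    nums_a, letters_a = zip(*seq_a)
    nums_b, letters_b = zip(*seq_b)
    sa, sb = "".join(letters_a), "".join(letters_b)
    if nums_a == nums_b and sa == sb:
        return ResidueMapping(tuple((n, n) for n in nums_a), "identity")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    # X (non-standard residues) is in BLOSUM62's alphabet, so no sanitizing
    alignment = aligner.align(sa, sb)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((nums_a[i], nums_b[j]))
    return ResidueMapping(tuple(pairs), "alignment")


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns the proper rotation R and translation t minimizing
    sum ||R a_i + t - b_i||^2, and the r.m.s.d. of the superposed pairs.
    Reflections are rejected by flipping the sign of the smallest singular
    vector when det(V U^T) < 0.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 atom pairs, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) geometry: superposition ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    diff = a0 @ rot.T - b0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rot, trans, rmsd, n)


def _mapped_ca_pairs(s_a: Structure, chain_a: str, s_b: Structure, chain_b: str,
                     mapping: ResidueMapping,
                     subset: set[int] | None) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Coordinates of mapped C-alpha pairs restricted to ``subset`` of a-seqnums."""
    ca_a = dict(select_ca(s_a, chain_a))
    ca_b = dict(select_ca(s_b, chain_b))
    pa, pb, nums = [], [], []
    for na, nb in mapping.pairs:
        if subset is not None and na not in subset:
            continue
        if na in ca_a and nb in ca_b:
            pa.append(ca_a[na])
            pb.append(ca_b[nb])
            nums.append(na)
    return np.array(pa).reshape(-1, 3), np.array(pb).reshape(-1, 3), nums


def rmsd_selection(s_a: Structure, s_b: Structure, mapping: ResidueMapping,
                   chain_a: str, chain_b: str,
                   selection: set[int] | None = None,
                   fit_on: set[int] | None = None) -> SuperpositionResult:
    """Superpose on ``fit_on`` C-alpha pairs, report r.m.s.d. over ``selection``.

    Both sets are a-structure seqnums; ``None`` means all mapped residues.
    ``fit_on`` defaults to ``selection`` (ordinary r.m.s.d.); passing a
    smaller ``fit_on`` gives "anchored" comparisons such as fitting on the
    N-terminal domain while reporting over the whole chain.
    """
    if fit_on is None:
        fit_on = selection
    fa, fb, _ = _mapped_ca_pairs(s_a, chain_a, s_b, chain_b, mapping, fit_on)
    if fa.shape[0] < 3:
        raise ValueError("fit_on maps to fewer than 3 common C-alpha pairs")
    fit = kabsch(fa, fb)
    sa, sb, _ = _mapped_ca_pairs(s_a, chain_a, s_b, chain_b, mapping, selection)
    if sa.shape[0] < 1:
        raise ValueError("selection maps to no common C-alpha pairs")
    diff = fit.transform(sa) - sb
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return SuperpositionResult(fit.rotation, fit.translation, rmsd, sa.shape[0])


def displacement_profile(s_a: Structure, s_b: Structure, mapping: ResidueMapping,
                         chain_a: str, chain_b: str,
                         anchor: set[int] | None = None,
                         anchor_label: str = "all mapped residues") -> DisplacementProfile:
    """Per-residue C-alpha displacement of b relative to a after anchoring.

    The two structures are superposed on the ``anchor`` residue set (kabsch
    on anchor C-alpha pairs); each mapped residue then contributes the
    Euclidean distance between its superposed C-alpha positions.  Peaks in
    the profile localize conformational change along the sequence.
    """
    fa, fb, _ = _mapped_ca_pairs(s_a, chain_a, s_b, chain_b, mapping, anchor)
    if fa.shape[0] < 3:
        raise ValueError("anchor maps to fewer than 3 common C-alpha pairs")
    fit = kabsch(fa, fb)
    pa, pb, nums = _mapped_ca_pairs(s_a, chain_a, s_b, chain_b, mapping, None)
    d = np.linalg.norm(fit.transform(pa) - pb, axis=1)
    return DisplacementProfile(tuple(zip(nums, d.tolist())), anchor_label)


def find_hinge(profile: DisplacementProfile, threshold: float | None = None) -> int:
    """Changepoint of a displacement profile: first residue of the mobile block.

    The hinge is located as the split maximizing the between-segment
    difference of mean displacement (a two-segment step-fit changepoint).
    """
    d = profile.displacements
    nums = profile.seqnums
    best, best_score = nums[0], -np.inf
    for i in range(1, len(d)):
        left, right = d[:i], d[i:]
        # score: reduction in SSE of a piecewise-constant fit
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        score = -sse
        if score > best_score:
            best_score, best = score, nums[i]
    return int(best)


def apply_crystal_symmetry(s: Structure, op_index: int,
                           lattice_shift: tuple[int, int, int] = (0, 0, 0)) -> Structure:
    """Copy of ``s`` with every atom moved by a crystal symmetry operator.

    ``op_index`` indexes the symmetry operations of the structure's space
    group (0 is always the identity); ``lattice_shift`` adds whole unit-cell
    translations.  Used to rebuild a two-subunit arrangement from a
    monomeric asymmetric unit (e.g. the P2_1 screw mate of a monomer) for
    dimer-on-dimer comparison.
    """
    if not s.spacegroup or s.cell is None:
        raise ValueError(f"structure {s.id!r}: spacegroup/cell unknown, "
                         "cannot apply crystal symmetry")
    sg = gemmi.SpaceGroup(s.spacegroup)
    ops = list(sg.operations())
    if not (0 <= op_index < len(ops)):
        raise IndexError(f"op_index {op_index} out of range for {s.spacegroup!r} "
                         f"({len(ops)} operations)")
    op = ops[op_index]
    cell = gemmi.UnitCell(*s.cell)
    shift = np.asarray(lattice_shift, dtype=float)

    out = s.copy()

    def move(res_list):
        for r in res_list:
            for a in r.atoms:
                frac = cell.fractionalize(gemmi.Position(*a.pos))
                fx = op.apply_to_xyz([frac.x, frac.y, frac.z])
                pos = cell.orthogonalize(gemmi.Fractional(*(np.asarray(fx) + shift)))
                a.pos = np.array([pos.x, pos.y, pos.z])

    for residues in out.chains.values():
        move(residues)
    move(out.waters)
    return out
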