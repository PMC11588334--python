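"""Synthetic data with recorded ground truth for every analysis stage.

Each generator emulates one experimental data type at the study's own
design points and returns both the data and the truth used to make it, so
recovery can be scored without re-deriving the answer from the data:

* :func:`make_ensemble` — a multi-structure crystal "ensemble": an ideal
  helix-turn-helix C-alpha scaffold decorated with planted conserved water
  sites (per-structure Gaussian jitter) plus uniform random background
  waters, each copy under its own rigid-body motion;
* :func:`make_progress_curves` — autophosphorylation progress curves at
  several chloride concentrations (default: the experimental design of
  4 uM enzyme, 50/150/250 mM chloride, samples at 0/4/10/15/20 min) with
  additive Gaussian noise on fractions;
* :func:`make_sls_series` — weight-average masses of a 2M <-> D equilibrium
  at the measured concentrations (0.8/1.2/1.8/2.4 mg/ml) with
  multiplicative noise;
* :func:`make_dsf_curve` — a logistic melt on the instrument grid
  (4 to 80 degC in 0.5 degC steps) with multiplicative noise.

All generators are pure functions of (spec, seed).

Two kinetic presets capture the qualitative contrast the mutagenesis shows:
``"wildtype"`` (moderate rate, stronger chloride binding) and
``"E314A"`` (faster autophosphorylation, weaker chloride binding).  They
are illustrative parameter sets chosen to reproduce that ordering, not
measured constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .equilibria import DSFCurve, SLSSeries, dimer_mass_fraction
from .kinetics import AutocatParams, ProgressCurve, simulate_autocat
from .structio import Atom, Residue, Structure

__all__ = [
    "EnsembleSpec",
    "KineticDesign",
    "KINETIC_PRESETS",
    "make_ensemble",
    "make_progress_curves",
    "make_sls_series",
    "make_dsf_curve",
]

# Illustrative parameter presets reproducing the wild-type vs activating-mutant
# ordering (higher rate, weaker chloride binding for the mutant-like preset).
KINETIC_PRESETS: dict[str, AutocatParams] = {
    # k calibrated so the 50 mM curve approaches completion within the
    # sampled 0-20 min window, as the experimental time-point design implies
    "wildtype": AutocatParams(k=0.10, K_Cl=120.0, p0=0.15, T=4.0),
    "E314A": AutocatParams(k=0.25, K_Cl=400.0, p0=0.15, T=4.0),
}

CHLORIDE_LEVELS_MM = (50.0, 150.0, 250.0)
TIMEPOINTS_MIN = (0.0, 4.0, 10.0, 15.0, 20.0)
SLS_CONCENTRATIONS_MGML = (0.8, 1.2, 1.8, 2.4)
DSF_GRID = (4.0, 80.0, 0.5)  # start, stop, step (degC)


@dataclass(frozen=True)
class EnsembleSpec:
    """Design of a synthetic multi-structure ensemble with planted waters."""

    n_structures: int = 5
    n_conserved_waters: int = 10
    n_random_waters: int = 30
    jitter_sigma: float = 0.25  # A, per-structure scatter of planted sites
    n_residues: int = 44  # helix-turn-helix scaffold length
    rigid_motion_scale: float = 15.0  # A, translation scale of per-copy motions
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_structures, self.n_conserved_waters, self.n_random_waters) < 0:
            raise ValueError("counts must be >= 0")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.n_residues < 40:
            raise ValueError("scaffold needs >= 40 residues")


@dataclass(frozen=True)
class KineticDesign:
    """Design of a synthetic chloride-series autophosphorylation experiment."""

    true_params: AutocatParams = KINETIC_PRESETS["wildtype"]
    chloride_levels: tuple[float, ...] = CHLORIDE_LEVELS_MM
    times: tuple[float, ...] = TIMEPOINTS_MIN
    noise_sigma: float = 0.03  # fraction units, additive
    n_replicates: int = 1
    site: str = "S308"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(c < 0 for c in self.chloride_levels):
            raise ValueError("chloride levels must be non-negative")


# ---------------------------------------------------------------------------
# structural ensemble


def _helix_turn_helix_ca(n_residues: int) -> np.ndarray:
    """C-alpha trace of an ideal helix-turn-helix: two antiparallel helices.

    Standard alpha-helix parameters: radius 2.3 A, rise 1.5 A per residue,
    100 degrees per residue.
    """
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    n1 = n_residues // 2
    n2 = n_residues - n1
    coords = []
    for i in range(n1):
        coords.append([radius * np.cos(twist * i), radius * np.sin(twist * i), rise * i])
    # second helix antiparallel, offset 10 A in x, descending in z
    z_top = rise * (n1 - 1) + 4.0
    for j in range(n2):
        coords.append([10.0 + radius * np.cos(-twist * j),
                       radius * np.sin(-twist * j), z_top - rise * j])
    return np.asarray(coords)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det +1)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_ensemble(spec: EnsembleSpec, out_dir: str | Path | None = None,
                  ) -> tuple[list[Structure], dict]:
    """Build a synthetic ensemble and its ground-truth site table.

    Returns (structures, truth).  ``truth["sites"]`` maps planted-site index
    to the scaffold-frame center and the per-structure water identity
    planted there; ``truth["random"]`` lists the background water ids.
    Background waters are rejection-sampled to stay at least 2.5 A (in the
    scaffold frame) from the planted centers *and* from background waters of
    every other structure: without the cross-structure exclusion the
    background itself would occasionally form genuine conserved sites and
    the recorded truth would be wrong.  With ``out_dir`` the structures are
    also written as PDB files plus a ``truth.json``.
    """
    rng = np.random.default_rng(spec.seed)
    ca = _helix_turn_helix_ca(spec.n_residues)
    lo, hi = ca.min(axis=0) - 4.0, ca.max(axis=0) + 4.0

    # planted conserved sites: uniform in the scaffold box, >= 3 A apart
    centers: list[np.ndarray] = []
    while len(centers) < spec.n_conserved_waters:
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) >= 3.0 for q in centers):
            centers.append(p)
    centers_arr = np.array(centers).reshape(-1, 3)

    structures: list[Structure] = []
    truth_sites = [{"site": i, "center": c.tolist(), "members": {}}
                   for i, c in enumerate(centers_arr)]
    truth_random: dict[str, list] = {}
    all_random_pos: list[np.ndarray] = []  # scaffold frame, across structures

    for s_idx in range(spec.n_structures):
        sid = f"synth{s_idx}"
        rot = _random_rotation(rng) if s_idx else np.eye(3)
        trans = (rng.uniform(-spec.rigid_motion_scale, spec.rigid_motion_scale, 3)
                 if s_idx else np.zeros(3))
        st = Structure(id=sid)
        st.chains["A"] = [
            Residue("A", i + 1, "ALA",
                    [Atom("CA", "C", rot @ ca[i] + trans, 1.0, 20.0)])
            for i in range(spec.n_residues)
        ]
        wnum = 1
        for i, c in enumerate(centers_arr):
            pos0 = c + rng.normal(0.0, spec.jitter_sigma, 3)
            st.waters.append(Residue("W", wnum, "HOH",
                                     [Atom("O", "O", rot @ pos0 + trans, 1.0, 30.0)]))
            truth_sites[i]["members"][sid] = ["W", wnum]
            wnum += 1
        randoms = []
        placed = 0
        while placed < spec.n_random_waters:
            p = rng.uniform(lo, hi)
            if np.min(np.linalg.norm(centers_arr - p, axis=1), initial=np.inf) < 2.5:
                continue
            if any(np.linalg.norm(p - q) < 2.5 for q in all_random_pos):
                continue  # background must not form accidental conserved sites
            all_random_pos.append(p)
            st.waters.append(Residue("W", wnum, "HOH",
                                     [Atom("O", "O", rot @ p + trans, 1.0, 30.0)]))
            randoms.append(["W", wnum])
            wnum += 1
            placed += 1
        truth_random[sid] = randoms
        structures.append(st)

    truth = {"spec": {"n_structures": spec.n_structures,
                      "n_conserved_waters": spec.n_conserved_waters,
                      "n_random_waters": spec.n_random_waters,
                      "jitter_sigma": spec.jitter_sigma,
                      "seed": spec.seed},
             "sites": truth_sites, "random": truth_random}

    if out_dir is not None:
        from .structio import write_structure

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for st in structures:
            write_structure(st, out_dir / f"{st.id}.pdb")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return structures, truth


# ---------------------------------------------------------------------------
# kinetics


def make_progress_curves(design: KineticDesign) -> tuple[list[ProgressCurve], dict]:
    """Simulate the chloride series and add Gaussian noise on fractions.

    Returns (curves, truth); curves are ordered by replicate then chloride.
    Noisy fractions are clipped to [0, 1].
    """
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.times, dtype=float)
    curves = []
    for _rep in range(design.n_replicates):
        for cl in design.chloride_levels:
            f = simulate_autocat(design.true_params, t, cl)
            if design.noise_sigma > 0:
                f = np.clip(f + rng.normal(0.0, design.noise_sigma, f.shape), 0.0, 1.0)
            curves.append(ProgressCurve(t.copy(), f, cl,
                                        design.true_params.T, design.site))
    truth = {"k": design.true_params.k, "K_Cl": design.true_params.K_Cl,
             "p0": design.true_params.p0, "T": design.true_params.T,
             "noise_sigma": design.noise_sigma, "seed": design.seed}
    return curves, truth


# ---------------------------------------------------------------------------
# equilibria


def make_sls_series(kd_uM: float,
                    concentrations_mgml=SLS_CONCENTRATIONS_MGML,
                    m_mono: float = 40.0, noise_frac: float = 0.0,
                    seed: int = 0) -> tuple[SLSSeries, dict]:
    """Weight-average masses of a monomer-dimer equilibrium at given Kd."""
    if kd_uM <= 0:
        raise ValueError("Kd must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations_mgml, dtype=float)
    c_uM = conc / m_mono * 1000.0
    f = np.asarray(dimer_mass_fraction(kd_uM, c_uM))
    masses = (1.0 - f) * m_mono + f * 2.0 * m_mono
    if noise_frac > 0:
        masses = masses * (1.0 + rng.normal(0.0, noise_frac, masses.shape))
    series = SLSSeries(conc, masses, m_mono)
    truth = {"kd_uM": kd_uM, "dimer_fractions": f.tolist(),
             "noise_frac": noise_frac, "seed": seed}
    return series, truth


def make_dsf_curve(tm: float, slope: float = 2.0,
                   plateaus: tuple[float, float] = (100.0, 1000.0),
                   grid: tuple[float, float, float] = DSF_GRID,
                   noise_frac: float = 0.0, seed: int = 0,
                   condition: str = "") -> tuple[DSFCurve, dict]:
    """Logistic melt on the instrument temperature grid, with noise.

    The default grid (4 to 80 degC inclusive, 0.5 degC steps) has 153 points.
    ``noise_frac`` scales multiplicative Gaussian noise on the amplitude.
    """
    start, stop, step = grid
    if not (start <= tm <= stop):
        raise ValueError(f"tm {tm} outside the temperature grid [{start}, {stop}]")
    rng = np.random.default_rng(seed)
    t = np.arange(start, stop + step / 2, step)
    f_low, f_high = plateaus
    f = f_low + (f_high - f_low) / (1.0 + np.exp((tm - t) / slope))
    if noise_frac > 0:
        f = f * (1.0 + rng.normal(0.0, noise_frac, f.shape))
    curve = DSFCurve(t, f, condition)
    truth = {"tm": tm, "slope": slope, "plateaus": list(plateaus),
             "noise_frac": noise_frac, "seed": seed}
    return curve, truth
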