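"""Monomer-dimer equilibrium and thermal-stability models.

Two small biophysical models used to interpret solution measurements of
kinase domains:

* **Static light scattering (SLS).**  A 90-degree SLS instrument reports the
  weight-average molar mass of the species mixture.  For a two-state
  monomer-dimer equilibrium 2M <-> D with dissociation constant
  Kd = [M]^2 / [D], mass action at total monomer-equivalent concentration
  c_tot gives [M] = (-Kd + sqrt(Kd^2 + 8 Kd c_tot)) / 4, and the apparent
  mass is the weight average (1 - f) m_mono + f m_dimer with
  f = 2[D] / c_tot the dimer *mass* fraction.  An apparent mass of 60 kD for
  a 40 kD monomer therefore reads as a 50/50 (by mass) monomer-dimer
  mixture.  :func:`fit_kd_dimer` inverts a concentration series into a Kd.

* **Differential scanning fluorimetry (DSF).**  Unfolding is fit with the
  symmetric logistic F(T) = f_low + (f_high - f_low) / (1 + exp((Tm - T)/s));
  the inflection point is the melt temperature Tm.  Fluorescence past the
  global maximum (aggregation roll-off) is trimmed before fitting, the
  standard practice for dye-based melts.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "SLSSeries",
    "DSFCurve",
    "MeltFit",
    "weight_average_mass",
    "dimer_fraction_from_mass",
    "monomer_concentration",
    "fit_kd_dimer",
    "fit_melt",
]


@dataclass(frozen=True)
class SLSSeries:
    """A concentration series of SLS apparent masses."""

    concentrations: np.ndarray  # mg/ml
    apparent_masses: np.ndarray  # kD
    monomer_mass: float = 40.0  # kD
    dimer_mass: float | None = None  # kD, defaults to 2 x monomer

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations",
                           np.asarray(self.concentrations, dtype=float))
        object.__setattr__(self, "apparent_masses",
                           np.asarray(self.apparent_masses, dtype=float))
        if self.dimer_mass is None:
            object.__setattr__(self, "dimer_mass", 2.0 * self.monomer_mass)
        if abs(self.dimer_mass - 2 * self.monomer_mass) > 0.01 * self.dimer_mass:
            raise ValueError("dimer mass must be twice the monomer mass (within 1%)")
        if np.any(self.concentrations <= 0) or self.monomer_mass <= 0:
            raise ValueError("concentrations and masses must be positive")

    @property
    def c_tot_uM(self) -> np.ndarray:
        """Total concentration in monomer-equivalent uM (mg/ml over kD, x1000)."""
        return self.concentrations / self.monomer_mass * 1000.0


@dataclass(frozen=True)
class DSFCurve:
    """One thermal melt: fluorescence vs temperature under one condition."""

    temperatures: np.ndarray  # degC, strictly increasing
    fluorescence: np.ndarray  # arbitrary units
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if t.shape != f.shape:
            raise ValueError("temperatures and fluorescence must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class MeltFit:
    tm: float  # degC (inflection point)
    slope: float  # degC (transition width)
    f_low: float
    f_high: float
    ssr: float
    converged: bool = True
    message: str = ""


def weight_average_mass(f_dimer: float, m_mono: float, m_dimer: float) -> float:
    """Weight-average mass of a monomer-dimer mixture; f_dimer is by mass."""
    if not (0.0 <= f_dimer <= 1.0):
        raise ValueError("f_dimer must lie in [0, 1]")
    return (1.0 - f_dimer) * m_mono + f_dimer * m_dimer


def dimer_fraction_from_mass(m_app: float, m_mono: float, m_dimer: float) -> float:
    """Invert the weight average: mass fraction of dimer from apparent mass."""
    if not (m_mono <= m_app <= m_dimer):
        clamped = min(max(m_app, m_mono), m_dimer)
        raise ValueError(
            f"apparent mass {m_app} kD outside [{m_mono}, {m_dimer}] kD; "
            f"nearest admissible value is {clamped} kD")
    return (m_app - m_mono) / (m_dimer - m_mono)


def monomer_concentration(kd_uM: float, c_tot_uM: float) -> float:
    """Free monomer (uM) for 2M <-> D at total monomer-equivalent c_tot.

    Root of [M] + 2 [M]^2 / Kd = c_tot:  [M] = (-Kd + sqrt(Kd^2 + 8 Kd c)) / 4.
    """
    if kd_uM <= 0:
        raise ValueError("Kd must be positive")
    return (-kd_uM + np.sqrt(kd_uM ** 2 + 8.0 * kd_uM * c_tot_uM)) / 4.0


def dimer_mass_fraction(kd_uM: float, c_tot_uM) -> np.ndarray | float:
    """Mass fraction of dimer 2[D]/c_tot at given Kd and total concentration."""
    c = np.asarray(c_tot_uM, dtype=float)
    m = (-kd_uM + np.sqrt(kd_uM ** 2 + 8.0 * kd_uM * c)) / 4.0
    return (c - m) / c  # 2[D] = c - [M]


def predicted_masses(kd_uM: float, series: SLSSeries) -> np.ndarray:
    f = dimer_mass_fraction(kd_uM, series.c_tot_uM)
    return (1.0 - f) * series.monomer_mass + f * series.dimer_mass


def fit_kd_dimer(series: SLSSeries) -> tuple[float, np.ndarray]:
    """Least-squares Kd (uM) from an SLS apparent-mass concentration series.

    Returns (Kd, per-point dimer mass fractions at the fitted Kd).
    """
    if len(np.unique(series.concentrations)) < 2:
        raise ValueError("need at least two distinct concentrations to identify Kd")

    c = series.c_tot_uM

    def resid(log_kd):
        return predicted_masses(float(np.exp(log_kd[0])), series) - series.apparent_masses

    # start from the point-wise inversion of the middle datum
    m_mid = float(np.clip(np.median(series.apparent_masses),
                          series.monomer_mass * 1.0001, series.dimer_mass * 0.9999))
    f_mid = (m_mid - series.monomer_mass) / (series.dimer_mass - series.monomer_mass)
    c_mid = float(np.median(c))
    m_free = (1 - f_mid) * c_mid
    kd0 = max(m_free ** 2 / (f_mid * c_mid / 2.0), 1e-6)
    sol = least_squares(resid, [np.log(kd0)], bounds=([-20.0], [25.0]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    kd = float(np.exp(sol.x[0]))
    return kd, np.asarray(dimer_mass_fraction(kd, c))


def _logistic(t, f_low, f_high, tm, slope):
    return f_low + (f_high - f_low) / (1.0 + np.exp((tm - t) / slope))


def fit_melt(curve: DSFCurve, trim_rolloff: bool = True) -> MeltFit:
    """Fit a DSF melt to the symmetric logistic; Tm is the inflection point.

    With ``trim_rolloff`` (default) only data up to the global fluorescence
    maximum are fit, discarding the post-transition aggregation decay.
    """
    t, f = curve.temperatures, curve.fluorescence
    if trim_rolloff:
        imax = int(np.argmax(f))
        if imax >= 7:  # keep the full pre-peak transition
            t, f = t[: imax + 1], f[: imax + 1]
    if len(t) < 8:
        return MeltFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                       "fewer than 8 points span the transition")
    span = float(f.max() - f.min())
    if span <= 0 or span < 0.02 * max(abs(f).max(), 1e-12):
        return MeltFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                       "no transition detected (flat curve)")
    # inflection guess: steepest finite-difference slope
    slopes = np.gradient(f, t)
    tm0 = float(t[int(np.argmax(slopes))])
    p0 = [float(f.min()), float(f.max()), tm0, max((t[-1] - t[0]) / 20.0, 0.5)]
    try:
        popt, _ = curve_fit(_logistic, t, f, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        return MeltFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, str(exc))
    f_low, f_high, tm, slope = popt
    if slope < 0:  # equivalent parameterization with swapped plateaus
        f_low, f_high, slope = f_high, f_low, -slope
    ssr = float(np.sum((_logistic(t, f_low, f_high, tm, slope) - f) ** 2))
    if f_high <= f_low:
        return MeltFit(tm, slope, f_low, f_high, ssr, False,
                       "fit is not an unfolding transition (f_high <= f_low)")
    if not (curve.temperatures[0] <= tm <= curve.temperatures[-1]):
        return MeltFit(tm, slope, f_low, f_high, ssr, False,
                       "inflection point outside the measured range")
    return MeltFit(float(tm), float(slope), float(f_low), float(f_high), ssr)
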