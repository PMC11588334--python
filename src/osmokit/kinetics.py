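"""Autocatalytic autophosphorylation kinetics with chloride inhibition.

Unphosphorylated WNK kinase domains activate by trans-autophosphorylation:
a phosphorylated molecule phosphorylates an unphosphorylated one,

    uWNK + pWNK -> pWNK + pWNK        (rate k_app * [u] * [p])

which gives logistic progress curves in the phosphorylated fraction.
Chloride inhibits; we model it as a rapid equilibrium that scales the rate
constant,

    k_app = k / (1 + [Cl-] / K_Cl)

(the algebraically identical alternative — chloride sequestering the
unphosphorylated species — gives the same progress curves, so the data
cannot distinguish them).  With total enzyme T and initial phosphorylated
seed p0 the ODE dp/dt = k_app (T - p) p has the closed form

    p(t) = T p0 e^{k_app T t} / (T - p0 + p0 e^{k_app T t})

A zero seed (p0 = 0) never starts: autocatalysis requires a nonzero initial
phosphorylated population, which is physically justified by incomplete
dephosphorylation of the enzyme preparation.  p0 is therefore a fitted
parameter, not fixed at zero.

Fitting follows the global-optimisation-then-local-refinement strategy of
progress-curve analysis tools: seeded differential evolution proposes
candidates, the best few are polished by least squares, and k, K_Cl, p0 are
shared across the chloride series of one enzyme while T is fixed at the
experimental concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import differential_evolution, least_squares

__all__ = [
    "AutocatParams",
    "ProgressCurve",
    "FitResult",
    "simulate_autocat",
    "simulate_autocat_ode",
    "fit_autocat",
    "phospho_fraction",
    "chloride_ic_profile",
]

DEFAULT_BOUNDS = {"k": (1e-5, 10.0), "K_Cl": (1.0, 5000.0), "p0_frac": (1e-5, 0.5)}


@dataclass(frozen=True)
class AutocatParams:
    """Parameters of the chloride-inhibited autocatalytic model.

    k : uM^-1 min^-1, intrinsic autocatalytic rate constant
    K_Cl : mM, chloride inhibition constant (larger = weaker binding)
    p0 : uM, initially phosphorylated enzyme (the autocatalytic seed)
    T : uM, total enzyme
    """

    k: float
    K_Cl: float
    p0: float
    T: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.K_Cl <= 0:
            raise ValueError("K_Cl must be > 0")
        if not (0 <= self.p0 <= self.T):
            raise ValueError("p0 must lie in [0, T]")

    def k_app(self, chloride_mM: float) -> float:
        return self.k / (1.0 + chloride_mM / self.K_Cl)


@dataclass(frozen=True)
class ProgressCurve:
    """One autophosphorylation time course at a fixed chloride concentration."""

    times: np.ndarray  # minutes, ascending
    fractions: np.ndarray  # phospho fraction in [0, 1]
    chloride: float  # total Cl-, mM
    enzyme_total: float  # uM
    site: str = "S308"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)
        if t.shape != f.shape:
            raise ValueError("times and fractions must have equal length")
        if np.any(np.diff(t) < 0) or np.any(t < 0):
            raise ValueError("times must be ascending and non-negative")
        if np.any((f < -1e-9) | (f > 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class FitResult:
    estimates: AutocatParams
    stderr: dict[str, float] | None
    ssr: float
    n_obs: int
    converged: bool
    per_curve_residuals: list[np.ndarray] = field(default_factory=list)
    message: str = ""


def simulate_autocat(params: AutocatParams, times: Sequence[float],
                     chloride: float) -> np.ndarray:
    """Closed-form phospho fraction p(t)/T of the autocatalytic model."""
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    if params.p0 == 0.0:
        return np.zeros_like(t)  # dead start: no seed, no autocatalysis
    ka = params.k_app(chloride)
    # p/T = p0 e^x / (T - p0 + p0 e^x), computed via the logistic for stability
    x = ka * params.T * t
    r = (params.T - params.p0) / params.p0
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + r * np.exp(-x))
    return frac


def simulate_autocat_ode(params: AutocatParams, times: Sequence[float],
                         chloride: float, rtol: float = 1e-10,
                         atol: float = 1e-12) -> np.ndarray:
    """Adaptive ODE integration of dp/dt = k_app (T - p) p; cross-check route."""
    t = np.asarray(times, dtype=float)
    ka = params.k_app(chloride)

    def rhs(_t, p):
        return ka * (params.T - p) * p

    t0, t1 = 0.0, float(t[-1]) if len(t) else 0.0
    sol = solve_ivp(rhs, (t0, max(t1, t0 + 1e-12)), [params.p0], t_eval=t,
                    rtol=rtol, atol=atol, method="LSODA", dense_output=False)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0] / params.T


def _residual_vector(theta: np.ndarray, curves: Sequence[ProgressCurve],
                     T: float) -> np.ndarray:
    k, kcl, p0 = theta
    params = AutocatParams(max(k, 0.0), max(kcl, 1e-9), min(max(p0, 0.0), T), T)
    res = [simulate_autocat(params, c.times, c.chloride) - c.fractions for c in curves]
    return np.concatenate(res)


def fit_autocat(curves: Sequence[ProgressCurve],
                init: AutocatParams | None = None,
                bounds: dict[str, tuple[float, float]] | None = None,
                seed: int = 0,
                de_maxiter: int = 150,
                n_polish: int = 5) -> FitResult:
    """Global least-squares fit of (k, K_Cl, p0) shared across a chloride series.

    T is fixed at the experimental total-enzyme concentration taken from the
    curves (which must agree).  Differential evolution (seeded, bounded)
    searches log-scaled parameters; the best candidates are refined by
    bounded least squares and the lowest-SSR refinement is returned with
    asymptotic standard errors from the Jacobian at the optimum.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one progress curve")
    Ts = {c.enzyme_total for c in curves}
    if len(Ts) != 1:
        raise ValueError("curves mix total-enzyme concentrations; fit them separately")
    T = Ts.pop()
    n_obs = sum(len(c.times) for c in curves)

    spans = [np.ptp(c.fractions) for c in curves]
    if max(spans) < 1e-3:
        return FitResult(init or AutocatParams(0.0, 1.0, 0.0, T), None,
                         float(np.sum(_residual_vector(np.zeros(3), curves, T) ** 2)),
                         n_obs, False, [],
                         "non-identifiable: no curve shows a time course "
                         "(flat/saturated fractions)")

    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b["k"][0], b["K_Cl"][0], b["p0_frac"][0] * T])
    hi = np.array([b["k"][1], b["K_Cl"][1], b["p0_frac"][1] * T])
    log_bounds = list(zip(np.log(lo), np.log(hi)))

    def obj(log_theta):
        r = _residual_vector(np.exp(log_theta), curves, T)
        return float(r @ r)

    rng = np.random.default_rng(seed)
    de = differential_evolution(obj, log_bounds, seed=rng, maxiter=de_maxiter,
                                popsize=15, tol=1e-10, polish=False, init="sobol")

    # polish the DE optimum plus the best remaining population members
    pop = getattr(de, "population", None)
    cands = [de.x]
    if pop is not None:
        energies = de.population_energies
        order = np.argsort(energies)
        cands += [pop[i] for i in order[:max(n_polish - 1, 0)]]
    if init is not None:
        cands.append(np.log(np.clip([init.k, init.K_Cl, init.p0], lo, hi)))

    best = None
    for x0 in cands:
        try:
            sol = least_squares(lambda lt: _residual_vector(np.exp(lt), curves, T),
                                x0, bounds=(np.log(lo), np.log(hi)),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        ssr = float(sol.fun @ sol.fun)
        if best is None or ssr < best[0]:
            best = (ssr, sol)
    if best is None:
        return FitResult(init or AutocatParams(0.0, 1.0, 0.0, T), None, np.inf,
                         n_obs, False, [], "all local refinements failed")
    ssr, sol = best
    k, kcl, p0 = np.exp(sol.x)
    est = AutocatParams(k, kcl, min(p0, T), T)

    stderr = None
    try:
        # J is w.r.t. log-params; chain rule back to the natural scale
        jac_nat = sol.jac @ np.diag(1.0 / np.exp(sol.x))
        dof = max(n_obs - 3, 1)
        s2 = ssr / dof
        cov = s2 * np.linalg.inv(jac_nat.T @ jac_nat)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        stderr = {"k": float(se[0]), "K_Cl": float(se[1]), "p0": float(se[2])}
    except np.linalg.LinAlgError:
        pass

    residuals = []
    i = 0
    full = _residual_vector(np.array([est.k, est.K_Cl, est.p0]), curves, T)
    for c in curves:
        residuals.append(full[i:i + len(c.times)])
        i += len(c.times)
    return FitResult(est, stderr, ssr, n_obs, True, residuals)


def phospho_fraction(trace_p: Sequence[tuple[float, float]],
                     trace_u: Sequence[tuple[float, float]]) -> float:
    """Phospho fraction from integrated extracted-ion chromatograms.

    ``trace_p``/``trace_u`` are (time, intensity) samples of the phospho-
    and unphospho-peptide ion traces; the fraction is the ratio of
    trapezoidal areas A_p / (A_p + A_u).
    """
    tp = np.asarray(trace_p, dtype=float)
    tu = np.asarray(trace_u, dtype=float)
    for name, tr in (("trace_p", tp), ("trace_u", tu)):
        if tr.ndim != 2 or tr.shape[1] != 2:
            raise ValueError(f"{name} must be a list of (time, intensity) pairs")
        if np.any(tr[:, 1] < 0):
            raise ValueError(f"{name} has negative intensities")
    a_p = float(np.trapezoid(tp[:, 1], tp[:, 0]))
    a_u = float(np.trapezoid(tu[:, 1], tu[:, 0]))
    if a_p + a_u == 0:
        raise ZeroDivisionError("both ion-trace integrals are zero: fraction undefined")
    return a_p / (a_p + a_u)


def chloride_ic_profile(fit: FitResult, chloride_grid: Sequence[float],
                        t_ref: float) -> np.ndarray:
    """Phospho fraction at a reference time across a chloride grid.

    Collapses a fitted chloride series to a single inhibition profile;
    monotone non-increasing in chloride for positive parameters.
    """
    if not fit.converged:
        raise ValueError("cannot profile an unconverged fit")
    return np.array([simulate_autocat(fit.estimates, [t_ref], cl)[0]
                     for cl in chloride_grid])
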