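"""Activation thermodynamics from rate or free-energy temperature series.

The central model is the macromolecular rate theory (MMRT) form of the
activation free energy with a constant activation heat capacity ΔCp‡::

    ΔG‡(T) = ΔH‡(T0) − T·ΔS‡(T0) + ΔCp‡·[(T − T0) − T·ln(T/T0)]

relative to an arbitrary reference temperature T0 (default 25 °C).  With
ΔCp‡ = 0 this reduces to the classical linear case and the Arrhenius plot
of ΔG‡/T against 1/T is a straight line; ΔCp‡ < 0 bends ΔG‡(T) toward a
minimum (d²ΔG‡/dT² = −ΔCp‡/T), so the rate plot curves and passes through
a temperature optimum that has nothing to do with unfolding.

Rates interconvert with activation free energies through the Eyring
transition-state expression k = (kB·T/h)·exp(−ΔG‡/RT) with transmission
coefficient 1; all fitting is done on free energies.  A van't Hoff fit of
ln K_eq against 1/T yields the enthalpy/entropy of a conformational
equilibrium such as an active/inactive ES ⇌ ES′ pre-equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import R, KB_OVER_H

__all__ = [
    "ArrheniusDataset",
    "ActivationParams",
    "VantHoffParams",
    "eq1_dg",
    "dg_from_rate",
    "rate_from_dg",
    "fit_linear_arrhenius",
    "fit_eq1",
    "vant_hoff_fit",
]


@dataclass(frozen=True)
class ArrheniusDataset:
    """Temperature series of activation free energies or rate constants.

    ``kind`` is ``'dg'`` (values in kcal/mol) or ``'rate'`` (values in s⁻¹).
    """

    T: np.ndarray
    values: np.ndarray
    kind: str = "dg"

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "values", v)
        if self.kind not in ("dg", "rate"):
            raise ValueError(f"kind must be 'dg' or 'rate', got {self.kind!r}")
        if T.size != v.size:
            raise ValueError("T and values must have equal length")
        if T.size < 2:
            raise ValueError("need at least 2 points")
        if np.any(T <= 0):
            raise ValueError("temperatures must be positive")
        if len(set(T.tolist())) != T.size:
            raise ValueError("temperatures must be pairwise distinct")
        if self.kind == "rate" and np.any(v <= 0):
            raise ValueError("rate constants must be positive")

    def __len__(self) -> int:
        return int(self.T.size)

    def as_dg(self) -> "ArrheniusDataset":
        """Convert rates to activation free energies via the Eyring transform."""
        if self.kind == "dg":
            return self
        return ArrheniusDataset(self.T, dg_from_rate(self.values, self.T), "dg")


@dataclass(frozen=True)
class ActivationParams:
    """Eq-1 / MMRT parameters: ΔH‡ and ΔS‡ at T0 plus a constant ΔCp‡."""

    dH_T0: float                  # kcal/mol
    dS_T0: float                  # kcal/mol/K
    dCp: float = 0.0              # kcal/mol/K
    T0: float = 298.15            # K
    r_squared: float | None = None
    param_stderrs: dict[str, float] | None = None
    converged: bool | None = None
    residuals: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.T0 > 0:
            raise ValueError(f"T0 must be positive, got {self.T0}")


@dataclass(frozen=True)
class VantHoffParams:
    """Equilibrium enthalpy/entropy from a linear van't Hoff fit."""

    dH_eq: float                  # kcal/mol
    dS_eq: float                  # kcal/mol/K
    r_squared: float | None = None


# ---------------------------------------------------------------------------
# Forward models and transforms
# ---------------------------------------------------------------------------

def eq1_dg(T, p: ActivationParams):
    """Activation free energy ΔG‡(T) of the MMRT model (kcal/mol).

    ``ΔH_T0 − T·ΔS_T0 + ΔCp·[(T − T0) − T·ln(T/T0)]``; vectorised over T.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    out = (
        p.dH_T0
        - T * p.dS_T0
        + p.dCp * ((T - p.T0) - T * np.log(T / p.T0))
    )
    return out if out.ndim else float(out)


def dg_from_rate(k, T):
    """Eyring transform: ΔG‡ = R·T·ln(kB·T/(h·k)) (kcal/mol), κ = 1."""
    k = np.asarray(k, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(k <= 0) or np.any(T <= 0):
        raise ValueError("rate and temperature must be positive")
    out = R * T * np.log(KB_OVER_H * T / k)
    return out if out.ndim else float(out)


def rate_from_dg(dg, T):
    """Inverse Eyring transform: k = (kB·T/h)·exp(−ΔG‡/(R·T)) (s⁻¹)."""
    dg = np.asarray(dg, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    out = KB_OVER_H * T * np.exp(-dg / (R * T))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

def fit_linear_arrhenius(ds: ArrheniusDataset, T0: float = 298.15) -> ActivationParams:
    """Linear Arrhenius fit: ΔG‡/T = ΔH‡·(1/T) − ΔS‡.

    Least squares of y = ΔG‡/T against x = 1/T; the slope is ΔH‡ and the
    negated intercept ΔS‡ (both temperature-independent, ΔCp‡ fixed at 0).
    ``r_squared`` refers to this regression, the form in which curvature of
    the plot is customarily judged.
    """
    ds = ds.as_dg()
    x = 1.0 / ds.T
    y = ds.values / ds.T
    if ds.T.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
        stderrs = None
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue ** 2)
        stderrs = {"dH_T0": float(res.stderr), "dS_T0": float(res.intercept_stderr)}
    p = ActivationParams(dH_T0=float(slope), dS_T0=float(-intercept), dCp=0.0, T0=T0,
                         r_squared=r2, param_stderrs=stderrs)
    resid = ds.values - eq1_dg(ds.T, p)
    return ActivationParams(**{**p.__dict__, "residuals": tuple(resid.tolist())})


def fit_eq1(
    ds: ArrheniusDataset,
    T0: float = 298.15,
    init: ActivationParams | None = None,
    weights: np.ndarray | None = None,
) -> ActivationParams:
    """Nonlinear fit of the MMRT model over (ΔH‡_T0, ΔS‡_T0, ΔCp‡).

    Rates are first converted to free energies.  The initial guess defaults
    to the linear Arrhenius fit with ΔCp‡ = 0.  Unweighted least squares
    unless ``weights`` (1/σ per point) is supplied.  Parameter standard
    errors come from the Jacobian-based covariance; ``r_squared`` reports the
    fraction of variance explained on the ΔG‡/T-vs-1/T plot, for direct
    comparison with the linear fit.
    """
    ds = ds.as_dg()
    if len(ds) < 4:
        raise ValueError(f"MMRT fit needs ≥ 4 points for 3 parameters, got {len(ds)}")
    if init is None:
        init = fit_linear_arrhenius(ds, T0=T0)
    p0 = [init.dH_T0, init.dS_T0, init.dCp]

    def model(T, dH, dS, dCp):
        return eq1_dg(T, ActivationParams(dH, dS, dCp, T0))

    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)
    try:
        popt, pcov = optimize.curve_fit(
            model, ds.T, ds.values, p0=p0, sigma=sigma, maxfev=20000
        )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError as exc:
        raise RuntimeError(f"MMRT fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 3
    fitted = ActivationParams(
        dH_T0=float(popt[0]), dS_T0=float(popt[1]), dCp=float(popt[2]), T0=T0,
        param_stderrs={"dH_T0": float(perr[0]), "dS_T0": float(perr[1]),
                       "dCp": float(perr[2])},
        converged=converged,
    )
    resid = ds.values - eq1_dg(ds.T, fitted)
    # r² on the Arrhenius-plot scale (ΔG/T vs 1/T).
    y = ds.values / ds.T
    yhat = eq1_dg(ds.T, fitted) / ds.T
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return ActivationParams(**{**fitted.__dict__, "r_squared": r2,
                               "residuals": tuple(resid.tolist())})


def vant_hoff_fit(T, K_eq) -> VantHoffParams:
    """van't Hoff fit: ln K_eq = −ΔH_eq/(R·T) + ΔS_eq/R.

    Least squares of ln K_eq against 1/T; the slope gives −ΔH_eq/R and the
    intercept ΔS_eq/R.
    """
    T = np.asarray(T, dtype=float)
    K = np.asarray(K_eq, dtype=float)
    if T.size != K.size or T.size < 2:
        raise ValueError("need matching T and K_eq arrays with ≥ 2 points")
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    if np.any(K <= 0):
        raise ValueError("equilibrium constants must be positive")
    if len(set(T.tolist())) != T.size:
        raise ValueError("temperatures must be pairwise distinct")
    x = 1.0 / T
    y = np.log(K)
    if T.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return VantHoffParams(dH_eq=float(-slope * R), dS_eq=float(intercept * R), r_squared=r2)
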