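"""Heat-capacity estimators and activation/binding bookkeeping.

Two standard routes give the constant-pressure heat capacity of a simulated
system from its energy time series:

* the **derivative** formula, ``Cp = d<H>/dT``, realised as the least-squares
  slope of the mean energy against the temperature setpoint over a small
  temperature grid, and
* the **fluctuation** formula, ``Cp = <δH²>/(R T²)``, realised per setpoint
  from the population variance of the energy and averaged over setpoints.

The enthalpy is approximated by the total energy of the simulated system
(the P·V term is negligible at ordinary pressures).  When only a potential
energy is available, the missing kinetic contribution is a constant
``N_df·R/2`` which is added back explicitly.

Error protocols follow common MD practice: two-block averaging (the full
estimator recomputed per block; for two blocks the error is half the
absolute block difference), the asymptotic standard error of the regression
slope (derivative route), and the s.e.m. of the per-temperature estimates
(fluctuation route).

Differences of heat capacities (transition state minus reactant state,
holo minus apo, ...) propagate each error type in quadrature.  The binding
cycle ``apo + ligand-in-water → holo + pure water`` is only meaningful when
the total number of degrees of freedom balances on both sides, since every
degree of freedom contributes to the absolute heat capacity; the bookkeeping
here checks that balance when counts are supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from math import sqrt

import numpy as np
from scipy import stats

from .constants import R
from .energy_io import EnergyTrajectory, TemperatureEnsemble, split_blocks

__all__ = [
    "CpEstimate",
    "BindingCycleResult",
    "mean_energy",
    "cp_derivative",
    "cp_fluctuation_single",
    "cp_fluctuation",
    "kinetic_correction",
    "cp_difference",
    "binding_cycle",
]


@dataclass(frozen=True)
class CpEstimate:
    """A heat-capacity value (kcal/mol/K) with method/component provenance.

    ``err_block`` is the block-averaging error, ``err_regression`` the
    asymptotic standard error of the derivative-formula slope, ``err_sem``
    the s.e.m. of per-temperature fluctuation estimates.  Absent errors are
    ``None``; present errors are ≥ 0.
    """

    value: float
    method: str                      # 'derivative' | 'fluctuation'
    component: str                   # 'e_tot' | 'u_tot' | 'u_group'
    kinetic_correction: float = 0.0
    err_block: float | None = None
    err_regression: float | None = None
    err_sem: float | None = None
    temperatures: tuple[float, ...] = ()
    n_samples_per_T: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in ("derivative", "fluctuation"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.component not in ("e_tot", "u_tot", "u_group", "ke"):
            raise ValueError(f"unknown component {self.component!r}")
        for name in ("err_block", "err_regression", "err_sem"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be ≥ 0, got {v}")
        if self.method == "derivative" and len(self.temperatures) > 1:
            if len(set(self.temperatures)) != len(self.temperatures):
                raise ValueError("derivative estimate requires distinct temperatures")

    @property
    def err(self) -> float:
        """Primary error: block if available, else s.e.m., else regression, else 0."""
        for v in (self.err_block, self.err_sem, self.err_regression):
            if v is not None:
                return v
        return 0.0

    def per_molecule(self, n_molecules: int) -> "CpEstimate":
        """Presentation helper: divide value and errors by a molecule count."""
        if n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        s = 1.0 / n_molecules
        return replace(
            self,
            value=self.value * s,
            kinetic_correction=self.kinetic_correction * s,
            err_block=None if self.err_block is None else self.err_block * s,
            err_regression=None if self.err_regression is None else self.err_regression * s,
            err_sem=None if self.err_sem is None else self.err_sem * s,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CpEstimate":
        d = json.loads(text)
        d["temperatures"] = tuple(d.get("temperatures", ()))
        d["n_samples_per_T"] = tuple(d.get("n_samples_per_T", ()))
        return cls(**d)


@dataclass(frozen=True)
class BindingCycleResult:
    """ΔCp of binding from the dof-balanced cycle apo + lig(aq) → holo + water."""

    cp_holo: CpEstimate
    cp_apo: CpEstimate
    cp_lig_solv: CpEstimate
    cp_pure_solv: CpEstimate
    delta_cp_bind: float
    err: float
    dof_balanced: bool | None
    dof_detail: dict[str, int] | None = None


# ---------------------------------------------------------------------------
# Means and kinetic bookkeeping
# ---------------------------------------------------------------------------

def mean_energy(
    traj: EnergyTrajectory, component: str = "e_tot", n_blocks: int = 2
) -> tuple[float, float]:
    """Mean of an energy component with a block standard error.

    The error is the standard deviation of the ``n_blocks`` block means over
    ``sqrt(n_blocks)``; for the default two blocks this is half the absolute
    difference of the two block means.
    """
    x = traj.component(component)
    blocks = split_blocks(traj, n_blocks)
    bmeans = np.array([float(np.mean(b.component(component))) for b in blocks])
    stderr = float(np.std(bmeans, ddof=1) / sqrt(n_blocks))
    return float(np.mean(x)), stderr


def kinetic_correction(n_df: int) -> float:
    """Heat capacity of the missing kinetic energy term, ``N_df·R/2`` (kcal/mol/K)."""
    if n_df < 0:
        raise ValueError(f"n_df must be ≥ 0, got {n_df}")
    return n_df * R / 2.0


def _resolve_kinetic(
    component: str, kinetic: str | int, n_df: int | None
) -> float:
    """Kinetic correction to apply for a given component/policy."""
    if kinetic == "none":
        return 0.0
    if component in ("e_tot", "ke"):
        return 0.0  # kinetic term already included / is the component itself
    if isinstance(kinetic, (int, np.integer)) and not isinstance(kinetic, bool):
        return kinetic_correction(int(kinetic))
    if kinetic == "auto":
        if n_df is None:
            raise ValueError(
                f"kinetic='auto' with component {component!r} needs n_df on the "
                "trajectories (or pass an explicit degree-of-freedom count)"
            )
        return kinetic_correction(n_df)
    raise ValueError(f"kinetic must be 'auto', 'none' or an integer, got {kinetic!r}")


# ---------------------------------------------------------------------------
# Derivative estimator (slope of <E> vs T)
# ---------------------------------------------------------------------------

def _slope(temps: np.ndarray, means: np.ndarray) -> tuple[float, float | None]:
    """LSQ slope and its asymptotic standard error (None for 2 points)."""
    if temps.size == 2:
        return float((means[1] - means[0]) / (temps[1] - temps[0])), None
    res = stats.linregress(temps, means)
    return float(res.slope), float(res.stderr)


def cp_derivative(
    ens: TemperatureEnsemble,
    component: str = "e_tot",
    kinetic: str | int = "auto",
    n_blocks: int = 2,
) -> CpEstimate:
    """Heat capacity as the slope of the mean energy over the setpoint grid.

    ``value`` is the least-squares slope of the per-run mean of ``component``
    against the setpoint temperature, plus the kinetic correction
    ``N_df·R/2`` when the component excludes kinetic energy and ``kinetic``
    is not ``'none'``.  ``err_regression`` is the asymptotic standard error
    of the slope (absent with only two temperatures); ``err_block`` redoes
    the whole regression on each of the ``n_blocks`` per-temperature blocks.
    """
    ens = ens.sorted()
    temps = ens.temperatures
    if temps.size < 2:
        raise ValueError("derivative estimator needs ≥ 2 temperatures")
    corr = _resolve_kinetic(component, kinetic, ens.n_df)

    means = np.array([float(np.mean(t.component(component))) for t in ens])
    slope, err_reg = _slope(temps, means)

    block_slopes = []
    for b in range(n_blocks):
        bmeans = np.array(
            [float(np.mean(split_blocks(t, n_blocks)[b].component(component))) for t in ens]
        )
        block_slopes.append(_slope(temps, bmeans)[0])
    err_block = float(np.std(block_slopes, ddof=1) / sqrt(n_blocks))

    return CpEstimate(
        value=slope + corr,
        method="derivative",
        component=component,
        kinetic_correction=corr,
        err_block=err_block,
        err_regression=err_reg,
        temperatures=tuple(float(t) for t in temps),
        n_samples_per_T=tuple(len(t) for t in ens),
    )


# ---------------------------------------------------------------------------
# Fluctuation estimator (<δE²>/RT²)
# ---------------------------------------------------------------------------

def cp_fluctuation_single(
    traj: EnergyTrajectory,
    component: str = "e_tot",
    kinetic: str | int = "auto",
    n_blocks: int | None = 2,
) -> CpEstimate:
    """Heat capacity from the energy variance of a single run.

    ``value = Var(component)/(R·T²) + kinetic correction`` with the
    population (1/N) variance and T the temperature setpoint.  ``err_block``
    recomputes the estimator per block when ``n_blocks`` is given.
    """
    x = traj.component(component)
    T = traj.temperature_setpoint
    corr = _resolve_kinetic(component, kinetic, traj.n_df)

    def _est(arr: np.ndarray) -> float:
        return float(np.var(arr) / (R * T * T))

    err_block = None
    if n_blocks is not None and len(traj) >= 2 * n_blocks:
        bvals = [_est(b.component(component)) for b in split_blocks(traj, n_blocks)]
        err_block = float(np.std(bvals, ddof=1) / sqrt(n_blocks))

    return CpEstimate(
        value=_est(x) + corr,
        method="fluctuation",
        component=component,
        kinetic_correction=corr,
        err_block=err_block,
        temperatures=(T,),
        n_samples_per_T=(len(traj),),
    )


def cp_fluctuation(
    ens: TemperatureEnsemble,
    component: str = "e_tot",
    kinetic: str | int = "auto",
) -> CpEstimate:
    """Fluctuation heat capacity averaged over the temperature grid.

    ``value`` is the unweighted mean of the per-temperature estimates and
    ``err_sem`` the standard error of that mean across temperatures.
    """
    ens = ens.sorted()
    singles = [
        cp_fluctuation_single(t, component=component, kinetic=kinetic, n_blocks=None)
        for t in ens
    ]
    vals = np.array([s.value for s in singles])
    sem = float(np.std(vals, ddof=1) / sqrt(vals.size))
    return CpEstimate(
        value=float(np.mean(vals)),
        method="fluctuation",
        component=component,
        kinetic_correction=singles[0].kinetic_correction,
        err_sem=sem,
        temperatures=tuple(ens.temperatures.tolist()),
        n_samples_per_T=tuple(len(t) for t in ens),
    )


# ---------------------------------------------------------------------------
# Differences and the binding cycle
# ---------------------------------------------------------------------------

def _quad(*errs: float | None) -> float | None:
    present = [e for e in errs if e is not None]
    if not present:
        return None
    return float(sqrt(sum(e * e for e in present)))


def _quad_strict(a: float | None, b: float | None) -> float | None:
    """Quadrature of a matched error pair; None unless both present."""
    if a is None or b is None:
        return None
    return float(sqrt(a * a + b * b))


def cp_difference(a: CpEstimate, b: CpEstimate) -> CpEstimate:
    """ΔCp = b − a (perturbed minus reference), errors in quadrature.

    Both estimates must carry the same method and component tags; differencing
    a derivative estimate against a fluctuation one (or e_tot against u_tot)
    is an apples-to-oranges comparison and raises.
    """
    if a.method != b.method or a.component != b.component:
        raise ValueError(
            f"cannot difference estimates with mismatched tags: "
            f"({a.method},{a.component}) vs ({b.method},{b.component})"
        )
    return CpEstimate(
        value=b.value - a.value,
        method=a.method,
        component=a.component,
        kinetic_correction=b.kinetic_correction - a.kinetic_correction,
        err_block=_quad_strict(a.err_block, b.err_block),
        err_regression=_quad_strict(a.err_regression, b.err_regression),
        err_sem=_quad_strict(a.err_sem, b.err_sem),
        temperatures=b.temperatures,
        n_samples_per_T=b.n_samples_per_T,
    )


def binding_cycle(
    cp_holo: CpEstimate,
    cp_apo: CpEstimate,
    cp_lig_solv: CpEstimate,
    cp_pure_solv: CpEstimate,
    dof: dict[str, int] | None = None,
) -> BindingCycleResult:
    """ΔCp of binding from apo-enzyme + ligand-in-water → holo-enzyme + pure water.

    ``delta_cp_bind = (Cp_holo + Cp_pure_water) − (Cp_apo + Cp_lig_in_water)``,
    the difference between the ligand's partial molar heat capacity in the
    enzyme and in water.  All four estimates must share method/component tags.
    When ``dof`` supplies degree-of-freedom counts (keys ``holo``, ``apo``,
    ``lig``, ``pure``), the cycle is checked for dof balance —
    ``dof_holo + dof_pure == dof_apo + dof_lig`` — and an imbalanced cycle
    raises, since each degree of freedom contributes to the absolute heat
    capacity and an unbalanced difference is ill-posed.
    """
    four = (cp_holo, cp_apo, cp_lig_solv, cp_pure_solv)
    tags = {(e.method, e.component) for e in four}
    if len(tags) != 1:
        raise ValueError(f"all four estimates must share method/component tags, got {tags}")

    dof_balanced: bool | None = None
    if dof is not None:
        missing = {"holo", "apo", "lig", "pure"} - set(dof)
        if missing:
            raise ValueError(f"dof counts missing keys: {sorted(missing)}")
        dof_balanced = (dof["holo"] + dof["pure"]) == (dof["apo"] + dof["lig"])
        if not dof_balanced:
            raise ValueError(
                "degree-of-freedom imbalance: holo+pure = "
                f"{dof['holo'] + dof['pure']} vs apo+lig = {dof['apo'] + dof['lig']}; "
                "the binding cycle is ill-posed"
            )

    delta = (cp_holo.value + cp_pure_solv.value) - (cp_apo.value + cp_lig_solv.value)
    err = _quad(*(e.err for e in four)) or 0.0
    return BindingCycleResult(
        cp_holo=cp_holo,
        cp_apo=cp_apo,
        cp_lig_solv=cp_lig_solv,
        cp_pure_solv=cp_pure_solv,
        delta_cp_bind=float(delta),
        err=err,
        dof_balanced=dof_balanced,
        dof_detail=dict(dof) if dof is not None else None,
    )
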