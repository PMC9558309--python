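"""Synthetic thermostatted dynamics with exact canonical oracles.

The toy system is an Einstein-crystal-style lattice: ``n`` independent
3-D particles, each coordinate moving in ``U(x) = ½k·x² + a₄·x⁴``.  For
``a₄ = 0`` the canonical heat capacity is analytic, ``Cv = 3nR``
(equipartition: R/2 kinetic + R/2 potential per coordinate), which makes
the lattice a transparent benchmark for the derivative and fluctuation
heat-capacity estimators and for thermostat artifacts:

* Langevin, Nosé–Hoover and stochastic velocity rescaling (v-rescale)
  sample the canonical ensemble — both estimators agree with 3nR;
* the Berendsen weak-coupling rescaling does not: its energy fluctuations
  are suppressed, increasingly so for larger relaxation time τ, so the
  fluctuation estimator undershoots while the derivative estimator is
  unaffected.

Integration is velocity Verlet.  Internal units: Å, fs, g/mol, with
energies converted to kcal/mol on output (1 kcal/mol = 4.184e−4
g/mol·Å²/fs²).

The module also houses the small forward models used to generate synthetic
kinetics data: the MMRT ΔG‡(T) generator with Gaussian noise, the
two-state (active ⇌ inactive ES′) observed-rate generator, and the
two-state empirical valence bond energy expressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .constants import R, KCAL_TO_MD, MD_TO_KCAL
from .energy_io import EnergyTrajectory
from .kinetics import (
    ActivationParams,
    ArrheniusDataset,
    eq1_dg,
    rate_from_dg,
)

__all__ = [
    "ToySystem",
    "ThermostatConfig",
    "EVBState",
    "build_harmonic_lattice",
    "simulate",
    "instantaneous_temperature",
    "canonical_cv_oracle",
    "evb_ground_energy",
    "evb_fixed_mix",
    "gen_eq1_dataset",
    "gen_two_state_rates",
]

THERMOSTATS = ("none", "berendsen", "nose_hoover", "langevin", "v_rescale")
_STOCHASTIC = ("langevin", "v_rescale")


@dataclass(frozen=True)
class ToySystem:
    """Independent 3-D oscillators with per-coordinate ½k·x² + a₄·x⁴.

    The spring constants carry a small deterministic log-spread
    (``k_dispersion``, default ±25%) across coordinates.  The canonical
    heat capacity of a harmonic coordinate is R independent of its
    frequency, so the analytic oracle is untouched, but the dispersion
    removes the resonance degeneracy that makes identical uncoupled
    oscillators pathologically non-ergodic under global deterministic
    thermostats (the classic Nosé–Hoover failure mode).

    Defaults give ω·dt ≈ 0.06 at dt = 1 fs for the stiffest coordinate
    (k = 72 kcal/mol/Å², m = 12 g/mol), comfortably inside the
    velocity-Verlet stability region.
    """

    n_particles: int
    mass: float = 12.0          # g/mol
    k_spring: float = 72.0      # kcal/mol/Å²
    a_quartic: float = 0.0      # kcal/mol/Å⁴
    dimensions: int = 3
    k_dispersion: float = 0.25  # fractional log-spread of spring constants

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be ≥ 1")
        if self.mass <= 0 or self.k_spring <= 0:
            raise ValueError("mass and k_spring must be positive")
        if self.a_quartic < 0:
            raise ValueError("a_quartic must be ≥ 0")
        if self.k_dispersion < 0:
            raise ValueError("k_dispersion must be ≥ 0")

    @property
    def n_df(self) -> int:
        return self.dimensions * self.n_particles

    @property
    def spring_constants(self) -> np.ndarray:
        """Per-coordinate spring constants, shape (n_particles, dimensions)."""
        m = self.n_particles * self.dimensions
        d = np.log1p(self.k_dispersion)
        facs = np.exp(np.linspace(-d, d, m)) if m > 1 else np.ones(1)
        return (self.k_spring * facs).reshape(self.n_particles, self.dimensions)

    @property
    def omega(self) -> float:
        """Largest angular frequency of the harmonic part, fs⁻¹."""
        kmax = self.k_spring * (1.0 + self.k_dispersion)
        return float(np.sqrt(kmax * KCAL_TO_MD / self.mass))

    @property
    def analytic_cp(self) -> float | None:
        """Exact canonical heat capacity, kcal/mol/K (None when anharmonic)."""
        if self.a_quartic == 0.0:
            return 3.0 * self.n_particles * R
        return None


@dataclass(frozen=True)
class ThermostatConfig:
    """Thermostat choice and coupling parameters.

    ``tau`` is the relaxation time in fs; ``couple_interval`` the number of
    integrator steps between thermostat applications; ``seed`` is required
    for the stochastic kinds (langevin, v_rescale).
    """

    kind: str = "langevin"
    tau: float = 100.0
    couple_interval: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in THERMOSTATS:
            raise ValueError(f"kind must be one of {THERMOSTATS}, got {self.kind!r}")
        if self.kind != "none" and not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.couple_interval < 1:
            raise ValueError("couple_interval must be ≥ 1")


def build_harmonic_lattice(
    n: int, mass: float = 12.0, k_spring: float = 72.0, a_quartic: float = 0.0
) -> ToySystem:
    """Construct the Einstein-crystal toy system (see :class:`ToySystem`)."""
    return ToySystem(n_particles=n, mass=mass, k_spring=k_spring, a_quartic=a_quartic)


def instantaneous_temperature(ke: float, n_df: int) -> float:
    """Kinetic temperature 2·KE/(N_df·R) in K, with KE in kcal/mol."""
    if n_df < 1:
        raise ValueError("n_df must be ≥ 1")
    return 2.0 * ke / (n_df * R)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(
    sys: ToySystem,
    th: ThermostatConfig,
    T: float,
    n_steps: int,
    dt: float = 1.0,
    sample_every: int = 10,
    seed: int | None = None,
    label: str | None = None,
) -> EnergyTrajectory:
    """Integrate the lattice under a thermostat; return the energy series.

    Velocity Verlet with the thermostat applied every ``couple_interval``
    steps:

    * ``berendsen`` — velocity scaling λ = √(1 + (m_c·dt/τ)(T₀/T_inst − 1));
    * ``nose_hoover`` — a massive Nosé–Hoover chain: every degree of
      freedom carries its own two-variable chain with Q = R·T·τ² and
      half-step friction updates.  A single global chain is non-ergodic on
      uncoupled oscillators; per-dof chains with τ near the vibrational
      period restore canonical sampling;
    * ``langevin`` — BAOAB splitting with the exact Ornstein–Uhlenbeck
      velocity update, friction γ = 1/τ;
    * ``v_rescale`` — stochastic kinetic-energy rescaling (Bussi et al.)
      with relaxation time τ;
    * ``none`` — plain NVE (microcanonical).

    Initial positions/velocities are drawn from the canonical distribution
    at T.  Output is sampled every ``sample_every`` steps; runs are
    bit-reproducible given (seed, parameters).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if sys.omega * dt > 0.2:
        raise ValueError(
            f"ω·dt = {sys.omega * dt:.3f} > 0.2: integration would be unstable; "
            "reduce dt or k_spring"
        )
    if th.kind in _STOCHASTIC and seed is None and th.seed is None:
        raise ValueError(f"thermostat {th.kind!r} is stochastic: a seed is required")
    rng = np.random.default_rng(seed if seed is not None else th.seed)

    n, m, a4 = sys.n_particles, sys.mass, sys.a_quartic
    k = sys.spring_constants                 # (n, dim), kcal/mol/Å²
    n_df = sys.n_df
    kT_md = R * T * KCAL_TO_MD           # internal energy units
    shape = (n, sys.dimensions)

    # Canonical initial conditions (harmonic part only for positions when a4>0,
    # which still equilibrates within a few periods).
    x = rng.normal(0.0, 1.0, shape) * np.sqrt(R * T / k)  # Å

    v = rng.normal(0.0, np.sqrt(kT_md / m), shape)

    def force(x):
        return -(k * x + 4.0 * a4 * x**3) * KCAL_TO_MD  # internal force units

    def pot(x):
        return float(np.sum(0.5 * k * x * x + a4 * x**4))  # kcal/mol

    def kin(v):
        return 0.5 * m * float(np.sum(v * v)) * MD_TO_KCAL  # kcal/mol

    mc = th.couple_interval
    dt_c = mc * dt
    target_ke = 0.5 * n_df * R * T       # kcal/mol

    # Massive Nosé–Hoover chain (length 2, one chain per degree of freedom).
    q1 = R * T * th.tau**2               # kcal/mol·fs² per dof
    q2 = R * T * th.tau**2
    xi1 = np.zeros(shape)
    xi2 = np.zeros(shape)

    # Langevin (BAOAB) constants.
    if th.kind == "langevin":
        gamma = 1.0 / th.tau
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kT_md / m)

    def nhc_half(v, xi1, xi2):
        """Half-step massive-chain update; returns (scaled v, xi1, xi2).

        Each degree of freedom carries its own two-variable chain — the
        standard remedy for the non-ergodicity of harmonic modes under a
        single global thermostat.
        """
        ke2 = m * v * v * MD_TO_KCAL          # 2·KE per dof, kcal/mol
        g2 = (q1 * xi1 * xi1 - R * T) / q2
        xi2 = xi2 + 0.25 * dt_c * g2
        xi1 = xi1 * np.exp(-0.125 * dt_c * xi2)
        g1 = (ke2 - R * T) / q1
        xi1 = xi1 + 0.25 * dt_c * g1
        xi1 = xi1 * np.exp(-0.125 * dt_c * xi2)
        s = np.exp(-0.5 * dt_c * xi1)
        v = v * s
        ke2 = ke2 * s * s
        xi1 = xi1 * np.exp(-0.125 * dt_c * xi2)
        g1 = (ke2 - R * T) / q1
        xi1 = xi1 + 0.25 * dt_c * g1
        xi1 = xi1 * np.exp(-0.125 * dt_c * xi2)
        g2 = (q1 * xi1 * xi1 - R * T) / q2
        xi2 = xi2 + 0.25 * dt_c * g2
        return v, xi1, xi2

    n_samples = n_steps // sample_every
    time = np.empty(n_samples)
    e_tot = np.empty(n_samples)
    u_arr = np.empty(n_samples)
    ke_arr = np.empty(n_samples)

    f = force(x)
    isample = 0
    for step in range(1, n_steps + 1):
        couple = th.kind != "none" and step % mc == 0

        if th.kind == "nose_hoover" and couple:
            v, xi1, xi2 = nhc_half(v, xi1, xi2)

        if th.kind == "langevin":
            # BAOAB: B half-kick, A half-drift, O, A half-drift, B half-kick.
            v = v + 0.5 * dt * f / m
            x = x + 0.5 * dt * v
            v = c1 * v + c2 * rng.standard_normal(shape)
            x = x + 0.5 * dt * v
            f = force(x)
            v = v + 0.5 * dt * f / m
        else:
            v = v + 0.5 * dt * f / m
            x = x + dt * v
            f = force(x)
            v = v + 0.5 * dt * f / m

        if couple:
            if th.kind == "berendsen":
                ke = kin(v)
                t_inst = instantaneous_temperature(ke, n_df)
                lam2 = 1.0 + (dt_c / th.tau) * (T / t_inst - 1.0)
                v = v * np.sqrt(max(lam2, 0.0))
            elif th.kind == "v_rescale":
                ke = kin(v)
                c = np.exp(-dt_c / th.tau)
                r1 = rng.standard_normal()
                rsum = r1 * r1 + (rng.chisquare(n_df - 1) if n_df > 1 else 0.0)
                ke_new = (
                    ke * c
                    + target_ke / n_df * (1.0 - c) * rsum
                    + 2.0 * r1 * np.sqrt(ke * c * target_ke / n_df * (1.0 - c))
                )
                v = v * np.sqrt(max(ke_new, 0.0) / ke)
            elif th.kind == "nose_hoover":
                v, xi1, xi2 = nhc_half(v, xi1, xi2)

        if step % sample_every == 0:
            u = pot(x)
            ke = kin(v)
            if not np.isfinite(u) or u + ke > 1e6:
                raise RuntimeError(
                    f"integration unstable at step {step}: E = {u + ke:.3g} kcal/mol"
                )
            time[isample] = step * dt / 1000.0  # ps
            u_arr[isample] = u
            ke_arr[isample] = ke
            e_tot[isample] = u + ke
            isample += 1

    return EnergyTrajectory(
        temperature_setpoint=T,
        time=time,
        e_tot=e_tot,
        u_tot=u_arr,
        ke=ke_arr,
        timestep=dt,
        n_df=n_df,
        label=label or f"{th.kind} tau={th.tau} T={T}",
    )


# ---------------------------------------------------------------------------
# Exact canonical oracle
# ---------------------------------------------------------------------------

def canonical_cv_oracle(sys: ToySystem, T: float) -> float:
    """Exact canonical heat capacity by 1-D quadrature, kcal/mol/K.

    Per coordinate, the potential contribution is Var(U)/(R·T²) under the
    Boltzmann weight exp(−U/RT) (identical to d⟨U⟩/dT), evaluated by
    adaptive quadrature; the kinetic contribution is exactly R/2.  For the
    purely harmonic lattice this returns 3nR to quadrature accuracy; the
    large-a₄ limit of the potential part per coordinate is R/4.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    a4 = sys.a_quartic
    if a4 == 0.0:
        return 3.0 * sys.n_particles * R

    beta = 1.0 / (R * T)

    def cv_coord(k: float) -> float:
        # The distribution width is set by the stiffer (more confining) term;
        # u(x) ≥ each term separately, so 8 thermal widths of the narrower
        # scale bound the support of the Boltzmann weight.
        w = 8.0 * min(np.sqrt(R * T / k), (R * T / a4) ** 0.25)

        def u(x):
            return 0.5 * k * x * x + a4 * x**4

        def boltz(x):
            return np.exp(-beta * u(x))

        kw = dict(limit=400, points=[0.0], epsabs=0.0, epsrel=1e-11)
        z, z_err = integrate.quad(boltz, -w, w, **kw)
        m1, _ = integrate.quad(lambda x: u(x) * boltz(x), -w, w, **kw)
        m2, _ = integrate.quad(lambda x: u(x) ** 2 * boltz(x), -w, w, **kw)
        if z <= 0 or z_err / z > 1e-8:
            raise RuntimeError("quadrature did not converge")
        mean_u = m1 / z
        var_u = m2 / z - mean_u * mean_u
        return var_u / (R * T * T) + R / 2.0

    ks = sys.spring_constants.ravel()
    return float(sum(cv_coord(float(k)) for k in ks))


# ---------------------------------------------------------------------------
# EVB two-state energies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EVBState:
    """Diabatic energies ε₁/ε₂, coupling H₁₂ and a fixed mixing weight c₁²."""

    e1: float
    e2: float
    h12: float = 0.0
    c1_sq: float = 0.5

    def __post_init__(self) -> None:
        if self.h12 < 0:
            raise ValueError("h12 must be ≥ 0")
        if not 0.0 <= self.c1_sq <= 1.0:
            raise ValueError("c1_sq must lie in [0, 1]")


def evb_ground_energy(s: EVBState) -> float:
    """Ground-state energy of the 2×2 secular problem.

    ``E_g = ½(ε₁+ε₂) − ½√((ε₁−ε₂)² + 4·H₁₂²)``; reduces to min(ε₁, ε₂)
    for H₁₂ = 0 and to ε − H₁₂ in the degenerate case ε₁ = ε₂ = ε.
    """
    gap = s.e1 - s.e2
    return 0.5 * (s.e1 + s.e2) - 0.5 * float(np.sqrt(gap * gap + 4.0 * s.h12 * s.h12))


def evb_fixed_mix(s: EVBState) -> float:
    """Fixed-coefficient approximation ``c₁²·ε₁ + (1−c₁²)·ε₂``.

    With c₁² = c₂² = 0.5 this is the force-field transition-state surface
    ½(ε₁+ε₂); it exceeds the true ground-state energy by
    ½√((ε₁−ε₂)² + 4H₁₂²).
    """
    return s.c1_sq * s.e1 + (1.0 - s.c1_sq) * s.e2


# ---------------------------------------------------------------------------
# Kinetics dataset generators
# ---------------------------------------------------------------------------

def gen_eq1_dataset(
    p: ActivationParams,
    temps,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ArrheniusDataset:
    """ΔG‡(T) dataset from the MMRT forward model with Gaussian noise."""
    temps = np.asarray(temps, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    dg = eq1_dg(temps, p)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dg = dg + rng.normal(0.0, noise_sd, temps.shape)
    return ArrheniusDataset(temps, dg, "dg")


def gen_two_state_rates(
    chem: ActivationParams,
    dH_eq: float,
    dS_eq: float,
    temps,
) -> ArrheniusDataset:
    """Observed rates when the reactive state equilibrates with an inactive one.

    The ES complex pre-equilibrates with an inactive ES′ state
    (K_inact(T) = exp(−(ΔH_eq − T·ΔS_eq)/(R·T))), so only the active
    fraction 1/(1+K_inact) crosses the chemical barrier::

        k_obs(T) = k_TST(T; chem) / (1 + K_inact(T))

    With ΔH_eq, ΔS_eq > 0 the inactive state takes over above
    T* = ΔH_eq/ΔS_eq, producing a rate optimum and a convex Arrhenius plot
    without any activation heat capacity.
    """
    temps = np.asarray(temps, dtype=float)
    k_tst = rate_from_dg(eq1_dg(temps, chem), temps)
    k_inact = np.exp(-(dH_eq - temps * dS_eq) / (R * temps))
    return ArrheniusDataset(temps, k_tst / (1.0 + k_inact), "rate")
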