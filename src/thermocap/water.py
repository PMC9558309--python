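"""Compact rigid-water (TIP3P) MD engine for heat-capacity benchmarks.

Liquid water is the standard benchmark for heat-capacity estimators, and
this module generates the required energy time series self-contained: a
periodic cubic box of rigid TIP3P molecules integrated with velocity
Verlet at a 2 fs timestep, SHAKE/RATTLE bond constraints, molecule-based
cutoff electrostatics and Lennard-Jones interactions (minimum image, no
mesh Ewald), a Berendsen or Nosé–Hoover thermostat, and an isotropic
Monte Carlo barostat for constant-pressure sampling.

Scope: this is a benchmark generator, not a production MD code.  It
supports exactly one solvent model (TIP3P), cubic periodic boxes and plain
truncation of the potential.  Truncated electrostatics raise the computed
heat capacity slightly relative to mesh-Ewald treatments (the same trend
reported for cutoff versus PME boxes), which is well inside the statistical
resolution of desk-scale runs.

All energies are returned in kcal/mol on :class:`~thermocap.energy_io.EnergyTrajectory`
objects ready for the estimators in :mod:`thermocap.cp_estimators`.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.spatial.transform import Rotation

from .constants import BAR_TO_KCAL_PER_A3, COULOMB_KCAL, KCAL_TO_MD, MD_TO_KCAL, R
from .energy_io import EnergyTrajectory

__all__ = ["simulate_water", "water_box"]

# TIP3P parameters.
_Q = np.array([-0.834, 0.417, 0.417])
_EPS_OO = 0.1521          # kcal/mol
_SIG_OO = 3.15061         # Å
_MASS = np.array([15.9994, 1.008, 1.008])   # g/mol
_R_OH = 0.9572            # Å
_ANGLE = np.deg2rad(104.52)
_R_HH = 2.0 * _R_OH * np.sin(_ANGLE / 2.0)
_M_WATER = float(_MASS.sum())

# Constraint table: atom pairs and squared target distances.
_C_PAIRS = np.array([[0, 1], [0, 2], [1, 2]], dtype=np.int64)
_C_D2 = np.array([_R_OH**2, _R_OH**2, _R_HH**2])

_A_LJ = 4.0 * _EPS_OO * _SIG_OO**12
_B_LJ = 4.0 * _EPS_OO * _SIG_OO**6


@njit(cache=True, fastmath=True)
def _forces(pos, L, rcut2, q, f):
    """Potential energy (kcal/mol) and forces (kcal/mol/Å) in-place.

    Molecule-based cutoff on the O–O minimum-image distance: if two
    molecules interact, all nine site pairs are computed with the same
    periodic shift, so molecules are never split across the cutoff.
    Electrostatics use the reaction-field form with a conducting boundary
    (U ∝ 1/r + r²/(2·r_c³) − 3/(2·r_c)) and the O–O Lennard-Jones term is
    shifted to zero at the cutoff.  The whole molecule-pair energy is
    additionally tapered by a switching function S(r_OO) over the final
    1 Å before the cutoff, so the potential is exactly continuous as
    molecules cross it: NVE dynamics conserve energy and thermostatted
    runs are not polluted by cutoff heating.
    """
    n = pos.shape[0]
    f[:] = 0.0
    u = 0.0
    rcut = np.sqrt(rcut2)
    rs = rcut - 1.0                     # switching region start
    rs2 = rs * rs
    sw_denom = (rcut2 - rs2) ** 3
    krf = 0.5 / (rcut2 * rcut)          # reaction-field quadratic coefficient
    crf = 1.5 / rcut                    # shift making U(r_c) = 0
    inv2c = 1.0 / rcut2
    inv6c = inv2c * inv2c * inv2c
    u_lj_cut = (_A_LJ * inv6c - _B_LJ) * inv6c
    for i in range(n - 1):
        oix = pos[i, 0, 0]
        oiy = pos[i, 0, 1]
        oiz = pos[i, 0, 2]
        for j in range(i + 1, n):
            dx = oix - pos[j, 0, 0]
            dy = oiy - pos[j, 0, 1]
            dz = oiz - pos[j, 0, 2]
            sx = L * np.floor(dx / L + 0.5)
            sy = L * np.floor(dy / L + 0.5)
            sz = L * np.floor(dz / L + 0.5)
            dx -= sx
            dy -= sy
            dz -= sz
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rcut2:
                continue
            # CHARMM-style switch on the O-O distance
            if r2 > rs2:
                sw = (rcut2 - r2) ** 2 * (rcut2 + 2.0 * r2 - 3.0 * rs2) / sw_denom
                # dS/dr divided by r
                dsw_r = 12.0 * (rcut2 - r2) * (rs2 - r2) / sw_denom
            else:
                sw = 1.0
                dsw_r = 0.0
            # O-O Lennard-Jones, shifted to zero at the cutoff
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            u_pair = (_A_LJ * inv6 - _B_LJ) * inv6 - u_lj_cut
            flj = sw * (12.0 * _A_LJ * inv6 - 6.0 * _B_LJ) * inv6 * inv2
            f[i, 0, 0] += flj * dx
            f[i, 0, 1] += flj * dy
            f[i, 0, 2] += flj * dz
            f[j, 0, 0] -= flj * dx
            f[j, 0, 1] -= flj * dy
            f[j, 0, 2] -= flj * dz
            # all site-site reaction-field Coulomb with the molecule shift
            for a in range(3):
                ax = pos[i, a, 0]
                ay = pos[i, a, 1]
                az = pos[i, a, 2]
                qa = q[a]
                for b in range(3):
                    bx = ax - pos[j, b, 0] - sx
                    by = ay - pos[j, b, 1] - sy
                    bz = az - pos[j, b, 2] - sz
                    rr2 = bx * bx + by * by + bz * bz
                    rinv = 1.0 / np.sqrt(rr2)
                    qq = COULOMB_KCAL * qa * q[b]
                    u_pair += qq * (rinv + krf * rr2 - crf)
                    fc = sw * qq * (rinv * rinv * rinv - 2.0 * krf)
                    f[i, a, 0] += fc * bx
                    f[i, a, 1] += fc * by
                    f[i, a, 2] += fc * bz
                    f[j, b, 0] -= fc * bx
                    f[j, b, 1] -= fc * by
                    f[j, b, 2] -= fc * bz
            u += sw * u_pair
            if dsw_r != 0.0:
                # -U_pair * dS/dr acting along the O-O axis
                gx = -u_pair * dsw_r * dx
                gy = -u_pair * dsw_r * dy
                gz = -u_pair * dsw_r * dz
                f[i, 0, 0] += gx
                f[i, 0, 1] += gy
                f[i, 0, 2] += gz
                f[j, 0, 0] -= gx
                f[j, 0, 1] -= gy
                f[j, 0, 2] -= gz
    return u


@njit(cache=True)
def _shake(pos, pos_old, vel, invm, dt, tol, maxiter):
    """SHAKE position constraints with matching velocity corrections."""
    n = pos.shape[0]
    for i in range(n):
        for _ in range(maxiter):
            done = True
            for c in range(3):
                a = _C_PAIRS[c, 0]
                b = _C_PAIRS[c, 1]
                rx = pos[i, a, 0] - pos[i, b, 0]
                ry = pos[i, a, 1] - pos[i, b, 1]
                rz = pos[i, a, 2] - pos[i, b, 2]
                diff = rx * rx + ry * ry + rz * rz - _C_D2[c]
                if abs(diff) > tol * _C_D2[c]:
                    done = False
                    sx = pos_old[i, a, 0] - pos_old[i, b, 0]
                    sy = pos_old[i, a, 1] - pos_old[i, b, 1]
                    sz = pos_old[i, a, 2] - pos_old[i, b, 2]
                    dot = rx * sx + ry * sy + rz * sz
                    g = diff / (2.0 * dot * (invm[a] + invm[b]))
                    ga = g * invm[a]
                    gb = g * invm[b]
                    pos[i, a, 0] -= ga * sx
                    pos[i, a, 1] -= ga * sy
                    pos[i, a, 2] -= ga * sz
                    pos[i, b, 0] += gb * sx
                    pos[i, b, 1] += gb * sy
                    pos[i, b, 2] += gb * sz
                    vel[i, a, 0] -= ga * sx / dt
                    vel[i, a, 1] -= ga * sy / dt
                    vel[i, a, 2] -= ga * sz / dt
                    vel[i, b, 0] += gb * sx / dt
                    vel[i, b, 1] += gb * sy / dt
                    vel[i, b, 2] += gb * sz / dt
            if done:
                break


@njit(cache=True)
def _rattle_velocities(pos, vel, invm, maxiter):
    """Project velocities onto the constraint manifold (r_ab · v_ab = 0)."""
    n = pos.shape[0]
    for i in range(n):
        for _ in range(maxiter):
            done = True
            for c in range(3):
                a = _C_PAIRS[c, 0]
                b = _C_PAIRS[c, 1]
                rx = pos[i, a, 0] - pos[i, b, 0]
                ry = pos[i, a, 1] - pos[i, b, 1]
                rz = pos[i, a, 2] - pos[i, b, 2]
                vx = vel[i, a, 0] - vel[i, b, 0]
                vy = vel[i, a, 1] - vel[i, b, 1]
                vz = vel[i, a, 2] - vel[i, b, 2]
                rv = rx * vx + ry * vy + rz * vz
                if abs(rv) > 1e-12:
                    done = False
                    kk = rv / (_C_D2[c] * (invm[a] + invm[b]))
                    ka = kk * invm[a]
                    kb = kk * invm[b]
                    vel[i, a, 0] -= ka * rx
                    vel[i, a, 1] -= ka * ry
                    vel[i, a, 2] -= ka * rz
                    vel[i, b, 0] += kb * rx
                    vel[i, b, 1] += kb * ry
                    vel[i, b, 2] += kb * rz
            if done:
                break


def water_box(n_molecules: int, density: float, rng: np.random.Generator):
    """Initial configuration: cubic lattice of randomly oriented molecules.

    Returns (positions (N,3,3) Å, box side L Å) at the requested mass
    density (g/cm³).
    """
    # 1 g/cm³ = 0.60221408 g/mol/Å³
    vol = n_molecules * _M_WATER / (density * 0.60221408)
    L = vol ** (1.0 / 3.0)
    nc = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    spacing = L / nc
    ref = np.array(
        [
            [0.0, 0.0, 0.0],
            [_R_OH * np.sin(_ANGLE / 2), _R_OH * np.cos(_ANGLE / 2), 0.0],
            [-_R_OH * np.sin(_ANGLE / 2), _R_OH * np.cos(_ANGLE / 2), 0.0],
        ]
    )
    sites = []
    for ix in range(nc):
        for iy in range(nc):
            for iz in range(nc):
                sites.append((ix, iy, iz))
                if len(sites) == n_molecules:
                    break
            else:
                continue
            break
        else:
            continue
        break
    rots = Rotation.random(n_molecules, random_state=np.random.RandomState(
        int(rng.integers(0, 2**31 - 1))))
    pos = np.empty((n_molecules, 3, 3))
    for i, (ix, iy, iz) in enumerate(sites):
        center = (np.array([ix, iy, iz]) + 0.5) * spacing
        pos[i] = center + rots[i].apply(ref)
    return pos, L


def _kinetic(vel: np.ndarray) -> float:
    return 0.5 * float(np.sum(_MASS[None, :, None] * vel * vel)) * MD_TO_KCAL


def _init_velocities(n: int, T: float, rng: np.random.Generator) -> np.ndarray:
    sigma = np.sqrt(R * T * KCAL_TO_MD / _MASS)          # Å/fs per atom type
    vel = rng.standard_normal((n, 3, 3)) * sigma[None, :, None]
    # remove net momentum
    ptot = np.sum(_MASS[None, :, None] * vel, axis=(0, 1))
    vel -= ptot / (n * _M_WATER)
    return vel


def simulate_water(
    n_molecules: int = 216,
    T: float = 300.0,
    thermostat: str = "berendsen",
    tau: float = 100.0,
    n_steps: int = 20000,
    dt: float = 2.0,
    sample_every: int = 25,
    seed: int | None = 0,
    pressure_bar: float = 1.0,
    barostat: bool = True,
    baro_every: int = 20,
    rcut: float = 8.0,
    equil_steps: int = 5000,
    density: float = 0.997,
    label: str | None = None,
    diagnostics: dict | None = None,
) -> EnergyTrajectory:
    """Run a periodic rigid-TIP3P box and return its energy time series.

    The run starts from a lattice configuration, equilibrates for
    ``equil_steps`` steps under a strongly coupled Berendsen thermostat
    (τ = 10 fs), then collects ``n_steps`` production steps under the
    requested thermostat (``'berendsen'``, ``'nose_hoover'`` or ``'none'``)
    with an isotropic Monte Carlo barostat at ``pressure_bar`` (disable with
    ``barostat=False`` for NVT/NVE).  Deterministic for a given seed.

    Returns an :class:`EnergyTrajectory` with e_tot/u_tot/ke in kcal/mol and
    ``n_df = 6·N − 3`` (three constraints per rigid molecule, zero total
    momentum).
    """
    if thermostat not in ("berendsen", "nose_hoover", "none"):
        raise ValueError(f"unsupported thermostat {thermostat!r}")
    if n_molecules < 2:
        raise ValueError("need at least 2 molecules")
    rng = np.random.default_rng(seed)

    pos, L = water_box(n_molecules, density, rng)
    vel = _init_velocities(n_molecules, T, rng)
    _rattle_velocities(pos, vel, 1.0 / _MASS, 50)

    n_df = 6 * n_molecules - 3
    invm = 1.0 / _MASS
    f = np.zeros_like(pos)
    pressure = pressure_bar * BAR_TO_KCAL_PER_A3

    state = {"L": L, "u": _forces(pos, L, rcut * rcut, _Q, f)}
    xi = 0.0
    q_nh = n_df * R * T * tau * tau      # kcal/mol fs²

    def nh_half(ke: float) -> float:
        nonlocal xi
        xi += 0.25 * dt * (2.0 * ke - n_df * R * T) / q_nh
        s = np.exp(-0.5 * dt * xi)
        vel[:] *= s
        ke *= s * s
        xi += 0.25 * dt * (2.0 * ke - n_df * R * T) / q_nh
        return ke

    def vv_step():
        a = f * (KCAL_TO_MD * invm[None, :, None])
        vel[:] += 0.5 * dt * a
        pos_old = pos.copy()
        pos[:] += dt * vel
        _shake(pos, pos_old, vel, invm, dt, 1e-8, 50)
        state["u"] = _forces(pos, state["L"], rcut * rcut, _Q, f)
        a = f * (KCAL_TO_MD * invm[None, :, None])
        vel[:] += 0.5 * dt * a
        _rattle_velocities(pos, vel, invm, 100)

    def mc_volume_move():
        L0 = state["L"]
        v0 = L0**3
        lnv_new = np.log(v0) + rng.uniform(-0.01, 0.01)
        v1 = np.exp(lnv_new)
        L1 = v1 ** (1.0 / 3.0)
        s = L1 / L0
        com = np.sum(_MASS[None, :, None] * pos, axis=1, keepdims=True) / _M_WATER
        pos_new = pos + (s - 1.0) * com
        f_new = np.zeros_like(f)
        u_new = _forces(pos_new, L1, rcut * rcut, _Q, f_new)
        dw = (
            (u_new - state["u"])
            + pressure * (v1 - v0)
            - (n_molecules + 1) * R * T * np.log(v1 / v0)
        )
        if rng.uniform() < np.exp(min(0.0, -dw / (R * T))):
            pos[:] = pos_new
            f[:] = f_new
            state["L"] = L1
            state["u"] = u_new

    def run(n: int, kind: str, tau_eff: float, record: bool):
        nonlocal xi
        n_samples = n // sample_every if record else 0
        time = np.empty(n_samples)
        e_arr = np.empty(n_samples)
        u_arr = np.empty(n_samples)
        k_arr = np.empty(n_samples)
        isample = 0
        for step in range(1, n + 1):
            if kind == "nose_hoover":
                nh_half(_kinetic(vel))
            vv_step()
            if kind == "nose_hoover":
                nh_half(_kinetic(vel))
            elif kind == "berendsen":
                ke = _kinetic(vel)
                t_inst = 2.0 * ke / (n_df * R)
                lam2 = 1.0 + (dt / tau_eff) * (T / t_inst - 1.0)
                vel[:] *= np.sqrt(max(lam2, 0.0))
            if barostat and step % baro_every == 0:
                mc_volume_move()
            if record and step % sample_every == 0:
                vol_accum.append(state["L"] ** 3)
                u = state["u"]
                ke = _kinetic(vel)
                if not np.isfinite(u) or u + ke > 1e6:
                    raise RuntimeError(
                        f"water run unstable at step {step}: E = {u + ke:.3g}"
                    )
                time[isample] = step * dt / 1000.0
                u_arr[isample] = u
                k_arr[isample] = ke
                e_arr[isample] = u + ke
                isample += 1
        return time, e_arr, u_arr, k_arr

    vol_accum: list[float] = []

    if equil_steps > 0:
        run(equil_steps, "berendsen", 10.0, record=False)
    xi = 0.0
    time, e_arr, u_arr, k_arr = run(n_steps, thermostat, tau, record=True)

    if diagnostics is not None:
        vol = float(np.mean(vol_accum)) if vol_accum else state["L"] ** 3
        diagnostics.update(
            box_length=state["L"],
            mean_volume=vol,
            mean_density=n_molecules * _M_WATER / (vol * 0.60221408),
            accept_note="final-state volume" if not vol_accum else "sampled",
        )

    return EnergyTrajectory(
        temperature_setpoint=T,
        time=time,
        e_tot=e_arr,
        u_tot=u_arr,
        ke=k_arr,
        timestep=dt,
        n_df=n_df,
        label=label or f"tip3p N={n_molecules} {thermostat} tau={tau} T={T}",
    )
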