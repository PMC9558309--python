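"""Shared fixtures: lattice simulation sweeps reused across test modules.

The thermostat sweeps are the expensive part of the suite, so they are
computed once per session and shared by the estimator-property tests and
the acceptance tests.  Conditions (n = 64 particles, five setpoints
280–320 K, 200 ps at 1 fs) mirror the package's documented benchmark
protocol; coupling times are resonant with the lattice vibrational period
for the canonical thermostats.
"""

from __future__ import annotations

import numpy as np
import pytest

from thermocap import (
    TemperatureEnsemble,
    ThermostatConfig,
    build_harmonic_lattice,
    simulate,
)

TEMPS = (280.0, 290.0, 300.0, 310.0, 320.0)
N_PARTICLES = 64
N_STEPS = 200_000

#: (kind, tau/fs) used for the cross-thermostat comparison.
SWEEP = {
    "langevin": 10.0,
    "nose_hoover": 20.0,
    "v_rescale": 20.0,
    "berendsen": 100.0,
}


@pytest.fixture(scope="session")
def lattice():
    return build_harmonic_lattice(N_PARTICLES)


def _run_ensemble(sys_, kind: str, tau: float, n_steps: int, seed0: int):
    th = ThermostatConfig(kind, tau=tau)
    trajs = tuple(
        simulate(sys_, th, T, n_steps=n_steps, seed=seed0 + 7 * i)
        for i, T in enumerate(TEMPS)
    )
    return TemperatureEnsemble(trajs)


@pytest.fixture(scope="session")
def thermostat_sweep(lattice):
    """One five-temperature ensemble per thermostat kind."""
    return {
        kind: _run_ensemble(lattice, kind, tau, N_STEPS, seed0=101)
        for kind, tau in SWEEP.items()
    }


@pytest.fixture(scope="session")
def berendsen_tau_sweep(lattice):
    """Berendsen ensembles for τ ∈ {10, 100, 1000}·dt (dt = 1 fs).

    The first quarter of each run is discarded: the initial energy (a
    canonical draw) relaxes toward the Berendsen steady state over ~τ, and
    for the weakest coupling that transient would otherwise dominate the
    windowed energy variance.
    """
    from thermocap import trim_equilibration

    out = {}
    for tau in (10.0, 100.0, 1000.0):
        ens = _run_ensemble(lattice, "berendsen", tau, 100_000, seed0=301)
        out[tau] = TemperatureEnsemble(
            tuple(trim_equilibration(t, 0.25) for t in ens))
    return out


def combined_error(est) -> float:
    """Quadrature of whichever of block/regression/s.e.m. errors are present."""
    errs = [e for e in (est.err_block, est.err_regression, est.err_sem) if e is not None]
    return float(np.sqrt(sum(e * e for e in errs))) if errs else 0.0
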