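# Methods

## Heat capacity from energy time series

For a system sampled in the isothermal(-isobaric) ensemble the constant-
pressure heat capacity can be obtained two ways from an MD energy series:

* **Derivative formula** — `Cp = ∂<H>/∂T`, realised as the least-squares
  slope of the mean total energy against the temperature setpoint over a
  small grid (default 280, 290, 300, 310, 320 K).  The enthalpy is
  approximated by the total energy `E_tot`; at 1 bar the `P·V` term
  contributes ~1e−4 kcal/mol to a box of hundreds of molecules and is
  ignored.
* **Fluctuation formula** — `Cp = <δE²>/(R·T²)` per setpoint, averaged
  (unweighted) over setpoints.  The variance is the population (1/N)
  variance — the thermodynamic definition — and `T` is the setpoint, not
  the instantaneous mean kinetic temperature; at realistic sample sizes
  both choices are indistinguishable, but they are fixed for
  reproducibility.

Molar units are used throughout (`R = 1.9872e−3 kcal/mol/K`), so values
are per mole of *systems*; `CpEstimate.per_molecule(n)` rescales for
presentation and never silently.

When only a potential energy is available (`u_tot`, or a group component
`u_group`), the missing kinetic contribution is the exact equipartition
constant `N_df·R/2`, added explicitly (`kinetic='auto'` requires the
degree-of-freedom count; for a group component the caller must supply the
group's own count).  `e_tot` input never receives a correction.

### Error protocols

* `err_block` — the full estimator is recomputed on `k` contiguous blocks
  per temperature (default `k = 2`) and the error is the standard
  deviation across block estimates divided by `√k`; for two blocks this is
  half the absolute block difference.  The two-block protocol reproduces
  the reference bookkeeping in the worked examples; the general-`k`
  formula is this package's convention, since only the two-block case is
  published.
* `err_regression` — the asymptotic standard error of the regression
  slope (derivative route only; undefined for two temperatures and
  reported as absent).
* `err_sem` — the standard error of the mean of the per-temperature
  fluctuation estimates (ddof = 1).

Differences (`cp_difference`, transition minus reactant) and the binding
cycle propagate matching error types in quadrature.  Estimates with
different method or component tags refuse to difference: comparing a
fluctuation number against a derivative number, or `e_tot` against
`u_tot`, is a category error that the types catch.

### Binding cycle

`ΔCp_bind` uses the dof-balanced cycle

    apo-enzyme + ligand-in-water  →  holo-enzyme + pure water

with the same number of water molecules in apo/holo and in the two
solution systems.  Because every degree of freedom contributes `≥ R/2` to
an absolute heat capacity, an unbalanced cycle produces a meaningless
difference; when dof counts are supplied the bookkeeping asserts
`dof_holo + dof_pure == dof_apo + dof_lig` and raises otherwise.

## Activation thermodynamics (MMRT)

The activation free energy with a constant activation heat capacity is

    ΔG‡(T) = ΔH‡(T0) − T·ΔS‡(T0) + ΔCp‡·[(T − T0) − T·ln(T/T0)]

with `T0` an arbitrary reference (default 298.15 K; fits are invariant to
`T0` up to reparameterisation, which the tests check).  Note the
curvature: `d²ΔG‡/dT² = −ΔCp‡/T`, so a *negative* ΔCp‡ bends ΔG‡(T)
toward a minimum — a rate optimum — and curves the Arrhenius plot.  The
literature often calls this shape "concave" because the *rate* plot is an
inverted U; the code and tests use the mathematical sign convention.

Fitting:

* `fit_linear_arrhenius` — least squares of `ΔG‡/T` on `1/T` (slope ΔH‡,
  intercept −ΔS‡).  `r²` is quoted on this plot because curvature is
  customarily judged there.
* `fit_eq1` — unweighted nonlinear least squares over (ΔH‡, ΔS‡, ΔCp‡)
  with the linear fit as the initial guess, via `scipy.optimize.curve_fit`;
  parameter standard errors from the Jacobian covariance.  Per-point
  weights are accepted but not default (the reference analysis is
  unweighted).
* Rates convert to free energies first through the Eyring form
  `ΔG‡ = R·T·ln(kB·T/(h·k))` with transmission coefficient 1; direct
  `ln k` fits are out of scope.
* `vant_hoff_fit` — `ln K_eq` on `1/T` for conformational equilibria such
  as an active/inactive ES ⇌ ES′ pre-equilibrium.

The two-state generator `gen_two_state_rates` implements the competing
explanation of curved Arrhenius plots: a temperature-favoured inactive
state with `K_inact = exp(−(ΔH_eq − T·ΔS_eq)/(R·T))` scales the TST rate
by the active fraction `1/(1 + K_inact)`, producing a rate optimum near
`ΔH_eq/ΔS_eq` with all ΔCp terms zero.

## Synthetic thermostatted dynamics

### Harmonic lattice

The toy system is an Einstein crystal: `n` independent particles, each
coordinate in `U(x) = ½k·x² + a₄·x⁴`.  Defaults `m = 12 g/mol`,
`k = 72 kcal/mol/Å²` give `ω·dt ≈ 0.06` at `dt = 1 fs`.  For `a₄ = 0` the
canonical heat capacity is exactly `3nR`; for `a₄ > 0` an adaptive-
quadrature oracle evaluates the per-coordinate potential-energy variance
under the Boltzmann weight (the large-`a₄` limit of the potential part is
`R/4` per coordinate, which the tests verify).

The spring constants carry a deterministic ±25% log-spread across
coordinates.  Each harmonic coordinate contributes exactly `R` regardless
of its frequency, so the analytic oracle is unchanged, but the spread
removes the resonance degeneracy of identical oscillators, which
otherwise sabotages deterministic global thermostats.

Integration is velocity Verlet.  Thermostats, applied every
`couple_interval` steps:

* **Berendsen** — velocity scaling `λ = √(1 + (m_c·dt/τ)(T0/T_inst − 1))`.
  Intentionally non-canonical: it is the negative control whose
  fluctuation suppression the estimators must expose.
* **Nosé–Hoover** — a *massive* chain: every degree of freedom has its own
  two-variable chain with `Q = R·T·τ²` and symmetric half-step updates.  A
  single global chain on uncoupled oscillators is the textbook
  non-ergodicity case — trajectories trap away from equipartition and the
  total-energy variance is wrong — and per-dof chains are the standard
  remedy.  Deterministic NH coupling must also be *resonant*: τ near the
  vibrational period (~20 fs here).  With slow coupling (τ ≳ 5/ω) the
  bath decouples adiabatically and finite runs over- or under-estimate
  the energy variance; the benchmark protocol therefore uses τ = 20 fs.
* **Langevin** — BAOAB splitting with the exact Ornstein–Uhlenbeck
  velocity update, `γ = 1/τ`.
* **v-rescale** — stochastic kinetic-energy rescaling with the exact
  chi-squared resampling rule and relaxation time τ.
* **none** — NVE; drift of the block-averaged total energy over 10⁵ steps
  is below 1e−4 relative (tested).

Initial conditions are drawn from the canonical distribution, runs are
bit-reproducible given a seed, and instability (|E| > 1e6 kcal/mol)
aborts with a diagnostic.

### Rigid-water benchmark engine

`thermocap.water.simulate_water` generates the liquid-water benchmark
series self-contained: rigid TIP3P in a cubic periodic box (default 216
molecules at 0.997 g/cm³ start density), velocity Verlet at 2 fs with
SHAKE/RATTLE constraints (`N_df = 6N − 3`), molecule-based cutoff
(default 8 Å, O–O minimum image, whole molecules always on one side of
the cutoff), reaction-field electrostatics with conducting boundary, LJ
shifted to zero at the cutoff, and a 1 Å molecular switching taper.  The
smoothing matters: hard truncation injects ~85 kcal/mol/ps into this box
and no thermostat setting can be trusted on top of that; with the
switched/RF potential NVE conserves energy to ~1e−4 relative over 10 ps
(tested).  Constant pressure uses an isotropic Monte Carlo barostat
(molecular scaling, ln V moves, attempted every 20 steps) at 1 bar.
Berendsen and (global, single-chain — liquids are ergodic) Nosé–Hoover
thermostats are provided.

Scope: one water model, cubic boxes, no mesh Ewald.  Relative to a PME
treatment the reaction-field/cutoff values of Cp per molecule are
expected a few percent high, the same direction the reference data show
for plain-cutoff boxes (0.0199 vs 0.0190 kcal/mol/K).

### What the synthetic data do and do not show

The lattice has an exact oracle and clean thermostat phenomenology, so it
validates the estimators and error protocols, not force-field realism.
The water engine adds realistic liquid-state anharmonicity and a
physically meaningful benchmark number, but with short cutoffs, desk-scale
boxes and tens of picoseconds of sampling its statistical errors (~5% on
the derivative value, ~10% on the fluctuation value) are an order larger
than nanosecond production runs would give.  Neither generator emulates a
solvated enzyme; the ~39 kcal/mol/K absolute enzyme values from the
reference data enter only as inputs to the difference/cycle arithmetic.

## Benchmark problem sizes

Chosen once as the package's documented protocol:

* Lattice sweeps: n = 64, five setpoints 280–320 K, 200 000 steps at 1 fs
  (200 ps) per setpoint, sampled every 10 steps; Berendsen τ-sweep runs
  100 ps per setpoint.
* Water benchmark: 216 molecules, five setpoints; Berendsen (τ = 100 fs)
  8 ps equilibration + 30 ps production per setpoint for the derivative
  estimate; Nosé–Hoover (τ = 100 fs) 8 ps + 60 ps for the fluctuation
  estimate (variances converge slower than means, the very point of the
  comparison).
* MMRT Monte-Carlo recovery: 200 replicates, σ = 0.05 kcal/mol noise,
  five temperatures.

## Known limitations

* Constant ΔCp only; no Cp(T) profiles over the 280–320 K window.
* Block averaging is the only time-correlation error model (no
  autocorrelation-time estimators).
* The water engine is a benchmark generator, not a production MD code: no
  PME, no pressure coupling other than the MC barostat, no mixed solvent,
  single thermostat group.
* Deterministic NH results depend on τ being resonant with the system's
  vibrational spectrum; the package documents rather than hides this.
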