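"""Activation and binding heat-capacity bookkeeping.

Absolute heat capacities of a solvated enzyme system are large (~39
kcal/mol/K for a 50 Å sphere) because every degree of freedom contributes;
the scientifically interesting quantities are *differences* between states:

  ΔCp‡  = Cp(TS) − Cp(ES)            activation heat capacity
  ΔCp^bind via the thermodynamic cycle
          apo + ligand-in-water → holo + pure water

The cycle only makes sense when the degree-of-freedom count balances on
both sides, which the bookkeeping checks.  Inputs here are the published
per-state values for a designer Kemp eliminase; errors propagate in
quadrature.
"""

from thermocap import CpEstimate, binding_cycle, cp_difference

es = CpEstimate(38.95, "derivative", "e_tot", err_block=0.08)
ts = CpEstimate(39.05, "derivative", "e_tot", err_block=0.09)
apo = CpEstimate(38.80, "derivative", "e_tot", err_block=0.07)
# solution leg supplied as ΔCp(water − solvated ligand) = −0.09 ± 0.02
lig = CpEstimate(12.00, "derivative", "e_tot", err_block=0.02)
pure = CpEstimate(12.00 - 0.09, "derivative", "e_tot", err_block=0.0)

act = cp_difference(es, ts)
print(f"ΔCp‡(TS−ES)   = {act.value:+.2f} ± {act.err_block:.2f} kcal/mol/K")

cycle = binding_cycle(ts, apo, lig, pure,
                      dof={"holo": 50000, "apo": 49910, "lig": 10090, "pure": 10000})
print(f"ΔCp‡(TS−apo)  = {cycle.delta_cp_bind:+.2f} ± {cycle.err:.2f} kcal/mol/K "
      f"(dof balanced: {cycle.dof_balanced})")

print("\nBoth differences are zero within error: these simulations show no "
      "negative activation or binding heat capacity, so a curved Arrhenius "
      "plot must have another cause (e.g. a change of rate-limiting step).")
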