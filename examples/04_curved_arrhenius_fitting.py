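"""Fit activation thermodynamics: linear Arrhenius versus the MMRT model.

Generates ΔG‡(T) data with a nonzero activation heat capacity
(ΔCp‡ = −0.3 kcal/mol/K), fits both the linear model (ΔG‡/T vs 1/T) and
the three-parameter MMRT form, and shows a two-state inactive-state
mechanism producing a rate optimum with *zero* ΔCp‡ — the two classic,
experimentally confusable explanations of curved Arrhenius plots.
"""

import numpy as np

from thermocap import (
    ActivationParams,
    fit_eq1,
    fit_linear_arrhenius,
    gen_eq1_dataset,
    gen_two_state_rates,
)

truth = ActivationParams(dH_T0=10.5, dS_T0=-0.0062, dCp=-0.3)
temps = (280.0, 290.0, 300.0, 310.0, 320.0)
data = gen_eq1_dataset(truth, temps, noise_sd=0.02, seed=1)

lin = fit_linear_arrhenius(data)
mmrt = fit_eq1(data)
print("data generated with ΔH‡=10.5, ΔS‡=-0.0062, ΔCp‡=-0.3 (σ=0.02 kcal/mol)")
print(f"linear fit : ΔH‡={lin.dH_T0:6.2f}  ΔS‡={lin.dS_T0:+.4f}  r²={lin.r_squared:.4f}")
print(f"MMRT fit   : ΔH‡={mmrt.dH_T0:6.2f}  ΔS‡={mmrt.dS_T0:+.4f}  "
      f"ΔCp‡={mmrt.dCp:+.3f} ± {mmrt.param_stderrs['dCp']:.3f}")

# An inactive-state equilibrium gives a rate optimum with ΔCp‡ = 0
chem = ActivationParams(10.5, -0.0062, 0.0)
grid = np.linspace(255.0, 325.0, 71)
rates = gen_two_state_rates(chem, dH_eq=30.0, dS_eq=0.11, temps=grid)
t_opt = grid[np.argmax(rates.values)]
print(f"\ntwo-state mechanism (ΔH_eq=30, ΔS_eq=0.11, ΔCp‡=0): "
      f"rate optimum at {t_opt:.0f} K")
print("A rate maximum alone therefore cannot distinguish a negative ΔCp‡ "
      "from an inactive-state pre-equilibrium; the MMRT fit quantifies the "
      "former, the generator reproduces the latter.")
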