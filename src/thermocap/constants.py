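"""Physical constants shared by every module.

Internal unit convention: energies in kcal/mol, temperatures in K,
times in ps (trajectories) or fs (integrator steps), lengths in Å.
"""

from __future__ import annotations

#: Molar gas constant, kcal/mol/K.
R = 1.98720425864083e-3

#: Boltzmann constant over Planck constant, K^-1 s^-1 (Eyring prefactor k_B*T/h).
KB_OVER_H = 2.083661912e10

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL = 4.184

#: kcal per kJ.
KCAL_PER_KJ = 1.0 / KJ_PER_KCAL

# Internal MD energy unit is g/mol * Å^2 / fs^2.
#   1 kcal/mol = 4184 J/mol = 4.184e-4 g/mol Å^2/fs^2.
KCAL_TO_MD = 4.184e-4
MD_TO_KCAL = 1.0 / KCAL_TO_MD

#: Coulomb prefactor, kcal/mol * Å / e^2.
COULOMB_KCAL = 332.0636

#: 1 bar expressed in kcal/mol/Å^3 (for the P·V work term of the barostat).
BAR_TO_KCAL_PER_A3 = 1.0e5 * 6.02214076e23 * 1.0e-30 / 4184.0
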