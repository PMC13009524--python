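"""Physical constants and package-wide defaults.

All concentrations are molar (mol dm⁻³), rates are mol m⁻² min⁻¹,
energies kJ mol⁻¹ unless stated otherwise.
"""

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314

#: Molarity of pure water, mol dm-3; standard-state factor for converting a
#: dm3 mol-1 adsorption constant to the mole-fraction scale inside ln().
WATER_MOLARITY = 55.5

#: Debye-Hueckel limiting-law constant A for water at 37 degC (log10 basis).
DAVIES_A_37C = 0.5215

#: Square root of the calcium oxalate monohydrate ion-concentration product at
#: equilibrium (solubility) at 37 degC, pH 6.0, I = 0.15 mol dm-3.
H0_SQRT_COM = 1.994e-4

#: BET specific surface area of the seed crystals, m2 g-1.
BET_SSA = 3.73

#: Experimental temperature (37.0 degC) in kelvin.
T_EXPERIMENT_K = 310.15

#: Temperature used in the Gibbs-energy evaluation (rounded to 310 K).
T_GIBBS_K = 310.0

#: Physisorption/chemisorption boundary for the adsorption energy, eV.
PHYSISORPTION_THRESHOLD_EV = -0.5
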