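# Aqueous-speciation constants for the Ca / oxalate / Na / Cl system at 37 degC.
#
# logK values are thermodynamic (activity-scale) association constants for the
# formation of the product from the listed reactants.  A negative stoichiometric
# coefficient on H+ means the reaction releases a proton (water is implicit),
# e.g. OH- is formed as H2O - H+ with logK = -pKw.
#
# Sources are literature compilations of critically selected stability
# constants (NIST 46 / Martell & Smith; Finlayson's renal-speciation set);
# where only a 25 degC value is tabulated it is used unchanged, since no
# temperature extrapolation is performed.  Every value may be overridden by
# supplying a user constants file.
#
# `enabled: false` entries are shipped for completeness but excluded from the
# default reaction set: sodium and chloride are treated as fully dissociated
# background electrolyte unless explicitly switched on.

species:
  - {name: "Ca2+",   charge:  2, role: component}
  - {name: "Ox2-",   charge: -2, role: component}   # oxalate, C2O4^2-
  - {name: "Na+",    charge:  1, role: component}
  - {name: "Cl-",    charge: -1, role: component}
  - {name: "H+",     charge:  1, role: component}   # fixed by pH
  - {name: "OH-",    charge: -1, role: complex}
  - {name: "CaOx",   charge:  0, role: complex}     # CaC2O4(aq)
  - {name: "CaHOx+", charge:  1, role: complex}     # CaHC2O4+
  - {name: "HOx-",   charge: -1, role: complex}     # HC2O4-
  - {name: "H2Ox",   charge:  0, role: complex}     # H2C2O4(aq)
  - {name: "NaOx-",  charge: -1, role: complex}     # NaC2O4-
  - {name: "CaOH+",  charge:  1, role: complex}

reactions:
  - product: "HOx-"
    reactants: {"H+": 1, "Ox2-": 1}
    logK: 4.266
    enabled: true
    source: "oxalate second protonation constant, NIST 46 (25 degC, I=0)"
  - product: "H2Ox"
    reactants: {"H+": 2, "Ox2-": 1}
    logK: 5.52
    enabled: true
    source: "cumulative oxalate protonation, NIST 46 (25 degC, I=0)"
  - product: "CaOx"
    reactants: {"Ca2+": 1, "Ox2-": 1}
    logK: 3.19
    enabled: true
    source: "CaC2O4(aq) ion pair, critically selected stability constants"
  - product: "CaHOx+"
    reactants: {"Ca2+": 1, "H+": 1, "Ox2-": 1}
    logK: 5.27
    enabled: true
    source: "Ca2+ + HC2O4- association (~1.0) plus oxalate protonation"
  - product: "OH-"
    reactants: {"H+": -1}
    logK: -13.62
    enabled: true
    source: "water autoionization, pKw = 13.62 at 37 degC"
  - product: "CaOH+"
    reactants: {"Ca2+": 1, "H+": -1}
    logK: -12.42
    enabled: true
    source: "Ca2+ + OH- association (logK 1.20) combined with pKw(37 degC)"
  - product: "NaOx-"
    reactants: {"Na+": 1, "Ox2-": 1}
    logK: 1.03
    enabled: false
    source: "NaC2O4- ion pair, NIST 46 (25 degC, I=0); disabled by default -- Na+ treated as inert background"

physical:
  debye_huckel_A: 0.5215   # log10 basis, water at 37 degC
  water_molarity: 55.5     # mol dm-3
  gas_constant: 8.314      # J mol-1 K-1
  h0_sqrt: 1.994e-4        # mol dm-3, COM solubility (sqrt ion product) at I=0.15
  specific_surface_area: 3.73  # m2 g-1, BET
  temperature_k: 310.15
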