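# Total energies and HOMO-LUMO gaps (eV) of caffeine, the calcium oxalate
# unit, and their complex, from the published DFT results (solvated, water).
# Orbital energies themselves were not published; the gaps are entered
# directly as pre-computed quantities.
label,e_total_ev,e_homo_ev,e_lumo_ev,e_gap_ev
caffeine,-15305.276,,,4.656
caox,-28704.271,,,
complex,-44009.820,,,5.278
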