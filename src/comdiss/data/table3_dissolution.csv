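# Constant-composition dissolution of COM seed crystals, 37.0 C, pH 6.0,
# I = 0.15 mol dm-3, T_Ca:T_Ox = 1:1.  Transcribed experiment table.
# sigma_printed is the published value (x10-2, two figures); analysis code
# recomputes sigma from t_ca_molar and the solubility H0^1/2 = 1.994e-4.
# Rates are interpreted as mol m-2 min-1 (BET-area normalized); the source
# prints the exponent as m-1, which is dimensionally inconsistent with an
# area normalization.
t_ca_molar,sigma_printed_x100,seed_mg,rpm,rate_control,rate_additive
1.791e-4,10,10,300,1.023e-6,0.832e-6
1.751e-4,12,10,300,1.271e-6,1.095e-6
1.692e-4,15,10,300,2.301e-6,1.712e-6
1.652e-4,17,10,300,2.606e-6,2.071e-6
1.592e-4,20,10,300,3.027e-6,2.652e-6
1.493e-4,25,10,300,4.581e-6,3.985e-6
1.453e-4,27,10,300,5.520e-6,4.814e-6
1.433e-4,28,10,300,5.955e-6,4.999e-6
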