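# Dissolution of COM seed crystals at sigma = 0.20, 37.0 C, pH 6.0,
# I = 0.15 mol dm-3, 10.0 mg seed, vs. coffee-extract inhibitor concentration.
# Row with inhibitor_molar = 0 is the control (R0).
# pct_inhibition_printed is the published column, kept for cross-checking;
# the analysis recomputes 100*(R0-Ri)/R0 from the rates.
# The published derived columns (1/C, R0/(R0-Ri), theta, C/theta) are NOT
# transcribed: the 1/C entry for C = 3.0e-6 (printed 2.300e5) is
# arithmetically impossible (1/C = 3.333e5), so every derived quantity is
# recomputed from (C, Ri, R0).
inhibitor_molar,rate,pct_inhibition_printed
0,3.027e-6,
2.000e-6,2.895e-6,4.367
2.220e-6,2.879e-6,4.854
2.500e-6,2.863e-6,5.406
3.000e-6,2.828e-6,6.579
4.000e-6,2.786e-6,7.956
5.000e-6,2.712e-6,10.417
6.000e-6,2.607e-6,13.859
7.000e-6,2.601e-6,14.084
8.000e-6,2.554e-6,15.625
9.000e-6,2.486e-6,17.857
10.000e-6,2.466e-6,18.519
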