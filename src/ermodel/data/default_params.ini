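# Calibrated hERalpha model parameters.
# Dissociation constants in nM (independent only; K5, K6, K10, K11, K12,
# K14 are derived by detailed balance).  K20 published as 10-20 nM; the
# midpoint 15 nM is used.  Rates in 1/s.  Totals in nM.

[binding]
K1 = 25.0
K2 = 0.2
K3 = 0.1
K4 = 0.25
K7 = 10.0
K8 = 150.0
K9 = 30.0
K13 = 0.8
K15 = 8.0
K16 = 2.4
K17 = 1.2
K18 = 50.0
K19 = 87.0
K20 = 15.0

[transcription]
k_sr = 0.195
k_sr_i = 0.02
k_sr_hi = 0.05
k_sr_b = 0.001
k_dr = 0.0025
k_sp = 0.001
k_dp = 2e-05

[totals]
ER_t = 0.0
H_t = 0.0
I_t = 0.0
D_t = 0.0
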