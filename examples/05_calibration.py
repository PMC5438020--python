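"""Calibrate the battery's type-I error and power by Monte Carlo.

Simulates complete study pairs (8 test-retest + 12 challenge subjects) at
several regulation strengths gamma and reports how often each test rejects
at alpha = 0.05. At gamma = 0 the rates estimate the false-positive rate
under pure measurement noise.
"""

import dopakin as dk

table = dk.calibration_sim(gammas=[0.0, 0.3, 0.6, 0.9], n_sim=500, seed=42)
print(table.to_string(index=False))
print()
print("The ANOVA channel stays at the nominal 5% level (the set-point model")
print("moves no group mean), while the correlation comparison gains power")
print("with gamma: that is the test that actually detects regulation.")
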