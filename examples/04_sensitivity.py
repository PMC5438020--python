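"""Propagate a +30% change in the trapping rate k3 to the influx constant.

Ki = K1*k3/(k2+k3) is a rectangular hyperbola in k3, so a +30% change in
k3 always produces a Ki change strictly between 0% and +30% when k2 > 0.
The empirical column re-estimates the change through the full
simulate-and-fit (reference-Patlak) pipeline.
"""

import dopakin as dk

res = dk.propagate_k3_change(K1=0.04, k2=0.06, k3=0.02, frac=30.0)
print(f"analytic: Ki {res.baseline_ki:.4f} -> {res.perturbed_ki:.4f} min^-1 "
      f"({res.percent_change_ki:+.1f} % for a +30 % k3 change)")
print()

table = dk.patlak_bias_sim(dk.DEFAULT_GRID, frac=30.0,
                           schedule=dk.get_preset("study2_32f"))
cols = ["k2", "k3", "percent_change_analytic", "percent_change_empirical", "difference"]
print(table[cols].round(2).to_string(index=False))
print()
print("The analytic change stays below +30 % at every grid point (the")
print("hyperbola dilutes k3 changes); the empirical column shows how much")
print("the graphical estimator distorts that mapping on a 95-min scan.")
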