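"""Simulate striatal and cerebellar time-activity curves and estimate
dopamine synthesis capacity (Ki_cer) by reference-tissue Patlak analysis.

The striatum traps the tracer irreversibly (k3 > 0); the cerebellum does
not and serves as the input surrogate. The late-time slope of the Patlak
plot is Ki_cer in min^-1.
"""

import dopakin as dk

schedule = dk.get_preset("study2_32f")  # 32 frames over 95 min
striatum = dk.simulate_region(dk.DEFAULT_STRIATUM, dk.DEFAULT_PLASMA, schedule,
                              noise_scale=0.05, seed=1, region_label="striatum")
cerebellum = dk.simulate_region(dk.DEFAULT_REFERENCE, dk.DEFAULT_PLASMA, schedule,
                                noise_scale=0.05, seed=2, region_label="cerebellum")

fit = dk.patlak_reference(striatum, cerebellum, t_star=24.0)
suv = dk.suv_at(cerebellum, 95.0, injected_mbq=150.0, weight_kg=75.0)

print(f"schedule        : {len(schedule)} frames, {schedule.total_min:.1f} min")
print(f"Ki_cer          : {fit.ki_cer:.5f} min^-1  (slope of the Patlak line)")
print(f"intercept       : {fit.intercept:.3f}      (distribution-volume term)")
print(f"fit window      : t* = {fit.t_star:.0f} min, {fit.n_points} frames, "
      f"R^2 = {fit.r_squared:.4f}")
print(f"cerebellar SUV  : {suv.value:.3f} at {suv.at_time:.0f} min")
print()
print("Ki_cer ~ 0.015 min^-1 indexes striatal dopamine synthesis capacity;")
print("R^2 near 1 confirms the tracer behaves irreversibly past t*.")
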