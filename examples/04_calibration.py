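"""Calibrate the kinetic model to a synthetic 1,5-AG cohort.

Generates a noise-free normal-pregnancy cohort at the published
best-fit parameters (k_i = 5.16, a = 0.99825, b = 5.78e-5) and refits
the time-varying-reabsorption variant. The steady state depends on
(k_i, a, b) only through k_i/(1-a) and b/(1-a), so those identifiable
ratios are what the data pin down; the individual coordinates along the
scaling ridge inherit the initialization.
"""

import gestag as g

truth = g.KineticParams(
    k_i=5.16, glucose=5.0, reabs=g.ReabsorptionParams(a=0.99825, b=5.78e-5)
)
series, echo = g.recovery_fixture(truth, noise_sd=0.0, seed=0, n_subjects=1)

fit = g.calibrate(series, g.variant_defaults("normal_bestfit_rtime"))
e = fit.estimates
print("variant normal_bestfit_rtime, noise-free cohort")
print(f"  sse        = {fit.sse:.3g} (ug/mL)^2 after {fit.n_eval} evaluations")
print(f"  k_i        = {e['k_i']:.4f}   (truth {echo['k_i']})")
print(f"  a          = {e['a']:.6f} (truth {echo['a']})")
print(f"  b          = {e['b']:.3g}  (truth {echo['b']})")
print(f"  k_i/(1-a)  = {e['k_i'] / (1 - e['a']):.2f} "
      f"(truth {echo['k_i'] / (1 - echo['a']):.2f})")
print(f"  b/(1-a)    = {e['b'] / (1 - e['a']):.5f} "
      f"(truth {echo['b'] / (1 - echo['a']):.5f})")
print("\nThe identifiable ratios match the truth; the raw coordinates sit")
print("elsewhere on the same zero-residual ridge.")

# the nominal model, for contrast, fits the late weeks poorly
nominal = g.calibrate(series, g.variant_defaults("normal_adjusted"))
print(f"\nnominal model (no free parameters): sse = {nominal.sse:.2f} (ug/mL)^2")
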