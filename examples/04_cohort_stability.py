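"""Coefficient stability across a synthetic cohort.

Fits the model for each of 20 synthetic subjects (perturbed tissue
parameters, independent acquisition noise) and summarizes the coefficient
distribution: the free-water and MT terms are stable, the small iron (R2*)
term has a markedly higher coefficient of variation.
"""

import linrelax as lr

base = lr.default_brain_spec(seed=7, grid_shape=(24, 24, 24))
result = lr.run_cohort(n_subjects=20, base_spec=base,
                       between_subject_sd=0.03, noise_sd=0.5, seed=7)

print(result.summary().to_string(index=False,
                                 float_format=lambda v: f"{v:.4f}"))
mean_pearson = sum(s.pearson for s in result.per_subject) / 20
print(f"\nmean Pearson across the cohort: {mean_pearson:.3f}")
print("  -> CoV (100*sd/mean) is smallest for the intercept and MT slope;")
print("     the R2* coefficient, small in magnitude, varies relatively far")
print("     more — the iron term is the least stable part of the model.")
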