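"""Model variants: iron-term ablation and the MTR surrogate.

Compares the full three-term model against (a) an intercept+MT model (no
iron term) and (b) a variant using the classical MT ratio instead of the
MT-saturation map.  Dropping the iron term concentrates residuals in the
iron-rich deep gray matter; swapping in MTR leaves transmit-field structure
in the residuals.
"""

import numpy as np

import linrelax as lr
from linrelax.pipeline import RunConfig, run_variant_comparison

cfg = RunConfig(
    phantom_spec=lr.linked_brain_spec(seed=2, grid_shape=(28, 28, 28)),
    noise_sd=0.5, seed=2)
phantom, qmaps, comp = run_variant_comparison(cfg)

print("variant          Pearson   coefficients")
for name, vf in comp.variants.items():
    coeffs = ", ".join(f"{b:.4f}" for b in vf.fit.beta)
    print(f"{name:15s}  {vf.fit.pearson:.4f}   ({coeffs})")

dgm = phantom.class_labels == list(phantom.class_names).index("deep_gm")
full = np.abs(comp.variants["full"].fit.residual_map)
red = np.abs(comp.variants["no_iron"].fit.residual_map)
sel = dgm & np.isfinite(full) & np.isfinite(red)
print(f"\nmean |residual| in iron-rich deep GM [s^-1]:"
      f"  full {np.mean(full[sel]):.4f}, no-iron {np.mean(red[sel]):.4f}")
print("  -> including the R2* term reduces the deep-GM residuals; the")
print("     residual-difference map highlights iron-rich structures.")

mtr_res = comp.variants["mtr_surrogate"].fit.residual_map
full_res = comp.variants["full"].fit.residual_map
ok = np.isfinite(mtr_res) & np.isfinite(full_res)
print(f"\n|corr(residual, B1 field)|: "
      f"MTR surrogate {abs(np.corrcoef(mtr_res[ok], phantom.b1_rel[ok])[0, 1]):.3f}, "
      f"MT saturation {abs(np.corrcoef(full_res[ok], phantom.b1_rel[ok])[0, 1]):.3f}")
print("  -> the MTR surrogate leaves bias-field structure in the residuals;")
print("     the MT-saturation map accounts for flip-angle and T1 variation.")
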