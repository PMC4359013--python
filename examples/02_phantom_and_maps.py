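"""Phantom simulation and quantitative map estimation.

Builds the default four-class brain phantom, simulates the three multi-echo
FLASH weightings noiselessly, runs the map-estimation chain (R2* log-linear
fit, echo averaging, dual-angle R1/PD, MT saturation), and reports how well
each estimated map recovers the ground truth over brain voxels.
"""

import numpy as np

import linrelax as lr

spec = lr.default_brain_spec(seed=1, grid_shape=(32, 32, 32))
phantom = lr.make_phantom(spec)
acq = lr.default_acquisition()
pdw, t1w, mtw = lr.simulate_mpm(phantom, acq, noise_sd=0.0, seed=1)
print(f"simulated {pdw.n_echoes} PDw, {t1w.n_echoes} T1w, {mtw.n_echoes} MTw "
      f"echoes on a {spec.grid_shape} grid")

qmaps = lr.compute_quantitative_maps(pdw, t1w, mtw, b1_rel=phantom.b1_rel)
print(f"effective TE of the averaged volumes: {qmaps.effective_te_ms:.2f} ms")

gm, wm, csf = lr.mask_probabilities(phantom)
mask = lr.make_mask(gm, wm, csf)
print(f"brain mask (GM/WM > 0.5, CSF < 0.5): {mask.sum()} voxels")

for name, est, true in (("R1  [s^-1]", qmaps.r1, phantom.r1_true),
                        ("MT  [p.u.]", qmaps.mt_sat, phantom.mt_true),
                        ("R2* [s^-1]", qmaps.r2s, phantom.r2s_true)):
    rel = 100 * np.abs(est[mask] / true[mask] - 1.0)
    print(f"  {name}: median |error| {np.nanmedian(rel):.3f}%, "
          f"max {np.nanmax(rel):.3f}%")
print("  -> R2* is exact on noiseless data; R1 and MT carry the small bias")
print("     of the rational dual-angle approximation.")
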