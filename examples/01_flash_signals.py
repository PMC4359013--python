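"""Steady-state FLASH signals: Ernst angle and MT attenuation.

Evaluates the spoiled gradient-echo signal for a white-matter-like voxel,
locates the Ernst angle, and shows how an off-resonance MT prepulse
attenuates the steady state.
"""

import numpy as np

import linrelax as lr

pd, r1, r2s = 1000.0, 1.0, 20.0          # a.u., s^-1, s^-1
tr = 23.7                                 # ms

sig = lr.flash_signal(pd, r1, r2s, flip_deg=6.0, tr_ms=tr,
                      echo_times_ms=[0.0, 8.45, 19.7])
print(f"FLASH signal at TE = 0 / 8.45 / 19.7 ms (flip 6 deg, TR {tr} ms):")
print(f"  {sig[0]:.2f} / {sig[1]:.2f} / {sig[2]:.2f} a.u.")
print("  -> the echo train decays as exp(-TE * R2*); the TE=0 value is the")
print("     Ernst steady state.")

flips = np.linspace(1, 30, 2000)
te0 = np.array([lr.flash_signal(pd, r1, 0.0, f, tr, [0.0])[0] for f in flips])
ernst = np.rad2deg(np.arccos(np.exp(-tr / 1000.0 * r1)))
print(f"\nSignal is maximal at flip {flips[np.argmax(te0)]:.2f} deg; "
      f"analytic Ernst angle {ernst:.2f} deg.")

for mt in (0.0, 1.0, 2.0):
    s = lr.mt_flash_signal(pd, r1, r2s, mt, 6.0, tr, [0.0])[0]
    print(f"MT saturation {mt:.0f} p.u. -> TE=0 signal {s:.2f} a.u.")
print("  -> each percent of per-TR saturation lowers the steady state, the")
print("     contrast mechanism behind the MT-weighted acquisition.")
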