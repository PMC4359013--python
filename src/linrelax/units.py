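"""Unit conventions and conversions.

All repetition and echo times are carried in milliseconds throughout the
API; all relaxation rates (R1, R2*) are in s^-1; MT saturation is in percent
units (p.u.); flip angles are in degrees at API boundaries and radians
internally.  Every ms <-> s conversion goes through this module so the
convention lives in exactly one place.
"""

from __future__ import annotations

import numpy as np

MS_PER_S = 1000.0


def ms_to_s(t_ms):
    """Convert a time (scalar or array) from milliseconds to seconds."""
    return np.asarray(t_ms, dtype=float) / MS_PER_S


def deg_to_rad(angle_deg):
    """Convert a flip angle (scalar or array) from degrees to radians."""
    return np.deg2rad(np.asarray(angle_deg, dtype=float))
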