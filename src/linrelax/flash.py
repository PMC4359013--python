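"""Steady-state multi-echo FLASH signal model and MPM acquisition simulator.

The spoiled gradient-echo (FLASH) steady-state signal follows the Ernst
equation with mono-exponential echo decay at rate R2*:

    S(TE) = PD * sin(a) * (1 - E1) / (1 - cos(a) * E1) * exp(-TE * R2*),
    E1 = exp(-TR * R1).

An off-resonance MT prepulse removes a fraction delta of the longitudinal
magnetization once per TR.  With the event order excite -> saturate ->
relax, the steady state before excitation is

    Mz_ss = (1 - E1) / (1 - (1 - delta) * cos(a) * E1),

and the signal is PD * sin(a) * Mz_ss * exp(-TE * R2*), which reduces
exactly to the plain FLASH signal at delta = 0.  Perfect spoiling is
assumed, and noise is additive Gaussian (magnitude data at high SNR on a
multi-channel coil is near-Gaussian; a documented simplification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .phantom import PhantomVolumes
from .units import deg_to_rad, ms_to_s


@dataclass(frozen=True)
class MTPulse:
    """Metadata describing the off-resonance saturation pulse.

    Carried for provenance only: the simulator parameterizes the pulse's
    effect directly by the per-TR saturation fraction delta.
    """

    duration_ms: float = 4.0
    nominal_flip_deg: float = 220.0
    offset_khz: float = 2.0


@dataclass(frozen=True)
class WeightingParams:
    """Acquisition parameters of one FLASH weighting."""

    weighting: str                        # "pdw" | "t1w" | "mtw"
    nominal_flip_deg: float
    tr_ms: float
    echo_times_ms: tuple[float, ...]
    mt_pulse: MTPulse | None = None

    def validate(self) -> None:
        if self.tr_ms <= 0:
            raise ValidationError(f"{self.weighting}: tr_ms must be > 0")
        if not (0.0 < self.nominal_flip_deg <= 90.0):
            raise ValidationError(
                f"{self.weighting}: flip angle must be in (0, 90] degrees"
            )
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.size == 0 or np.any(np.diff(te) <= 0):
            raise ValidationError(
                f"{self.weighting}: echo_times_ms must be strictly increasing"
            )
        if np.any(te >= self.tr_ms) or np.any(te <= 0):
            raise ValidationError(
                f"{self.weighting}: echo times must lie in (0, tr_ms)"
            )


@dataclass(frozen=True)
class AcquisitionParams:
    """The three FLASH weightings of an MPM protocol."""

    pdw: WeightingParams
    t1w: WeightingParams
    mtw: WeightingParams

    def validate(self) -> None:
        for w in (self.pdw, self.t1w, self.mtw):
            w.validate()


#: First-six echo grid shared by all weightings; mean TE = 8.45 ms.
ECHOES_6_MS = (2.2, 4.7, 7.2, 9.7, 12.2, 14.7)
#: The PD-weighted acquisition extends the same grid to 8 echoes (max 19.7 ms).
ECHOES_8_MS = ECHOES_6_MS + (17.2, 19.7)


def default_acquisition() -> AcquisitionParams:
    """Default MPM protocol: PDw 23.7 ms/6deg (8 echoes), T1w 18.7 ms/20deg
    and MTw 23.7 ms/6deg (6 echoes each)."""
    return AcquisitionParams(
        pdw=WeightingParams("pdw", nominal_flip_deg=6.0, tr_ms=23.7,
                            echo_times_ms=ECHOES_8_MS),
        t1w=WeightingParams("t1w", nominal_flip_deg=20.0, tr_ms=18.7,
                            echo_times_ms=ECHOES_6_MS),
        mtw=WeightingParams("mtw", nominal_flip_deg=6.0, tr_ms=23.7,
                            echo_times_ms=ECHOES_6_MS, mt_pulse=MTPulse()),
    )


@dataclass
class WeightedSeries:
    """Multi-echo signal volumes for one weighting (space x echo)."""

    weighting: str
    volumes: np.ndarray
    echo_times_ms: tuple[float, ...]
    acquisition: AcquisitionParams | None = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.shape[-1] != len(self.echo_times_ms):
            raise ValidationError(
                "number of echo volumes must equal number of echo times "
                f"({self.volumes.shape[-1]} != {len(self.echo_times_ms)})"
            )

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)


def _validate_signal_inputs(pd, r1, tr_ms, flip_deg) -> None:
    if np.any(np.asarray(tr_ms) <= 0):
        raise ValidationError("tr_ms must be strictly positive")
    if np.any(np.asarray(r1) <= 0):
        raise ValidationError("r1 must be strictly positive")
    if np.any(np.asarray(pd) <= 0):
        raise ValidationError("pd must be strictly positive")
    flip = np.asarray(flip_deg)
    if np.any(flip <= 0) or np.any(flip > 90):
        raise ValidationError("flip angle must be in (0, 90] degrees")


def flash_signal(pd, r1, r2s, flip_deg, tr_ms, echo_times_ms) -> np.ndarray:
    """Spoiled FLASH steady-state signal at each echo time.

    ``pd``, ``r1``, ``r2s`` and ``flip_deg`` may be scalars or broadcastable
    arrays; the returned array has one trailing echo axis.
    """
    _validate_signal_inputs(pd, r1, tr_ms, flip_deg)
    if np.any(np.asarray(r2s) < 0):
        raise ValidationError("r2s must be >= 0")
    pd, r1, r2s = np.broadcast_arrays(
        np.asarray(pd, float), np.asarray(r1, float), np.asarray(r2s, float)
    )
    alpha = deg_to_rad(flip_deg)
    e1 = np.exp(-ms_to_s(tr_ms) * r1)
    s0 = pd * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)
    te_s = ms_to_s(np.asarray(echo_times_ms, float))
    return s0[..., None] * np.exp(-r2s[..., None] * te_s)


def mt_flash_signal(pd, r1, r2s, mt_sat, flip_deg, tr_ms, echo_times_ms) -> np.ndarray:
    """FLASH steady-state signal with a per-TR MT saturation of ``mt_sat`` p.u.

    Event order within a TR: excitation, saturation of the remaining
    longitudinal magnetization by (1 - delta), then relaxation over TR.
    Reduces exactly to :func:`flash_signal` at ``mt_sat = 0``.
    """
    _validate_signal_inputs(pd, r1, tr_ms, flip_deg)
    delta = np.asarray(mt_sat, float) / 100.0
    if np.any(delta < 0) or np.any(delta >= 1):
        raise ValidationError("mt_sat must be in [0, 100) p.u.")
    if np.any(np.asarray(r2s) < 0):
        raise ValidationError("r2s must be >= 0")
    pd, r1, r2s, delta = np.broadcast_arrays(
        np.asarray(pd, float), np.asarray(r1, float),
        np.asarray(r2s, float), delta,
    )
    alpha = deg_to_rad(flip_deg)
    e1 = np.exp(-ms_to_s(tr_ms) * r1)
    mz = (1.0 - e1) / (1.0 - (1.0 - delta) * np.cos(alpha) * e1)
    s0 = pd * np.sin(alpha) * mz
    te_s = ms_to_s(np.asarray(echo_times_ms, float))
    return s0[..., None] * np.exp(-r2s[..., None] * te_s)


def simulate_mpm(phantom: PhantomVolumes, acq: AcquisitionParams,
                 noise_sd: float = 0.0, seed: int | None = 0,
                 ) -> tuple[WeightedSeries, WeightedSeries, WeightedSeries]:
    """Simulate the three weighted multi-echo series from phantom truth.

    The local flip angle is ``nominal flip * b1_rel`` voxelwise.  Additive
    zero-mean Gaussian noise of standard deviation ``noise_sd`` (a.u.) is
    applied to every echo volume; the draw is seeded and reproducible.
    Returns ``(pdw, t1w, mtw)``.
    """
    acq.validate()
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    def _noisy(sig: np.ndarray) -> np.ndarray:
        if noise_sd == 0.0:
            return sig
        return sig + rng.normal(0.0, noise_sd, size=sig.shape)

    flips_pd = acq.pdw.nominal_flip_deg * phantom.b1_rel
    flips_t1 = acq.t1w.nominal_flip_deg * phantom.b1_rel
    flips_mt = acq.mtw.nominal_flip_deg * phantom.b1_rel

    pdw = WeightedSeries(
        "pdw",
        _noisy(flash_signal(phantom.pd_true, phantom.r1_true, phantom.r2s_true,
                            flips_pd, acq.pdw.tr_ms, acq.pdw.echo_times_ms)),
        acq.pdw.echo_times_ms, acq)
    t1w = WeightedSeries(
        "t1w",
        _noisy(flash_signal(phantom.pd_true, phantom.r1_true, phantom.r2s_true,
                            flips_t1, acq.t1w.tr_ms, acq.t1w.echo_times_ms)),
        acq.t1w.echo_times_ms, acq)
    mtw = WeightedSeries(
        "mtw",
        _noisy(mt_flash_signal(phantom.pd_true, phantom.r1_true,
                               phantom.r2s_true, phantom.mt_true,
                               flips_mt, acq.mtw.tr_ms, acq.mtw.echo_times_ms)),
        acq.mtw.echo_times_ms, acq)
    return pdw, t1w, mtw
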