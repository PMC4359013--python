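"""NIfTI-1 volume I/O and flat key-value configuration files.

All volumetric maps are exchanged as NIfTI-1 (one file per map, identity
affine by default, unit string recorded in the header description field).
Configurations are flat YAML key-value files with units encoded in key
names (``tr_ms``, ``noise_sd_au``, ...).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import FormatError, ValidationError
from .flash import AcquisitionParams, MTPulse, WeightingParams
from .phantom import PhantomSpec, TissueClassParams


@dataclass
class Volume:
    """A loaded volume: data array plus grid metadata."""

    data: np.ndarray
    affine: np.ndarray
    description: str = ""

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def load_volume(path) -> Volume:
    """Load a NIfTI-1 volume; malformed files raise :class:`FormatError`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        descrip = ""
        if hasattr(img.header, "get"):
            raw = img.header.get("descrip", b"")
            descrip = bytes(raw).decode("utf-8", "ignore").rstrip("\x00")
    except FormatError:
        raise
    except Exception as exc:  # nibabel raises a zoo of parse errors
        raise FormatError(f"could not read {path} as NIfTI-1: {exc}") from exc
    return Volume(data=data, affine=np.asarray(img.affine), description=descrip)


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None,
                description: str = "") -> None:
    """Write a volume as NIfTI-1 with the unit string in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def check_same_grid(*volumes: np.ndarray) -> None:
    """Fail fast on mismatched grids before any computation starts."""
    shapes = {np.asarray(v).shape[:3] for v in volumes}
    if len(shapes) > 1:
        raise ValidationError(f"volumes are on mismatched grids: {sorted(shapes)}")


# ---------------------------------------------------------------------------
# flat key-value configs

def save_config(path, config: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=True))


def load_config(path) -> dict:
    path = Path(path)
    try:
        out = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(out, dict):
        raise FormatError(f"config {path} is not a key-value mapping")
    return out


def acquisition_to_dict(acq: AcquisitionParams) -> dict:
    out = {}
    for w in (acq.pdw, acq.t1w, acq.mtw):
        key = w.weighting
        out[f"{key}_flip_deg"] = float(w.nominal_flip_deg)
        out[f"{key}_tr_ms"] = float(w.tr_ms)
        out[f"{key}_echo_times_ms"] = [float(t) for t in w.echo_times_ms]
        if w.mt_pulse is not None:
            out[f"{key}_mt_pulse_duration_ms"] = float(w.mt_pulse.duration_ms)
            out[f"{key}_mt_pulse_flip_deg"] = float(w.mt_pulse.nominal_flip_deg)
            out[f"{key}_mt_pulse_offset_khz"] = float(w.mt_pulse.offset_khz)
    return out


def acquisition_from_dict(d: dict) -> AcquisitionParams:
    def weighting(key: str) -> WeightingParams:
        pulse = None
        if f"{key}_mt_pulse_duration_ms" in d:
            pulse = MTPulse(duration_ms=d[f"{key}_mt_pulse_duration_ms"],
                            nominal_flip_deg=d[f"{key}_mt_pulse_flip_deg"],
                            offset_khz=d[f"{key}_mt_pulse_offset_khz"])
        try:
            return WeightingParams(
                weighting=key,
                nominal_flip_deg=float(d[f"{key}_flip_deg"]),
                tr_ms=float(d[f"{key}_tr_ms"]),
                echo_times_ms=tuple(float(t) for t in d[f"{key}_echo_times_ms"]),
                mt_pulse=pulse,
            )
        except KeyError as exc:
            raise FormatError(f"acquisition config missing key {exc}") from exc

    acq = AcquisitionParams(pdw=weighting("pdw"), t1w=weighting("t1w"),
                            mtw=weighting("mtw"))
    acq.validate()
    return acq


def phantom_spec_to_dict(spec: PhantomSpec) -> dict:
    out = {
        "grid_shape": list(spec.grid_shape),
        "smoothness_vox": float(spec.smoothness),
        "b1_min": float(spec.b1_range[0]),
        "b1_max": float(spec.b1_range[1]),
        "seed": int(spec.seed),
        "classes": [
            {
                "name": cp.name,
                "r1_per_s": float(cp.r1),
                "pd_au": float(cp.pd),
                "mt_sat_pu": float(cp.mt_sat),
                "r2s_per_s": float(cp.r2s),
                "within_class_sd_frac": float(cp.within_class_sd),
            }
            for cp in spec.class_params
        ],
    }
    if spec.r1_link_beta is not None:
        out["r1_link_beta"] = [float(b) for b in spec.r1_link_beta]
    return out


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    try:
        classes = tuple(
            TissueClassParams(
                name=c["name"], r1=c["r1_per_s"], pd=c["pd_au"],
                mt_sat=c["mt_sat_pu"], r2s=c["r2s_per_s"],
                within_class_sd=c.get("within_class_sd_frac", 0.05),
            )
            for c in d["classes"]
        )
        spec = PhantomSpec(
            grid_shape=tuple(int(n) for n in d["grid_shape"]),
            class_params=classes,
            smoothness=float(d.get("smoothness_vox", 1.5)),
            b1_range=(float(d.get("b1_min", 0.9)), float(d.get("b1_max", 1.1))),
            seed=int(d.get("seed", 0)),
            r1_link_beta=(tuple(float(b) for b in d["r1_link_beta"])
                          if "r1_link_beta" in d else None),
        )
    except KeyError as exc:
        raise FormatError(f"phantom spec config missing key {exc}") from exc
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# provenance

def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_provenance(out_dir, config: dict, seed: int, stage: str) -> Path:
    """Record the exact inputs (config dict, hash, seed) beside the outputs."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "stage": stage,
        "seed": int(seed),
        "config": config,
        "config_sha256": config_hash(config),
        "linrelax_version": __version__,
    }
    path = out_dir / f"provenance_{stage}.json"
    path.write_text(json.dumps(record, sort_keys=True, indent=2, default=str))
    return path
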