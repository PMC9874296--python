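"""Reading and writing the pipeline's on-disk formats.

Volumetric data travel as NIfTI-1 with voxel spacing in the header (a
missing/zero spacing is an error — 1 mm is never assumed); multi-echo
stacks are 4-D NIfTI plus a JSON sidecar carrying the echo times; masks are
0/1 NIfTI; tables are CSV with documented column names; PET acquisition
metadata, ground-truth records and manifests are JSON; configuration is
YAML.

NIfTI stores arrays (x, y, z); in memory this package indexes (z, y, x),
so read/write transpose accordingly and round-trip bit-exactly.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .pet import PETAcquisition
from .volumes import MultiEchoVolume, ROIMask, ScalarVolume


def _affine_from_spacing(spacing) -> np.ndarray:
    # spacing is (z, y, x) mm; NIfTI axes are (x, y, z)
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def _spacing_from_header(img, path) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(
            f"{path}: NIfTI header declares no valid voxel spacing "
            f"(zooms {zooms}); refusing to assume 1 mm"
        )
    return (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name.split(".")[0] + ".json")


def write_scalar_volume(vol: ScalarVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.data.T, _affine_from_spacing(vol.spacing))
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, path)
    _sidecar(path).write_text(json.dumps({"unit": vol.unit}, indent=2))
    return path


def read_scalar_volume(path, unit: str | None = None) -> ScalarVolume:
    path = Path(path)
    img = nib.load(path)
    spacing = _spacing_from_header(img, path)
    data = np.asarray(img.dataobj, dtype=float).T
    if unit is None:
        sidecar = _sidecar(path)
        unit = (json.loads(sidecar.read_text()).get("unit", "a.u.")
                if sidecar.exists() else "a.u.")
    return ScalarVolume(data=data, spacing=spacing, unit=unit)


def write_multi_echo(vol: MultiEchoVolume, path) -> Path:
    """4-D NIfTI (x, y, z, echo) + JSON sidecar with the echo times (ms)."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.transpose(vol.data, (3, 2, 1, 0)), _affine_from_spacing(vol.spacing)
    )
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0))
    nib.save(img, path)
    _sidecar(path).write_text(json.dumps(
        {"echo_times_ms": [float(t) for t in vol.echo_times]}, indent=2))
    return path


def read_multi_echo(path) -> MultiEchoVolume:
    path = Path(path)
    img = nib.load(path)
    spacing = _spacing_from_header(img, path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"multi-echo sidecar {sidecar} not found")
    echo_times = json.loads(sidecar.read_text())["echo_times_ms"]
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (3, 2, 1, 0))
    return MultiEchoVolume(data=data, echo_times=echo_times, spacing=spacing)


def write_mask(roi: ROIMask, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        roi.mask.T.astype(np.uint8), _affine_from_spacing(roi.spacing)
    )
    img.header.set_zooms((roi.spacing[2], roi.spacing[1], roi.spacing[0]))
    nib.save(img, path)
    return path


def read_mask(path, label: str = "") -> ROIMask:
    path = Path(path)
    img = nib.load(path)
    spacing = _spacing_from_header(img, path)
    mask = np.asarray(img.dataobj).T > 0
    return ROIMask(mask=mask, spacing=spacing, label=label or path.stem)


def write_pet_meta(acq: PETAcquisition, path) -> Path:
    """Acquisition metadata sidecar (the activity volume goes to NIfTI)."""
    path = Path(path)
    path.write_text(json.dumps({
        "injected_dose": acq.injected_dose,
        "injection_time": acq.injection_time,
        "scan_time": acq.scan_time,
        "half_life": acq.half_life,
        "unit": acq.dose_unit,
    }, indent=2))
    return path


def read_pet_acquisition(volume_path, meta_path) -> PETAcquisition:
    meta = json.loads(Path(meta_path).read_text())
    vol = read_scalar_volume(volume_path, unit=f"{meta.get('unit', 'a.u.')}/mL")
    return PETAcquisition(
        activity=vol,
        injected_dose=float(meta["injected_dose"]),
        injection_time=float(meta["injection_time"]),
        scan_time=float(meta["scan_time"]),
        half_life=float(meta["half_life"]),
        dose_unit=meta.get("unit", "a.u."),
    )


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def save_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialise {type(obj)}")
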