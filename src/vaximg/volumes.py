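"""Core volumetric containers shared by the MRI, PET and radiomics stages.

Arrays are indexed ``(z, y, x)`` (slice, row, column), 0-based, with world
positions at voxel centers.  Spacing is millimetres per axis in the same
order; all volumes are reported in mm³.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Spacing = tuple[float, float, float]


def _validated_spacing(spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass
class ScalarVolume:
    """A 3-D voxel array with physical spacing and a unit tag.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Voxel values.
    spacing : (float, float, float)
        Voxel size in mm per axis, same order as ``data``.
    unit : str
        Unit tag, e.g. ``"ms"`` (T2 map), ``"a.u."`` (M0 / raw signal),
        ``"a.u./mL"`` (activity concentration), ``"%ID/g"`` or ``"HU"``.
    """

    data: np.ndarray
    spacing: Spacing
    unit: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"ScalarVolume data must be 3-D, got {self.data.ndim}-D")
        self.spacing = _validated_spacing(self.spacing)
        if not self.unit:
            raise ValueError("ScalarVolume requires a unit tag")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "ScalarVolume":
        """New volume with the same geometry but different voxel data."""
        return ScalarVolume(data=data, spacing=self.spacing, unit=unit or self.unit)


@dataclass
class MultiEchoVolume:
    """A multi-echo MR acquisition: one 3-D image per echo time.

    ``data`` has shape (echo, z, y, x); ``echo_times`` are the echo times TE
    in milliseconds, strictly increasing and positive.
    """

    data: np.ndarray
    echo_times: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"MultiEchoVolume data must be 4-D, got {self.data.ndim}-D")
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.echo_times.ndim != 1 or len(self.echo_times) != self.data.shape[0]:
            raise ValueError(
                f"echo_times length {self.echo_times.size} does not match "
                f"echo dimension {self.data.shape[0]}"
            )
        if np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing and positive")
        self.spacing = _validated_spacing(self.spacing)

    @property
    def n_echoes(self) -> int:
        return int(self.data.shape[0])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ROIMask:
    """A boolean region-of-interest mask sharing the geometry of a volume."""

    mask: np.ndarray
    spacing: Spacing
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"ROIMask must be 3-D, got {self.mask.ndim}-D")
        self.spacing = _validated_spacing(self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    def require_nonempty(self) -> None:
        if self.voxel_count == 0:
            raise ValueError(f"ROI {self.label!r} is empty")

    def check_compatible(self, vol: "ScalarVolume | MultiEchoVolume") -> None:
        vol_shape = vol.data.shape[-3:]
        if self.mask.shape != vol_shape:
            raise ValueError(
                f"ROI shape {self.mask.shape} does not match volume shape {vol_shape}"
            )
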