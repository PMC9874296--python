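"""PET quantification: decay correction, %ID/g conversion, enhancement
volumetry and total tracer uptake.

Activity concentration is carried per millilitre; converting to per-gram
values assumes soft-tissue density 1 g/mL, so %ID/g and %ID/mL coincide.
Dose units are whatever the caller measured the injected dose in (µCi, MBq,
...) as long as volume and dose use the same unit; ``injected_dose`` is the
*net* dose (syringe residual already subtracted by the caller).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import ROIMask, ScalarVolume


@dataclass
class PETAcquisition:
    """A single static PET frame plus the metadata needed to quantify it.

    ``activity`` holds the measured activity concentration at scan time
    (same dose unit as ``injected_dose``, per mL); times in minutes.
    """

    activity: ScalarVolume
    injected_dose: float
    injection_time: float
    scan_time: float
    half_life: float
    dose_unit: str = "a.u."

    def __post_init__(self) -> None:
        if self.injected_dose <= 0:
            raise ValueError("injected_dose must be positive")
        if self.scan_time < self.injection_time:
            raise ValueError("scan_time must not precede injection_time")
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")


def decay_correct(acq: PETAcquisition) -> ScalarVolume:
    """Correct measured activity back to the injection time.

    Radioactive decay between injection and scan is undone by multiplying
    every voxel by ``2**(dt / half_life)`` with ``dt = scan_time -
    injection_time``.
    """
    dt = acq.scan_time - acq.injection_time
    factor = 2.0 ** (dt / acq.half_life)
    return acq.activity.with_data(acq.activity.data * factor)


def percent_id_per_g(corrected: ScalarVolume, injected_dose: float) -> ScalarVolume:
    """Convert decay-corrected activity concentration to %ID/g.

    Voxel value = 100 × concentration / injected dose, with density
    1 g/mL so per-mL equals per-g.
    """
    if injected_dose <= 0:
        raise ValueError("injected_dose must be positive")
    return corrected.with_data(100.0 * corrected.data / injected_dose, unit="%ID/g")


def pet_enhancement_volume(
    vol: ScalarVolume,
    baseline_mean: float,
    baseline_sd: float,
    search_roi: ROIMask,
    k_sd: float = 2.0,
) -> tuple[ROIMask, float]:
    """Volume of uptake exceeding the baseline-scan threshold.

    Threshold = baseline mean + ``k_sd`` × baseline SD (statistics of the
    baseline-timepoint scan over the same anatomical region, supplied by the
    caller); voxels strictly above it within ``search_roi`` count toward the
    enhancement volume.
    """
    if baseline_sd < 0:
        raise ValueError("baseline_sd must be non-negative")
    search_roi.check_compatible(vol)
    search_roi.require_nonempty()
    threshold = baseline_mean + k_sd * baseline_sd
    mask = search_roi.mask & (vol.data > threshold)
    out = ROIMask(mask, vol.spacing, label=f"pet_enhancement>{threshold:g}")
    return out, out.volume_mm3


def total_uptake(mean_idg: float, enhancement_volume_mm3: float) -> float:
    """Total tracer uptake (glycolytic burden): mean %ID/g × volume.

    Units: %ID·mm³/g.
    """
    if mean_idg < 0 or enhancement_volume_mm3 < 0:
        raise ValueError("mean %ID/g and volume must be non-negative")
    return mean_idg * enhancement_volume_mm3
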