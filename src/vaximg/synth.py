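"""Synthetic phantoms and single-cell tables with known ground truth.

Every downstream stage (relaxometry, PET quantification, single-cell
phenotyping, spatial metrics, temporal statistics) is exercised against the
objects generated here, so each generator returns both the data and a truth
record holding the parameters the estimators are supposed to recover.

Geometry conventions: limbs are axis-aligned cylinders running along the
slice (z) axis, lesions and lymph nodes are spheres — simple shapes whose
volumes have closed forms, so recovery checks can compare against analytic
truth.  MR noise is additive Gaussian by default (``noise_model="rician"``
is available); this keeps the noiseless mono-exponential signal an exact
member of the fitted model class.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import MultiEchoVolume, ROIMask, ScalarVolume
from .pet import PETAcquisition

# TE grid of an 8-echo multi-slice multi-echo acquisition with 7 ms echo
# spacing (TE = 7 ... 56 ms).
DEFAULT_ECHO_TIMES = tuple(7.0 * k for k in range(1, 9))

#: Physical decay constant of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77


# ---------------------------------------------------------------------------
# MRI phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Ground truth for a bilateral-limb multi-echo MR phantom."""

    lesion_mask: np.ndarray
    lesion_t2: float          # ms
    background_t2: float      # ms
    lesion_m0: float          # a.u.
    background_m0: float      # a.u.
    lesion_volume_mm3: float
    noise_sd: float
    seed: int
    spacing: tuple[float, float, float]
    left_limb_mask: np.ndarray = field(repr=False, default=None)
    right_limb_mask: np.ndarray = field(repr=False, default=None)
    node_mask: np.ndarray | None = field(repr=False, default=None)
    node_t2: float | None = None
    lesion_center_mm: tuple[float, float, float] | None = None
    lesion_radius_mm: float | None = None


def _cylinder_mask(shape, spacing, center_yx_mm, radius_mm):
    """Axis-aligned cylinder along z: (y, x) within radius of a center."""
    _, ny, nx = shape
    y = (np.arange(ny) * spacing[1])[:, None]
    x = (np.arange(nx) * spacing[2])[None, :]
    inside = (y - center_yx_mm[0]) ** 2 + (x - center_yx_mm[1]) ** 2 <= radius_mm ** 2
    return np.broadcast_to(inside[None, :, :], shape).copy()


def _sphere_mask(shape, spacing, center_mm, radius_mm):
    z = (np.arange(shape[0]) * spacing[0])[:, None, None]
    y = (np.arange(shape[1]) * spacing[1])[None, :, None]
    x = (np.arange(shape[2]) * spacing[2])[None, None, :]
    d2 = (z - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 + (x - center_mm[2]) ** 2
    return d2 <= radius_mm ** 2


def make_mri_phantom(
    shape: tuple[int, int, int] = (25, 128, 128),
    spacing: tuple[float, float, float] = (1.5, 0.469, 0.469),
    echo_times=DEFAULT_ECHO_TIMES,
    background_t2: float = 30.0,
    lesion_t2: float = 80.0,
    background_m0: float = 1000.0,
    lesion_m0: float = 1000.0,
    lesion_radius_mm: float = 3.0,
    lesion_center_mm: tuple[float, float, float] | None = None,
    node_radius_mm: float = 0.0,
    node_t2: float = 60.0,
    noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    seed: int = 0,
) -> tuple[MultiEchoVolume, PhantomTruth]:
    """Bilateral-limb multi-echo phantom with a unilateral high-T2 lesion.

    Two parallel "limb" cylinders run along z; the lesion sphere (edema-like,
    elevated T2) sits only in the right limb, mimicking a unilateral
    intramuscular injection site.  An optional small sphere with its own T2
    stands in for the draining popliteal lymph node.  The noiseless voxel
    signal is ``M0 * exp(-TE / T2)`` per compartment.

    Returns the acquisition and a :class:`PhantomTruth` carrying the masks
    and parameters downstream estimators should recover.
    """
    echo_times = np.asarray(echo_times, dtype=float)
    for name, value in [
        ("background_t2", background_t2), ("lesion_t2", lesion_t2),
        ("background_m0", background_m0), ("lesion_m0", lesion_m0),
    ]:
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")
    if lesion_t2 == background_t2:
        raise ValueError("lesion T2 must differ from background T2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise_model {noise_model!r}")

    nz, ny, nx = shape
    fov_y = ny * spacing[1]
    fov_x = nx * spacing[2]
    fov_z = nz * spacing[0]
    limb_radius = 0.18 * fov_x
    left_center = (0.5 * fov_y, 0.27 * fov_x)
    right_center = (0.5 * fov_y, 0.73 * fov_x)
    left = _cylinder_mask(shape, spacing, left_center, limb_radius)
    right = _cylinder_mask(shape, spacing, right_center, limb_radius)

    if lesion_center_mm is None:
        lesion_center_mm = (0.5 * fov_z, right_center[0], right_center[1])
    lesion = _sphere_mask(shape, spacing, lesion_center_mm, lesion_radius_mm) & right

    node = None
    if node_radius_mm > 0:
        node_center = (0.25 * fov_z, right_center[0], right_center[1])
        node = _sphere_mask(shape, spacing, node_center, node_radius_mm) & right
        node &= ~lesion

    t2_map = np.full(shape, np.nan)
    m0_map = np.zeros(shape)
    body = left | right
    t2_map[body] = background_t2
    m0_map[body] = background_m0
    t2_map[lesion] = lesion_t2
    m0_map[lesion] = lesion_m0
    if node is not None:
        t2_map[node] = node_t2

    rng = np.random.default_rng(seed)
    data = np.zeros((len(echo_times),) + tuple(shape))
    for i, te in enumerate(echo_times):
        signal = np.zeros(shape)
        signal[body] = m0_map[body] * np.exp(-te / t2_map[body])
        if noise_sd > 0:
            if noise_model == "gaussian":
                signal = signal + rng.normal(0.0, noise_sd, shape)
            else:  # rician magnitude
                re = signal + rng.normal(0.0, noise_sd, shape)
                im = rng.normal(0.0, noise_sd, shape)
                signal = np.hypot(re, im)
        data[i] = signal

    voxel_volume = float(np.prod(spacing))
    truth = PhantomTruth(
        lesion_mask=lesion,
        lesion_t2=lesion_t2,
        background_t2=background_t2,
        lesion_m0=lesion_m0,
        background_m0=background_m0,
        lesion_volume_mm3=float(lesion.sum()) * voxel_volume,
        noise_sd=noise_sd,
        seed=seed,
        spacing=tuple(spacing),
        left_limb_mask=left,
        right_limb_mask=right,
        node_mask=node,
        node_t2=node_t2 if node is not None else None,
        lesion_center_mm=tuple(lesion_center_mm),
        lesion_radius_mm=lesion_radius_mm,
    )
    vol = MultiEchoVolume(data=data, echo_times=echo_times, spacing=spacing)
    return vol, truth


# ---------------------------------------------------------------------------
# PET phantom
# ---------------------------------------------------------------------------

@dataclass
class PETPhantomTruth:
    """Ground truth for a static-frame PET uptake phantom.

    ``frac_per_ml`` is the true uptake map as fraction of the injected dose
    per millilitre of tissue; integrating it over the phantom gives the
    total in-phantom dose fraction.
    """

    frac_per_ml: np.ndarray
    lesion_mask: np.ndarray
    node_mask: np.ndarray
    body_mask: np.ndarray
    lesion_fraction: float
    node_fraction: float
    background_fraction: float
    total_fraction: float
    lesion_volume_mm3: float
    injected_dose: float
    seed: int
    spacing: tuple[float, float, float]
    lesion_center_mm: tuple[float, float, float] | None = None
    lesion_radius_mm: float | None = None


def make_pet_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (0.66, 0.66, 0.66),
    injected_dose: float = 400.0,
    injection_to_scan_min: float = 60.0,
    half_life_min: float = F18_HALF_LIFE_MIN,
    lesion_fraction: float = 0.02,
    node_fraction: float = 0.002,
    background_fraction: float = 0.05,
    lesion_radius_mm: float = 4.0,
    node_radius_mm: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PETAcquisition, PETPhantomTruth]:
    """Static PET frame with a hot injection-site lesion and a hot node.

    Dose fractions (lesion, node, uniform background over the body cylinder)
    are spread uniformly over their regions; the true activity concentration
    is ``injected_dose * frac_per_ml``, forward-decayed to scan time by
    ``2**(-dt / half_life)`` so the decay-correction step can be verified
    exactly.
    """
    if injected_dose <= 0:
        raise ValueError("injected_dose must be positive")
    if half_life_min <= 0:
        raise ValueError("half_life_min must be positive")
    if injection_to_scan_min < 0:
        raise ValueError("injection_to_scan_min must be non-negative")
    for name, f in [("lesion_fraction", lesion_fraction),
                    ("node_fraction", node_fraction),
                    ("background_fraction", background_fraction)]:
        if f < 0:
            raise ValueError(f"{name} must be non-negative")
    if lesion_fraction + node_fraction + background_fraction > 1.0:
        raise ValueError("uptake fractions must not sum above 1")

    nz, ny, nx = shape
    fov_z = nz * spacing[0]
    fov_y = ny * spacing[1]
    fov_x = nx * spacing[2]
    body = _cylinder_mask(shape, spacing, (0.5 * fov_y, 0.5 * fov_x), 0.38 * fov_x)
    lesion = _sphere_mask(
        shape, spacing, (0.55 * fov_z, 0.5 * fov_y, 0.65 * fov_x), lesion_radius_mm
    ) & body
    node = _sphere_mask(
        shape, spacing, (0.25 * fov_z, 0.5 * fov_y, 0.65 * fov_x), node_radius_mm
    ) & body & ~lesion
    background = body & ~lesion & ~node

    voxel_ml = float(np.prod(spacing)) / 1000.0  # mm³ → mL
    frac_per_ml = np.zeros(shape)
    for mask, frac in [(lesion, lesion_fraction), (node, node_fraction),
                       (background, background_fraction)]:
        n = int(mask.sum())
        if n and frac > 0:
            frac_per_ml[mask] = frac / (n * voxel_ml)

    decay_factor = 2.0 ** (-injection_to_scan_min / half_life_min)
    activity = injected_dose * frac_per_ml * decay_factor
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        activity = activity + rng.normal(0.0, noise_sd, shape)

    acq = PETAcquisition(
        activity=ScalarVolume(activity, spacing, unit="a.u./mL"),
        injected_dose=injected_dose,
        injection_time=0.0,
        scan_time=injection_to_scan_min,
        half_life=half_life_min,
    )
    truth = PETPhantomTruth(
        frac_per_ml=frac_per_ml,
        lesion_mask=lesion,
        node_mask=node,
        body_mask=body,
        lesion_fraction=lesion_fraction if lesion.any() else 0.0,
        node_fraction=node_fraction if node.any() else 0.0,
        background_fraction=background_fraction if background.any() else 0.0,
        total_fraction=float(frac_per_ml.sum() * voxel_ml),
        lesion_volume_mm3=float(lesion.sum()) * float(np.prod(spacing)),
        injected_dose=injected_dose,
        seed=seed,
        spacing=tuple(spacing),
        lesion_center_mm=(0.55 * fov_z, 0.5 * fov_y, 0.65 * fov_x),
        lesion_radius_mm=lesion_radius_mm,
    )
    return acq, truth


# ---------------------------------------------------------------------------
# Lymph-node single-cell tables
# ---------------------------------------------------------------------------

#: Default antibody panel channels.
DEFAULT_CHANNELS = (
    "MHCII", "CD20", "CD3", "CD4", "CD8", "CD21", "CD68", "FoxP3", "Bcl6",
)

#: True phenotype → channels positive in that phenotype.  Channels not
#: listed are drawn from the negative component.  The marker logic mirrors
#: canonical lymph-node populations: antigen presenting cells (MHCII+),
#: B cells (CD20+), CD8 T cells (CD3+CD8+), follicular B cells (CD20+Bcl6+),
#: helper T cells (CD3+CD4+), phagocytes (CD68+), regulatory T cells
#: (CD4+FoxP3+), follicular dendritic cells (CD21+CD20-) and follicular
#: helper T cells (CD3+Bcl6+).
DEFAULT_PHENOTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "follicular dendritic cell": ("CD21",),
    "follicular B cell": ("CD20", "Bcl6"),
    "follicular helper T cell": ("CD3", "Bcl6", "CD4"),
    "regulatory T cell": ("CD3", "CD4", "FoxP3"),
    "CD8 T cell": ("CD3", "CD8"),
    "helper T cell": ("CD3", "CD4"),
    "phagocyte": ("CD68", "MHCII"),
    "B cell": ("CD20",),
    "antigen presenting cell": ("MHCII",),
    "unassigned": (),
}

#: Default phenotype composition of a stimulated draining lymph node
#: (fractions of all cells; B-cell dominated, as lymph nodes are).
DEFAULT_PHENOTYPE_FRACTIONS: dict[str, float] = {
    "follicular dendritic cell": 0.03,
    "follicular B cell": 0.15,
    "follicular helper T cell": 0.04,
    "regulatory T cell": 0.04,
    "CD8 T cell": 0.12,
    "helper T cell": 0.15,
    "phagocyte": 0.08,
    "B cell": 0.25,
    "antigen presenting cell": 0.10,
    "unassigned": 0.04,
}


@dataclass
class CellSimTruth:
    """Ground truth for a simulated lymph-node section cell table."""

    n_follicles: int
    phenotype: np.ndarray                 # per-cell true label
    channel_params: dict                  # channel → dict(neg_mean, neg_sd, pos_mean, pos_sd, pos_frac)
    follicle_centers_um: np.ndarray       # (n_follicles, 2)
    follicle_dispersion_um: float
    phenotype_fractions: dict
    field_um: tuple[float, float]
    seed: int


def make_cell_table(
    n_cells: int = 10_000,
    channels=DEFAULT_CHANNELS,
    phenotype_markers: dict | None = None,
    phenotype_fractions: dict | None = None,
    n_follicles: int = 5,
    follicle_dispersion_um: float = 40.0,
    field_um: tuple[float, float] = (1000.0, 1000.0),
    neg_mean: float = 1.0,
    neg_sd: float = 0.3,
    pos_mean: float = 8.0,
    pos_sd: float = 1.2,
    sample_id: str = "S1",
    n_rois: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, CellSimTruth]:
    """Simulate a segmented lymph-node section as a per-cell intensity table.

    Each cell carries one true phenotype; its per-channel mean intensity is
    drawn from the positive Gaussian component for the phenotype's marker
    channels and from the negative component otherwise.  Follicular
    dendritic cells sit at follicle centers, follicular B cells and
    follicular helper T cells disperse around them (Gaussian spread
    ``follicle_dispersion_um``); all other types are uniform over the field.

    The table follows the documented CSV schema: ``cell_id, sample_id,
    roi_id, x_um, y_um, area_um2, <channel>...``.
    """
    markers = dict(phenotype_markers or DEFAULT_PHENOTYPE_MARKERS)
    fractions = dict(phenotype_fractions or DEFAULT_PHENOTYPE_FRACTIONS)
    channels = list(channels)
    if set(fractions) - set(markers):
        raise ValueError("every phenotype with a fraction needs a marker rule")
    for name, chans in markers.items():
        unknown = set(chans) - set(channels)
        if unknown:
            raise ValueError(f"phenotype {name!r} references unsimulated channels {sorted(unknown)}")
    if pos_mean <= neg_mean:
        raise ValueError("positive mixture mean must exceed negative mean")
    total = sum(fractions.values())
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"phenotype fractions must sum to 1, got {total}")

    rng = np.random.default_rng(seed)
    names = list(fractions)
    probs = np.array([fractions[n] for n in names])
    labels = rng.choice(names, size=n_cells, p=probs)

    # Spatial layout: follicles for FDC / follicular populations.
    margin = 3 * follicle_dispersion_um
    centers = np.column_stack([
        rng.uniform(margin, field_um[0] - margin, n_follicles),
        rng.uniform(margin, field_um[1] - margin, n_follicles),
    ])
    xy = np.column_stack([
        rng.uniform(0, field_um[0], n_cells),
        rng.uniform(0, field_um[1], n_cells),
    ])
    follicular = np.isin(labels, ["follicular B cell", "follicular helper T cell"])
    fdc = labels == "follicular dendritic cell"
    assignment = rng.integers(0, n_follicles, n_cells)
    for sel, spread in [(fdc, 0.2 * follicle_dispersion_um),
                        (follicular, follicle_dispersion_um)]:
        n_sel = int(sel.sum())
        if n_sel:
            xy[sel] = centers[assignment[sel]] + rng.normal(0, spread, (n_sel, 2))

    intensities = np.empty((n_cells, len(channels)))
    channel_params: dict[str, dict[str, float]] = {}
    for j, ch in enumerate(channels):
        positive = np.array([ch in markers[lab] for lab in labels])
        vals = rng.normal(neg_mean, neg_sd, n_cells)
        vals[positive] = rng.normal(pos_mean, pos_sd, int(positive.sum()))
        intensities[:, j] = vals
        channel_params[ch] = {
            "neg_mean": neg_mean, "neg_sd": neg_sd,
            "pos_mean": pos_mean, "pos_sd": pos_sd,
            "pos_frac": float(positive.mean()),
        }

    roi_id = (np.arange(n_cells) % max(1, n_rois)) + 1
    table = pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),
        "sample_id": sample_id,
        "roi_id": [f"ROI{r}" for r in roi_id],
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        "area_um2": rng.uniform(30.0, 120.0, n_cells),
    })
    for j, ch in enumerate(channels):
        table[ch] = intensities[:, j]
    table["true_phenotype"] = labels

    truth = CellSimTruth(
        n_follicles=n_follicles,
        phenotype=labels,
        channel_params=channel_params,
        follicle_centers_um=centers,
        follicle_dispersion_um=follicle_dispersion_um,
        phenotype_fractions=fractions,
        field_um=tuple(field_um),
        seed=seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Temporal endpoint series
# ---------------------------------------------------------------------------

DEFAULT_TIMEPOINTS_HR = (0.0, 4.0, 24.0, 48.0, 72.0)


def lognormal_pulse(t, peak_time: float, peak_amplitude: float, width: float = 0.8):
    """Log-normal-shaped pulse peaking at ``peak_time`` with given amplitude.

    Zero at t = 0 (pre-injection baseline), rising and decaying
    asymmetrically like an acute inflammatory response curve.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = peak_amplitude * np.exp(
        -0.5 * (np.log(t[pos] / peak_time) / width) ** 2
    )
    return out


def make_endpoint_series(
    group_params: dict[str, dict] | None = None,
    cohorts=("Prime",),
    n_per_group: int = 4,
    timepoints=DEFAULT_TIMEPOINTS_HR,
    noise_cv: float = 0.2,
    baseline: float = 0.0,
    endpoint: str = "enhancement_volume_mm3",
    pulse_width: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject temporal endpoint curves with multiplicative noise.

    ``group_params`` maps treatment group → ``{"peak_time": hr,
    "peak_amplitude": value}``.  Each subject's value at t is
    ``(baseline + pulse(t)) * lognormal(mean 1, cv noise_cv)``.  The default
    groups mimic a two-platform comparison with low-amplitude carrier
    controls.

    Returns a tidy table: subject, group, cohort, time_hr, endpoint, value.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if 0.0 not in timepoints:
        raise ValueError("timepoints must include 0 (baseline)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if group_params is None:
        group_params = {
            "CMV SAM": {"peak_time": 48.0, "peak_amplitude": 8000.0},
            "CMV AS01": {"peak_time": 24.0, "peak_amplitude": 2500.0},
            "AS01": {"peak_time": 24.0, "peak_amplitude": 800.0},
            "LNP": {"peak_time": 24.0, "peak_amplitude": 900.0},
        }

    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
        mu = -0.5 * sigma ** 2  # mean-one multiplicative noise
    rows = []
    subject_counter = 0
    for cohort in cohorts:
        for group, params in group_params.items():
            mean_curve = baseline + lognormal_pulse(
                timepoints, params["peak_time"], params["peak_amplitude"],
                width=pulse_width,
            )
            for _ in range(n_per_group):
                subject_counter += 1
                subject = f"R{subject_counter:03d}"
                if noise_cv > 0:
                    noise = rng.lognormal(mu, sigma, len(timepoints))
                else:
                    noise = np.ones(len(timepoints))
                for t, v in zip(timepoints, mean_curve * noise):
                    rows.append({
                        "subject": subject, "group": group, "cohort": cohort,
                        "time_hr": float(t), "endpoint": endpoint,
                        "value": float(v),
                    })
    return pd.DataFrame(rows)


def mri_control_search_rois(truth: PhantomTruth) -> tuple[ROIMask, ROIMask]:
    """Control (contralateral left limb) and search (right limb) ROIs."""
    control = ROIMask(truth.left_limb_mask, truth.spacing, label="left_limb")
    search = ROIMask(truth.right_limb_mask, truth.spacing, label="right_limb")
    return control, search


def spherical_roi(
    shape, spacing, center_mm, radius_mm, label: str = "sphere",
    within: np.ndarray | None = None,
) -> ROIMask:
    """Spherical ROI rasterised on a voxel grid, optionally clipped.

    Threshold-based volumetry over a search region much larger than the
    lesion accumulates false positives at the tail rate of the threshold,
    so recovery analyses use an anatomically tight search sphere around the
    injection site — the counterpart of the manually drawn muscle-bed ROI.
    """
    mask = _sphere_mask(shape, spacing, center_mm, radius_mm)
    if within is not None:
        mask = mask & within
    return ROIMask(mask, spacing, label=label)
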