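"""Synthetic pulmonary-nodule phantoms and simulated observer segmentations.

The real study data (CT volumes with seven manual/automatic segmentations per
nodule) are private, so this module generates the study's raw material: CT-like
spherical nodules in three density classes — solid (SN), part-solid (pSN) and
pure ground-glass (pGGN) — plus a configurable panel of simulated "observers"
whose masks differ from the reference by a spatially smooth random boundary
perturbation.

Observer model
--------------
A mask is perturbed by thresholding its signed Euclidean distance transform
(positive inside, mm) against a smooth Gaussian random field::

    perturbed = { x : d(x) + f(x) > 0 },   f = bias_mm + jitter_mm * g(x)

where ``g`` is unit-variance low-pass-filtered white noise with correlation
length ``smoothness`` (mm).  ``bias_mm`` shifts the boundary systematically
(positive = over-segmentation), ``jitter_mm`` sets the random boundary
roughness amplitude, and the construction guarantees closed perturbed regions
with near-linear control of the boundary offset in mm.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.stats import norm

from .volume_io import MaskVolume, VolumeGrid, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "ObserverProfile",
    "StudyDesign",
    "generate_phantom",
    "simulate_observer_mask",
    "calibrate_profile_to_dice",
    "default_observer_profiles",
    "sample_nodule_specs",
    "generate_study",
    "lognormal_params_from_median_iqr",
]

NODULE_TYPES = ("SN", "pSN", "pGGN")

# CT-like attenuation defaults (HU).  Lung parenchyma is near -850 HU; solid
# nodule tissue sits around +60 HU; pure ground-glass opacity is intermediate,
# which gives pGGN a lower contrast-to-noise ratio against the background.
DEFAULT_BACKGROUND_HU = -850.0
SOLID_HU = 60.0
GGN_HU = -500.0
DEFAULT_NOISE_SD_HU = 20.0

#: per-class multiplier on observer jitter; the blurred tumor–lung interface
#: of ground-glass lesions makes their boundary effectively harder to place.
DEFAULT_CLASS_JITTER_SCALE = {"SN": 1.0, "pSN": 1.0, "pGGN": 1.25}

#: Median pairwise Dice levels of the six non-reference segmentation groups
#: (five human readers plus one automatic algorithm) that the default panel
#: is calibrated to reproduce.
DEFAULT_OBSERVER_TARGETS = {
    "B": 0.75,
    "C": 0.76,
    "D": 0.80,
    "E": 0.72,
    "F": 0.66,
    "AI": 0.69,
}

MAX_DIAMETER_MM = 30.0


def _subseed(*parts: int | str) -> int:
    """Deterministic 31-bit seed derived from heterogeneous parts."""
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


@dataclass
class PhantomSpec:
    """Geometry and attenuation of one spherical nodule phantom."""

    nodule_type: str
    diameter_mm: float
    center_mm: tuple[float, float, float]
    core_fraction: float = 0.5
    nodule_hu: float | None = None
    shell_hu: float = GGN_HU
    background_hu: float = DEFAULT_BACKGROUND_HU
    noise_sd_hu: float = DEFAULT_NOISE_SD_HU
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nodule_type not in NODULE_TYPES:
            raise ValueError(f"nodule_type must be one of {NODULE_TYPES}")
        if self.nodule_hu is None:
            self.nodule_hu = GGN_HU if self.nodule_type == "pGGN" else SOLID_HU
        if not 0 < self.diameter_mm < MAX_DIAMETER_MM:
            raise ValueError(
                f"diameter_mm must be in (0, {MAX_DIAMETER_MM}) mm (lesions of "
                f"3 cm and above are excluded); got {self.diameter_mm}"
            )
        if self.nodule_type == "pSN" and not 0.0 < self.core_fraction < 1.0:
            raise ValueError("core_fraction must be in (0, 1) for pSN")
        if self.nodule_type == "pGGN" and not (
            self.background_hu < self.nodule_hu < SOLID_HU
        ):
            raise ValueError(
                "pGGN attenuation must lie strictly between background "
                f"({self.background_hu}) and solid level ({SOLID_HU}); "
                f"got {self.nodule_hu}"
            )
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be nonnegative")
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive reals")


def _radial_distance(spec: PhantomSpec) -> np.ndarray:
    """Physical distance of every voxel center from the nodule center (mm)."""
    axes = [
        np.arange(n) * s - c
        for n, s, c in zip(spec.grid_shape, spec.spacing_mm, spec.center_mm)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(xx**2 + yy**2 + zz**2)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, MaskVolume]:
    """Render the CT-like volume and its noise-free reference mask.

    The reference mask contains the voxels whose centers lie within the
    sphere.  SN phantoms are uniformly at ``nodule_hu`` inside; pGGN at an
    intermediate attenuation; pSN combine a ground-glass shell with a solid
    core of radius ``core_fraction`` times the nodule radius.  Gaussian noise
    of sd ``noise_sd_hu`` is added everywhere.  Deterministic given ``seed``.
    """
    r = spec.diameter_mm / 2.0
    for a in range(3):
        extent = (spec.grid_shape[a] - 1) * spec.spacing_mm[a]
        if (
            spec.center_mm[a] - r < spec.spacing_mm[a] / 2
            or spec.center_mm[a] + r > extent - spec.spacing_mm[a] / 2
        ):
            raise ValueError(
                f"nodule of diameter {spec.diameter_mm} mm at {spec.center_mm} "
                f"touches the grid boundary along axis {a}; enlarge the grid "
                "or recenter"
            )
    dist = _radial_distance(spec)
    mask = dist <= r
    values = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
    if spec.nodule_type == "pSN":
        values[mask] = spec.shell_hu
        values[dist <= spec.core_fraction * r] = spec.nodule_hu
    else:
        values[mask] = spec.nodule_hu
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd_hu, size=values.shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    origin = np.zeros(3)
    return VolumeGrid(values, spacing, origin), MaskVolume(mask, spacing, origin)


@dataclass
class ObserverProfile:
    """Boundary-perturbation profile of one simulated segmentation observer.

    ``bias_mm`` is a signed systematic boundary offset (positive dilates),
    ``jitter_mm`` the random roughness amplitude, ``smoothness`` the spatial
    correlation length of the perturbation field in mm.  ``target_dice``, when
    set, marks the profile for calibration: ``jitter_mm`` is then solved so
    the profile's mean Dice against a reference mask hits the target.
    """

    name: str
    bias_mm: float = 0.0
    jitter_mm: float = 0.0
    smoothness: float = 1.5
    seed: int = 0
    target_dice: float | None = None

    def __post_init__(self) -> None:
        if self.jitter_mm < 0:
            raise ValueError("jitter_mm must be nonnegative")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


def _signed_distance_mm(mask: MaskVolume) -> np.ndarray:
    """Signed distance to the mask surface in mm: positive inside.

    The voxel-center EDT measures center-to-center distances, which
    over-counts the distance to the *surface*; subtracting a sub-voxel
    anchoring constant (0.3 of the mean spacing, between the face-neighbor
    offset and the lattice-diagonal average) re-anchors the zero level to the
    digitized boundary so a bias of +b mm dilates by b mm to within the
    voxelization error — verified against direct voxel-count oracles on
    digitized spheres.
    """
    m = mask.values
    half = 0.3 * float(np.mean(mask.spacing_mm))
    inside = ndimage.distance_transform_edt(m, sampling=mask.spacing_mm)
    outside = ndimage.distance_transform_edt(~m, sampling=mask.spacing_mm)
    return np.where(m, inside - half, half - outside)


def _smooth_unit_field(
    shape: tuple[int, ...],
    spacing_mm: np.ndarray,
    smoothness_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [smoothness_mm / s for s in spacing_mm]
    g = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = g.std()
    if sd == 0:  # degenerate (e.g. 1-voxel grid)
        return np.zeros(shape)
    return g / sd


def simulate_observer_mask(
    reference: MaskVolume,
    profile: ObserverProfile,
    nodule_seed: int,
    jitter_scale: float = 1.0,
) -> MaskVolume:
    """Perturb the reference segmentation according to an observer profile.

    Deterministic given ``(profile.seed, nodule_seed)``.  An observer
    delineates a single lesion, so only the largest 26-connected component of
    the thresholded region is kept.  If the perturbation (nearly) empties the
    mask — fewer than 2 voxels survive — the jitter is halved and the draw
    repeated (seed stream advanced) up to 5 times before raising.
    """
    if reference.n_foreground == 0:
        raise ValueError("reference mask is empty")
    d = _signed_distance_mm(reference)
    jitter = profile.jitter_mm * jitter_scale
    if profile.bias_mm == 0.0 and jitter == 0.0:
        return reference.with_values(reference.values.copy())
    struct = np.ones((3, 3, 3), dtype=bool)
    for attempt in range(6):
        rng = np.random.default_rng(
            _subseed(profile.seed, nodule_seed, attempt)
        )
        g = _smooth_unit_field(
            reference.values.shape, reference.spacing_mm, profile.smoothness, rng
        )
        f = profile.bias_mm + jitter * g
        out = d + f > 0
        if out.any():
            labels, n = ndimage.label(out, structure=struct)
            if n > 1:
                sizes = np.bincount(labels.ravel())[1:]
                out = labels == (int(np.argmax(sizes)) + 1)
            if out.sum() >= 2:
                return reference.with_values(out)
        jitter *= 0.5
    raise RuntimeError(
        f"observer {profile.name!r}: perturbation emptied the mask in 5 "
        "damped retries; reduce jitter_mm or negative bias_mm"
    )


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / (a.sum() + b.sum())


def _mean_dice(
    reference: MaskVolume,
    profile: ObserverProfile,
    n_seeds: int,
    jitter_scale: float = 1.0,
) -> float:
    vals = [
        _dice_arrays(
            reference.values,
            simulate_observer_mask(reference, profile, s, jitter_scale).values,
        )
        for s in range(n_seeds)
    ]
    return float(np.mean(vals))


def calibrate_profile_to_dice(
    reference: MaskVolume,
    target_dice: float,
    template: ObserverProfile | None = None,
    n_seeds: int = 20,
    tol: float = 0.02,
    max_jitter_mm: float = 6.0,
) -> ObserverProfile:
    """Solve for the jitter that realizes a target mean Dice on a reference.

    Bisection on ``jitter_mm`` (bias and smoothness taken from ``template``)
    until the mean Dice over ``n_seeds`` simulations is within ``tol`` of
    ``target_dice``.  Raises if the target is outside the attainable range.
    """
    if not 0 < target_dice <= 1:
        raise ValueError("target_dice must be in (0, 1]")
    template = template or ObserverProfile(name="calibrated")
    if template.jitter_mm and template.jitter_mm < max_jitter_mm:
        max_jitter_mm = max(template.jitter_mm, 1e-6)

    def realized(j: float) -> float:
        return _mean_dice(reference, replace(template, jitter_mm=j), n_seeds)

    hi_dice = realized(0.0)
    if target_dice >= hi_dice:
        if target_dice - hi_dice <= tol:
            return replace(template, jitter_mm=0.0, target_dice=target_dice)
        raise ValueError(
            f"target Dice {target_dice} unattainable: maximum with this "
            f"template is {hi_dice:.3f}"
        )
    lo_dice = realized(max_jitter_mm)
    if target_dice < lo_dice - tol:
        raise ValueError(
            f"target Dice {target_dice} unattainable: attainable range with "
            f"jitter ≤ {max_jitter_mm} mm is [{lo_dice:.3f}, {hi_dice:.3f}]"
        )
    lo_j, hi_j = 0.0, max_jitter_mm
    j = max_jitter_mm / 2
    for _ in range(40):
        j = 0.5 * (lo_j + hi_j)
        val = realized(j)
        if abs(val - target_dice) <= tol * 0.5 or hi_j - lo_j < 1e-4:
            break
        if val > target_dice:
            lo_j = j  # too little jitter, Dice too high
        else:
            hi_j = j
    return replace(template, jitter_mm=j, target_dice=target_dice)


def default_observer_profiles() -> list[ObserverProfile]:
    """The default 7-observer panel.

    Observer A is the zero-perturbation reference (the senior reader whose
    masks anchor the pairwise comparisons); the other six carry ``target_dice``
    levels matching the study's reported per-observer median Dice and are
    calibrated against a representative phantom before use.
    """
    profiles = [ObserverProfile(name="A", bias_mm=0.0, jitter_mm=0.0, seed=101)]
    for i, (name, target) in enumerate(DEFAULT_OBSERVER_TARGETS.items()):
        profiles.append(
            ObserverProfile(
                name=name, jitter_mm=1.0, seed=201 + i, target_dice=target
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Study-level sampling
# ---------------------------------------------------------------------------


def lognormal_params_from_median_iqr(
    median: float, iqr: float
) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and IQR."""
    if median <= 0 or iqr <= 0:
        raise ValueError("median and iqr must be positive")
    mu = np.log(median)
    z = norm.ppf(0.75)

    def gap(sigma: float) -> float:
        return median * (np.exp(z * sigma) - np.exp(-z * sigma)) - iqr

    sigma = brentq(gap, 1e-6, 5.0)
    return float(mu), float(sigma)


@dataclass
class StudyDesign:
    """Composition of a synthetic inter-observer study.

    Defaults mirror the source cohort: 232 nodules split 81 SN / 40 pSN /
    111 pGGN, diameters log-normal with median 0.56 cm and IQR 0.40 cm
    (truncated to 2–30 mm and to the grid), and a 7-observer panel.
    """

    n_nodules: int = 232
    type_proportions: tuple[float, float, float] = (81 / 232, 40 / 232, 111 / 232)
    diameter_median_cm: float = 0.56
    diameter_iqr_cm: float = 0.40
    observer_profiles: list[ObserverProfile] = field(
        default_factory=default_observer_profiles
    )
    class_jitter_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_JITTER_SCALE)
    )
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd_hu: float = DEFAULT_NOISE_SD_HU
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodules <= 0:
            raise ValueError("n_nodules must be positive")
        if len(self.type_proportions) != 3 or not np.isclose(
            sum(self.type_proportions), 1.0
        ):
            raise ValueError("type_proportions must be 3 reals summing to 1")
        if len(self.observer_profiles) < 2:
            raise ValueError("need at least 2 observer profiles")


def sample_nodule_specs(design: StudyDesign) -> list[PhantomSpec]:
    """Draw the per-nodule phantom specs for a study, reproducibly.

    Diameters are sampled from the truncated log-normal; the grid is enlarged
    (to even extents) for nodules that would not fit the default crop, and the
    center is jittered by up to ±1.5 mm around the grid middle.
    """
    rng = np.random.default_rng(_subseed(design.master_seed, "nodules"))
    mu, sigma = lognormal_params_from_median_iqr(
        design.diameter_median_cm * 10, design.diameter_iqr_cm * 10
    )
    types = rng.choice(NODULE_TYPES, size=design.n_nodules, p=design.type_proportions)
    specs: list[PhantomSpec] = []
    for i in range(design.n_nodules):
        d = 0.0
        while not 2.0 < d < MAX_DIAMETER_MM - 0.5:
            d = float(np.exp(rng.normal(mu, sigma)))
        shape = []
        for a in range(3):
            need = int(np.ceil((d + 8.0) / design.spacing_mm[a]))
            n = max(design.grid_shape[a], need + need % 2)
            shape.append(n)
        center = tuple(
            (shape[a] - 1) * design.spacing_mm[a] / 2 + rng.uniform(-1.5, 1.5)
            for a in range(3)
        )
        specs.append(
            PhantomSpec(
                nodule_type=str(types[i]),
                diameter_mm=d,
                center_mm=center,
                grid_shape=tuple(shape),
                spacing_mm=design.spacing_mm,
                noise_sd_hu=design.noise_sd_hu,
                seed=_subseed(design.master_seed, "phantom", i),
            )
        )
    return specs


def resolve_profiles(design: StudyDesign) -> list[ObserverProfile]:
    """Calibrate every profile that carries a ``target_dice``.

    Calibration runs against a representative solid phantom at the design's
    median diameter, so the realized per-observer median Dice over a study
    lands near the target.
    """
    ref_spec = PhantomSpec(
        nodule_type="SN",
        diameter_mm=design.diameter_median_cm * 10,
        center_mm=tuple(
            (n - 1) * s / 2 for n, s in zip(design.grid_shape, design.spacing_mm)
        ),
        grid_shape=design.grid_shape,
        spacing_mm=design.spacing_mm,
        noise_sd_hu=0.0,
        seed=_subseed(design.master_seed, "calibration"),
    )
    _, ref_mask = generate_phantom(ref_spec)
    out = []
    for p in design.observer_profiles:
        if p.target_dice is not None and p.target_dice < 1.0:
            out.append(calibrate_profile_to_dice(ref_mask, p.target_dice, template=p))
        else:
            out.append(p)
    return out


def generate_study(
    design: StudyDesign, out_dir: str | Path, fmt: str = "nii.gz"
) -> pd.DataFrame:
    """Write a full synthetic study to disk and return its manifest.

    Per nodule: one volume, one reference mask, one mask per observer, all as
    NIfTI (default) or NRRD.  The manifest CSV has one row per nodule with the
    type, true diameter, seeds and file paths; everything is a pure function
    of ``design.master_seed``.
    """
    if fmt not in ("nii.gz", "nii", "nrrd"):
        raise ValueError(f"unsupported format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = resolve_profiles(design)
    specs = sample_nodule_specs(design)
    rows = []
    for i, spec in enumerate(specs):
        nid = f"nodule{i:04d}"
        vol, ref = generate_phantom(spec)
        vol_path = out_dir / f"{nid}_volume.{fmt}"
        ref_path = out_dir / f"{nid}_mask_reference.{fmt}"
        write_volume(vol, vol_path)
        write_mask(ref, ref_path)
        row = {
            "nodule_id": nid,
            "nodule_type": spec.nodule_type,
            "true_diameter_mm": spec.diameter_mm,
            "phantom_seed": spec.seed,
            "volume_path": str(vol_path),
            "reference_mask_path": str(ref_path),
        }
        scale = design.class_jitter_scale.get(spec.nodule_type, 1.0)
        for p in profiles:
            m = simulate_observer_mask(
                ref, p, nodule_seed=_subseed(design.master_seed, "obs", i), jitter_scale=scale
            )
            mpath = out_dir / f"{nid}_mask_{p.name}.{fmt}"
            write_mask(m, mpath)
            row[f"mask_{p.name}"] = str(mpath)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
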