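"""Synthetic paired CSCT / CTAC phantoms with known calcium ground truth.

The phantom is parametric-geometric, not anatomically realistic: its job is
to exercise every pipeline stage — threshold topology, PCA shape features,
centerline distances, classifier separability, Agatston arithmetic — with
an analytically known answer.  A thorax-like scene (soft-tissue body, two
lungs, ellipsoidal heart, descending aorta, vertebral body) is rendered at
4x supersampling and block-averaged onto two grids:

* a CSCT-like grid (0.35 mm in-plane, 3 mm slices, low noise, no motion),
* a CTAC-like grid (1.35 mm in-plane, 3 mm slices, high noise, and an
  anisotropic Gaussian blur emulating unsynchronized cardiac motion).

Calcified lesions are uniform spheres (peak 130-800 HU) placed on three
labelled coronary centerlines on the heart surface; distractor calcium
(aortic-wall plaques, vertebral bone) gives the classifier realistic
negatives.  Partial-volume effects arise naturally from the area-weighted
downsampling, so the same anatomy yields systematically lower calcium
scores on the coarse CTAC grid than on the fine CSCT grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .candidates import candidates_from_mask, LesionCandidate
from .features import CoronaryTemplate, CENTERLINE_LABELS
from .scoring import agatston_score, risk_category, volume_score, ScoreRecord
from .volume import CTVolume, VoxelMask, save_volume

HU_AIR = -1000.0
HU_LUNG = -800.0
HU_SOFT_TISSUE = 40.0
HU_BLOOD = 45.0
HU_VERTEBRA = 600.0

# azimuth (deg) of each coronary curve around the heart's z axis; the
# vertebral body sits at +90 deg and the aorta near -164 deg, so these keep
# true lesions well away from distractor calcium even after motion blur
_CURVE_AZIMUTH_DEG = {"RCA": -75.0, "LAD": -15.0, "LCX": 45.0}
_CURVE_POLAR_RANGE_DEG = (30.0, 150.0)
_CURVE_N_POINTS = 40


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically invalid."""


@dataclass
class LesionSpec:
    """One spherical calcification on a labelled coronary curve.

    ``t`` in [0, 1] parametrizes the position along the curve.
    """

    label: str
    t: float
    radius_mm: float
    peak_hu: float

    def __post_init__(self) -> None:
        if self.label not in _CURVE_AZIMUTH_DEG:
            raise PhantomSpecError(f"unknown coronary label {self.label!r}")
        if not 0.0 <= self.t <= 1.0:
            raise PhantomSpecError(f"lesion position t={self.t} outside [0, 1]")
        if self.radius_mm <= 0:
            raise PhantomSpecError("lesion radius must be positive")
        if not 130.0 <= self.peak_hu <= 800.0:
            raise PhantomSpecError(f"lesion peak {self.peak_hu} HU outside [130, 800]")


@dataclass
class AorticCalcSpec:
    """A distractor plaque on the aortic wall, away from the heart."""

    z_frac: float          # fractional position along the scan's z extent
    radius_mm: float
    hu: float = 400.0


@dataclass
class PhantomSpec:
    """Scene description for one synthetic patient."""

    shape_csct: tuple[int, int, int] = (12, 160, 160)
    spacing_csct: tuple[float, float, float] = (3.0, 0.35, 0.35)
    shape_ctac: tuple[int, int, int] = (12, 42, 42)
    spacing_ctac: tuple[float, float, float] = (3.0, 1.35, 1.35)
    supersample: int = 4
    heart_scale: float = 1.0
    heart_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lesions: tuple[LesionSpec, ...] = ()
    aortic_calcs: tuple[AorticCalcSpec, ...] = ()
    noise_sd_csct: float = 10.0
    noise_sd_ctac: float = 25.0
    motion_blur_mm: float = 3.0
    seed: int = 0

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array(self.shape_csct) * np.array(self.spacing_csct)


@dataclass
class _Anatomy:
    """Resolved physical geometry (all mm, (z, y, x) order)."""

    center: np.ndarray
    body_radii: np.ndarray
    lung_offset_x: float
    lung_radii: np.ndarray
    heart_center: np.ndarray
    heart_radii: np.ndarray
    aorta_offset: np.ndarray      # (y, x) offset of the aorta axis
    aorta_radius: float
    vertebra_offset: np.ndarray   # (y, x)
    vertebra_radius: float


def _resolve_anatomy(spec: PhantomSpec) -> _Anatomy:
    center = spec.extent_mm / 2.0
    heart_center = center + np.asarray(spec.heart_shift_mm)
    heart_radii = np.array([14.0, 13.0, 13.0]) * spec.heart_scale
    return _Anatomy(
        center=center,
        body_radii=np.array([1e6, 26.0, 26.0]),   # effectively a cylinder in z
        lung_offset_x=21.0,
        lung_radii=np.array([1e6, 18.0, 8.0]),
        heart_center=heart_center,
        heart_radii=heart_radii,
        aorta_offset=np.array([-6.0, -21.0]),
        aorta_radius=4.0,
        vertebra_offset=np.array([21.0, 0.0]),
        vertebra_radius=4.5,
    )


def _curve_points(anatomy: _Anatomy, label: str, n: int = _CURVE_N_POINTS) -> np.ndarray:
    phi = np.deg2rad(_CURVE_AZIMUTH_DEG[label])
    theta = np.deg2rad(np.linspace(*_CURVE_POLAR_RANGE_DEG, n))
    u = np.stack([np.cos(theta), np.sin(theta) * np.sin(phi),
                  np.sin(theta) * np.cos(phi)], axis=1)
    return anatomy.heart_center + anatomy.heart_radii * u


def _lesion_center(anatomy: _Anatomy, lesion: LesionSpec) -> np.ndarray:
    t0, t1 = np.deg2rad(_CURVE_POLAR_RANGE_DEG)
    theta = t0 + lesion.t * (t1 - t0)
    phi = np.deg2rad(_CURVE_AZIMUTH_DEG[lesion.label])
    u = np.array([np.cos(theta), np.sin(theta) * np.sin(phi),
                  np.sin(theta) * np.cos(phi)])
    return anatomy.heart_center + anatomy.heart_radii * u


def _aortic_calc_center(anatomy: _Anatomy, spec: PhantomSpec, calc: AorticCalcSpec) -> np.ndarray:
    # on the aortic wall, on the side facing away from the heart
    away = anatomy.aorta_offset / np.linalg.norm(anatomy.aorta_offset)
    yx = anatomy.center[1:] + anatomy.aorta_offset + away * anatomy.aorta_radius
    z = calc.z_frac * spec.extent_mm[0]
    return np.array([z, yx[0], yx[1]])


def validate_spec(spec: PhantomSpec) -> None:
    """Reject lesions outside the volume or closer than a 3 mm surface gap."""
    anatomy = _resolve_anatomy(spec)
    extent = spec.extent_mm
    centers = [_lesion_center(anatomy, l) for l in spec.lesions]
    for lesion, c in zip(spec.lesions, centers):
        if np.any(c - lesion.radius_mm < 0) or np.any(c + lesion.radius_mm > extent):
            raise PhantomSpecError(
                f"lesion on {lesion.label} at t={lesion.t:.2f} extends outside the volume"
            )
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            gap = np.linalg.norm(centers[i] - centers[j]) \
                - spec.lesions[i].radius_mm - spec.lesions[j].radius_mm
            # 6 mm keeps lesions separated by more than one coarse-grid voxel
            # diagonal, so distinct lesions never share or touch voxels
            if gap < 6.0:
                raise PhantomSpecError(
                    f"lesions {i} and {j} are {gap:.1f} mm apart (need >= 6 mm surface gap)"
                )


def _axis_coords(n: int, step: float) -> np.ndarray:
    return (np.arange(n, dtype=np.float32) + 0.5) * np.float32(step)


def _block_mean(arr: np.ndarray, f: int) -> np.ndarray:
    s = arr.shape
    return arr.reshape(s[0] // f, f, s[1] // f, f, s[2] // f, f).mean(axis=(1, 3, 5))


def _sphere_box(center, radius, steps, n_super, f):
    """f-aligned supersampled index slices of a sphere's bounding box."""
    lo = np.floor((np.asarray(center) - radius) / np.asarray(steps)).astype(int)
    hi = np.ceil((np.asarray(center) + radius) / np.asarray(steps)).astype(int) + 1
    lo = np.maximum(lo // f * f, 0)
    hi = np.minimum(-(-hi // f) * f, n_super)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _render_scan(
    spec: PhantomSpec,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    blur_mm: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[CTVolume, CTVolume, list[VoxelMask]]:
    """Render one scan type.

    Returns (noisy volume, noise-free volume, per-lesion truth masks).
    Truth masks are voxels at or above 130 HU in the noise-free (but
    motion-blurred, for CTAC) rendering that receive signal from the lesion.
    The body, lungs, aorta and vertebra are z-invariant, so they are
    rendered as 2D cross-sections broadcast across slices; spheres are
    painted only inside their bounding boxes.
    """
    anatomy = _resolve_anatomy(spec)
    f = spec.supersample
    n_super = np.array(shape) * f
    steps = np.array(spacing) / f
    z = _axis_coords(n_super[0], steps[0])
    y = _axis_coords(n_super[1], steps[1])
    x = _axis_coords(n_super[2], steps[2])
    c = anatomy.center.astype(np.float32)

    def ellipse2d(center_yx, radii_yx):
        return ((y[:, None] - center_yx[0]) / radii_yx[0]) ** 2 \
            + ((x[None, :] - center_yx[1]) / radii_yx[1]) ** 2 <= 1.0

    plane = np.full((n_super[1], n_super[2]), HU_AIR, np.float32)
    body2d = ellipse2d(c[1:], anatomy.body_radii[1:])
    plane[body2d] = HU_SOFT_TISSUE
    for sign in (-1.0, 1.0):
        lung2d = ellipse2d(c[1:] + [0.0, sign * anatomy.lung_offset_x],
                           anatomy.lung_radii[1:])
        plane[lung2d & body2d] = HU_LUNG
    plane[ellipse2d(c[1:] + anatomy.aorta_offset,
                    (anatomy.aorta_radius, anatomy.aorta_radius))] = HU_BLOOD
    plane[ellipse2d(c[1:] + anatomy.vertebra_offset,
                    (anatomy.vertebra_radius, anatomy.vertebra_radius))] = HU_VERTEBRA
    hu = np.broadcast_to(plane, tuple(n_super)).copy()

    # heart ellipsoid: per-slice elliptical cross-sections
    hc, hr = anatomy.heart_center, anatomy.heart_radii
    r2_yx = ((y[:, None] - hc[1]) / hr[1]) ** 2 + ((x[None, :] - hc[2]) / hr[2]) ** 2
    z_budget = 1.0 - ((z - hc[0]) / hr[0]) ** 2
    for iz in np.flatnonzero(z_budget > 0):
        hu[iz][r2_yx <= z_budget[iz]] = HU_BLOOD

    def paint_sphere(center, radius, value):
        box = _sphere_box(center, radius, steps, n_super, f)
        zz = z[box[0]][:, None, None]
        yy = y[box[1]][None, :, None]
        xx = x[box[2]][None, None, :]
        mask = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                + (xx - center[2]) ** 2 <= radius ** 2)
        hu[box][mask] = value
        return box, mask

    for calc in spec.aortic_calcs:
        paint_sphere(_aortic_calc_center(anatomy, spec, calc), calc.radius_mm, calc.hu)

    lesion_fields = []
    for lesion in spec.lesions:
        # blur margin keeps the locally computed halo faithful to a
        # full-volume convolution
        margin = 4.0 * blur_mm + max(spacing)
        center = _lesion_center(anatomy, lesion)
        paint_sphere(center, lesion.radius_mm, lesion.peak_hu)
        box = _sphere_box(center, lesion.radius_mm + margin, steps, n_super, f)
        zz = z[box[0]][:, None, None]
        yy = y[box[1]][None, :, None]
        xx = x[box[2]][None, None, :]
        fld = (((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                + (xx - center[2]) ** 2) <= lesion.radius_mm ** 2).astype(np.float32)
        lesion_fields.append((box, fld, lesion))

    sigma_vox = None
    if blur_mm > 0:
        # motion is predominantly in-plane; a weak z component models
        # through-plane drift during the non-gated acquisition
        sigma_mm = np.array([0.3 * blur_mm, blur_mm, blur_mm])
        sigma_vox = sigma_mm / steps
        hu = ndimage.gaussian_filter(hu, sigma=sigma_vox)

    clean = _block_mean(hu, f).astype(np.float32)
    origin = tuple(np.array(spacing) / 2.0)
    clean_vol = CTVolume(data=clean, spacing=spacing, origin=origin)

    truth_masks = []
    supra = clean >= 130.0
    for box, fld, lesion in lesion_fields:
        if sigma_vox is not None:
            fld = ndimage.gaussian_filter(fld, sigma=sigma_vox)
        frac = _block_mean(fld, f)
        # a voxel belongs to the lesion's truth only if the lesion's own
        # (possibly blurred) volume fraction suffices to lift it over the
        # 130 HU threshold from the blood-pool level; supra-threshold
        # voxels owed to nearby distractor calcium are thereby excluded
        frac_min = (130.0 - HU_BLOOD) / (lesion.peak_hu - HU_BLOOD)
        coarse = tuple(slice(s.start // f, s.stop // f) for s in box)
        data = np.zeros(shape, bool)
        data[coarse] = supra[coarse] & (frac >= frac_min)
        truth_masks.append(VoxelMask(data=data, spacing=spacing, origin=origin))

    noisy = clean.copy()
    if noise_sd > 0:
        noisy = noisy + rng.normal(0.0, noise_sd, size=noisy.shape).astype(np.float32)
        # scanners deliver the bounded HU range; keeps volumes round-trip safe
        noisy = np.clip(noisy, -1024.0, 3071.0)
    noisy_vol = CTVolume(data=noisy, spacing=spacing, origin=origin)
    return noisy_vol, clean_vol, truth_masks


@dataclass
class PhantomTruth:
    """Ground truth of one synthetic patient, per scan type."""

    lesion_masks: dict[str, list[VoxelMask]]       # scan type -> per-lesion masks
    lesions: dict[str, list[LesionCandidate]]      # scan type -> scoreable lesions
    agatston: dict[str, float]
    volume_mm3: dict[str, float]
    centerlines: dict[str, np.ndarray]
    clean: dict[str, CTVolume]                     # noise-free volumes

    def union_mask(self, scan_type: str) -> VoxelMask:
        masks = self.lesion_masks[scan_type]
        first = masks[0] if masks else None
        ref = self.clean[scan_type]
        data = np.zeros(ref.shape, bool)
        for m in masks:
            data |= m.data
        return VoxelMask(data=data, spacing=ref.spacing, origin=ref.origin)


def _truth_lesions(
    masks: list[VoxelMask], clean: CTVolume
) -> list[LesionCandidate]:
    """Scoreable truth lesions: connected components of each per-lesion mask
    with the same >= 2 voxel rule the candidate extractor applies."""
    lesions: list[LesionCandidate] = []
    for mask in masks:
        lesions.extend(candidates_from_mask(mask, clean))
    for i, lesion in enumerate(lesions):
        lesion.id = i + 1
    return lesions


def generate_pair(spec: PhantomSpec) -> tuple[CTVolume, CTVolume, PhantomTruth]:
    """Render one patient: (CSCT-like, CTAC-like, ground truth).

    Both volumes show the same anatomy; the CSCT rendering is fine-grid,
    low-noise and motion-free, the CTAC rendering coarse-grid, noisy and
    motion-blurred.  Identical seeds give identical output.
    """
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    anatomy = _resolve_anatomy(spec)

    csct, csct_clean, csct_masks = _render_scan(
        spec, spec.shape_csct, spec.spacing_csct, 0.0, spec.noise_sd_csct, rng
    )
    ctac, ctac_clean, ctac_masks = _render_scan(
        spec, spec.shape_ctac, spec.spacing_ctac, spec.motion_blur_mm,
        spec.noise_sd_ctac, rng
    )

    truth = PhantomTruth(
        lesion_masks={"CSCT": csct_masks, "CTAC": ctac_masks},
        lesions={}, agatston={}, volume_mm3={},
        centerlines={label: _curve_points(anatomy, label) for label in CENTERLINE_LABELS},
        clean={"CSCT": csct_clean, "CTAC": ctac_clean},
    )
    for scan_type, masks, clean in (
        ("CSCT", csct_masks, csct_clean), ("CTAC", ctac_masks, ctac_clean)
    ):
        lesions = _truth_lesions(masks, clean)
        truth.lesions[scan_type] = lesions
        truth.agatston[scan_type] = agatston_score(lesions, clean)
        truth.volume_mm3[scan_type] = volume_score(lesions, clean)
    return csct, ctac, truth


def make_template(spec: PhantomSpec | None = None) -> CoronaryTemplate:
    """Canonical-geometry template for coronary-tree estimation.

    The registration mask is the body region (HU > -200) of the noise-free
    CTAC rendering of the canonical (unscaled, unshifted) anatomy, matching
    how the subject-side region is segmented.
    """
    spec = replace(
        spec or PhantomSpec(),
        heart_scale=1.0, heart_shift_mm=(0.0, 0.0, 0.0),
        lesions=(), aortic_calcs=(), noise_sd_csct=0.0, noise_sd_ctac=0.0,
        motion_blur_mm=0.0,
    )
    anatomy = _resolve_anatomy(spec)
    _, clean, _ = _render_scan(
        spec, spec.shape_ctac, spec.spacing_ctac, 0.0, 0.0,
        np.random.default_rng(0),
    )
    mask = VoxelMask(data=np.asarray(clean.data) > -200.0,
                     spacing=clean.spacing, origin=clean.origin)
    return CoronaryTemplate(
        mask=mask,
        centerlines={label: _curve_points(anatomy, label) for label in CENTERLINE_LABELS},
        heart_center_mm=tuple(anatomy.heart_center),
        heart_half_extent_mm=tuple(anatomy.heart_radii),
    )


@dataclass
class CohortRanges:
    """Per-patient sampling ranges for :func:`generate_cohort`."""

    n_lesions: tuple[int, int] = (1, 6)
    lesion_radius_mm: tuple[float, float] = (2.0, 4.5)
    lesion_peak_hu: tuple[float, float] = (220.0, 750.0)
    n_aortic_calcs: tuple[int, int] = (1, 3)
    aortic_calc_radius_mm: tuple[float, float] = (1.5, 3.0)
    aortic_calc_hu: tuple[float, float] = (200.0, 600.0)
    heart_scale: tuple[float, float] = (0.92, 1.08)
    heart_shift_mm: float = 1.5
    zero_cac_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_lesions", "lesion_radius_mm", "lesion_peak_hu",
                     "n_aortic_calcs", "aortic_calc_radius_mm", "aortic_calc_hu",
                     "heart_scale"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0.0 <= self.zero_cac_fraction <= 1.0:
            raise ValueError("zero_cac_fraction must be in [0, 1]")


@dataclass
class PhantomPatient:
    patient_id: str
    spec: PhantomSpec
    csct: CTVolume
    ctac: CTVolume
    truth: PhantomTruth


@dataclass
class Cohort:
    patients: list[PhantomPatient]
    template: CoronaryTemplate
    truth_scores: pd.DataFrame


def _sample_spec(
    base: PhantomSpec, ranges: CohortRanges, rng: np.random.Generator, zero_cac: bool
) -> PhantomSpec:
    spec = replace(
        base,
        heart_scale=float(rng.uniform(*ranges.heart_scale)),
        heart_shift_mm=tuple(rng.uniform(-ranges.heart_shift_mm, ranges.heart_shift_mm, 3)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    n_calcs = int(rng.integers(ranges.n_aortic_calcs[0], ranges.n_aortic_calcs[1] + 1))
    spec = replace(spec, aortic_calcs=tuple(
        AorticCalcSpec(
            z_frac=float(rng.uniform(0.2, 0.8)),
            radius_mm=float(rng.uniform(*ranges.aortic_calc_radius_mm)),
            hu=float(rng.uniform(*ranges.aortic_calc_hu)),
        )
        for _ in range(n_calcs)
    ))
    if zero_cac:
        return spec
    n_lesions = int(rng.integers(ranges.n_lesions[0], ranges.n_lesions[1] + 1))
    lesions: list[LesionSpec] = []
    for _ in range(n_lesions):
        for _attempt in range(200):
            cand = LesionSpec(
                label=str(rng.choice(CENTERLINE_LABELS)),
                t=float(rng.uniform(0.05, 0.95)),
                radius_mm=float(rng.uniform(*ranges.lesion_radius_mm)),
                peak_hu=float(rng.uniform(*ranges.lesion_peak_hu)),
            )
            try:
                validate_spec(replace(spec, lesions=tuple(lesions + [cand])))
            except PhantomSpecError:
                continue
            lesions.append(cand)
            break
    return replace(spec, lesions=tuple(lesions))


def generate_cohort(
    n_patients: int,
    seed: int = 0,
    ranges: CohortRanges | None = None,
    base_spec: PhantomSpec | None = None,
) -> Cohort:
    """Generate a cohort of independent synthetic patients.

    Each patient draws a spec from ``ranges`` with a per-patient derived
    seed; ``zero_cac_fraction`` of patients (rounded down, at least one for
    fractions > 0 in cohorts of >= 10) carry no coronary lesions, echoing
    the zero-score subgroup of a clinical population.  The returned truth
    score table has one row per patient and scan type.
    """
    if n_patients < 1:
        raise ValueError("cohort needs at least one patient")
    ranges = ranges or CohortRanges()
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    n_zero = int(round(ranges.zero_cac_fraction * n_patients))
    zero_flags = np.zeros(n_patients, bool)
    zero_flags[rng.choice(n_patients, size=n_zero, replace=False)] = True

    patients, rows = [], []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        spec = _sample_spec(base, ranges, rng, zero_cac=bool(zero_flags[i]))
        csct, ctac, truth = generate_pair(spec)
        patients.append(PhantomPatient(pid, spec, csct, ctac, truth))
        for scan_type in ("CSCT", "CTAC"):
            rows.append(
                {
                    "patient_id": pid,
                    "scan_type": scan_type,
                    "agatston": truth.agatston[scan_type],
                    "volume_mm3": truth.volume_mm3[scan_type],
                    "n_lesions": len(truth.lesions[scan_type]),
                    "category": risk_category(truth.agatston[scan_type]),
                }
            )
    return Cohort(
        patients=patients,
        template=make_template(base),
        truth_scores=pd.DataFrame(rows),
    )


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> None:
    """Write volumes, truth masks, template and score table to ``out_dir``."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    cohort.template.save(out_dir)
    for patient in cohort.patients:
        pdir = os.path.join(out_dir, patient.patient_id)
        os.makedirs(pdir, exist_ok=True)
        save_volume(patient.csct, os.path.join(pdir, "csct.nii.gz"))
        save_volume(patient.ctac, os.path.join(pdir, "ctac.nii.gz"))
        for scan_type in ("CSCT", "CTAC"):
            save_volume(
                patient.truth.union_mask(scan_type),
                os.path.join(pdir, f"truth_{scan_type.lower()}.nii.gz"),
            )
    cohort.truth_scores.to_csv(os.path.join(out_dir, "truth_scores.csv"), index=False)
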