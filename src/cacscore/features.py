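"""Per-candidate features: volume, shape, intensity and location.

Shape is summarised by ratios of the eigenvalues of the covariance of the
candidate's voxel coordinates (a principal component analysis); working in
physical millimetres keeps 3 mm slices from distorting the ratios.
Intensity combines raw HU statistics with statistics of Gaussian-smoothed
copies of the volume at several physical scales, which capture how a
candidate behaves under blurring — small noise specks vanish, real
calcifications persist.  Location is described by distances to an estimate
of the coronary artery tree, obtained by mapping a labelled template into
the subject with an affine moment-matching transform, plus the candidate
position in heart-centred normalized coordinates.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .candidates import LesionCandidate
from .volume import CTVolume, VoxelMask, load_mask, save_volume

CENTERLINE_LABELS = ("RCA", "LAD", "LCX")

FEATURE_SCHEMA_VERSION = "cacscore-features-1"


class TreeEstimationError(RuntimeError):
    """Raised when no heart-like region can be located in the subject."""


@dataclass
class FeatureConfig:
    """Feature computation settings.

    gaussian_scales_mm
        Physical standard deviations of the Gaussian smoothing stages.
    body_threshold_hu
        Intensity above which a voxel is considered part of the body
        (excludes air and lung) when estimating the template transform.
    """

    gaussian_scales_mm: tuple[float, ...] = (1.0, 2.0, 4.0)
    body_threshold_hu: float = -200.0

    def feature_names(self) -> list[str]:
        names = ["volume_mm3", "shape_r21", "shape_r31", "shape_r32",
                 "int_max", "int_mean", "int_sd"]
        for s in self.gaussian_scales_mm:
            tag = f"{s:g}mm"
            names += [f"int_smooth{tag}_max", f"int_smooth{tag}_mean"]
        for label in CENTERLINE_LABELS:
            names.append(f"loc_dist_{label.lower()}_mm")
        names += ["loc_dist_union_mm", "loc_norm_z", "loc_norm_y", "loc_norm_x"]
        return names


@dataclass
class CoronaryTemplate:
    """Labelled template: registration mask, centerlines, heart geometry.

    ``mask`` is the body-region mask used for moment matching; centerline
    polylines are in the template's physical mm coordinates.
    """

    mask: VoxelMask
    centerlines: dict[str, np.ndarray]           # label -> (n, 3) mm points
    heart_center_mm: tuple[float, float, float]
    heart_half_extent_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        for label, pts in self.centerlines.items():
            pts = np.asarray(pts, float)
            if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
                raise ValueError(f"centerline {label!r} must be an (n>=2, 3) point array")
            self.centerlines[label] = pts

    def save(self, directory: str | os.PathLike, stem: str = "template") -> None:
        directory = os.fspath(directory)
        save_volume(self.mask, os.path.join(directory, f"{stem}_mask.nii.gz"))
        payload = {
            "heart_center_mm": list(self.heart_center_mm),
            "heart_half_extent_mm": list(self.heart_half_extent_mm),
            "centerlines": [
                {"label": label, "points_mm": pts.tolist()}
                for label, pts in self.centerlines.items()
            ],
        }
        with open(os.path.join(directory, f"{stem}.json"), "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, directory: str | os.PathLike, stem: str = "template") -> "CoronaryTemplate":
        directory = os.fspath(directory)
        mask = load_mask(os.path.join(directory, f"{stem}_mask.nii.gz"))
        with open(os.path.join(directory, f"{stem}.json")) as fh:
            payload = json.load(fh)
        centerlines = {
            entry["label"]: np.asarray(entry["points_mm"], float)
            for entry in payload["centerlines"]
        }
        return cls(
            mask=mask,
            centerlines=centerlines,
            heart_center_mm=tuple(payload["heart_center_mm"]),
            heart_half_extent_mm=tuple(payload["heart_half_extent_mm"]),
        )


@dataclass
class CoronaryTreeEstimate:
    """Centerlines mapped into a subject grid plus per-label distance maps."""

    centerlines: dict[str, np.ndarray]           # label -> (n, 3) mm points
    distance_maps: dict[str, np.ndarray]         # label and "union" -> mm field
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    heart_center_mm: tuple[float, float, float]
    heart_half_extent_mm: tuple[float, float, float]


def shape_features(
    candidate: LesionCandidate, spacing: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Eigenvalue ratios (r21, r31, r32) of the voxel-coordinate PCA.

    Eigenvalues of the covariance of physical (mm) voxel positions, sorted
    descending (l1 >= l2 >= l3); a ratio with a zero denominator is 0 by
    convention (degenerate flat/linear candidates).
    """
    if candidate.n_voxels < 2:
        raise ValueError("shape features require >= 2 voxels")
    coords = candidate.voxel_indices * np.asarray(spacing, float)
    cov = np.cov(coords.T, bias=True)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    l1, l2, l3 = eigvals

    def ratio(num: float, den: float) -> float:
        return float(num / den) if den > 0 else 0.0

    return ratio(l2, l1), ratio(l3, l1), ratio(l3, l2)


def smooth_volume(volume: CTVolume, scale_mm: float) -> np.ndarray:
    """Gaussian-smooth with a physical sigma, converted per axis to voxels."""
    if scale_mm <= 0:
        raise ValueError(f"Gaussian scale must be > 0 mm, got {scale_mm}")
    sigma_vox = [scale_mm / s for s in volume.spacing]
    return ndimage.gaussian_filter(np.asarray(volume.data, float), sigma=sigma_vox)


def intensity_features(
    candidate: LesionCandidate,
    volume: CTVolume,
    scales_mm: tuple[float, ...] = (1.0, 2.0, 4.0),
    smoothed: dict[float, np.ndarray] | None = None,
) -> dict[str, float]:
    """Raw and multi-scale smoothed intensity statistics over member voxels.

    ``smoothed`` may carry precomputed smoothed arrays keyed by scale so the
    (whole-volume) filtering is done once per scan, not per candidate.
    """
    if not scales_mm:
        raise ValueError("at least one Gaussian scale is required")
    zz, yy, xx = candidate.voxel_indices.T
    values = np.asarray(volume.data, float)[zz, yy, xx]
    out = {
        "int_max": float(values.max()),
        "int_mean": float(values.mean()),
        "int_sd": float(values.std()),
    }
    for s in scales_mm:
        arr = smoothed[s] if smoothed is not None else smooth_volume(volume, s)
        sm = arr[zz, yy, xx]
        tag = f"{s:g}mm"
        out[f"int_smooth{tag}_max"] = float(sm.max())
        out[f"int_smooth{tag}_mean"] = float(sm.mean())
    return out


def _mask_moments(mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray):
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise TreeEstimationError("no foreground voxels for moment matching")
    pts = idx * spacing + origin
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T, bias=True)
    return centroid, cov


def _moment_affine(cov_subject: np.ndarray, cov_template: np.ndarray) -> np.ndarray:
    """Linear part mapping template second moments onto the subject's.

    Uses matched principal axes when the spectra are well separated; with
    near-degenerate eigenvalues the principal directions are unstable, so
    the transform falls back to per-axis scaling.
    """
    ws, vs = np.linalg.eigh(cov_subject)
    wt, vt = np.linalg.eigh(cov_template)
    ws, wt = ws[::-1], wt[::-1]
    vs, vt = vs[:, ::-1], vt[:, ::-1]

    def well_separated(w):
        return np.all(np.diff(w) < -0.10 * w[0])

    if well_separated(ws) and well_separated(wt):
        # deterministic sign: largest-magnitude component of each axis positive
        for v in (vs, vt):
            for k in range(3):
                if v[np.argmax(np.abs(v[:, k])), k] < 0:
                    v[:, k] *= -1
        scale = np.sqrt(np.clip(ws, 1e-12, None) / np.clip(wt, 1e-12, None))
        return vs @ np.diag(scale) @ vt.T
    diag_s = np.sqrt(np.clip(np.diag(cov_subject), 1e-12, None))
    diag_t = np.sqrt(np.clip(np.diag(cov_template), 1e-12, None))
    return np.diag(diag_s / diag_t)


def _rasterize_polyline(points_mm: np.ndarray, volume_like) -> np.ndarray:
    """Binary voxel raster of a polyline, densely resampled below voxel pitch."""
    spacing = np.asarray(volume_like.spacing)
    shape = volume_like.data.shape if hasattr(volume_like, "data") else volume_like.shape
    step = spacing.min() / 2.0
    samples = []
    for a, b in zip(points_mm[:-1], points_mm[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        samples.append(a + t * (b - a))
    pts = np.vstack(samples)
    idx = np.rint((pts - np.asarray(volume_like.origin)) / spacing).astype(int)
    keep = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    raster = np.zeros(shape, bool)
    raster[tuple(idx[keep].T)] = True
    return raster


def estimate_coronary_tree(
    volume: CTVolume,
    template: CoronaryTemplate,
    body_threshold_hu: float = -200.0,
) -> CoronaryTreeEstimate:
    """Map the template's coronary centerlines into ``volume``.

    The subject's body region (HU above ``body_threshold_hu``) is aligned
    with the template mask by matching intensity-mask moments: centroid,
    principal axes and per-axis scale define an affine transform, which is
    applied to the centerlines and the heart geometry.  Distance maps (mm)
    are then computed per label and for the union with an exact Euclidean
    distance transform.
    """
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    subject_mask = np.asarray(volume.data) > body_threshold_hu
    if not subject_mask.any() or subject_mask.all():
        raise TreeEstimationError(
            "subject volume has no contrast at the body threshold; cannot register"
        )
    c_subj, cov_subj = _mask_moments(subject_mask, spacing, origin)
    c_tmpl, cov_tmpl = _mask_moments(
        template.mask.data, np.asarray(template.mask.spacing), np.asarray(template.mask.origin)
    )
    A = _moment_affine(cov_subj, cov_tmpl)

    def apply(points: np.ndarray) -> np.ndarray:
        return (points - c_tmpl) @ A.T + c_subj

    centerlines = {label: apply(pts) for label, pts in template.centerlines.items()}
    heart_center = apply(np.asarray(template.heart_center_mm)[None, :])[0]
    half_extent = np.abs(A @ np.asarray(template.heart_half_extent_mm))

    distance_maps: dict[str, np.ndarray] = {}
    union_raster = np.zeros(volume.shape, bool)
    for label, pts in centerlines.items():
        raster = _rasterize_polyline(pts, volume)
        union_raster |= raster
        distance_maps[label] = ndimage.distance_transform_edt(~raster, sampling=spacing)
    distance_maps["union"] = ndimage.distance_transform_edt(~union_raster, sampling=spacing)

    return CoronaryTreeEstimate(
        centerlines=centerlines,
        distance_maps=distance_maps,
        spacing=tuple(spacing),
        origin=tuple(origin),
        heart_center_mm=tuple(heart_center),
        heart_half_extent_mm=tuple(half_extent),
    )


def location_features(
    candidate: LesionCandidate, tree: CoronaryTreeEstimate
) -> dict[str, float]:
    """Distances to each labelled centerline and heart-centred coordinates.

    Distance maps are sampled at the candidate centroid with trilinear
    interpolation; normalized coordinates are (centroid - heart centre)
    divided by the heart bounding-box half-extent per axis.
    """
    centroid = np.asarray(candidate.centroid_mm)
    idx = (centroid - np.asarray(tree.origin)) / np.asarray(tree.spacing)
    shape = np.asarray(next(iter(tree.distance_maps.values())).shape)
    if np.any(idx < -0.5) or np.any(idx > shape - 0.5):
        raise ValueError(f"candidate centroid {tuple(centroid)} lies outside the volume")
    out: dict[str, float] = {}
    for label in CENTERLINE_LABELS:
        out[f"loc_dist_{label.lower()}_mm"] = float(
            ndimage.map_coordinates(tree.distance_maps[label], idx[:, None], order=1,
                                    mode="nearest")[0]
        )
    out["loc_dist_union_mm"] = float(
        ndimage.map_coordinates(tree.distance_maps["union"], idx[:, None], order=1,
                                mode="nearest")[0]
    )
    norm = (centroid - np.asarray(tree.heart_center_mm)) / np.asarray(tree.heart_half_extent_mm)
    out["loc_norm_z"], out["loc_norm_y"], out["loc_norm_x"] = map(float, norm)
    return out


def featurize(
    candidates: list[LesionCandidate],
    volume: CTVolume,
    tree: CoronaryTreeEstimate,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Assemble the full feature matrix, one row per candidate, order kept.

    Columns follow ``config.feature_names()`` — the stable, versioned schema
    (:data:`FEATURE_SCHEMA_VERSION`).
    """
    config = config or FeatureConfig()
    names = config.feature_names()
    if not candidates:
        return pd.DataFrame(columns=names)
    smoothed = {s: smooth_volume(volume, s) for s in config.gaussian_scales_mm}
    rows = []
    for cand in candidates:
        r21, r31, r32 = shape_features(cand, volume.spacing)
        row = {"volume_mm3": cand.volume_mm3,
               "shape_r21": r21, "shape_r31": r31, "shape_r32": r32}
        row.update(intensity_features(cand, volume, config.gaussian_scales_mm, smoothed))
        row.update(location_features(cand, tree))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=names)
    if not np.isfinite(frame.to_numpy(float)).all():
        raise ValueError("non-finite feature values produced")
    return frame
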