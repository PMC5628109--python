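"""Lesion candidate extraction by thresholding and 3D connected components.

Potential calcifications are the maximal connected sets of voxels at or
above the scoring threshold (130 HU by clinical convention).  Single-voxel
components are discarded: at attenuation-map noise levels an isolated
supra-threshold voxel cannot be distinguished from noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume, VoxelMask

DEFAULT_THRESHOLD_HU = 130.0

# structuring elements for the three standard 3D neighbourhood orders
_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LesionCandidate:
    """A connected supra-threshold component with derived summaries.

    ``per_slice`` maps each axial slice index z to ``(voxel count, max HU)``
    within that slice — the substrate of the per-slice Agatston terms.
    """

    id: int
    voxel_indices: np.ndarray          # (n, 3) int array of (z, y, x)
    volume_mm3: float
    max_hu: float
    centroid_mm: tuple[float, float, float]
    per_slice: dict[int, tuple[int, float]]

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    def mask(self, volume: CTVolume) -> VoxelMask:
        m = VoxelMask.like(volume)
        zz, yy, xx = self.voxel_indices.T
        m.data[zz, yy, xx] = True
        return m


def _component_to_candidate(
    cid: int, indices: np.ndarray, volume: CTVolume
) -> LesionCandidate:
    zz, yy, xx = indices.T
    values = np.asarray(volume.data, float)[zz, yy, xx]
    per_slice: dict[int, tuple[int, float]] = {}
    for z in np.unique(zz):
        in_slice = zz == z
        per_slice[int(z)] = (int(in_slice.sum()), float(values[in_slice].max()))
    centroid = volume.index_to_physical(indices.mean(axis=0))
    return LesionCandidate(
        id=cid,
        voxel_indices=indices,
        volume_mm3=len(indices) * volume.voxel_volume_mm3,
        max_hu=float(values.max()),
        centroid_mm=tuple(centroid),
        per_slice=per_slice,
    )


def extract_candidates(
    volume: CTVolume,
    threshold: float = DEFAULT_THRESHOLD_HU,
    connectivity: int = 26,
    min_voxels: int = 2,
) -> list[LesionCandidate]:
    """Extract candidate lesions from ``volume``.

    Components are maximal connected sets of voxels with HU >= ``threshold``
    (inclusive, matching the 130–199 Agatston weight band) under the chosen
    neighbourhood order.  Components smaller than ``min_voxels`` (default 2)
    are dropped.  Candidates are ordered by decreasing volume with ties
    broken by the (z,y,x) of their first voxel in lexicographic scan order;
    ids are 1..n in that order.

    Parameters
    ----------
    connectivity
        3D neighbourhood order: 6 (faces), 18 (faces+edges) or 26 (full).
    """
    if volume.data.size == 0:
        raise ValueError("cannot extract candidates from an empty volume")
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}, got {connectivity}")
    if threshold < -1024:
        raise ValueError(f"threshold {threshold} below the HU floor")

    binary = np.asarray(volume.data) >= threshold
    labels, n = ndimage.label(binary, structure=_STRUCTS[connectivity])
    if n == 0:
        return []

    # voxel lists per component, in lexicographic scan order
    all_idx = np.argwhere(labels > 0)
    lab_flat = labels[all_idx[:, 0], all_idx[:, 1], all_idx[:, 2]]
    order = np.argsort(lab_flat, kind="stable")
    all_idx, lab_flat = all_idx[order], lab_flat[order]
    splits = np.searchsorted(lab_flat, np.arange(2, n + 1))
    comps = [c for c in np.split(all_idx, splits) if len(c) >= min_voxels]

    # sort by decreasing size, ties by first voxel in scan order
    comps.sort(key=lambda c: (-len(c), tuple(c[0])))
    return [_component_to_candidate(i + 1, c, volume) for i, c in enumerate(comps)]


def candidates_from_mask(
    mask: VoxelMask,
    volume: CTVolume,
    connectivity: int = 26,
    min_voxels: int = 2,
) -> list[LesionCandidate]:
    """Connected components of a binary mask, summarised against ``volume``.

    Applies the same >= ``min_voxels`` rule and ordering as
    :func:`extract_candidates`; used to score reference masks with the exact
    machinery used for automatic detections.
    """
    if mask.data.shape != volume.shape:
        raise ValueError("mask and volume grids differ")
    labels, n = ndimage.label(mask.data, structure=_STRUCTS[connectivity])
    comps = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) >= min_voxels:
            comps.append(idx)
    comps.sort(key=lambda c: (-len(c), tuple(c[0])))
    return [_component_to_candidate(i + 1, c, volume) for i, c in enumerate(comps)]


def candidates_to_frame(candidates: list[LesionCandidate]) -> pd.DataFrame:
    """Tabulate candidates (id, n_voxels, volume, max HU, centroid) for CSV export."""
    rows = [
        {
            "id": c.id,
            "n_voxels": c.n_voxels,
            "volume_mm3": c.volume_mm3,
            "max_hu": c.max_hu,
            "centroid_z_mm": c.centroid_mm[0],
            "centroid_y_mm": c.centroid_mm[1],
            "centroid_x_mm": c.centroid_mm[2],
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id", "n_voxels", "volume_mm3", "max_hu",
            "centroid_z_mm", "centroid_y_mm", "centroid_x_mm",
        ],
    )
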