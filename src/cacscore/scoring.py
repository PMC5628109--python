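"""Agatston and volume calcium scores, CVD risk categories, rank matching.

The Agatston score of a lesion is the sum over axial slices of the
calcified area (mm^2) multiplied by a weight derived from the slice's peak
attenuation: 1 for 130–199 HU, 2 for 200–299, 3 for 300–399, 4 for >= 400.
Scores are kept at full precision; no per-lesion rounding is applied.

Risk categories follow the standard five-level scheme on the Agatston
score: {0}, (0, 10], (10, 100], (100, 400], (400, inf) — levels 1..5.
The boundaries are half-open on the right so that fractional scores (which
arise with sub-mm^2 pixels) are categorized unambiguously while preserving
the clinically crucial zero / positive distinction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .candidates import LesionCandidate
from .volume import CTVolume

#: upper edges of risk categories 1..4 (category 5 is unbounded)
CATEGORY_UPPER_BOUNDS = (0.0, 10.0, 100.0, 400.0)
CATEGORY_NAMES = ("very low", "low", "intermediate", "high", "very high")
N_CATEGORIES = 5

_WEIGHT_EDGES = (130.0, 200.0, 300.0, 400.0)


@dataclass
class ScoreRecord:
    """Per patient/scan calcium quantification summary."""

    patient_id: str
    scan_type: str  # CSCT | CTAC_rest | CTAC_stress
    agatston: float
    volume_mm3: float
    n_lesions: int
    category: int

    def __post_init__(self) -> None:
        if self.agatston < 0 or self.volume_mm3 < 0 or self.n_lesions < 0:
            raise ValueError("scores and lesion count must be non-negative")
        if (self.agatston == 0) != (self.category == 1):
            raise ValueError("zero Agatston score must coincide with category 1")
        if self.n_lesions == 0 and (self.agatston != 0 or self.volume_mm3 != 0):
            raise ValueError("no lesions implies zero scores")


def agatston_weight(max_hu: float) -> int:
    """Density weight of one axial-slice contribution from its peak HU."""
    if max_hu < _WEIGHT_EDGES[0]:
        return 0
    return int(np.searchsorted(_WEIGHT_EDGES, max_hu, side="right"))


def agatston_score(lesions: list[LesionCandidate], volume: CTVolume) -> float:
    """Total Agatston score of ``lesions`` extracted from ``volume``.

    score = sum over lesions, over axial slices of
    (voxel count in slice) * (pixel area mm^2) * weight(slice max HU).
    """
    area = volume.pixel_area_mm2
    shape = volume.shape
    total = 0.0
    for lesion in lesions:
        if (lesion.voxel_indices < 0).any() or (lesion.voxel_indices >= shape).any():
            raise ValueError(f"lesion {lesion.id} has voxels outside the volume")
        for _z, (count, slice_max) in lesion.per_slice.items():
            total += count * area * agatston_weight(slice_max)
    return total


def volume_score(lesions: list[LesionCandidate], volume: CTVolume) -> float:
    """Total calcified volume in mm^3 (member voxels times voxel volume)."""
    shape = volume.shape
    for lesion in lesions:
        if (lesion.voxel_indices < 0).any() or (lesion.voxel_indices >= shape).any():
            raise ValueError(f"lesion {lesion.id} has voxels outside the volume")
    return sum(l.n_voxels for l in lesions) * volume.voxel_volume_mm3


def risk_category(agatston: float) -> int:
    """Map an Agatston score to its ordinal CVD risk level 1..5."""
    if agatston < 0:
        raise ValueError(f"Agatston score must be >= 0, got {agatston}")
    if agatston == 0:
        return 1
    return 2 + int(np.searchsorted(CATEGORY_UPPER_BOUNDS[1:], agatston, side="left"))


def score_scan(
    lesions: list[LesionCandidate],
    volume: CTVolume,
    patient_id: str = "",
    scan_type: str = "",
) -> ScoreRecord:
    """Quantify one scan: Agatston, volume score, lesion count, category."""
    a = agatston_score(lesions, volume)
    return ScoreRecord(
        patient_id=patient_id,
        scan_type=scan_type,
        agatston=a,
        volume_mm3=volume_score(lesions, volume),
        n_lesions=len(lesions),
        category=risk_category(a),
    )


def rank_assign(
    reference_categories: list[int] | np.ndarray,
    test_scores: list[float] | np.ndarray,
) -> list[int]:
    """Rank-based category assignment for cross-scan-type comparison.

    Scores from two acquisition settings are not directly comparable, but
    the ranking of patients is assumed preserved.  The reference
    categorization fixes a quota per category; test patients, sorted
    ascending by score, fill the quotas from the lowest category upward.

    Two refinements keep the assignment well defined and clinically sound:

    * patients whose test score is exactly 0 always receive level 1, even
      when that overflows the level-1 quota (a zero score cannot indicate
      calcium whatever the reference distribution looked like);
    * a group of patients with exactly equal scores spans quota slots of
      possibly several categories; the whole group receives the single
      category holding the majority of the group's slots, the lower
      category when the split is even.
    """
    ref = np.asarray(reference_categories, int)
    scores = np.asarray(test_scores, float)
    if ref.shape != scores.shape:
        raise ValueError(
            f"reference ({len(ref)}) and test ({len(scores)}) lengths differ"
        )
    n = len(scores)
    quotas = np.bincount(ref, minlength=N_CATEGORIES + 1)[1:]
    if quotas.sum() != n:
        raise ValueError("reference categories must be integers in 1..5")

    # category of each rank slot: quotas[0] slots of level 1, then level 2, ...
    slot_category = np.repeat(np.arange(1, N_CATEGORIES + 1), quotas)

    order = np.argsort(scores, kind="stable")
    assigned = np.empty(n, int)
    rank = 0
    while rank < n:
        # maximal tie group of equal scores
        group = [order[rank]]
        while rank + len(group) < n and scores[order[rank + len(group)]] == scores[order[rank]]:
            group.append(order[rank + len(group)])
        slots = slot_category[rank : rank + len(group)]
        counts = np.bincount(slots, minlength=N_CATEGORIES + 1)
        majority = int(np.argmax(counts))  # argmax takes the lower level on ties
        assigned[group] = majority
        rank += len(group)

    assigned[scores == 0] = 1
    return assigned.tolist()


def records_to_frame(records: list[ScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "scan_type": r.scan_type,
                "agatston": r.agatston,
                "volume_mm3": r.volume_mm3,
                "n_lesions": r.n_lesions,
                "category": r.category,
            }
            for r in records
        ],
        columns=["patient_id", "scan_type", "agatston", "volume_mm3", "n_lesions", "category"],
    )
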