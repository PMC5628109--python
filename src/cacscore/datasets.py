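"""Bundled example data: published risk-categorization cross-tables.

These 5x5 tables come from a published 128-patient clinical comparison of
calcium-score risk categorization on Rb-82 PET/CT attenuation-correction
(CTAC) scans and dedicated calcium-scoring CT (CSCT).  Rows are reference
categories, columns test categories, ordered very low (score 0), low
(1-10), intermediate (11-100), high (101-400), very high (>400).

They serve as worked examples for the agreement statistics: the reported
linearly weighted kappas are 0.85 and 0.89 for manual-vs-automatic scoring
in CTAC at rest and stress, and 0.82 / 0.74 (rest, manual / automatic) and
0.79 / 0.70 (stress) for CSCT-vs-CTAC after rank-based category matching.
"""

from __future__ import annotations

import numpy as np

from .stats import ConfusionMatrix

RISK_LABELS = ("very_low", "low", "intermediate", "high", "very_high")

#: manual (rows) vs automatic (columns) CAC scoring in CTAC at rest
CTAC_REST_MANUAL_VS_AUTO = np.array(
    [
        [17, 0, 0, 0, 0],
        [3, 2, 1, 0, 0],
        [2, 0, 14, 1, 1],
        [2, 0, 4, 30, 1],
        [0, 0, 0, 7, 43],
    ]
)

#: manual (rows) vs automatic (columns) CAC scoring in CTAC at stress
CTAC_STRESS_MANUAL_VS_AUTO = np.array(
    [
        [18, 0, 2, 0, 0],
        [0, 2, 0, 0, 0],
        [1, 1, 22, 0, 0],
        [1, 0, 3, 28, 2],
        [0, 0, 0, 5, 43],
    ]
)

#: CSCT manual (rows) vs CTAC-rest manual scoring (columns), rank-matched
CSCT_VS_CTAC_REST_MANUAL = np.array(
    [
        [12, 1, 0, 0, 0],
        [5, 0, 1, 0, 0],
        [0, 2, 6, 4, 0],
        [0, 0, 3, 25, 7],
        [0, 0, 1, 6, 55],
    ]
)

#: CSCT manual (rows) vs CTAC-rest automatic scoring (columns), rank-matched
CSCT_VS_CTAC_REST_AUTO = np.array(
    [
        [13, 0, 0, 0, 0],
        [5, 0, 1, 0, 0],
        [4, 0, 3, 5, 0],
        [2, 0, 2, 22, 9],
        [0, 0, 1, 8, 53],
    ]
)

#: CSCT manual (rows) vs CTAC-stress manual scoring (columns), rank-matched
CSCT_VS_CTAC_STRESS_MANUAL = np.array(
    [
        [13, 0, 0, 0, 0],
        [5, 0, 1, 0, 0],
        [1, 0, 6, 5, 0],
        [0, 0, 3, 24, 8],
        [1, 0, 1, 6, 54],
    ]
)

#: CSCT manual (rows) vs CTAC-stress automatic scoring (columns), rank-matched
CSCT_VS_CTAC_STRESS_AUTO = np.array(
    [
        [11, 0, 1, 1, 0],
        [5, 0, 1, 0, 0],
        [1, 0, 6, 5, 0],
        [2, 0, 3, 20, 10],
        [1, 0, 2, 7, 52],
    ]
)

EXAMPLE_TABLES: dict[str, np.ndarray] = {
    "ctac_rest_manual_vs_auto": CTAC_REST_MANUAL_VS_AUTO,
    "ctac_stress_manual_vs_auto": CTAC_STRESS_MANUAL_VS_AUTO,
    "csct_vs_ctac_rest_manual": CSCT_VS_CTAC_REST_MANUAL,
    "csct_vs_ctac_rest_auto": CSCT_VS_CTAC_REST_AUTO,
    "csct_vs_ctac_stress_manual": CSCT_VS_CTAC_STRESS_MANUAL,
    "csct_vs_ctac_stress_auto": CSCT_VS_CTAC_STRESS_AUTO,
}


def example_confusion(name: str) -> ConfusionMatrix:
    """Load one of the bundled cross-tables as a :class:`ConfusionMatrix`."""
    if name not in EXAMPLE_TABLES:
        raise KeyError(f"unknown table {name!r}; available: {sorted(EXAMPLE_TABLES)}")
    return ConfusionMatrix(counts=EXAMPLE_TABLES[name].copy(), labels=RISK_LABELS)
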