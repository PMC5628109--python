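"""End-to-end experiment orchestration on a phantom cohort or a directory.

Runs extraction -> features -> patient-level cross-validated classification
-> Agatston quantification -> risk categorization -> agreement statistics,
and assembles a JSON-serializable report.  Every number in the report is
reproducible from the configuration and seed it embeds.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .candidates import candidates_from_mask, extract_candidates, LesionCandidate
from .classify import cross_validate, LabeledExample, LABEL_BACKGROUND, LABEL_CAC
from .config import RunConfig
from .features import CoronaryTemplate, estimate_coronary_tree, featurize, FeatureConfig
from .phantom import Cohort
from .scoring import agatston_score, rank_assign, risk_category, volume_score
from .stats import (
    accuracy,
    AgreementResult,
    ConfusionMatrix,
    detection_metrics,
    icc_absolute,
    weighted_kappa,
    wilcoxon_signed_rank,
)
from .volume import CTVolume, load_mask, load_volume, VoxelMask


def _candidate_label(candidate: LesionCandidate, truth_mask: VoxelMask) -> int:
    zz, yy, xx = candidate.voxel_indices.T
    return LABEL_CAC if truth_mask.data[zz, yy, xx].any() else LABEL_BACKGROUND


def _agreement_dict(m: ConfusionMatrix) -> dict:
    kap = weighted_kappa(m)
    acc = accuracy(m)
    out = {
        "confusion": m.counts.tolist(),
        "n": m.n,
        "accuracy": acc.accuracy,
        "accuracy_ci95": list(acc.accuracy_ci95),
        "kappa_undefined": bool(kap.undefined),
    }
    if kap.undefined:
        out.update({"kappa": None, "kappa_se": None, "kappa_ci95": None})
    else:
        out.update({
            "kappa": kap.kappa, "kappa_se": kap.kappa_se,
            "kappa_ci95": list(kap.kappa_ci95),
        })
    return out


class _PatientScan:
    """Working state for one CTAC scan inside an experiment."""

    def __init__(
        self,
        patient_id: str,
        volume: CTVolume,
        truth_mask: VoxelMask,
        reference_agatston: float,
        csct_agatston: float,
    ):
        self.patient_id = patient_id
        self.volume = volume
        self.truth_mask = truth_mask
        self.reference_agatston = reference_agatston
        self.csct_agatston = csct_agatston
        self.candidates: list[LesionCandidate] = []
        self.features: pd.DataFrame | None = None


def _collect_from_cohort(cohort: Cohort) -> tuple[list[_PatientScan], CoronaryTemplate]:
    scans = []
    for patient in cohort.patients:
        scans.append(
            _PatientScan(
                patient_id=patient.patient_id,
                volume=patient.ctac,
                truth_mask=patient.truth.union_mask("CTAC"),
                reference_agatston=patient.truth.agatston["CTAC"],
                csct_agatston=patient.truth.agatston["CSCT"],
            )
        )
    return scans, cohort.template


def _collect_from_dir(cohort_dir: str) -> tuple[list[_PatientScan], CoronaryTemplate]:
    template = CoronaryTemplate.load(cohort_dir)
    scores = pd.read_csv(os.path.join(cohort_dir, "truth_scores.csv"))
    scans = []
    for pid, group in scores.groupby("patient_id"):
        pdir = os.path.join(cohort_dir, str(pid))
        if not os.path.isdir(pdir):
            raise IOError(f"missing patient directory {pdir}")
        ctac_path = os.path.join(pdir, "ctac.nii.gz")
        mask_path = os.path.join(pdir, "truth_ctac.nii.gz")
        if not os.path.exists(mask_path):
            raise IOError(f"missing reference mask {mask_path}; cannot train")
        by_type = group.set_index("scan_type")["agatston"]
        scans.append(
            _PatientScan(
                patient_id=str(pid),
                volume=load_volume(ctac_path),
                truth_mask=load_mask(mask_path),
                reference_agatston=float(by_type["CTAC"]),
                csct_agatston=float(by_type["CSCT"]),
            )
        )
    scans.sort(key=lambda s: s.patient_id)
    return scans, template


def run_experiment(cohort: Cohort | str | os.PathLike, config: RunConfig | None = None) -> dict:
    """Run the full automatic-scoring experiment and return the report.

    ``cohort`` is either an in-memory phantom :class:`~cacscore.phantom.Cohort`
    or a directory written by the cohort simulator (volumes + reference
    masks + template + truth score table).
    """
    config = config or RunConfig()
    if isinstance(cohort, Cohort):
        scans, template = _collect_from_cohort(cohort)
    else:
        scans, template = _collect_from_dir(os.fspath(cohort))

    feature_config = FeatureConfig(gaussian_scales_mm=config.gaussian_scales_mm)
    examples: list[LabeledExample] = []
    example_owner: list[tuple[_PatientScan, int]] = []
    for scan in scans:
        scan.candidates = extract_candidates(
            scan.volume, threshold=config.threshold_hu, connectivity=config.connectivity
        )
        tree = estimate_coronary_tree(scan.volume, template)
        scan.features = featurize(scan.candidates, scan.volume, tree, feature_config)
        for i, cand in enumerate(scan.candidates):
            examples.append(
                LabeledExample(
                    patient_id=scan.patient_id,
                    scan_id=scan.patient_id,
                    features=scan.features.iloc[i].to_numpy(float),
                    label=_candidate_label(cand, scan.truth_mask),
                )
            )
            example_owner.append((scan, i))

    labels = np.array([e.label for e in examples], int)
    if len(examples) and len(np.unique(labels)) >= 2:
        cv = cross_validate(examples, n_folds=config.n_folds, seed=config.seed,
                            n_trees=config.n_trees)
        proba = cv["proba"].to_numpy()
    else:
        # degenerate cohort (e.g. no calcium anywhere): nothing to learn,
        # every candidate is scored as background
        proba = np.zeros(len(examples))

    detected: dict[str, list[LesionCandidate]] = {s.patient_id: [] for s in scans}
    for (scan, idx), p in zip(example_owner, proba):
        if p >= config.decision_threshold:
            detected[scan.patient_id].append(scan.candidates[idx])

    rows = []
    for scan in scans:
        det = detected[scan.patient_id]
        auto_agatston = agatston_score(det, scan.volume)
        rows.append(
            {
                "patient_id": scan.patient_id,
                "reference_agatston": scan.reference_agatston,
                "csct_agatston": scan.csct_agatston,
                "auto_agatston": auto_agatston,
                "auto_volume_mm3": volume_score(det, scan.volume),
                "auto_n_lesions": len(det),
                "reference_category": risk_category(scan.reference_agatston),
                "auto_category": risk_category(auto_agatston),
            }
        )
    score_table = pd.DataFrame(rows)

    det_scans = [
        (
            candidates_from_mask(scan.truth_mask, scan.volume),
            detected[scan.patient_id],
            scan.volume.voxel_volume_mm3,
        )
        for scan in scans
    ]
    det_metrics = detection_metrics(det_scans)

    auto_vs_manual = ConfusionMatrix.from_assignments(
        score_table["reference_category"].tolist(),
        score_table["auto_category"].tolist(),
        k=5,
    )

    csct_categories = [risk_category(a) for a in score_table["csct_agatston"]]
    ranked_auto = rank_assign(csct_categories, score_table["auto_agatston"].tolist())
    ranked_manual = rank_assign(csct_categories, score_table["reference_agatston"].tolist())
    csct_vs_auto = ConfusionMatrix.from_assignments(csct_categories, ranked_auto, k=5)
    csct_vs_manual = ConfusionMatrix.from_assignments(csct_categories, ranked_manual, k=5)

    report: dict = {
        "config": config.to_dict(),
        "n_patients": len(scans),
        "n_candidates": len(examples),
        "detection": {
            "lesion_sensitivity": det_metrics.lesion_sensitivity,
            "volume_sensitivity": det_metrics.volume_sensitivity,
            "fp_lesions_per_scan": det_metrics.fp_lesions_per_scan,
            "fp_volume_per_scan_mm3": det_metrics.fp_volume_per_scan,
            "n_scans_with_reference": det_metrics.n_scans_with_reference,
        },
        "auto_vs_manual_ctac": _agreement_dict(auto_vs_manual),
        "csct_vs_ctac_auto_ranked": _agreement_dict(csct_vs_auto),
        "csct_vs_ctac_manual_ranked": _agreement_dict(csct_vs_manual),
        "scores": score_table.to_dict(orient="records"),
    }

    if len(scans) >= 3:
        icc = icc_absolute(
            score_table[["reference_agatston", "auto_agatston"]].to_numpy(float)
        )
        report["icc_manual_vs_auto_ctac"] = {
            "icc": None if icc.undefined else icc.icc,
            "ci95": None if icc.undefined else list(icc.ci95),
            "undefined": bool(icc.undefined),
        }
    for name, a, b in (
        ("wilcoxon_csct_vs_ctac_manual", "csct_agatston", "reference_agatston"),
        ("wilcoxon_csct_vs_ctac_auto", "csct_agatston", "auto_agatston"),
    ):
        try:
            res = wilcoxon_signed_rank(score_table[a].to_numpy(), score_table[b].to_numpy())
            report[name] = {
                "statistic": res.statistic, "p_value": res.p_value,
                "n_pairs_used": res.n_pairs_used, "method": res.method,
            }
        except ValueError:
            report[name] = {"statistic": None, "p_value": None,
                            "n_pairs_used": 0, "method": "undefined"}
    return report
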