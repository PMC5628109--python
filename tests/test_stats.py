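"""Agreement statistics: weighted kappa, accuracy, ICC, Wilcoxon, detection."""

import numpy as np
import pytest

from cacscore import (
    accuracy,
    compare_accuracies,
    compare_kappas,
    ConfusionMatrix,
    CTVolume,
    detection_metrics,
    extract_candidates,
    icc_absolute,
    weighted_kappa,
    wilcoxon_signed_rank,
)
from cacscore.datasets import example_confusion, EXAMPLE_TABLES


def _labels_from_table(counts):
    ref, test = [], []
    for i, row in enumerate(counts):
        for j, c in enumerate(row):
            ref += [i] * c
            test += [j] * c
    return np.array(ref), np.array(test)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        m = ConfusionMatrix(np.diag([10, 10, 10, 10, 10]))
        assert weighted_kappa(m).kappa == pytest.approx(1.0)

    def test_chance_level_agreement(self):
        m = ConfusionMatrix(np.array([[5, 5], [5, 5]]))
        assert weighted_kappa(m).kappa == pytest.approx(0.0)

    def test_degenerate_single_cell_flagged_undefined(self):
        m = ConfusionMatrix(np.array([[12, 0], [0, 0]]))
        assert weighted_kappa(m).undefined

    def test_two_by_two_weighting_degeneracy(self, rng):
        counts = rng.integers(1, 30, size=(2, 2))
        m = ConfusionMatrix(counts)
        lin = weighted_kappa(m, "linear").kappa
        quad = weighted_kappa(m, "quadratic").kappa
        assert lin == pytest.approx(quad)

    @pytest.mark.parametrize("weighting", ["linear", "quadratic"])
    def test_matches_independent_implementation(self, weighting, rng):
        """Point estimates agree with sklearn's Cohen kappa on random tables."""
        from sklearn.metrics import cohen_kappa_score

        for _ in range(10):
            counts = rng.integers(0, 15, size=(4, 4)) + np.eye(4, dtype=int)
            ref, test = _labels_from_table(counts)
            ours = weighted_kappa(ConfusionMatrix(counts), weighting).kappa
            theirs = cohen_kappa_score(ref, test, labels=range(4), weights=weighting)
            assert ours == pytest.approx(theirs)

    def test_ordinality_matters_under_category_scrambling(self):
        m = example_confusion("ctac_rest_manual_vs_auto")
        perm = np.array([2, 0, 4, 1, 3])
        scrambled = ConfusionMatrix(m.counts[np.ix_(perm, perm)])
        assert weighted_kappa(scrambled).kappa != pytest.approx(weighted_kappa(m).kappa)

    def test_mean_kappa_near_zero_for_independent_margins(self):
        """Monte Carlo: independently assigned categories give kappa ~ 0."""
        rng = np.random.default_rng(99)
        draws, n, k = 10_000, 60, 5
        ref = rng.integers(0, k, size=(draws, n))
        test = rng.integers(0, k, size=(draws, n))
        kappas = np.empty(draws)
        for b in range(draws):
            counts = np.zeros((k, k), int)
            np.add.at(counts, (ref[b], test[b]), 1)
            kappas[b] = weighted_kappa(ConfusionMatrix(counts)).kappa
        assert abs(kappas.mean()) < 3 * kappas.std() / np.sqrt(draws) + 0.01

    def test_example_tables_fixture_integrity(self):
        row_sums = {
            "ctac_rest_manual_vs_auto": [17, 6, 18, 37, 50],
            "ctac_stress_manual_vs_auto": [20, 2, 24, 34, 48],
            "csct_vs_ctac_rest_manual": [13, 6, 12, 35, 62],
            "csct_vs_ctac_rest_auto": [13, 6, 12, 35, 62],
            "csct_vs_ctac_stress_manual": [13, 6, 12, 35, 62],
            "csct_vs_ctac_stress_auto": [13, 6, 12, 35, 62],
        }
        for name, counts in EXAMPLE_TABLES.items():
            assert counts.sum() == 128
            assert counts.sum(axis=1).tolist() == row_sums[name]


class TestAccuracy:
    def test_diagonal_and_off_diagonal_extremes(self):
        assert accuracy(ConfusionMatrix(np.diag([3, 4, 5]))).accuracy == 1.0
        off = np.array([[0, 7], [3, 0]])
        assert accuracy(ConfusionMatrix(off)).accuracy == 0.0

    def test_ci_is_ordered_and_contains_point(self):
        m = example_confusion("ctac_rest_manual_vs_auto")
        res = accuracy(m)
        lo, hi = res.accuracy_ci95
        assert lo < res.accuracy < hi


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0], [2.0, 2.0]])
        assert icc_absolute(x).icc == pytest.approx(1.0)

    def test_hand_computed_two_way_anova_example(self):
        assert icc_absolute(np.array([[1, 2], [3, 4], [5, 6]], float)).icc \
            == pytest.approx(8 / 9)

    def test_offset_penalized_unlike_pearson(self, rng):
        a = rng.normal(0, 1, 20)
        x = np.column_stack([a, a + 10.0])
        res = icc_absolute(x)
        assert res.icc < 0.2
        assert np.corrcoef(x.T)[0, 1] == pytest.approx(1.0)

    def test_matches_independent_implementation(self, rng):
        """Cross-check against pingouin's two-way absolute-agreement ICC."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(50, 20, size=(15, 2)) + rng.normal(0, 5, size=(15, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile(["a", "b"], 15),
                "score": x.ravel(),
            }
        )
        theirs = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type").loc["ICC(A,1)"]
        ours = icc_absolute(x)
        assert ours.icc == pytest.approx(theirs["ICC"], abs=1e-6)
        np.testing.assert_allclose(ours.ci95, theirs["CI95"], atol=2e-2)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute(np.array([[1.0, 2.0], [3.0, 4.0]]))


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_exact_six_pair_shift(self):
        x = np.arange(1.0, 7.0)
        res = wilcoxon_signed_rank(x, x + 1.0)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)

    def test_antisymmetric_differences_are_null_centred(self):
        x = np.zeros(8)
        y = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        res = wilcoxon_signed_rank(x, y)
        assert res.p_value > 0.9
        assert res.statistic == pytest.approx(8 * 9 / 4)  # null centre n(n+1)/4

    def test_large_sample_uses_normal_approximation(self, rng):
        x = rng.normal(0, 1, 40)
        res = wilcoxon_signed_rank(x, x - 0.5)
        assert res.method == "approx"
        assert 0 <= res.p_value <= 1


class TestCompareEstimates:
    def test_identical_results_z_zero(self):
        m = example_confusion("ctac_rest_manual_vs_auto")
        r = weighted_kappa(m)
        z, p = compare_kappas(r, r)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_three_sigma_difference(self):
        from cacscore.stats import AgreementResult

        r1 = AgreementResult(n=100, kappa=0.8, kappa_se=0.03)
        r2 = AgreementResult(n=100, kappa=0.8 - 3 * np.hypot(0.03, 0.04), kappa_se=0.04)
        z, p = compare_kappas(r1, r2)
        assert z == pytest.approx(3.0)
        assert p == pytest.approx(0.0027, abs=2e-4)

    def test_antisymmetry_and_accuracy_variant(self):
        a = accuracy(example_confusion("ctac_rest_manual_vs_auto"))
        b = accuracy(example_confusion("csct_vs_ctac_stress_auto"))
        z1, _ = compare_accuracies(a, b)
        z2, _ = compare_accuracies(b, a)
        assert z1 == pytest.approx(-z2)


class TestDetectionMetrics:
    @staticmethod
    def _lesions(volume, *blobs):
        data = np.zeros(volume.shape, np.float32)
        for blob in blobs:
            for idx in blob:
                data[idx] = 300.0
        return extract_candidates(CTVolume(data, spacing=volume.spacing), 130.0)

    @pytest.fixture()
    def vol(self):
        return CTVolume(np.zeros((8, 8, 8), np.float32), spacing=(3.0, 1.35, 1.35))

    def test_self_comparison_is_perfect(self, vol):
        ref = self._lesions(vol, [(1, 1, 1), (1, 1, 2)], [(5, 5, 5), (5, 5, 6)])
        out = detection_metrics([(ref, ref, vol.voxel_volume_mm3)])
        assert out.lesion_sensitivity == 1.0
        assert out.volume_sensitivity == 1.0
        assert out.fp_lesions_per_scan == 0.0
        assert out.fp_volume_per_scan == 0.0

    def test_two_of_three_detected_plus_spurious(self, vol):
        ref = self._lesions(
            vol, [(1, 1, 1), (1, 1, 2)], [(3, 3, 3), (3, 3, 4)], [(6, 6, 6), (6, 6, 7)]
        )
        det = self._lesions(
            vol, [(1, 1, 1), (1, 1, 2)], [(3, 3, 3), (3, 3, 4)], [(0, 6, 0), (0, 6, 1)]
        )
        out = detection_metrics([(ref, det, vol.voxel_volume_mm3)])
        assert out.lesion_sensitivity == pytest.approx(2 / 3)
        assert out.fp_lesions_per_scan == 1.0
        assert out.fp_volume_per_scan == pytest.approx(2 * vol.voxel_volume_mm3)

    def test_no_detections(self, vol):
        ref = self._lesions(vol, [(1, 1, 1), (1, 1, 2)])
        out = detection_metrics([(ref, [], vol.voxel_volume_mm3)])
        assert out.lesion_sensitivity == 0.0
        assert out.fp_lesions_per_scan == 0.0

    def test_reference_free_scans_only_contribute_fp(self, vol):
        det = self._lesions(vol, [(2, 2, 2), (2, 2, 3)])
        out = detection_metrics(
            [([], det, vol.voxel_volume_mm3), ([], [], vol.voxel_volume_mm3)]
        )
        assert np.isnan(out.lesion_sensitivity)
        assert out.fp_lesions_per_scan == 0.5
        assert out.n_scans_with_reference == 0


def test_confusion_matrix_csv_round_trip(tmp_path):
    m = example_confusion("ctac_stress_manual_vs_auto")
    path = str(tmp_path / "m.csv")
    m.to_csv(path)
    back = ConfusionMatrix.from_csv(path)
    np.testing.assert_array_equal(back.counts, m.counts)


def test_confusion_matrix_validation():
    with pytest.raises(ValueError):
        ConfusionMatrix(np.zeros((3, 2)))
    with pytest.raises(ValueError):
        ConfusionMatrix(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        ConfusionMatrix(np.array([[1, -1], [0, 2]]))


class TestKappaPropertyBounds:
    """Range invariants over arbitrary confusion tables."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _tables():
        from hypothesis import strategies as st

        return st.lists(
            st.lists(st.integers(0, 40), min_size=4, max_size=4),
            min_size=4, max_size=4,
        ).filter(lambda rows: sum(map(sum, rows)) > 0)

    @given(_tables())
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_kappa_bounded_and_accuracy_in_unit_interval(self, rows):
        m = ConfusionMatrix(np.array(rows))
        res = weighted_kappa(m)
        if not res.undefined:
            assert -1.0 - 1e-9 <= res.kappa <= 1.0 + 1e-9
        acc = accuracy(m)
        assert 0.0 <= acc.accuracy <= 1.0
        lo, hi = acc.accuracy_ci95
        assert lo <= hi
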