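"""Shape, intensity and location features; template-based tree estimation."""

from dataclasses import replace

import numpy as np
import pytest

import cacscore as cs
from cacscore.candidates import LesionCandidate
from cacscore.features import (
    CoronaryTreeEstimate,
    FeatureConfig,
    smooth_volume,
    TreeEstimationError,
)


def _candidate_from_indices(indices, volume):
    data = np.asarray(volume.data, float)
    idx = np.asarray(indices, int)
    zz, yy, xx = idx.T
    vals = data[zz, yy, xx]
    per_slice = {
        int(z): (int((zz == z).sum()), float(vals[zz == z].max()))
        for z in np.unique(zz)
    }
    return LesionCandidate(
        id=1,
        voxel_indices=idx,
        volume_mm3=len(idx) * volume.voxel_volume_mm3,
        max_hu=float(vals.max()),
        centroid_mm=tuple(volume.index_to_physical(idx.mean(axis=0))),
        per_slice=per_slice,
    )


@pytest.fixture()
def iso_volume():
    return cs.CTVolume(np.full((9, 9, 9), 200.0, np.float32), spacing=(1.0, 1.0, 1.0))


class TestShapeFeatures:
    def test_collinear_voxels_are_degenerate(self, iso_volume):
        cand = _candidate_from_indices([(4, 4, i) for i in range(5)], iso_volume)
        assert cs.shape_features(cand, iso_volume.spacing) == (0.0, 0.0, 0.0)

    def test_symmetric_cube_is_isotropic(self, iso_volume):
        idx = [(z, y, x) for z in range(3) for y in range(3) for x in range(3)]
        cand = _candidate_from_indices(idx, iso_volume)
        assert cs.shape_features(cand, iso_volume.spacing) == pytest.approx((1, 1, 1))

    def test_planar_voxels(self, iso_volume):
        idx = [(4, y, x) for y in range(3) for x in range(3)]
        cand = _candidate_from_indices(idx, iso_volume)
        assert cs.shape_features(cand, iso_volume.spacing) == pytest.approx((1, 0, 0))

    def test_invariant_to_axis_permutation_and_spacing_scale(self, iso_volume):
        idx = [(0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 1, 1), (2, 0, 1)]
        cand = _candidate_from_indices(idx, iso_volume)
        base = cs.shape_features(cand, (1.0, 1.0, 1.0))
        rotated = _candidate_from_indices([(x, z, y) for z, y, x in idx], iso_volume)
        assert cs.shape_features(rotated, (1.0, 1.0, 1.0)) == pytest.approx(base)
        assert cs.shape_features(cand, (2.5, 2.5, 2.5)) == pytest.approx(base)

    def test_anisotropic_spacing_changes_ratios(self, iso_volume):
        idx = [(z, y, x) for z in range(2) for y in range(3) for x in range(3)]
        cand = _candidate_from_indices(idx, iso_volume)
        iso = cs.shape_features(cand, (1.0, 1.0, 1.0))
        aniso = cs.shape_features(cand, (3.0, 1.0, 1.0))
        assert iso != pytest.approx(aniso)


class TestIntensityFeatures:
    def test_constant_lesion_statistics(self, iso_volume):
        cand = _candidate_from_indices([(4, 4, 4), (4, 4, 5)], iso_volume)
        out = cs.intensity_features(cand, iso_volume, scales_mm=(1.0,))
        assert out["int_max"] == 200.0
        assert out["int_mean"] == 200.0
        assert out["int_sd"] == 0.0

    def test_smoothing_preserves_constant_field(self, iso_volume):
        cand = _candidate_from_indices([(4, 4, 4), (4, 5, 4)], iso_volume)
        out = cs.intensity_features(cand, iso_volume, scales_mm=(1.0, 2.0, 4.0))
        for s in ("1mm", "2mm", "4mm"):
            assert out[f"int_smooth{s}_max"] == pytest.approx(200.0)

    def test_spike_smoothed_between_background_and_peak(self):
        data = np.full((11, 11, 11), -50.0, np.float32)
        data[5, 5, 5] = 500.0
        vol = cs.CTVolume(data, spacing=(1.0, 1.0, 1.0))
        cand = _candidate_from_indices([(5, 5, 5), (5, 5, 6)], vol)
        out = cs.intensity_features(cand, vol, scales_mm=(2.0,))
        assert -50.0 < out["int_smooth2mm_max"] < 500.0

    def test_physical_sigma_converted_per_axis(self):
        data = np.zeros((9, 9, 9), np.float32)
        data[4, 4, 4] = 1000.0
        aniso = cs.CTVolume(data, spacing=(3.0, 1.0, 1.0))
        sm = smooth_volume(aniso, 2.0)
        # one physical step along z (1 voxel = 3 mm) attenuates more than
        # one voxel step along x (1 mm)
        assert sm[5, 4, 4] < sm[4, 4, 5]

    def test_invalid_scale_rejected(self, iso_volume):
        with pytest.raises(ValueError):
            smooth_volume(iso_volume, 0.0)


class TestTreeEstimation:
    def test_self_registration_is_identity(self, template):
        subject = cs.CTVolume(
            np.where(template.mask.data, 40.0, -800.0).astype(np.float32),
            spacing=template.mask.spacing,
            origin=template.mask.origin,
        )
        tree = cs.estimate_coronary_tree(subject, template)
        for label, pts in template.centerlines.items():
            np.testing.assert_allclose(tree.centerlines[label], pts, atol=1e-6)

    def test_translation_recovered(self, template):
        shift = np.array([0.0, 10.0, 0.0])
        subject = cs.CTVolume(
            np.where(template.mask.data, 40.0, -800.0).astype(np.float32),
            spacing=template.mask.spacing,
            origin=tuple(np.asarray(template.mask.origin) + shift),
        )
        tree = cs.estimate_coronary_tree(subject, template)
        for label, pts in template.centerlines.items():
            np.testing.assert_allclose(
                tree.centerlines[label], pts + shift, atol=max(subject.spacing)
            )

    def test_distance_map_zero_at_vertex(self, clean_pair, template):
        _, ctac, _ = clean_pair
        tree = cs.estimate_coronary_tree(ctac, template)
        vertex = tree.centerlines["RCA"][5]
        idx = np.rint(
            (vertex - np.asarray(tree.origin)) / np.asarray(tree.spacing)
        ).astype(int)
        assert tree.distance_maps["RCA"][tuple(idx)] == 0.0
        assert (tree.distance_maps["union"] <= tree.distance_maps["RCA"] + 1e-9).all()

    def test_uniform_subject_rejected(self, template):
        flat = cs.CTVolume(np.zeros((12, 42, 42), np.float32), spacing=(3.0, 1.35, 1.35))
        with pytest.raises(TreeEstimationError):
            cs.estimate_coronary_tree(flat, template)


class TestLocationFeatures:
    @pytest.fixture()
    def straight_tree(self):
        """Hand-built tree: one straight RCA along z at (y, x) = (20, 20)."""
        shape, spacing = (12, 40, 40), (3.0, 1.0, 1.0)
        line = np.array([[1.5, 20.0, 20.0], [34.5, 20.0, 20.0]])
        vol = cs.CTVolume(np.zeros(shape, np.float32), spacing=spacing,
                          origin=(1.5, 0.5, 0.5))
        from cacscore.features import _rasterize_polyline
        from scipy import ndimage as ndi

        maps = {}
        for label in ("RCA", "LAD", "LCX"):
            pts = line if label == "RCA" else line + np.array([0.0, 100.0, 100.0])
            raster = _rasterize_polyline(pts, vol)
            maps[label] = ndi.distance_transform_edt(~raster, sampling=spacing)
        union = np.minimum.reduce([maps[l] for l in ("RCA", "LAD", "LCX")])
        maps["union"] = union
        return CoronaryTreeEstimate(
            centerlines={"RCA": line}, distance_maps=maps,
            spacing=spacing, origin=vol.origin,
            heart_center_mm=(18.0, 20.0, 20.0), heart_half_extent_mm=(14.0, 13.0, 13.0),
        ), vol

    def test_centroid_on_vertex_distance_zero(self, straight_tree):
        tree, vol = straight_tree
        cand = _candidate_from_indices([(4, 19, 19), (4, 20, 20), (4, 21, 21)], vol)
        assert cand.centroid_mm == pytest.approx((13.5, 20.5, 20.5))
        out = cs.location_features(cand, tree)
        assert out["loc_dist_rca_mm"] < np.linalg.norm(vol.spacing) / 2

    def test_point_five_mm_from_line(self, straight_tree):
        tree, vol = straight_tree
        cand = _candidate_from_indices([(4, 24, 19), (4, 24, 20)], vol)
        # centroid at y=25.0, x=20.0 -> 5 mm from the line at (20, 20)
        out = cs.location_features(cand, tree)
        assert out["loc_dist_union_mm"] == pytest.approx(
            5.0, abs=np.linalg.norm(vol.spacing) / 2
        )

    def test_heart_centre_maps_to_origin_of_normalized_coords(self, straight_tree):
        tree, vol = straight_tree
        cand = _candidate_from_indices([(5, 19, 19), (5, 20, 20)], vol)
        out = cs.location_features(cand, tree)
        centroid = np.asarray(cand.centroid_mm)
        expected = (centroid - np.array([18.0, 20.0, 20.0])) / np.array([14.0, 13.0, 13.0])
        assert (out["loc_norm_z"], out["loc_norm_y"], out["loc_norm_x"]) \
            == pytest.approx(tuple(expected))


class TestFeaturize:
    def test_empty_candidates_empty_frame(self, clean_pair, template):
        _, ctac, _ = clean_pair
        tree = cs.estimate_coronary_tree(ctac, template)
        frame = cs.featurize([], ctac, tree)
        assert len(frame) == 0
        assert list(frame.columns) == FeatureConfig().feature_names()

    def test_schema_length_and_order_stability(self, clean_pair, template):
        _, ctac, _ = clean_pair
        cands = cs.extract_candidates(ctac, 130.0)
        tree = cs.estimate_coronary_tree(ctac, template)
        frame = cs.featurize(cands, ctac, tree)
        assert frame.shape == (len(cands), len(FeatureConfig().feature_names()))
        assert np.isfinite(frame.to_numpy(float)).all()
        shape_cols = frame[["shape_r21", "shape_r31", "shape_r32"]].to_numpy()
        assert ((shape_cols >= 0) & (shape_cols <= 1 + 1e-9)).all()

    def test_permutation_equivariance_and_determinism(self, clean_pair, template):
        _, ctac, _ = clean_pair
        cands = cs.extract_candidates(ctac, 130.0)
        tree = cs.estimate_coronary_tree(ctac, template)
        frame = cs.featurize(cands, ctac, tree)
        again = cs.featurize(cands, ctac, tree)
        assert frame.equals(again)
        perm = cs.featurize(cands[::-1], ctac, tree)
        np.testing.assert_allclose(
            perm.to_numpy(float), frame.to_numpy(float)[::-1]
        )


def test_template_round_trip(tmp_path, template):
    template.save(tmp_path)
    back = cs.CoronaryTemplate.load(tmp_path)
    assert set(back.centerlines) == set(template.centerlines)
    for label in back.centerlines:
        np.testing.assert_allclose(back.centerlines[label],
                                   template.centerlines[label])
    np.testing.assert_array_equal(back.mask.data, template.mask.data)
    assert back.heart_center_mm == pytest.approx(template.heart_center_mm)
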