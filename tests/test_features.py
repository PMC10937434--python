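"""Geometry and feature-extraction oracles on analytic shapes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oarqa import features
from oarqa.core import Contour, ImageVolume
from oarqa.features import (FEATURE_NAMES, count_parts, extents,
                            extract_features, fractional_overlap,
                            min_surface_distance, orient_eigenvector,
                            pca_shape_orientation, prune_correlated,
                            relative_centroid, representative_eigenvector,
                            sphericity)

from conftest import box_mask, make_set, sphere_mask


def voxel_contour(indices, shape=(40, 40, 40), spacing=(1.0, 1.0, 1.0),
                  oar_type="test"):
    m = np.zeros(shape, dtype=bool)
    for idx in indices:
        m[tuple(idx)] = True
    return Contour(mask=m, oar_type=oar_type, spacing=spacing)


class TestCentroidAndExtent:
    def test_reference_is_brainstem_and_pituitary_for_brainstem(self):
        bs = voxel_contour([(10, 10, 10)], oar_type="brainstem")
        pit = voxel_contour([(10, 10, 14)], oar_type="pituitary")
        other = voxel_contour([(20, 10, 10)], oar_type="cord")
        sset = make_set([bs, pit, other])
        # contour relative to the brainstem centroid
        assert relative_centroid(other, sset) == pytest.approx([10, 0, 0])
        # the brainstem itself references the pituitary
        assert relative_centroid(bs, sset) == pytest.approx([0, 0, -4])

    def test_two_voxel_centroid_is_mean_of_centers(self):
        bs = voxel_contour([(0, 0, 0)], oar_type="brainstem")
        c = voxel_contour([(0, 0, 0), (10, 0, 0)], oar_type="cord")
        sset = make_set([bs, c])
        assert relative_centroid(c, sset) == pytest.approx([5, 0, 0])

    def test_missing_reference_is_fatal(self):
        c = voxel_contour([(0, 0, 0)], oar_type="cord")
        with pytest.raises(features.MissingReferenceError):
            relative_centroid(c, make_set([c]))

    @pytest.mark.parametrize("indices,spacing,expected", [
        ([(5, 5, 5)], (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)),
        ([(3, 0, 0), (10, 0, 0)], (1.27, 1.27, 2.0), (8.89, 0.0, 0.0)),
    ])
    def test_extent_span_of_voxel_centers(self, indices, spacing, expected):
        c = voxel_contour(indices, spacing=spacing)
        assert extents(c) == pytest.approx(expected, abs=1e-9)

    def test_extent_of_box_is_center_to_center_span(self):
        c = Contour(mask=box_mask((40, 40, 40), (0, 0, 0), (10, 20, 30)),
                    oar_type="box", spacing=(1.0, 1.0, 1.0))
        assert extents(c) == pytest.approx([9, 19, 29])


class TestPca:
    def test_sphere_is_isotropic(self, sphere_contour):
        out = pca_shape_orientation(sphere_contour)
        assert out["lambda2_ratio"] == pytest.approx(1.0, rel=0.05)
        assert out["lambda3_ratio"] == pytest.approx(1.0, rel=0.05)

    def test_tube_first_axis_is_z(self):
        m = np.zeros((20, 20, 60), dtype=bool)
        m[9:12, 9:12, 5:55] = True
        out = pca_shape_orientation(Contour(mask=m, oar_type="tube",
                                            spacing=(1.0, 1.0, 1.0)))
        assert abs(out["pc1"][2]) == pytest.approx(1.0, abs=1e-6)
        assert out["lambda2_ratio"] < 0.05

    def test_box_eigenvalue_ratios_scale_with_side_squared(self):
        # uniform box: covariance eigenvalues are proportional to side^2
        c = Contour(mask=box_mask((50, 30, 20), (2, 2, 2), (42, 22, 12)),
                    oar_type="box", spacing=(1.0, 1.0, 1.0))
        out = pca_shape_orientation(c)
        assert out["lambda2_ratio"] == pytest.approx(0.25, rel=0.10)
        assert out["lambda3_ratio"] == pytest.approx(0.0625, rel=0.10)


class TestRepresentativeEigenvector:
    def test_identical_vectors(self):
        v = np.array([[0, 0, 1.0]] * 4)
        assert representative_eigenvector(v) == pytest.approx([0, 0, 1.0])

    def test_most_aligned_member_wins(self):
        v = np.array([[1, 0, 0], [0, 1, 0], [0.707, 0.707, 0]])
        # scores: 0.707, 0.707, 1.414 -> the diagonal vector
        assert representative_eigenvector(v) == pytest.approx(
            [0.707, 0.707, 0])

    def test_tie_breaks_to_lowest_index(self):
        v = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        assert representative_eigenvector(v) == pytest.approx([1, 0, 0])

    @pytest.mark.parametrize("v,r,expected", [
        ([1, 0, 0], [1, 0, 0], [1, 0, 0]),
        ([-1, 0, 0], [1, 0, 0], [1, 0, 0]),
        ([0, 1, 0], [1, 0, 0], [0, 1, 0]),  # orthogonal: unchanged
    ])
    def test_orientation_flip(self, v, r, expected):
        assert orient_eigenvector(np.array(v, float), np.array(r, float)) \
            == pytest.approx(expected)


class TestSphericityAndParts:
    def test_single_voxel_equals_cube_closed_form(self):
        c = voxel_contour([(5, 5, 5)], spacing=(1.0, 1.0, 1.0))
        assert sphericity(c) == pytest.approx((np.pi / 6) ** (1 / 3),
                                              abs=1e-3)

    def test_voxelized_cube_near_closed_form(self):
        c = Contour(mask=box_mask((30, 30, 30), (5, 5, 5), (25, 25, 25)),
                    oar_type="cube", spacing=(1.0, 1.0, 1.0))
        assert sphericity(c) == pytest.approx((np.pi / 6) ** (1 / 3),
                                              rel=0.05)

    def test_voxelized_sphere_near_one(self, sphere_contour):
        assert sphericity(sphere_contour) == pytest.approx(1.0, abs=0.05)

    def test_parts_counting(self, sphere_contour):
        assert count_parts(sphere_contour) == 1
        m = sphere_contour.mask.copy()
        m[1, 1, 1] = True
        assert count_parts(Contour(mask=m, oar_type="x")) == 2

    def test_corner_adjacent_voxels_are_one_part(self):
        # 26-connectivity joins diagonal neighbours
        c = voxel_contour([(5, 5, 5), (6, 6, 6)])
        assert count_parts(c) == 1


class TestPairGeometry:
    def test_overlapping_masks_have_zero_distance(self, unit_grid):
        a = Contour(mask=sphere_mask(unit_grid["shape"], (30, 30, 30), 8),
                    oar_type="a")
        b = Contour(mask=sphere_mask(unit_grid["shape"], (34, 30, 30), 8),
                    oar_type="b")
        assert min_surface_distance(a, b) == 0.0
        assert fractional_overlap(a, b) > 0

    def test_point_distance(self):
        a = voxel_contour([(5, 5, 5)])
        b = voxel_contour([(15, 5, 5)])
        assert min_surface_distance(a, b) == pytest.approx(10.0)

    def test_sphere_gap_matches_analytic(self, unit_grid):
        a = Contour(mask=sphere_mask(unit_grid["shape"], (15, 30, 30), 5),
                    oar_type="a")
        b = Contour(mask=sphere_mask(unit_grid["shape"], (35, 30, 30), 5),
                    oar_type="b")
        # centres 20 mm apart, radii 5 mm -> 10 mm gap (voxelization slack)
        assert min_surface_distance(a, b) == pytest.approx(10.0, abs=1.8)

    def test_fractional_overlap_directional(self):
        sel = Contour(mask=box_mask((20, 20, 20), (0, 0, 0), (10, 10, 10)),
                      oar_type="sel")
        comp = Contour(mask=box_mask((20, 20, 20), (5, 0, 0), (20, 20, 20)),
                       oar_type="comp")
        assert fractional_overlap(sel, sel) == 1.0
        assert fractional_overlap(sel, comp) == pytest.approx(0.5)
        disjoint = Contour(mask=box_mask((20, 20, 20), (15, 15, 15),
                                         (20, 20, 20)), oar_type="d")
        assert fractional_overlap(sel, disjoint) == 0.0


class TestExtractAndPrune:
    def _simple_set(self, offset=(0, 0, 0)):
        shape = (64, 64, 64)
        o = np.asarray(offset)
        bs = Contour(mask=sphere_mask(shape, (32, 32, 32) + o, 6),
                     oar_type="brainstem")
        pit = Contour(mask=sphere_mask(shape, (32, 26, 40) + o, 3),
                      oar_type="pituitary")
        cord = Contour(mask=sphere_mask(shape, (32, 32, 16) + o, 5),
                       oar_type="cord")
        rng = np.random.default_rng(0)
        img = ImageVolume(voxels=rng.normal(30, 10, shape),
                          spacing=(1.0, 1.0, 1.0))
        return make_set([bs, pit, cord], image=img)

    def test_table_shape_and_determinism(self):
        sset = self._simple_set()
        t1 = extract_features(sset)
        t2 = extract_features(sset)
        assert list(t1.columns) == ["set_id", "oar_type", *FEATURE_NAMES]
        assert len(t1) == 3
        pd.testing.assert_frame_equal(t1, t2)

    def test_sphere_volume_column(self, sphere_contour):
        bs = Contour(mask=sphere_mask((60, 60, 60), (10, 10, 10), 4),
                     oar_type="brainstem")
        pit = Contour(mask=sphere_mask((60, 60, 60), (10, 10, 20), 3),
                      oar_type="pituitary")
        sset = make_set([bs, pit, sphere_contour])
        t = extract_features(sset)
        vol = t.set_index("oar_type").loc["sphere", "volume_cc"]
        assert vol == pytest.approx(4.0 / 3.0 * np.pi, rel=0.02)

    def test_translation_invariance_of_relative_features(self):
        # shifting the whole structure set must not change relative
        # centroids, shape ratios, sphericity or volume
        base = extract_features(self._simple_set())
        moved = extract_features(self._simple_set(offset=(4, 3, 5)))
        cols = ["centroid_x", "centroid_y", "centroid_z", "lambda2_ratio",
                "lambda3_ratio", "sphericity", "volume_cc",
                "extent_x", "extent_y", "extent_z"]
        np.testing.assert_allclose(base[cols].to_numpy(),
                                   moved[cols].to_numpy(), atol=1e-5)

    def test_prune_drops_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": -x,
                           "d": rng.normal(size=500)})
        kept = prune_correlated(df, threshold=0.7)
        assert "d" in kept
        assert len([k for k in kept if k in ("a", "b", "c")]) == 1

    def test_prune_keeps_independent_noise(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(1000, 6)),
                          columns=list("abcdef"))
        assert prune_correlated(df, threshold=0.7) == list("abcdef")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_overlap_zero_iff_distance_positive(seed):
    """overlap > 0 <=> min surface distance = 0, for random box pairs."""
    rng = np.random.default_rng(seed)
    lo1, lo2 = rng.integers(0, 12, size=(2, 3))
    sz1, sz2 = rng.integers(2, 8, size=(2, 3))
    a = Contour(mask=box_mask((24, 24, 24), lo1, lo1 + sz1), oar_type="a")
    b = Contour(mask=box_mask((24, 24, 24), lo2, lo2 + sz2), oar_type="b")
    ovl = fractional_overlap(a, b)
    dist = min_surface_distance(a, b)
    assert (ovl > 0) == (dist == 0.0)
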