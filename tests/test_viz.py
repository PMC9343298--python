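"""Activation maps: rectification, interpolation, class differencing,
half-max thresholding, Dice."""

from __future__ import annotations

import numpy as np
import pytest

from comanet import (class_difference_map, layer_activation_map,
                     localization_score, subject_map, threshold_map)
from comanet.exceptions import ValidationError
from comanet.viz import DiffMap, interpolate_to_grid, positive_filter_mean


class TestInterpolation:
    def test_constant_field_stays_constant(self):
        field = np.full((5, 5, 5), 3.7, dtype=np.float32)
        out = interpolate_to_grid(field, (11, 12, 13))
        assert out.shape == (11, 12, 13)
        assert np.allclose(out, 3.7, atol=1e-6)

    def test_identity_when_already_on_grid(self):
        field = np.random.default_rng(0).random((6, 6, 6))
        assert interpolate_to_grid(field, (6, 6, 6)) is field


class TestActivationMaps:
    def test_rectified_filter_mean(self):
        acts = np.array([[[[-1.0, 2.0]]], [[[3.0, -4.0]]]])  # (2 filters, 1,1,2)
        out = positive_filter_mean(acts)
        assert out.shape == (1, 1, 2)
        assert np.allclose(out, [[[1.5, 1.0]]])

    def test_layer_map_is_nonnegative_and_on_the_input_grid(self, tiny_fitted_clf):
        clf, x, _ = tiny_fitted_clf
        amap = layer_activation_map(clf, x[0], layer=1, subject_id="s0")
        assert amap.data.shape == clf.input_shape_
        assert amap.data.min() >= 0.0

    def test_first_layer_pre_interpolation_shrinks_by_two(self, tiny_fitted_clf):
        clf, x, _ = tiny_fitted_clf
        acts = clf.conv_activations(x[:1], layer=1)
        assert acts.shape[2:] == tuple(d - 2 for d in clf.input_shape_)

    def test_subject_map_is_the_mean_over_layers(self, tiny_fitted_clf):
        clf, x, _ = tiny_fitted_clf
        smap = subject_map(clf, x[0])
        layer_maps = [layer_activation_map(clf, x[0], layer=i).data
                      for i in range(1, 7)]
        assert np.allclose(smap.data, np.mean(layer_maps, axis=0), atol=1e-5)
        assert smap.data.min() >= 0.0


class TestClassDifference:
    def test_identical_class_maps_cancel(self):
        maps = np.stack([np.ones((4, 4, 4)), np.ones((4, 4, 4))])
        diff = class_difference_map(maps, ["coma", "control"], [True, True])
        assert np.allclose(diff.data, 0.0)

    def test_complementary_maps(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 4, 4))
        x[0, 0, 0], x[1, 1, 1] = 0.0, 1.0  # pin the min-max range
        maps = np.stack([x, 1.0 - x])
        diff = class_difference_map(maps, ["coma", "control"], [True, True])
        assert np.allclose(diff.data, np.abs(2 * x - 1), atol=1e-12)

    def test_misclassified_subjects_are_excluded(self):
        rng = np.random.default_rng(1)
        a, b, junk = rng.random((3, 4, 4, 4))
        with_junk = class_difference_map(
            np.stack([a, b, junk]), ["coma", "control", "coma"],
            [True, True, False])
        without = class_difference_map(np.stack([a, b]), ["coma", "control"],
                                       [True, True])
        assert np.array_equal(with_junk.data, without.data)

    def test_class_without_correct_subjects_is_an_error(self):
        maps = np.ones((2, 3, 3, 3))
        with pytest.raises(ValidationError):
            class_difference_map(maps, ["coma", "control"], [True, False])


class TestThreshold:
    def test_half_max_rule(self):
        data = np.array([[[1.0, 0.49, 0.51, 0.2]]])
        thr = threshold_map(DiffMap(data=data))
        assert thr.threshold == 0.5
        assert np.array_equal(thr.mask, data >= 0.5)
        assert thr.data[0, 0, 1] == 0.0 and thr.data[0, 0, 2] == 0.51

    def test_constant_positive_map_keeps_every_voxel(self):
        thr = threshold_map(DiffMap(data=np.full((3, 3, 3), 0.4)))
        assert thr.mask.all()

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValidationError):
            threshold_map(DiffMap(data=np.zeros((3, 3, 3))))

    def test_peak_voxel_always_survives(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 2.0
        thr = threshold_map(DiffMap(data=data))
        assert thr.mask[1, 1, 1]


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[:2] = True
        assert localization_score(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[3] = True, True
        assert localization_score(a, b) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            localization_score(np.zeros((3, 3, 3), bool), np.zeros((4, 3, 3), bool))
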