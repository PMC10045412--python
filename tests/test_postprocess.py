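"""Gradient map, markers, energy landscape, watershed, type voting."""

import numpy as np
import pytest
from skimage.draw import ellipse
from skimage.measure import label as cc_label

from gsnhv.metrics import aji
from gsnhv.postprocess import (PostprocessParams, gradient_map, compute_marker,
                               energy_landscape, instance_segment, assign_types)
from gsnhv.targets import binarize, compute_hv_map


def two_touching_ellipses(size=60, gap=16):
    inst = np.zeros((size, size), dtype=np.int32)
    rr, cc = ellipse(size // 2, size // 2 - gap // 2 - 1, 10, 9, shape=inst.shape)
    inst[rr, cc] = 1
    rr, cc = ellipse(size // 2, size // 2 + gap // 2 + 1, 10, 9, shape=inst.shape)
    inst[rr, cc] = 2
    assert inst.max() == 2
    return inst


class TestGradientMap:
    def test_constant_input_maps_to_zero(self):
        sm = gradient_map(np.full((20, 20), 0.3), np.full((20, 20), -0.7))
        np.testing.assert_array_equal(sm, 0.0)

    def test_peak_on_shared_boundary_of_touching_instances(self):
        inst = two_touching_ellipses()
        hv = compute_hv_map(inst)
        sm = gradient_map(hv[..., 0], hv[..., 1])
        # the two ellipses meet near the central column: the shared
        # boundary attains the global maximum of Sm
        mid = inst.shape[1] // 2
        contact = sm[:, mid - 2:mid + 3]
        assert contact.max() == pytest.approx(sm.max(), abs=1e-9)
        # and the contact stands far above the interior ramps
        interiors = sm[(inst > 0) & (np.abs(np.arange(sm.shape[1])[None, :]
                                            - mid) > 6)]
        assert contact.max() > 2 * np.median(interiors)

    def test_range_is_unit_interval(self, small_dataset):
        for patch in small_dataset[:3]:
            hv = compute_hv_map(patch.instances)
            sm = gradient_map(hv[..., 0], hv[..., 1])
            assert sm.min() >= 0.0 and sm.max() <= 1.0


class TestMarkerAndEnergy:
    def test_full_confidence_no_boundary_marks_everything(self):
        q = np.ones((8, 8))
        sm = np.zeros((8, 8))
        np.testing.assert_array_equal(compute_marker(q, sm, 0.5, 0.4), 1)

    def test_boundary_everywhere_suppresses_all_markers(self):
        q = np.ones((8, 8))
        sm = np.ones((8, 8))
        np.testing.assert_array_equal(compute_marker(q, sm, 0.5, 0.4), 0)

    def test_touching_pair_yields_two_marker_components(self):
        inst = two_touching_ellipses()
        hv = compute_hv_map(inst)
        sm = gradient_map(hv[..., 0], hv[..., 1])
        marker = compute_marker(binarize(inst).astype(float), sm, 0.5, 0.4)
        assert cc_label(marker, connectivity=2).max() == 2

    def test_energy_zero_outside_confident_foreground(self, rng):
        q = rng.random((10, 10))
        sm = rng.random((10, 10))
        e = energy_landscape(q, sm, 0.5, 0.4)
        assert np.all(e[q <= 0.5] == 0)
        assert np.all(e[sm > 0.4] == 0)
        assert set(np.unique(e)) <= {0.0, 1.0}

    def test_continuous_energy_keeps_probability_values(self, rng):
        q = rng.random((10, 10))
        sm = rng.random((10, 10))
        e = energy_landscape(q, sm, 0.5, 0.4, continuous=True)
        inside = q > 0.5
        np.testing.assert_allclose(e[inside], ((1 - sm) * q)[inside])

    def test_raising_k_never_removes_marker_pixels(self):
        inst = two_touching_ellipses()
        hv = compute_hv_map(inst)
        sm = gradient_map(hv[..., 0], hv[..., 1])
        q = binarize(inst).astype(float)
        previous = 0
        for k in (0.2, 0.4, 0.6, 0.8):
            count = compute_marker(q, sm, 0.5, k).sum()
            assert count >= previous
            previous = count


class TestInstanceSegment:
    def test_single_blob_is_recovered_exactly(self):
        inst = np.zeros((40, 40), dtype=np.int32)
        rr, cc = ellipse(20, 20, 9, 12, shape=inst.shape)
        inst[rr, cc] = 1
        pred = instance_segment(binarize(inst).astype(float),
                                compute_hv_map(inst))
        np.testing.assert_array_equal(pred, inst)

    def test_touching_pair_is_split_accurately(self):
        inst = two_touching_ellipses()
        pred = instance_segment(binarize(inst).astype(float),
                                compute_hv_map(inst))
        assert pred.max() == 2
        assert aji(inst, pred) >= 0.9

    def test_empty_probability_map_gives_empty_instances(self):
        pred = instance_segment(np.zeros((30, 30)),
                                np.zeros((30, 30, 2)))
        np.testing.assert_array_equal(pred, 0)

    def test_foreground_without_markers_warns_and_returns_empty(self, caplog):
        # an aggressive speckle filter can eat every marker seed
        inst = two_touching_ellipses()
        q = binarize(inst).astype(float)
        p = compute_hv_map(inst)
        params = PostprocessParams(min_object_px=10 ** 6)
        with caplog.at_level("WARNING"):
            pred = instance_segment(q, p, params)
        assert pred.max() == 0
        assert any("marker" in r.message for r in caplog.records)

    def test_idempotent_on_its_own_reconstruction(self, small_dataset):
        patch = small_dataset[0]
        first = instance_segment(binarize(patch.instances).astype(float),
                                 compute_hv_map(patch.instances))
        second = instance_segment(binarize(first).astype(float),
                                  compute_hv_map(first))
        assert first.max() == second.max()

    def test_labels_consecutive_and_cover_foreground(self, small_dataset):
        patch = small_dataset[1]
        q = binarize(patch.instances).astype(float)
        pred = instance_segment(q, compute_hv_map(patch.instances))
        labels = np.unique(pred)
        np.testing.assert_array_equal(labels, np.arange(labels.max() + 1))
        assert ((pred > 0) == (q > 0.5)).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PostprocessParams(h=0.0)
        with pytest.raises(ValueError):
            PostprocessParams(sobel_ksize=4)


class TestAssignTypes:
    def _uniform_r(self, shape, cls, n_classes=3):
        r = np.zeros(shape + (n_classes + 1,))
        r[..., cls] = 1.0
        return r

    def test_unanimous_vote(self):
        inst = np.zeros((6, 6), dtype=np.int32)
        inst[1:4, 1:4] = 1
        pred = assign_types(inst, self._uniform_r((6, 6), 2))
        assert pred.types == {1: 2}
        assert pred.type_confidence[1] == 1.0

    def test_majority_vote_with_confidence(self):
        inst = np.zeros((1, 10), dtype=np.int32)
        inst[0, :10] = 1
        r = np.zeros((1, 10, 4))
        r[0, :6, 1] = 1.0  # 6 votes class 1
        r[0, 6:, 3] = 1.0  # 4 votes class 3
        pred = assign_types(inst, r)
        assert pred.types[1] == 1
        assert pred.type_confidence[1] == pytest.approx(0.6)

    def test_exact_tie_breaks_to_lowest_class(self):
        inst = np.zeros((1, 10), dtype=np.int32)
        inst[0, :10] = 1
        r = np.zeros((1, 10, 4))
        r[0, :5, 3] = 1.0
        r[0, 5:, 2] = 1.0
        pred = assign_types(inst, r)
        assert pred.types[1] == 2

    def test_background_channel_never_wins(self):
        inst = np.ones((4, 4), dtype=np.int32)
        r = np.zeros((4, 4, 4))
        r[..., 0] = 0.9   # background dominant per-pixel
        r[..., 2] = 0.1
        pred = assign_types(inst, r)
        assert pred.types[1] == 2


def test_separation_property_on_touching_patches():
    """Ideal (q, p) through the full pipeline resolves touching nuclei."""
    from gsnhv.experiments import separation_experiment
    result = separation_experiment(seed=7, n_patches=25)
    assert result["exact_count_fraction"] >= 0.9
    assert result["mean_aji"] >= 0.9
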