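"""Overlap/distance metrics against brute-force oracles; inference plumbing."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from parotidseg.evaluate import (
    dsc,
    evaluate_cases,
    hd95,
    precision_recall,
    sliding_window_predict,
    unite_parotids,
)
from parotidseg.grid import ImageVolume, LabelVolume
from parotidseg.nn import AttentionUNet3D, NetworkSpec


def _surface_bf(mask):
    """Oracle surface: foreground voxel with a background 6-neighbour."""
    out = np.zeros_like(mask, dtype=bool)
    padded = np.pad(mask, 1)
    for idx in np.argwhere(mask):
        z, y, x = idx + 1
        neigh = [
            padded[z - 1, y, x], padded[z + 1, y, x],
            padded[z, y - 1, x], padded[z, y + 1, x],
            padded[z, y, x - 1], padded[z, y, x + 1],
        ]
        if not all(neigh):
            out[tuple(idx)] = True
    return out


def _hd95_bf(a, b, spacing):
    """Oracle: all-pairs distances between surface voxels."""
    sa = np.argwhere(_surface_bf(a)) * np.asarray(spacing)
    sb = np.argwhere(_surface_bf(b)) * np.asarray(spacing)
    d = cdist(sa, sb)
    return max(
        np.percentile(d.min(axis=1), 95),
        np.percentile(d.min(axis=0), 95),
    )


def _random_masks(rng, shape=(12, 12, 12), p=0.2):
    a = ndi_blob(rng, shape, p)
    b = ndi_blob(rng, shape, p)
    return a, b


def ndi_blob(rng, shape, p):
    from scipy import ndimage

    raw = rng.random(shape) < p
    return ndimage.binary_dilation(raw) & (rng.random(shape) < 0.8)


class TestUniteParotids:
    def test_mixed_toy_grid(self):
        labels = LabelVolume(data=np.array([[[0, 1, 2, 0]]]))
        np.testing.assert_array_equal(unite_parotids(labels).data, [[[0, 1, 1, 0]]])

    def test_union_count_is_sum(self, small_phantom):
        _, labels = small_phantom
        united = unite_parotids(labels)
        assert united.data.sum() == np.count_nonzero(labels.data == 1) + np.count_nonzero(
            labels.data == 2
        )

    def test_empty_input(self):
        labels = LabelVolume(data=np.zeros((3, 3, 3), dtype=np.int16))
        assert unite_parotids(labels).data.sum() == 0


class TestOverlapMetrics:
    def test_identical_and_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        assert dsc(a, a) == 1.0
        assert dsc(a, ~a) == 0.0
        assert precision_recall(a, a) == (1.0, 1.0)

    def test_hand_counted_example(self):
        pred = np.zeros((1, 1, 6), bool)
        gt = np.zeros((1, 1, 6), bool)
        pred[0, 0, :2] = True          # 2 voxels
        gt[0, 0, :4] = True            # 4 voxels, 2 shared
        assert dsc(pred, gt) == pytest.approx(2 * 2 / (2 + 4))

    def test_confusion_count_toy(self):
        # TP=2, FP=1, FN=2
        pred = np.array([[[1, 1, 1, 0, 0]]], bool)
        gt = np.array([[[1, 1, 0, 1, 1]]], bool)
        p, r = precision_recall(pred, gt)
        assert p == pytest.approx(2 / 3)
        assert r == pytest.approx(0.5)

    def test_strict_subset(self):
        gt = np.zeros((4, 4, 4), bool)
        gt[1:3, 1:3, 1:3] = True
        pred = gt.copy()
        pred[2, 2, 2] = False
        p, r = precision_recall(pred, gt)
        assert p == 1.0 and r < 1.0

    def test_oracle_equivalence_on_random_masks(self, rng):
        """DSC/P/R match brute-force confusion counting; the harmonic
        identity DSC = 2PR/(P+R) holds whenever defined."""
        for _ in range(100):
            a, b = _random_masks(rng)
            tp = int(np.sum(a & b))
            fp = int(np.sum(a & ~b))
            fn = int(np.sum(~a & b))
            d = dsc(a, b)
            if 2 * tp + fp + fn > 0:
                assert d == pytest.approx(2 * tp / (2 * tp + fp + fn))
            p, r = precision_recall(a, b)
            if tp + fp and tp + fn and p + r > 0:
                assert d == pytest.approx(2 * p * r / (p + r))

    def test_axis_permutation_invariance(self, rng):
        a, b = _random_masks(rng)
        for perm in [(1, 2, 0), (2, 0, 1)]:
            assert dsc(a, b) == pytest.approx(dsc(a.transpose(perm), b.transpose(perm)))

    def test_dilation_toward_gt_never_decreases_dsc(self):
        from scipy import ndimage

        gt = np.zeros((16, 16, 16), bool)
        gt[4:12, 4:12, 4:12] = True
        pred = np.zeros_like(gt)
        pred[7:9, 7:9, 7:9] = True
        prev = dsc(pred, gt)
        for _ in range(4):
            pred = ndimage.binary_dilation(pred) & gt
            cur = dsc(pred, gt)
            assert cur >= prev
            prev = cur

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 3), bool))


class TestHD95:
    def test_identical_masks_zero(self):
        a = np.zeros((6, 6, 6), bool)
        a[2:4, 2:4, 2:4] = True
        assert hd95(a, a, (1, 1, 1)) == 0.0

    def test_single_voxels_along_z(self):
        a = np.zeros((8, 3, 3), bool)
        b = np.zeros((8, 3, 3), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        assert hd95(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0)
        assert hd95(a, b, (3.0, 1.0, 1.0)) == pytest.approx(9.0)

    def test_empty_mask_flagged_nan(self):
        a = np.zeros((4, 4, 4), bool)
        b = a.copy()
        b[1, 1, 1] = True
        assert np.isnan(hd95(a, b, (1, 1, 1)))

    def test_oracle_equivalence_random_masks(self, rng):
        """Spacing-aware HD95 equals the all-pairs brute-force computation."""
        spacings = [(1.0, 1.0, 1.0), (3.0, 0.87, 0.87), (2.0, 1.0, 1.5)]
        checked = 0
        while checked < 25:
            a, b = _random_masks(rng, shape=(10, 10, 10), p=0.15)
            if not (a.any() and b.any()):
                continue
            spacing = spacings[checked % len(spacings)]
            assert hd95(a, b, spacing) == pytest.approx(_hd95_bf(a, b, spacing), abs=1e-9)
            checked += 1

    def test_spacing_permutation_consistency(self, rng):
        a, b = _random_masks(rng)
        if not (a.any() and b.any()):
            pytest.skip("degenerate draw")
        perm = (2, 0, 1)
        h1 = hd95(a, b, (3.0, 1.0, 2.0))
        h2 = hd95(a.transpose(perm), b.transpose(perm), (2.0, 3.0, 1.0))
        assert h1 == pytest.approx(h2)


class TestEvaluateCases:
    def _mask(self, fill):
        data = np.zeros((6, 6, 6), dtype=np.int16)
        data[fill] = 1
        return LabelVolume(data=data)

    def test_mean_and_std(self):
        gt = self._mask((slice(1, 5), slice(1, 5), slice(1, 5)))
        pred_a = gt  # dsc 1
        pred_b = self._mask((slice(1, 5), slice(1, 5), slice(1, 3)))
        report = evaluate_cases([(pred_a, gt), (pred_b, gt)])
        d1 = report.per_case["dsc"].tolist()
        assert report.dsc_mean == pytest.approx(np.mean(d1))
        assert report.dsc_std == pytest.approx(np.std(d1))

    def test_empty_prediction_excluded_from_hd(self):
        gt = self._mask((slice(1, 5), slice(1, 5), slice(1, 5)))
        empty = LabelVolume(data=np.zeros((6, 6, 6), dtype=np.int16))
        report = evaluate_cases([(gt, gt), (empty, gt)])
        assert report.hd95_undefined_count == 1
        assert report.hd95_mean == pytest.approx(0.0)

    def test_perfect_single_case(self):
        gt = self._mask((slice(2, 4), slice(2, 4), slice(2, 4)))
        report = evaluate_cases([(gt, gt)])
        assert (report.dsc_mean, report.hd95_mean) == (1.0, 0.0)
        assert (report.precision_mean, report.recall_mean) == (1.0, 1.0)

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            evaluate_cases([])


@pytest.fixture(scope="module")
def tiny_net():
    spec = NetworkSpec(
        encoder_filters=(2, 4, 8, 16), bottleneck_filters=32, window=(16, 16, 16)
    )
    return AttentionUNet3D(spec, seed=0)


class TestSlidingWindow:
    def test_window_sized_volume_equals_single_forward(self, tiny_net, rng):
        data = rng.random((16, 16, 16)).astype(np.float32)
        vol = ImageVolume(data=data, units="normalized")
        pred = sliding_window_predict(tiny_net, vol)
        direct = np.argmax(tiny_net.forward(data[None, None])[0], axis=0)
        np.testing.assert_array_equal(pred.data, direct)

    def test_constant_zero_logits_tie_to_background(self, rng):
        spec = NetworkSpec(
            encoder_filters=(2, 4, 8, 16), bottleneck_filters=32, window=(16, 16, 16)
        )
        net = AttentionUNet3D(spec, seed=0)
        net.head.params["W"][:] = 0.0
        net.head.params["b"][:] = 0.0
        vol = ImageVolume(data=rng.random((16, 20, 24)).astype(np.float32), units="normalized")
        pred = sliding_window_predict(net, vol)
        assert np.all(pred.data == 0)

    def test_output_geometry_matches_input(self, tiny_net, rng):
        vol = ImageVolume(
            data=rng.random((10, 25, 33)).astype(np.float32),
            spacing=(3.0, 0.87, 0.87),
            units="normalized",
        )
        pred = sliding_window_predict(tiny_net, vol)
        assert pred.shape == vol.shape
        assert pred.spacing == vol.spacing
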