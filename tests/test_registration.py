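"""Histogram matching, similarity metrics, affine/demons behaviour, warping."""

import warnings

import numpy as np
import pytest
from scipy import stats

from parotidseg.grid import ImageVolume, LabelVolume
from parotidseg.phantom import DeformationSpec, apply_known_deformation, simulate_cbct
from parotidseg.registration import (
    AffineParams,
    AffineRegConfig,
    DemonsConfig,
    affine_register,
    demons_register,
    histogram_match,
    similarity_metrics,
    warp_labels,
)

from conftest import small_phantom_config


def _ks(a, b):
    return stats.ks_2samp(a.ravel(), b.ravel()).statistic


class TestHistogramMatch:
    def test_self_match_is_identity(self, small_phantom):
        vol, _ = small_phantom
        out = histogram_match(vol, vol)
        np.testing.assert_allclose(out.data, vol.data, atol=1.0)

    def test_shift_removed(self, small_phantom):
        vol, _ = small_phantom
        shifted = vol.with_data(vol.data + 200.0)
        out = histogram_match(shifted, vol)
        assert _ks(out.data, vol.data) < 0.05
        assert _ks(shifted.data, vol.data) > _ks(out.data, vol.data)

    def test_monotone_ordering_preserved(self, small_phantom, rng):
        vol, _ = small_phantom
        cbct = simulate_cbct(vol, seed=2)
        out = histogram_match(cbct, vol)
        flat_in = cbct.data.ravel()
        flat_out = out.data.ravel()
        idx = rng.integers(0, flat_in.size, size=(500, 2))
        for i, j in idx:
            if flat_in[i] < flat_in[j]:
                assert flat_out[i] <= flat_out[j] + 1e-6

    def test_agrees_with_skimage_oracle(self, small_phantom):
        """Independent cross-check against the exact-ECDF matcher."""
        from skimage.exposure import match_histograms

        vol, _ = small_phantom
        cbct = simulate_cbct(vol, seed=9)
        ours = histogram_match(cbct, vol).data
        ref = match_histograms(cbct.data, vol.data)
        span = np.ptp(vol.data)
        assert np.mean(np.abs(ours - ref)) < 0.02 * span

    def test_constant_image_warns_unchanged(self, small_phantom):
        vol, _ = small_phantom
        const = vol.with_data(np.full(vol.shape, 40.0, dtype=np.float32))
        with warnings.catch_warnings(record=True) as captured:
            warnings.simplefilter("always")
            out = histogram_match(const, vol)
        assert any("constant" in str(w.message) for w in captured)
        np.testing.assert_array_equal(out.data, const.data)


class TestSimilarityMetrics:
    def test_self_similarity(self, small_phantom):
        vol, _ = small_phantom
        m = similarity_metrics(vol, vol)
        assert m.mse == 0.0
        assert m.ncc == pytest.approx(1.0)

    def test_self_mi_equals_marginal_entropy(self, small_phantom):
        vol, _ = small_phantom
        m = similarity_metrics(vol, vol, bins=32)
        hist, _ = np.histogram(vol.data.ravel(), bins=32)
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert m.mi == pytest.approx(entropy, abs=1e-9)

    def test_independence_limit(self, rng):
        a = rng.standard_normal((50, 50, 50))
        b = a.copy().ravel()
        rng.shuffle(b)
        va = ImageVolume(data=a)
        vb = ImageVolume(data=b.reshape(a.shape))
        m = similarity_metrics(va, vb)
        assert m.mi < 0.05
        assert abs(m.ncc) < 0.05

    def test_mi_symmetry(self, small_phantom, rng):
        vol, _ = small_phantom
        other = simulate_cbct(vol, seed=5)
        assert similarity_metrics(vol, other).mi == pytest.approx(
            similarity_metrics(other, vol).mi, abs=1e-9
        )

    def test_ncc_affine_invariance(self, small_phantom):
        vol, _ = small_phantom
        other = simulate_cbct(vol, seed=6)
        base = similarity_metrics(vol, other).ncc
        rescaled = other.with_data(3.0 * other.data + 100.0)
        assert similarity_metrics(vol, rescaled).ncc == pytest.approx(base, abs=1e-6)

    def test_zero_variance_flagged(self):
        a = ImageVolume(data=np.zeros((4, 4, 4)))
        m = similarity_metrics(a, a)
        assert np.isnan(m.ncc)

    def test_geometry_mismatch(self):
        with pytest.raises(ValueError):
            similarity_metrics(
                ImageVolume(data=np.zeros((4, 4, 4))), ImageVolume(data=np.zeros((4, 4, 5)))
            )


@pytest.fixture(scope="module")
def quick_affine_cfg():
    # trimmed schedules keep the unit test fast; acceptance runs the full ones
    return AffineRegConfig(
        rigid_iterations=(30, 20, 10, 5), affine_iterations=(30, 20, 10, 5)
    )


class TestAffineRegister:
    def test_identity_pair_recovers_identity(self, small_phantom, quick_affine_cfg):
        vol, _ = small_phantom
        params, _, report = affine_register(vol, vol, quick_affine_cfg, seed=0)
        assert np.abs(params.translation).max() < 0.1  # mm
        # rotation/shear bound ~0.1 degree: off-diagonal entries stay tiny
        off_diag = params.matrix - np.diag(np.diag(params.matrix))
        assert np.abs(off_diag).max() < 2e-3
        # sampled-MI noise can drift the scale by a few tenths of a percent
        assert np.abs(np.diag(params.matrix) - 1.0).max() < 0.01
        assert report.mi_after >= report.mi_before - 0.05

    def test_translation_equivariance(self, small_phantom, quick_affine_cfg):
        """Pre-translating the moving image shifts the recovered transform."""
        vol, labels = small_phantom
        t_mm = 3.0 * vol.spacing[2]
        spec = DeformationSpec(type="translation", translation_mm=(0.0, 0.0, t_mm))
        moved, _, _, _ = apply_known_deformation(vol, labels, spec)
        params, _, report = affine_register(vol, moved, quick_affine_cfg, seed=0)
        assert params.translation[2] == pytest.approx(t_mm, abs=0.5 * vol.spacing[2])
        assert report.mi_after > report.mi_before

    def test_degenerate_transform_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineParams(matrix=np.zeros((3, 3)))


class TestDemonsRegister:
    def test_identity_pair_zero_field(self, small_phantom):
        vol, _ = small_phantom
        field, warped, report = demons_register(vol, vol, DemonsConfig(iterations=25))
        mean_mag_vox = np.sqrt((field**2).sum(axis=0)).mean() / np.mean(vol.spacing)
        assert mean_mag_vox < 0.05
        assert report.mse_after <= report.mse_before + 1e-9

    def test_translation_reduces_mse(self, small_phantom):
        vol, labels = small_phantom
        spec = DeformationSpec(type="translation", translation_mm=(0.0, 0.0, vol.spacing[2]))
        moved, _, _, _ = apply_known_deformation(vol, labels, spec)
        _, _, report = demons_register(moved, vol, DemonsConfig(iterations=100))
        assert report.mse_after < report.mse_before

    def test_smoothness_increases_with_sigma(self, small_phantom):
        vol, labels = small_phantom
        spec = DeformationSpec(type="sinusoidal", amplitude_vox=1.5, period_vox=16.0, seed=1)
        warped, _, _, _ = apply_known_deformation(vol, labels, spec)
        grads = []
        for sigma in (1.0, 3.0):
            field, _, _ = demons_register(warped, vol, DemonsConfig(sigma, iterations=60))
            g = np.stack(np.gradient(field, axis=(1, 2, 3)))
            grads.append(np.abs(g).max())
        assert np.isfinite(grads).all()
        assert grads[1] <= grads[0]

    def test_geometry_mismatch_rejected(self, small_phantom):
        vol, _ = small_phantom
        other = ImageVolume(data=vol.data[:-2], spacing=vol.spacing)
        with pytest.raises(ValueError, match="same grid"):
            demons_register(vol, other)


class TestWarpLabels:
    def test_identity_affine_unchanged(self, small_phantom):
        vol, labels = small_phantom
        out = warp_labels(labels, vol, affine=AffineParams())
        np.testing.assert_array_equal(out.data, labels.data)

    def test_pure_translation_moves_centroid(self, small_phantom):
        vol, labels = small_phantom
        shift_vox = 5.0
        t_mm = shift_vox * vol.spacing[2]
        # affine maps fixed points into moving space: +t picks up content at +t,
        # i.e. the mask appears shifted by -t on the fixed grid
        aff = AffineParams(translation=(0.0, 0.0, t_mm))
        out = warp_labels(labels, vol, affine=aff)
        c0 = np.argwhere(labels.data == 2).mean(axis=0)
        c1 = np.argwhere(out.data == 2).mean(axis=0)
        np.testing.assert_allclose(c1 - c0, [0, 0, -shift_vox], atol=0.5)

    def test_label_set_preserved(self, small_phantom, rng):
        vol, labels = small_phantom
        field = rng.normal(0.0, 1.5, size=(3,) + vol.shape).astype(np.float32)
        out = warp_labels(labels, vol, field_mm=field)
        assert set(np.unique(out.data)) <= {0, 1, 2}

    def test_missing_transform_rejected(self, small_phantom):
        _, labels = small_phantom
        with pytest.raises(ValueError):
            warp_labels(labels, labels)
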