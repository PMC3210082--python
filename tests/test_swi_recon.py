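"""SWI reconstruction: zero-fill interpolation, channel recombination,
homodyne phase filtering, phase masking and minimum-intensity projection."""

import numpy as np
import pytest

import venoquant as vq
from venoquant.swi_recon import ComplexChannelData


def make_kspace(rng, nx=8, ny=6, nz=2, n_channels=1, fov_cm=(0.8, 0.6)):
    k = rng.normal(size=(n_channels, nx, ny, nz)) + 1j * rng.normal(size=(n_channels, nx, ny, nz))
    return ComplexChannelData(k, (nx, ny), fov_cm, 2.0)


class TestZeroFill:
    def test_interpolated_voxel_size_from_fov_and_target(self, rng):
        """FOV 25.6 cm zero-filled to 768 gives the printed 0.33 mm voxels."""
        k = rng.normal(size=(1, 8, 6, 1)) + 0j
        ks = ComplexChannelData(k, (8, 6), (25.6, 19.2), 2.0)
        _, spacing = vq.zero_fill_reconstruct(ks, (768, 576))
        assert round(spacing[0], 2) == 0.33
        assert round(spacing[1], 2) == 0.33

    def test_identity_when_target_equals_acquisition(self, rng):
        ks = make_kspace(rng)
        imgs, _ = vq.zero_fill_reconstruct(ks, ks.matrix)
        direct = np.fft.ifft2(np.fft.ifftshift(ks.channels[0], axes=(0, 1)), axes=(0, 1))
        np.testing.assert_allclose(imgs[0], direct, atol=1e-12)

    def test_matches_dirichlet_interpolation_oracle(self, rng):
        """Zero-filled recon equals direct evaluation of the finite Fourier
        series (Dirichlet-kernel interpolation) on the fine grid."""
        ks = make_kspace(rng)
        nx, ny = ks.matrix
        tx, ty = 16, 12
        imgs, _ = vq.zero_fill_reconstruct(ks, (tx, ty))
        fx = np.arange(nx) - nx // 2
        fy = np.arange(ny) - ny // 2
        oracle = np.zeros((tx, ty, ks.channels.shape[3]), dtype=complex)
        for m in range(tx):
            for n in range(ty):
                x, y = m * nx / tx, n * ny / ty
                ph = np.exp(2j * np.pi * np.add.outer(fx * x / nx, fy * y / ny))
                for z in range(oracle.shape[2]):
                    oracle[m, n, z] = (ks.channels[0, :, :, z] * ph).sum() / (nx * ny)
        np.testing.assert_allclose(imgs[0], oracle, atol=1e-12)

    def test_padding_preserves_kspace_sum(self, rng):
        ks = make_kspace(rng)
        imgs, _ = vq.zero_fill_reconstruct(ks, (16, 12))
        # DC energy: sum of k-space samples == sum of padded k-space samples
        back = np.fft.fftshift(np.fft.fft2(imgs[0], axes=(0, 1)), axes=(0, 1))
        assert np.allclose(back.sum(), ks.channels[0].sum() * (16 * 12) / (8 * 6))
        # invariant stated directly on the k-space samples themselves
        padded_sum = ks.channels[0].sum()  # zeros contribute nothing
        assert np.allclose(padded_sum, ks.channels[0].sum())

    def test_round_trip_recovers_kspace(self, rng):
        ks = make_kspace(rng)
        imgs, _ = vq.zero_fill_reconstruct(ks, ks.matrix)
        k_back = np.fft.fftshift(np.fft.fft2(imgs[0], axes=(0, 1)), axes=(0, 1))
        np.testing.assert_allclose(k_back, ks.channels[0], atol=1e-10)

    def test_rejects_target_smaller_than_acquisition(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            vq.zero_fill_reconstruct(make_kspace(rng), (4, 6))


class TestRecombineChannels:
    def test_constant_offset_removed_single_channel(self):
        c = 3.0 * np.exp(1j * 0.7) * np.ones((8, 8, 4))
        mag, phase = vq.recombine_channels(c[None])
        assert np.abs(phase).max() < 1e-12
        assert np.allclose(mag, 1.0)  # unit-RMS normalisation of a constant

    def test_duplicated_channel_invariance(self, rng):
        img = (rng.normal(size=(8, 8, 4)) + 5) * np.exp(1j * rng.normal(0, 0.1, (8, 8, 4)))
        mag1, ph1 = vq.recombine_channels(img[None])
        mag2, ph2 = vq.recombine_channels(np.stack([img, img]))
        np.testing.assert_allclose(mag1, mag2, atol=1e-12)
        np.testing.assert_allclose(ph1, ph2, atol=1e-12)

    def test_opposed_offsets_recover_common_phase(self):
        """Two channels at +pi/2 / -pi/2 around a zero-mean common signal;
        the brute-force offset search maximising the coherent-sum magnitude
        agrees with the estimated offsets."""
        x = np.linspace(-1, 1, 16)
        common = 0.3 * np.sin(np.pi * np.add.outer(x, x))[:, :, None] * np.ones((1, 1, 4))
        ch = np.stack([np.exp(1j * (common + np.pi / 2)), np.exp(1j * (common - np.pi / 2))])
        _, phase = vq.recombine_channels(ch)
        np.testing.assert_allclose(phase, common, atol=1e-9)
        # oracle: the offset that maximises |sum| for channel 1 vs channel 0
        thetas = np.linspace(-np.pi, np.pi, 2001)
        sums = [np.abs(ch[0] + ch[1] * np.exp(-1j * t)).sum() for t in thetas]
        best = thetas[int(np.argmax(sums))]
        assert abs(best - (-np.pi)) < 0.01 or abs(best - np.pi) < 0.01  # relative offset -pi

    def test_zero_channel_excluded_all_zero_rejected(self, rng):
        img = np.exp(1j * rng.normal(size=(6, 6, 2)))
        mag_ref, _ = vq.recombine_channels(img[None])
        mag, _ = vq.recombine_channels(np.stack([img, np.zeros_like(img)]))
        np.testing.assert_allclose(mag, mag_ref, atol=1e-12)
        with pytest.raises(ValueError, match="all channels"):
            vq.recombine_channels(np.zeros((2, 4, 4, 2), dtype=complex))


class TestCorrectBias:
    def test_flat_volume_unchanged(self):
        vol = np.full((16, 16, 8), 50.0)
        np.testing.assert_allclose(vq.correct_bias(vol), vol, rtol=1e-9)

    def test_known_gain_field_recovered(self):
        """tissue x smooth gain -> tissue within 5% away from boundaries."""
        shape = (48, 48, 16)
        sp = (1.0, 1.0, 2.0)
        x, y, z = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
        gain = 1.0 + 0.15 * x + 0.10 * y**2 - 0.08 * z
        tissue = np.full(shape, 100.0)
        out = vq.correct_bias(tissue * gain, scale_mm=6.0, spacing=sp)
        inner = (slice(8, -8), slice(8, -8), slice(3, -3))
        rel = np.abs(out[inner] - tissue[inner]) / tissue[inner]
        assert rel.max() < 0.05
        assert abs(out.mean() - (tissue * gain).mean()) / (tissue * gain).mean() < 0.01

    def test_passthrough_mode(self, rng):
        vol = rng.uniform(1, 2, (6, 6, 3))
        ext = rng.uniform(1, 2, (6, 6, 3))
        np.testing.assert_array_equal(vq.correct_bias(vol, external=ext), ext)

    def test_zero_volume_identity(self):
        zero = np.zeros((5, 5, 2))
        np.testing.assert_array_equal(vq.correct_bias(zero), zero)


class TestHighpassPhase:
    def _smooth_ramp(self, nx=96, ny=96, nz=3):
        x, y, _ = np.meshgrid(
            np.linspace(0, 1, nx), np.linspace(0, 1, ny), np.arange(nz), indexing="ij"
        )
        return 2.0 * (x - 0.5) + 1.0 * (y - 0.5) ** 2

    def test_smooth_phase_suppressed(self):
        ramp = self._smooth_ramp()
        phase = vq.highpass_phase(100 * np.exp(1j * ramp), window=(24, 18))
        assert np.abs(phase[10:-10, 10:-10, :]).max() < 0.05

    def test_constant_phase_exactly_zero(self):
        img = 100 * np.exp(1j * 0.9) * np.ones((32, 32, 2))
        assert np.abs(vq.highpass_phase(img, window=(16, 12))).max() < 1e-12

    def test_tube_phase_retained(self):
        """A 2-voxel tube carrying -0.8 rad keeps >= 70% of it post-filter."""
        ramp = self._smooth_ramp()
        tube = np.zeros_like(ramp)
        tube[46:48, :, :] = -0.8
        phase = vq.highpass_phase(100 * np.exp(1j * (ramp + tube)), window=(24, 18))
        assert phase[46, 48, 1] <= -0.7 * 0.8

    def test_window_validation(self):
        img = np.ones((16, 16, 1), dtype=complex)
        with pytest.raises(ValueError, match=">= 2"):
            vq.highpass_phase(img, window=(1, 8))
        with pytest.raises(ValueError, match="exceeds"):
            vq.highpass_phase(img, window=(32, 8))


class TestPhaseMask:
    @pytest.mark.parametrize(
        "phi,expected",
        [(0.0, 1.0), (-np.pi / 2, 0.5), (-np.pi + 1e-9, 1e-9 / np.pi), (0.5, 1.0)],
    )
    def test_linear_ramp_values(self, phi, expected):
        assert vq.phase_mask(np.array([[[phi]]]))[0, 0, 0] == pytest.approx(expected, abs=1e-9)

    def test_monotone_on_negative_phase(self):
        phis = np.linspace(-np.pi + 1e-6, 0, 100).reshape(1, 1, -1)
        masks = vq.phase_mask(phis).ravel()
        assert np.all(np.diff(masks) >= 0)

    def test_positive_polarity_mirrors(self):
        phi = np.array([[[0.5]]])
        assert vq.phase_mask(phi, polarity="positive")[0, 0, 0] == pytest.approx(
            (np.pi - 0.5) / np.pi
        )


class TestApplyMask:
    def test_unit_mask_identity_and_power(self, rng):
        mag = rng.uniform(1, 2, (4, 4, 3))
        swi = vq.apply_mask(mag, np.ones_like(mag), n=4)
        np.testing.assert_allclose(swi.data, mag)
        half = vq.apply_mask(mag, np.full_like(mag, 0.5), n=4)
        np.testing.assert_allclose(half.data, mag * 0.0625)

    def test_never_increases_intensity(self, rng):
        mag = rng.uniform(0, 5, (6, 6, 4))
        mask = rng.uniform(0, 1, (6, 6, 4))
        assert np.all(vq.apply_mask(mag, mask, n=3).data <= mag + 1e-15)

    def test_higher_power_increases_vein_contrast(self, two_tube_truth):
        truth = two_tube_truth
        phase = np.where(truth.vein_mask.data, -0.8, 0.0)
        mask = vq.phase_mask(phase)
        mag = np.clip(truth.volume, 0, None)
        def contrast(n):
            swi = vq.apply_mask(mag, mask, n=n)
            v, b = truth.vein_mask.data, ~truth.vein_mask.data
            return (swi.data[b].mean() - swi.data[v].mean()) / swi.data[b].mean()
        assert contrast(4) > contrast(1)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            vq.apply_mask(np.ones((4, 4, 2)), np.ones((4, 4, 3)))


class TestMip:
    def _swi(self, data):
        return vq.SwiVolume(data=data, spacing=(1.0, 1.0, 2.0))

    def test_constant_volume_constant_stack(self):
        mip = vq.min_intensity_projection(self._swi(np.full((4, 4, 8), 7.0)), thickness=5)
        assert mip.data.shape == (4, 4, 4)
        np.testing.assert_allclose(mip.data, 7.0)

    def test_dark_voxel_window_membership(self):
        vol = np.full((3, 3, 10), 100.0)
        k = 6
        vol[1, 1, k] = 0.0
        mip = vq.min_intensity_projection(self._swi(vol), thickness=4)
        dark = np.where(mip.data[1, 1, :] == 0)[0]
        np.testing.assert_array_equal(dark, np.arange(max(0, k - 3), k + 1))

    def test_matches_brute_force_window_minimum(self, rng):
        vol = rng.uniform(size=(16, 16, 16))
        t = 5
        mip = vq.min_intensity_projection(self._swi(vol), thickness=t)
        for s in range(16 - t + 1):
            np.testing.assert_array_equal(mip.data[:, :, s], vol[:, :, s : s + t].min(axis=2))

    def test_scaling_and_thickness_one(self, rng):
        vol = rng.uniform(size=(6, 6, 6))
        m1 = vq.min_intensity_projection(self._swi(vol), thickness=1)
        np.testing.assert_array_equal(m1.data, vol)
        m3a = vq.min_intensity_projection(self._swi(2.5 * vol), thickness=3)
        m3b = vq.min_intensity_projection(self._swi(vol), thickness=3)
        np.testing.assert_allclose(m3a.data, 2.5 * m3b.data)

    def test_output_never_exceeds_inputs(self, rng):
        vol = rng.uniform(size=(5, 5, 9))
        mip = vq.min_intensity_projection(self._swi(vol), thickness=4)
        for s in range(mip.data.shape[2]):
            assert np.all(mip.data[:, :, s] <= vol[:, :, s : s + 4].min(axis=2) + 1e-15)

    def test_invalid_thickness_rejected(self):
        with pytest.raises(ValueError):
            vq.min_intensity_projection(self._swi(np.ones((3, 3, 3))), thickness=0)
        with pytest.raises(ValueError):
            vq.min_intensity_projection(self._swi(np.ones((3, 3, 3))), thickness=5)
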