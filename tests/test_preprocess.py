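"""Preprocessing contracts: backgrounds, ratio normalization, detection stack, filtering."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from puffkit.preprocess import (MovieStack, butterworth_detrend, compute_ratio_stack,
                                make_detection_stack, remove_flash_frames,
                                rolling_ball_subtract, subtract_background)

from conftest import constant_stack


class TestSubtractBackground:
    def test_scalar_subtraction_and_identity(self):
        st = constant_stack(100.0)
        assert np.all(subtract_background(st, 40.0).data == 60.0)
        assert np.array_equal(subtract_background(st, 0.0).data, st.data)

    def test_matches_elementwise_oracle(self, rng):
        data = rng.uniform(50, 200, size=(8, 8, 8))
        st = MovieStack(data, 0.16, 0.005)
        out = subtract_background(st, 30.0)
        assert np.allclose(out.data, np.clip(data - 30.0, 0, None))

    def test_region_mean_per_frame(self, rng):
        data = rng.uniform(50, 200, size=(5, 10, 10))
        st = MovieStack(data, 0.16, 0.005)
        region = (slice(0, 3), slice(0, 3))
        out = subtract_background(st, region)
        bg = data[:, :3, :3].reshape(5, -1).mean(axis=1)
        assert np.allclose(out.data, np.clip(data - bg[:, None, None], 0, None))

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(constant_stack(), (slice(0, 0), slice(0, 0)))


class TestRollingBall:
    def test_flat_image_maps_to_zero(self):
        img = np.full((80, 80), 37.0)
        assert np.allclose(rolling_ball_subtract(img, 50), 0.0, atol=1e-6)

    def test_spike_preserved(self):
        img = np.full((120, 120), 10.0)
        img[60, 60] += 100.0
        out = rolling_ball_subtract(img, 50)
        assert out[60, 60] == pytest.approx(100.0, rel=0.01)

    def test_idempotent_on_spikes(self):
        # once the flat background is removed, a second pass changes nothing
        img = np.full((60, 60), 100.0)
        for y, x, amp in [(10, 12, 80.0), (30, 40, 50.0), (50, 20, 120.0)]:
            img[y, x] += amp
        once = rolling_ball_subtract(img, 20)
        twice = rolling_ball_subtract(once, 20)
        # the ball sags by r - sqrt(r^2 - 1) under a 1-px spike; beyond that
        # geometric bound a second pass changes nothing
        sag = 20 - np.sqrt(20 ** 2 - 1)
        assert np.abs(twice - once).max() <= 2 * sag

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(np.zeros((10, 10)), 50)


class TestRemoveFlashFrames:
    def test_frame_count_and_bookkeeping(self):
        st = constant_stack(shape=(100, 4, 4), flash_frame=40)
        out = remove_flash_frames(st, n_frames=2)
        assert out.n_frames == 98
        assert out.removed_frames == [40, 41]
        # original index 42 now sits at position 40 and keeps its time
        assert out.orig_index[40] == 42
        assert out.frame_time_s(40) == pytest.approx(42 * 0.005)

    def test_zero_removal_is_identity(self):
        st = constant_stack(shape=(50, 4, 4), flash_frame=10)
        assert remove_flash_frames(st, n_frames=0) is st

    def test_out_of_range_rejected(self):
        st = constant_stack(shape=(50, 4, 4), flash_frame=49)
        with pytest.raises(ValueError):
            remove_flash_frames(st, n_frames=2)


class TestRatioStack:
    def test_constant_stack_gives_unit_ratio(self):
        st = constant_stack(100.0, shape=(30, 4, 4), flash_frame=20)
        rs = compute_ratio_stack(st, baseline_frames=10)
        assert np.allclose(rs.data, 1.0)

    def test_arithmetic_example(self):
        data = np.full((400, 4, 4), 100.0)
        data[395, 1, 2] = 150.0
        st = MovieStack(data, 0.16, 0.005, flash_frame=392)
        rs = compute_ratio_stack(st, baseline_frames=390)
        assert rs.data[395, 1, 2] == pytest.approx(1.5)

    def test_matches_per_pixel_oracle(self, rng):
        data = rng.uniform(50, 150, (40, 6, 6))
        st = MovieStack(data, 0.16, 0.005, flash_frame=30)
        rs = compute_ratio_stack(st, baseline_frames=20)
        for y in range(6):
            for x in range(6):
                f0 = data[:20, y, x].mean()
                assert np.allclose(rs.data[:, y, x], data[:, y, x] / f0)

    def test_baseline_mean_is_one_per_pixel(self, rng):
        data = rng.uniform(50, 150, (60, 5, 5))
        st = MovieStack(data, 0.16, 0.005, flash_frame=50)
        rs = compute_ratio_stack(st, baseline_frames=40)
        assert np.allclose(rs.data[:40].mean(axis=0), 1.0, atol=1e-9)

    def test_zero_baseline_pixel_named(self):
        data = np.full((20, 4, 4), 100.0)
        data[:, 2, 3] = 0.0
        st = MovieStack(data, 0.16, 0.005, flash_frame=15)
        with pytest.raises(ValueError, match=r"y=2.*x=3"):
            compute_ratio_stack(st, baseline_frames=10)

    def test_short_baseline_warns_and_truncates(self):
        st = constant_stack(100.0, shape=(50, 4, 4), flash_frame=30)
        with pytest.warns(UserWarning, match="pre-flash"):
            rs = compute_ratio_stack(st, baseline_frames=390)
        assert rs.baseline_frames == 30


class TestDetectionStack:
    def _ratio(self, rng, T=60, n=6, noise=0.02, baseline_frames=40):
        data = 100.0 * (1 + rng.normal(0, noise, (T, n, n)))
        st = MovieStack(data, 0.16, 0.005, flash_frame=baseline_frames)
        return compute_ratio_stack(st, baseline_frames=baseline_frames)

    def test_sd_scaling(self, rng):
        rs = self._ratio(rng)
        rs.baseline_sd[:] = 0.1
        out = make_detection_stack(rs, blur_sigma_px=0.0)
        base_mean = rs.data[:rs.baseline_frames].mean(axis=0)
        assert np.allclose(out, (rs.data - base_mean) * 10.0)

    def test_blur_leaves_constant_frame_unchanged(self, rng):
        rs = self._ratio(rng)
        rs.data[:] = 1.37
        rs.baseline_sd[:] = 0.1
        out = make_detection_stack(rs, blur_sigma_px=2.0)
        # baseline mean is 1.37 everywhere so the normalized frame is 0
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_impulse_blur_matches_kernel_peak(self, rng):
        rs = self._ratio(rng, n=21)
        rs.data[:] = 1.0
        rs.data[50, 10, 10] = 2.0
        rs.baseline_sd[:] = 1.0
        base = rs.data[:rs.baseline_frames].mean(axis=0)
        out = make_detection_stack(rs, blur_sigma_px=2.0)
        impulse = np.zeros((21, 21))
        impulse[10, 10] = 1.0
        kernel_peak = gaussian_filter(impulse, 2.0)[10, 10]
        expected = gaussian_filter((rs.data[50] - base), 2.0)[10, 10]
        assert out[50, 10, 10] == pytest.approx(expected, rel=1e-9)
        assert abs(out[50, 10, 10] - kernel_peak) < 1e-9

    def test_unit_noise_after_normalization(self, rng):
        # baseline-SD normalization makes per-pixel baseline noise SD ~ 1
        rs = self._ratio(rng, T=400, n=8, baseline_frames=390)
        out = make_detection_stack(rs, blur_sigma_px=0.0)
        sds = out[:390].std(axis=0, ddof=1)
        assert np.all(np.abs(sds - 1.0) < 0.1)

    def test_all_zero_sd_rejected(self, rng):
        rs = self._ratio(rng)
        rs.baseline_sd[:] = 0.0
        with pytest.raises(ValueError):
            make_detection_stack(rs)


class TestButterworth:
    def test_constant_preserved(self):
        x = np.full(2000, 1.23)
        assert np.allclose(butterworth_detrend(x), 1.23, atol=1e-9)

    def test_slow_sinusoid_strongly_attenuated(self):
        # frequency at 0.1x the cutoff must lose >= 90% amplitude
        n = 20000
        f = 0.1 * 0.01 / 2  # cycles per sample at 0.1x cutoff (cutoff = 0.01 Nyquist)
        x = np.sin(2 * np.pi * f * np.arange(n))
        y = butterworth_detrend(x, 0.01)
        core = y[n // 4: 3 * n // 4]
        assert np.abs(core - core.mean()).max() < 0.1

    def test_ramp_removed_transient_preserved(self):
        # 200 fps: ramp drift removed, 50-ms triangular transient kept >= 90%
        n = 6000
        t = np.arange(n) * 0.005
        ramp = 0.05 * t
        tri = np.zeros(n)
        c = 3000
        width = 5  # 50-ms base width at 5-ms frames
        tri[c - width:c + width + 1] = 1.0 - np.abs(np.arange(-width, width + 1)) / width
        x = 1.0 + ramp + tri
        y = butterworth_detrend(x, 0.01, baseline_frames=400)
        resid_slope = np.polyfit(t[:2500], y[:2500], 1)[0]
        assert abs(resid_slope) < 0.05 * 0.05
        local_base = y[c - 200:c - 50].mean()
        assert y[c] - local_base >= 0.9
        assert y[:400].mean() == pytest.approx(x[:400].mean(), abs=0.02)

    @pytest.mark.parametrize("cut", [0.0, 1.0, -0.5, 2.0])
    def test_bad_cutoff_rejected(self, cut):
        with pytest.raises(ValueError):
            butterworth_detrend(np.ones(100), cut)
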