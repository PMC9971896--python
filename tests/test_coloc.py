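"""Puncta detection and colocalization: LoG localization, Manders, Pearson, Costes."""

import numpy as np
import pytest
from scipy.stats import kstest

from puffkit.coloc import (costes_randomization, detect_puncta_log, filter_puncta,
                           manders_split, map_point_intensities, pearson_image,
                           colocalize)
from puffkit.synthetic import SimPunctaConfig, simulate_puncta_pair


def _spot_image(n, spots, sigma=2.0):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    img = np.zeros((n, n))
    for x, y, amp in spots:
        img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))
    return img


class TestDetectPunctaLog:
    def test_constant_image_no_puncta(self):
        assert detect_puncta_log(np.full((50, 50), 7.0), 0.16) == []

    def test_two_spots_localized(self):
        img = _spot_image(60, [(20.0, 30.0, 100.0), (30.0, 30.0, 80.0)], sigma=1.3)
        puncta = detect_puncta_log(img, 0.16, 0.6)
        assert len(puncta) == 2
        found = sorted((p.x_px, p.y_px) for p in puncta)
        assert found[0][0] == pytest.approx(20.0, abs=0.25)
        assert found[1][0] == pytest.approx(30.0, abs=0.25)
        for x, y in found:
            assert y == pytest.approx(30.0, abs=0.25)

    def test_subpixel_position(self):
        img = _spot_image(40, [(20.3, 18.4, 50.0)], sigma=1.3)
        puncta = detect_puncta_log(img, 0.16, 0.6)
        assert len(puncta) == 1
        assert puncta[0].x_px == pytest.approx(20.3, abs=0.25)
        assert puncta[0].y_px == pytest.approx(18.4, abs=0.25)

    def test_quality_sorted_descending(self):
        img = _spot_image(60, [(20, 20, 50.0), (40, 40, 100.0)], sigma=1.3)
        puncta = detect_puncta_log(img, 0.16, 0.6)
        assert puncta[0].quality >= puncta[1].quality

    def test_too_small_diameter_rejected(self):
        with pytest.raises(ValueError):
            detect_puncta_log(np.zeros((20, 20)), 0.4, 0.6)


class TestFilterPuncta:
    def test_permissive_filter_is_identity(self):
        img = _spot_image(60, [(20, 20, 50.0), (40, 40, 100.0)], sigma=1.3)
        puncta = detect_puncta_log(img, 0.16, 0.6)
        assert filter_puncta(puncta, 0.0, 100.0, 0.16) == puncta

    def test_size_filter_counts(self):
        # 20 small (sigma 0.4/sqrt(8) um) and 5 large (0.8/sqrt(8) um) spots
        small_d, big_d = 0.4, 0.8
        gy, gx = np.mgrid[0:5, 0:5]
        pos = np.column_stack([20.0 + 40.0 * gx.ravel(), 20.0 + 40.0 * gy.ravel()])
        px = 0.16
        sig = [small_d / (2 * np.sqrt(2)) / px] * 20 + [big_d / (2 * np.sqrt(2)) / px] * 5
        yy, xx = np.mgrid[0:200, 0:200].astype(float)
        img = np.zeros((200, 200))
        for (x, y), s in zip(pos, sig):
            img += 100.0 * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s ** 2))
        puncta = detect_puncta_log(img, px, 0.6)
        kept = filter_puncta(puncta, 0.0, 0.6, px)
        assert len(puncta) == 25
        assert len(kept) == 20

    def test_quality_cut_above_all_empties(self):
        img = _spot_image(60, [(20, 20, 50.0)], sigma=1.3)
        puncta = detect_puncta_log(img, 0.16, 0.6)
        assert filter_puncta(puncta, 1e9, 100.0, 0.16) == []


class TestMapPointIntensities:
    def test_identity_images_identity_line(self):
        img = _spot_image(60, [(20, 20, 50.0), (40, 40, 100.0)], sigma=1.3)
        puncta = detect_puncta_log(img, 0.16, 0.6)
        tab = map_point_intensities(puncta, img, img)
        assert np.allclose(tab.intensity_a, tab.intensity_b)

    def test_gain_two_slope_two(self):
        img = _spot_image(60, [(20, 20, 50.0), (40, 40, 100.0)], sigma=1.3)
        puncta = detect_puncta_log(img, 0.16, 0.6)
        tab = map_point_intensities(puncta, img, 2.0 * img)
        assert np.allclose(tab.intensity_b, 2.0 * tab.intensity_a)

    def test_simulated_intensity_correlation_recovered(self):
        cfg = SimPunctaConfig(n_spots=200, colocalized_fraction=1.0,
                              intensity_correlation=0.8, field_size_px=400,
                              spot_sigma_um=0.2, seed=9)
        a, b, _ = simulate_puncta_pair(cfg)
        puncta = detect_puncta_log(a, cfg.pixel_size_um, 0.6)
        tab = map_point_intensities(puncta, a, b)
        r = np.corrcoef(tab.intensity_a, tab.intensity_b)[0, 1]
        n = len(tab)
        z = np.arctanh(0.8)
        lo, hi = np.tanh(z - 2.5 / np.sqrt(n - 3)), np.tanh(z + 2.5 / np.sqrt(n - 3))
        assert lo < r < hi

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            map_point_intensities([], np.zeros((4, 4)), np.zeros((5, 5)))


class TestManders:
    def test_identical_images_equal_thresholds_give_one(self):
        img = _spot_image(40, [(10, 10, 50.0), (30, 25, 80.0)], sigma=1.5)
        m1, m2 = manders_split(img, img, 5.0, 5.0)
        assert m1 == pytest.approx(1.0)
        assert m2 == pytest.approx(1.0)

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[:5] = 10.0
        b[5:] = 10.0
        assert manders_split(a, b, 1.0, 1.0) == (0.0, 0.0)

    def test_direct_summation_oracle(self):
        a = np.array([[2.0, 0.0], [1.0, 0.0]])
        b = np.array([[3.0, 1.0], [0.0, 0.0]])
        m1, m2 = manders_split(a, b, 0.0, 0.0)
        assert m1 == pytest.approx(2.0 / 3.0)
        assert m2 == pytest.approx(3.0 / 4.0)

    def test_scalar_gain_invariance(self, rng):
        a = rng.uniform(0, 10, (16, 16))
        b = rng.uniform(0, 10, (16, 16))
        m = manders_split(a, b, 2.0, 3.0)
        m_scaled = manders_split(5.0 * a, b, 10.0, 3.0)
        assert m_scaled == pytest.approx(m)

    def test_monotone_in_other_channel_threshold(self, rng):
        a = rng.uniform(0, 10, (16, 16))
        b = rng.uniform(0, 10, (16, 16))
        m1s = [manders_split(a, b, 2.0, thr_b)[0] for thr_b in (0.0, 2.0, 5.0, 8.0)]
        assert m1s == sorted(m1s, reverse=True)

    def test_empty_channel_gives_nan(self):
        with pytest.warns(UserWarning):
            m1, _ = manders_split(np.zeros((4, 4)), np.ones((4, 4)), 0.5, 0.5)
        assert np.isnan(m1)


class TestPearsonImage:
    def test_identity_and_inversion(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        assert pearson_image(a, a) == pytest.approx(1.0)
        assert pearson_image(a, -a + 3.0) == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        b = rng.uniform(0, 1, (16, 16))
        x, y = a.ravel(), b.ravel()
        r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert pearson_image(a, b) == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pearson_image(np.ones((4, 4)), np.zeros((4, 4))))


class TestCostes:
    def test_identical_structured_pair_p_one(self):
        cfg = SimPunctaConfig(n_spots=40, colocalized_fraction=1.0,
                              intensity_correlation=1.0, seed=5)
        a, b, _ = simulate_puncta_pair(cfg)
        r, p = costes_randomization(a, b, block_px=5, n_iter=100, seed=0)
        assert r == pytest.approx(1.0)
        assert p == 1.0

    def test_seed_reproducibility(self):
        cfg = SimPunctaConfig(n_spots=30, colocalized_fraction=0.5, seed=6)
        a, b, _ = simulate_puncta_pair(cfg)
        out1 = costes_randomization(a, b, seed=7)
        out2 = costes_randomization(a, b, seed=7)
        assert out1 == out2

    def test_null_p_approximately_uniform(self):
        # independent block-scale images: p over repeated noise draws is
        # approximately uniform (KS non-rejection at alpha = 0.01)
        rng = np.random.default_rng(99)
        ps = []
        for k in range(200):
            a = np.repeat(np.repeat(rng.normal(size=(8, 8)), 5, 0), 5, 1)
            b = np.repeat(np.repeat(rng.normal(size=(8, 8)), 5, 0), 5, 1)
            _, p = costes_randomization(a, b, block_px=5, n_iter=49, seed=k)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_image_smaller_than_block_rejected(self):
        with pytest.raises(ValueError):
            costes_randomization(np.zeros((3, 3)), np.zeros((3, 3)), block_px=5)

    def test_colocalize_report_fields(self):
        cfg = SimPunctaConfig(n_spots=40, seed=8)
        a, b, _ = simulate_puncta_pair(cfg)
        res = colocalize(a, b, 1.0, 1.0, seed=3)
        assert res.m1 == pytest.approx(1.0) and res.m2 == pytest.approx(1.0)
        assert res.costes_p >= 0.95
        assert res.n_randomizations == 100 and res.block_px == 5
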