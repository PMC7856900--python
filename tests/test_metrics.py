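"""Evaluation metrics against literal-formula oracles and hand arithmetic."""

import math

import numpy as np
import pytest

from pamrestore.metrics import (
    DegenerateImageError,
    SSIMConstants,
    error_map,
    line_profile_snr,
    psnr,
    ssim,
    summarize_distribution,
)


def psnr_literal(ref, rec):
    """Naive transcription: 20 log10( max(ref) sqrt(N) / ||ref-rec||_2 )."""
    n = ref.size
    l2 = math.sqrt(float(np.sum((ref - rec) ** 2)))
    return 20.0 * math.log10(ref.max() * math.sqrt(n) / l2)


def ssim_literal(ref, rec, c1, c2, c3):
    """Naive transcription of the three-term global SSIM product."""
    mu_r = float(np.mean(ref))
    mu_c = float(np.mean(rec))
    sd_r = float(np.sqrt(np.mean((ref - mu_r) ** 2)))
    sd_c = float(np.sqrt(np.mean((rec - mu_c) ** 2)))
    cov = float(np.mean((ref - mu_r) * (rec - mu_c)))
    term1 = (2 * mu_r * mu_c + c1) / (mu_r**2 + mu_c**2 + c1)
    term2 = (2 * cov + c2) / (sd_r**2 + sd_c**2 + c2)
    term3 = (cov + c3) / (sd_r * sd_c + c3)
    return term1 * term2 * term3


class TestPSNR:
    def test_hand_example_single_pixel_error(self):
        ref = np.ones((2, 2))
        rec = ref.copy()
        rec[0, 0] = 0.5
        assert psnr(ref, rec) == pytest.approx(12.0412, abs=1e-4)

    def test_hand_example_constant_offset(self):
        ref = np.zeros((8, 8))
        ref[0, 0] = 1.0
        rec = ref + 0.1
        # MSE = 0.01, peak 1 -> 20 dB
        assert psnr(ref, rec) == pytest.approx(20.0)

    def test_scale_invariance(self, rng):
        ref, rec = rng.random((16, 16)), rng.random((16, 16))
        assert psnr(0.5 * ref, 0.5 * rec) == pytest.approx(psnr(ref, rec))

    def test_noise_monotonicity(self, rng):
        ref = rng.random((64, 64))
        vals = [psnr(ref, np.clip(ref + rng.normal(0, s, ref.shape), 0, 1)) for s in (0.01, 0.05, 0.2)]
        assert vals[0] > vals[1] > vals[2]

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateImageError):
            psnr(np.ones((4, 4)), np.ones((4, 4)))
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.ones((4, 4)))


class TestSSIM:
    def test_identity_is_one(self, rng):
        x = rng.random((16, 16))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert ssim(a, b) == pytest.approx(ssim(b, a), rel=1e-12)

    def test_hand_example_constant_images(self):
        ref = np.full((4, 4), 0.5)
        rec = np.full((4, 4), 0.25)
        consts = SSIMConstants(c1=1e-4, c2=1e-4, c3=1e-4)
        expected = (2 * 0.5 * 0.25 + 1e-4) / (0.5**2 + 0.25**2 + 1e-4)  # 0.2501/0.3126
        assert ssim(ref, rec, consts) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.80006, abs=5e-5)

    def test_bounded_above_by_one(self, rng):
        for _ in range(20):
            a, b = rng.random((12, 12)), rng.random((12, 12))
            assert ssim(a, b) <= 1.0 + 1e-12

    def test_zero_variance_zero_c3_convention(self):
        consts = SSIMConstants(c1=1e-4, c2=9e-4, c3=0.0)
        val = ssim(np.full((4, 4), 0.5), np.full((4, 4), 0.5), consts)
        assert val == pytest.approx(1.0)


class TestMetricOracles:
    def test_psnr_and_ssim_match_literal_formulas(self, rng):
        consts = SSIMConstants()
        for _ in range(100):
            ref = rng.random((16, 16))
            rec = rng.random((16, 16))
            p, p0 = psnr(ref, rec), psnr_literal(ref, rec)
            s, s0 = ssim(ref, rec, consts), ssim_literal(ref, rec, consts.c1, consts.c2, consts.c3)
            assert abs(p - p0) / abs(p0) < 1e-9
            assert abs(s - s0) / abs(s0) < 1e-9


class TestLineProfileSNR:
    def test_forced_definition_example(self):
        img = np.zeros((32, 32))
        img[16, :] = 0.8  # vessel line with peak 0.8
        # 2-value background whose sample SD is exactly 0.1
        img[2, 3] = 0.1 * math.sqrt(2)
        snr = line_profile_snr(img, ((16, 4), (16, 27)), (2, 3, 2, 4))
        assert snr == pytest.approx(8.0)

    def test_scale_invariance(self, rng):
        img = rng.random((32, 32))
        line = ((10.0, 2.0), (10.0, 29.0))
        box = (20, 30, 2, 30)
        assert line_profile_snr(2 * img, line, box) == pytest.approx(
            line_profile_snr(img, line, box)
        )

    def test_pure_noise_snr_above_one(self, rng):
        img = np.abs(rng.normal(0, 0.1, (64, 64)))
        snr = line_profile_snr(img, ((10.0, 2.0), (10.0, 60.0)), (30, 60, 2, 60))
        assert snr > 1.0

    def test_overlapping_background_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError):
            line_profile_snr(img, ((8, 0), (8, 15)), (6, 10, 2, 6))

    def test_zero_background_sd(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        with pytest.raises(DegenerateImageError):
            line_profile_snr(img, ((8, 0), (8, 15)), (0, 4, 0, 4))


class TestErrorMapAndSummary:
    def test_error_map_identity_and_nonnegative(self, rng):
        x = rng.random((8, 8))
        np.testing.assert_array_equal(error_map(x, x), 0.0)
        y = rng.random((8, 8))
        em = error_map(x, y)
        assert (em >= 0).all()
        assert em.sum() == pytest.approx(x.size * np.abs(x - y).mean())

    def test_summary_hand_example(self):
        mean, sd, (counts, edges) = summarize_distribution([1, 2, 3])
        assert mean == 2.0 and sd == pytest.approx(1.0)
        assert counts.sum() == 3

    def test_constant_list_sd_zero(self):
        mean, sd, _ = summarize_distribution([5.0] * 10)
        assert mean == 5.0 and sd == 0.0

    def test_mean_of_concatenation(self, rng):
        a, b = rng.random(10), rng.random(10)
        m_ab, _, _ = summarize_distribution(np.concatenate([a, b]))
        m_a, _, _ = summarize_distribution(a)
        m_b, _, _ = summarize_distribution(b)
        assert m_ab == pytest.approx((m_a + m_b) / 2)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            summarize_distribution([1.0])
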