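import itertools

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.stats import wilcoxon as scipy_wilcoxon

from nadd_ct import MetricsReport, psnr, ssim, vif, wilcoxon_one_sided
from nadd_ct.metrics import EVAL_RANGE_HU


@pytest.fixture(scope="module")
def textured_image():
    rng = np.random.default_rng(0)
    return gaussian_filter(rng.uniform(-200, 600, size=(96, 96)), 3.0)


class TestPsnr:
    def test_constant_offset_closed_form(self, textured_image):
        # MSE of a constant offset c is c^2 -> PSNR = 10 log10(P^2/c^2)
        c = 10.0
        expected = 10.0 * np.log10(EVAL_RANGE_HU**2 / c**2)
        assert psnr(textured_image + c, textured_image) == pytest.approx(expected)

    def test_identical_images_flagged_infinite(self, textured_image):
        assert psnr(textured_image, textured_image) == np.inf

    def test_matches_direct_mse_oracle(self, textured_image):
        rng = np.random.default_rng(1)
        noisy = textured_image + rng.normal(0, 25, textured_image.shape)
        mse = np.mean((noisy - textured_image) ** 2)
        assert psnr(noisy, textured_image) == pytest.approx(
            10.0 * np.log10(EVAL_RANGE_HU**2 / mse)
        )

    def test_shape_mismatch_raises(self, textured_image):
        with pytest.raises(ValueError):
            psnr(textured_image[:10], textured_image)


class TestSsim:
    def test_identical_images_score_one(self, textured_image):
        assert ssim(textured_image, textured_image) == pytest.approx(1.0)

    def test_anticorrelated_structure_scores_negative(self):
        # a pattern with ~zero local mean isolates the structure term, whose
        # sign flips for a = -ref; contrast must dominate the constants
        x = np.arange(64)
        pattern = 500.0 * np.sin(2 * np.pi * x / 4.0)[None, :] * np.ones((64, 1))
        assert ssim(-pattern, pattern) < 0.0

    def test_constant_images_closed_form(self):
        # with zero variance the structure/contrast term is C2/C2 = 1, so
        # SSIM = (2 c1 c2 + C1) / (c1^2 + c2^2 + C1)
        c1, c2 = 300.0, 500.0
        C1 = (0.01 * EVAL_RANGE_HU) ** 2
        expected = (2 * c1 * c2 + C1) / (c1**2 + c2**2 + C1)
        a = np.full((32, 32), c1)
        b = np.full((32, 32), c2)
        assert ssim(a, b) == pytest.approx(expected, rel=1e-6)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)), win_size=11)


class TestVif:
    def test_perfect_copy_scores_one(self, textured_image):
        assert vif(textured_image, textured_image) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_under_increasing_noise(self, textured_image):
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 1, textured_image.shape)
        scores = [vif(textured_image + s * noise, textured_image) for s in (0.0, 10.0, 40.0, 120.0)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_blur_degrades_score(self, textured_image):
        assert vif(gaussian_filter(textured_image, 2.0), textured_image) < 0.9

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            vif(np.zeros((32, 32)), np.full((32, 32), 7.0))


def brute_force_one_sided_p(diffs):
    """Independent oracle: enumerate all 2^n sign assignments explicitly."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    abs_d = np.abs(d)
    order = np.argsort(abs_d, kind="stable")
    ranks = np.empty(n)
    sorted_abs = abs_d[order]
    i, pos = 0, 1
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (pos + pos + (j - i)) / 2.0
        pos += j - i + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_five_positive_differences(self):
        res = wilcoxon_one_sided([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.p == pytest.approx(1.0 / 32.0)
        assert res.method == "exact"

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, size=15)
            mine = wilcoxon_one_sided(d).p
            ref = scipy_wilcoxon(d, alternative="greater", method="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_exact_with_ties_matches_brute_force(self):
        d = [1.0, 1.0, -1.0, 2.0, 2.0, 3.0, 0.5, -0.5]
        assert wilcoxon_one_sided(d).p == pytest.approx(brute_force_one_sided_p(d), abs=1e-12)

    def test_approximation_close_to_exact_null(self):
        # scipy's exact enumeration at n=30 vs our continuity-corrected normal
        rng = np.random.default_rng(4)
        d = rng.normal(0.2, 1.0, size=30)
        mine = wilcoxon_one_sided(d)
        assert mine.method == "approx"
        exact = scipy_wilcoxon(d, alternative="greater", method="exact").pvalue
        assert mine.p == pytest.approx(exact, abs=0.005)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.0, 1.0, size=12)
        p_pos = wilcoxon_one_sided(d).p
        p_neg = wilcoxon_one_sided(-d).p
        # exact null symmetry: P(W >= w) + P(W >= S - w) = 1 + P(W = w)
        assert p_pos + p_neg > 1.0
        assert p_pos + p_neg < 1.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            wilcoxon_one_sided([1.0, 2.0])


class TestMetricsReport:
    def build_report(self):
        rng = np.random.default_rng(6)
        ref = gaussian_filter(rng.uniform(0, 400, (48, 48)), 2.0)
        rep = MetricsReport()
        for k in range(6):
            noisy = ref + rng.normal(0, 60, ref.shape)
            better = ref + rng.normal(0, 20, ref.shape)
            rep.add("low_dose", f"S{k//3}", f"S{k//3}.z{k}", noisy, ref)
            rep.add("denoised", f"S{k//3}", f"S{k//3}.z{k}", better, ref)
        return rep

    def test_means_recompute_from_records(self):
        rep = self.build_report()
        means = rep.arm_means()
        for arm in ("low_dose", "denoised"):
            rows = [r for r in rep.records if r.arm == arm]
            assert means[arm]["ssim"] == np.mean([r.ssim for r in rows])

    def test_pairwise_comparison_detects_improvement(self):
        rep = self.build_report()
        comp = rep.compare("denoised", "low_dose", "ssim")
        assert comp.p_value < 0.05
        assert comp.n == 6

    def test_json_round_trip_is_bit_identical(self, tmp_path):
        rep = self.build_report()
        rep.compare("denoised", "low_dose", "psnr")
        path = tmp_path / "report.json"
        rep.to_json(path)
        back = MetricsReport.from_json(path)
        assert back.records == rep.records
        assert back.comparisons == rep.comparisons
        assert back.arm_means() == rep.arm_means()

    def test_csv_export(self, tmp_path):
        rep = self.build_report()
        path = tmp_path / "per_slice.csv"
        rep.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "arm,subject_id,slice_id,ssim,psnr,vif"
        assert len(lines) == 1 + len(rep.records)
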