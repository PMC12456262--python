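import numpy as np
import pytest

from nadd_ct import (
    DoseConfig,
    Sinogram,
    forward_project,
    inject_noise,
    make_dose_pair,
    make_noise_realizations,
    make_phantom,
    reconstruct,
    to_intensity,
)
from nadd_ct.noise import DoseConfigError, directional_anisotropy, medium_dose
from nadd_ct.phantoms import PhantomSpec

from conftest import disk_image


def flat_sinogram(geometry, p_value):
    return Sinogram(np.full(geometry.sinogram_shape(), p_value), geometry)


class TestDoseConfig:
    def test_low_dose_is_one_tenth_by_default(self):
        cfg = DoseConfig(I0_standard=1e5)
        assert cfg.dose_factor == 0.1
        assert cfg.I0_low == pytest.approx(1e4)

    def test_medium_dose_preset_is_one_quarter(self):
        cfg = medium_dose(DoseConfig(I0_standard=1e5))
        assert cfg.dose_factor == 0.25
        assert cfg.I0_low == pytest.approx(2.5e4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(I0_standard=0.0),
            dict(dose_factor=0.0),
            dict(dose_factor=1.5),
            dict(count_floor=0.0),
            dict(count_floor=1.0),
            dict(N=11),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(DoseConfigError):
            DoseConfig(**kwargs)


class TestIntensityConversion:
    def test_zero_projection_gives_full_intensity(self, micro_geometry):
        assert np.allclose(to_intensity(flat_sinogram(micro_geometry, 0.0), 1000.0), 1000.0)

    def test_log_ten_attenuation(self, micro_geometry):
        I = to_intensity(flat_sinogram(micro_geometry, np.log(10.0)), 1000.0)
        assert np.allclose(I, 100.0, rtol=1e-6)

    def test_monotone_in_p(self):
        p = np.linspace(0, 5, 50)
        I = to_intensity(p, 1e4)
        assert np.all(np.diff(I) < 0)

    def test_nonpositive_I0_rejected(self, micro_geometry):
        with pytest.raises(DoseConfigError):
            to_intensity(flat_sinogram(micro_geometry, 0.0), 0.0)


class TestNoiseInjection:
    """Monte-Carlo checks against the Poisson/delta-method oracles."""

    def test_counts_are_mean_preserving(self, micro_geometry):
        # p=0, I0=1000: mean count over all pixels ~ 1000 +- 3*sqrt(1000/n)
        g = micro_geometry
        rng = np.random.default_rng(42)
        p = flat_sinogram(g, 0.0)
        p_hat = inject_noise(p, 1000.0, rng)
        counts = 1000.0 * np.exp(-p_hat.values.astype(np.float64))
        n = counts.size
        assert abs(counts.mean() - 1000.0) < 3.0 * np.sqrt(1000.0 / n)

    def test_variance_matches_delta_method(self, micro_geometry):
        # Var(p_hat - p) ~ e^p / I0; at p=2, I0=1e4 within 5% over >=1e6 draws
        g = micro_geometry
        p_val, I0 = 2.0, 1.0e4
        draws_needed = int(1e6)
        reps = int(np.ceil(draws_needed / (g.n_views * g.n_det)))
        rng = np.random.default_rng(7)
        sq = 0.0
        n = 0
        p = flat_sinogram(g, p_val)
        for _ in range(reps):
            dev = inject_noise(p, I0, rng).values.astype(np.float64) - p_val
            sq += float((dev**2).sum())
            n += dev.size
        assert n >= draws_needed
        var = sq / n
        assert var == pytest.approx(np.exp(p_val) / I0, rel=0.05)

    def test_high_intensity_limit_is_noise_free(self, micro_geometry):
        # delta method: std ~ sqrt(e^p / I0) = 1.65e-4 at p=1, I0=1e8
        g = micro_geometry
        rng = np.random.default_rng(1)
        p = flat_sinogram(g, 1.0)
        dev = inject_noise(p, 1.0e8, rng).values.astype(np.float64) - 1.0
        assert dev.std() < 2e-4

    def test_deterministic_under_fixed_stream(self, micro_geometry):
        p = flat_sinogram(micro_geometry, 1.0)
        a = inject_noise(p, 1e4, np.random.default_rng(5))
        b = inject_noise(p, 1e4, np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)

    def test_count_floor_keeps_result_finite(self, micro_geometry):
        # absurdly low intensity: many zero counts, still finite output
        p = flat_sinogram(micro_geometry, 5.0)
        p_hat = inject_noise(p, 10.0, np.random.default_rng(0), count_floor=0.5)
        assert np.isfinite(p_hat.values).all()


class TestDosePair:
    def test_equal_dose_factor_shares_distribution(self, micro_geometry):
        cfg = DoseConfig(I0_standard=1e4, dose_factor=1.0, seed=9)
        p = flat_sinogram(micro_geometry, 1.0)
        q_low, q_tgt = make_dose_pair(p, cfg)
        # same I0: the two draws are i.i.d. -> equal variance within MC bounds
        v1, v2 = q_low.values.var(), q_tgt.values.var()
        assert v1 == pytest.approx(v2, rel=0.1)

    def test_low_dose_noisier_than_target(self, desk_geometry):
        g = desk_geometry
        p = forward_project(disk_image(g, radius_mm=80.0, hu=0.0), g)
        cfg = DoseConfig(seed=2)
        q_low, q_tgt = make_dose_pair(p, cfg)
        clean = reconstruct(p, g).pixels
        noise_low = reconstruct(q_low, g).pixels - clean
        noise_tgt = reconstruct(q_tgt, g).pixels - clean
        ny, nx = g.image_shape()
        roi = np.s_[ny // 2 - 10 : ny // 2 + 10, nx // 2 - 10 : nx // 2 + 10]
        ratio = noise_low[roi].std() / noise_tgt[roi].std()
        assert ratio > 1.0
        # variance ~ 1/I0 through the linear FBP: ratio ~ sqrt(10) within 15%
        assert ratio == pytest.approx(np.sqrt(10.0), rel=0.15)


class TestRealizations:
    def test_zero_realizations_degrade_to_baseline(self, micro_geometry):
        q = flat_sinogram(micro_geometry, 1.0).with_values(
            np.full(micro_geometry.sinogram_shape(), 1.0), role="noisy"
        )
        rset = make_noise_realizations(q, DoseConfig(N=0, seed=0))
        assert len(rset) == 0

    def test_exactly_ten_pairs_at_maximum(self, micro_geometry):
        g = micro_geometry
        p = forward_project(disk_image(g, radius_mm=40.0, hu=0.0), g)
        q = inject_noise(p, 1e4, np.random.default_rng(0), role="noisy")
        rset = make_noise_realizations(q, DoseConfig(N=10, seed=1), g)
        assert len(rset.sinograms) == len(rset.images) == 10

    def test_exceeding_max_rejected(self):
        with pytest.raises(DoseConfigError):
            DoseConfig(N=12, max_realizations=10)

    def test_noise_images_are_zero_mean_and_uncorrelated(self, micro_geometry):
        g = micro_geometry
        p = forward_project(disk_image(g, radius_mm=40.0, hu=0.0), g)
        # high intensity keeps the delta-method linearization accurate
        q = inject_noise(p, 1e6, np.random.default_rng(3), role="noisy")
        cfg = DoseConfig(I0_standard=1e7, N=4, seed=4)
        rset = make_noise_realizations(q, cfg, g)
        stack = rset.stack()
        # spatial mean ~ 0 relative to the noise scale
        for h in stack:
            assert abs(h.mean()) < 0.1 * h.std()
        # distinct realizations are uncorrelated
        for i in range(len(stack)):
            for j in range(i + 1, len(stack)):
                r = np.corrcoef(stack[i].ravel(), stack[j].ravel())[0, 1]
                assert abs(r) < 0.05

    def test_full_chain_bit_reproducible(self, micro_geometry):
        g = micro_geometry
        spec = PhantomSpec(body_half_axes=(50.0, 45.0), seed=5)
        cfg = DoseConfig(N=2, seed=6)

        def chain():
            p = forward_project(make_phantom(spec, g), g)
            q, t = make_dose_pair(p, cfg)
            rset = make_noise_realizations(q, cfg, g)
            return q.values, t.values, rset.stack()

        q1, t1, s1 = chain()
        q2, t2, s2 = chain()
        assert np.array_equal(q1, q2)
        assert np.array_equal(t1, t2)
        assert np.array_equal(s1, s2)


class TestStreakAnisotropy:
    def test_eccentric_phantom_yields_anisotropic_noise(self, desk_geometry):
        g = desk_geometry
        spec = PhantomSpec(
            body_half_axes=(120.0, 55.0), eccentricity="eccentric", n_inserts=0, seed=1
        )
        p = forward_project(make_phantom(spec, g), g)
        cfg = DoseConfig(N=2, seed=3)
        q, _ = make_dose_pair(p, cfg)
        rset = make_noise_realizations(q, cfg, g)
        ny, nx = g.image_shape()
        roi = np.s_[ny // 2 - 20 : ny // 2 + 20, nx // 2 - 30 : nx // 2 + 30]
        ratios = [directional_anisotropy(h.pixels[roi]) for h in rset.images]
        assert np.mean(ratios) > 1.5

    def test_circular_phantom_noise_is_isotropic(self, desk_geometry):
        g = desk_geometry
        spec = PhantomSpec(
            body_half_axes=(90.0, 90.0), eccentricity="non_eccentric", n_inserts=0, seed=1
        )
        p = forward_project(make_phantom(spec, g), g)
        cfg = DoseConfig(N=4, seed=3)
        q, _ = make_dose_pair(p, cfg)
        rset = make_noise_realizations(q, cfg, g)
        ny, nx = g.image_shape()
        roi = np.s_[ny // 2 - 20 : ny // 2 + 20, nx // 2 - 20 : nx // 2 + 20]
        ratio = np.mean([directional_anisotropy(h.pixels[roi]) for h in rset.images])
        assert ratio == pytest.approx(1.0, abs=0.1)
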