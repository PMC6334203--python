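"""Scenario generator: spectral initial fields and two-region diffusion."""

import numpy as np
import pytest
from scipy.stats import kstest

from epmodkit.scenario_gen import (ALPHA_CHOICES, F0_CHOICES, DiffusionScenario,
                                   InitialField, SpectrumConfig, cell_centres,
                                   generate_initial_field, interpolate_to_mesh,
                                   interpolate_to_nodes, make_scenario,
                                   rasterise_field, sample_scenario,
                                   sample_spectrum_config, scar_mask)


class TestSpectrumConfig:
    def test_deterministic_under_fixed_seed(self):
        a = sample_spectrum_config(np.random.default_rng(7))
        b = sample_spectrum_config(np.random.default_rng(7))
        assert a == b

    def test_choice_frequencies_within_3_sigma(self):
        rng = np.random.default_rng(0)
        cfgs = [sample_spectrum_config(rng) for _ in range(10_000)]
        alphas = np.array([c.alpha for c in cfgs])
        f0s = np.array([c.f_0 for c in cfgs])
        # binomial: p=1/2, sigma = sqrt(n p (1-p))
        sig_a = np.sqrt(10_000 * 0.25)
        for a in ALPHA_CHOICES:
            assert abs(np.sum(alphas == a) - 5000) < 3 * sig_a
        sig_f = np.sqrt(10_000 * (1 / 3) * (2 / 3))
        for f in F0_CHOICES:
            assert abs(np.sum(f0s == f) - 10_000 / 3) < 3 * sig_f
        assert all(c.f_c == 3.0 for c in cfgs)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist|alias"):
            SpectrumConfig(f_0=16, gen_resolution=24)


class TestInitialField:
    def test_real_windowed_normalised(self):
        rng = np.random.default_rng(3)
        cfg = sample_spectrum_config(rng)
        fld = generate_initial_field(cfg, rng)
        v = fld.values
        peak = np.max(np.abs(v))
        assert peak == pytest.approx(cfg.contrast)
        ring = np.concatenate([v[0], v[-1], v[:, 0], v[:, -1]])
        assert np.max(np.abs(ring)) < 1e-6 * peak

    def test_bit_identical_regeneration(self):
        cfg = SpectrumConfig(alpha=-2, f_0=12)
        a = generate_initial_field(cfg, np.random.default_rng(9)).values
        b = generate_initial_field(cfg, np.random.default_rng(9)).values
        np.testing.assert_array_equal(a, b)

    def test_power_absent_beyond_cutoff(self):
        cfg = SpectrumConfig(f_0=8)
        raw = generate_initial_field(cfg, np.random.default_rng(1),
                                     apply_window=False).values
        S = np.abs(np.fft.fft2(raw)) ** 2
        f = np.fft.fftfreq(cfg.gen_resolution, d=1 / cfg.gen_resolution)
        fx, fy = np.meshgrid(f, f, indexing="ij")
        frac = S[fx**2 + fy**2 >= cfg.f_0**2].sum() / S.sum()
        assert frac < 1e-8


class TestScenarioSampling:
    def test_isotropic_when_gamma_one(self):
        s = make_scenario(theta=0.2, beta=0.0, gamma=1.0, lam=3.0,
                          fast_axis="vertical", d_max=3.5)
        assert s.d0 == s.d1
        assert s.d0_scar == s.d1_scar

    def test_worked_arithmetic_example(self):
        s = make_scenario(theta=0.0, beta=0.0, gamma=2.0, lam=4.0,
                          fast_axis="horizontal", d_max=3.6)
        assert (s.d0, s.d1, s.d0_scar, s.d1_scar) == (3.6, 1.8, 0.9, 0.45)

    def test_sampled_intervals_and_exact_ratios(self):
        rng = np.random.default_rng(11)
        scens = [sample_scenario(rng) for _ in range(10_000)]
        gam = np.array([s.gamma for s in scens])
        lam = np.array([s.lam for s in scens])
        dmax = np.array([max(s.d0, s.d1) for s in scens])
        theta = np.array([s.theta for s in scens])
        beta = np.array([s.beta for s in scens])
        assert gam.min() >= 1.0 and gam.max() <= 3.0
        assert lam.min() >= 2.0 and lam.max() <= 7.0
        assert dmax.min() >= 3.2 and dmax.max() <= 3.8
        # ratio constraints hold to machine precision
        for s in scens[:2000]:
            assert max(s.d0, s.d1) / min(s.d0, s.d1) == pytest.approx(s.gamma, rel=1e-12)
            assert s.d0 / s.d0_scar == pytest.approx(s.lam, rel=1e-12)
            assert s.d1 / s.d1_scar == pytest.approx(s.lam, rel=1e-12)
        # uniform marginals at alpha = 0.01
        assert kstest(theta, "uniform", args=(0, np.pi)).pvalue > 0.01
        assert kstest(beta, "uniform", args=(-1, 2)).pvalue > 0.01
        assert kstest(gam, "uniform", args=(1, 2)).pvalue > 0.01
        assert kstest(lam, "uniform", args=(2, 5)).pvalue > 0.01
        assert kstest(dmax, "uniform", args=(3.2, 0.6)).pvalue > 0.01


class TestRasterise:
    def test_centre_line_splits_domain_in_half(self):
        s = make_scenario(theta=0.0, beta=0.0, gamma=2.0, lam=3.0,
                          fast_axis="horizontal", d_max=3.5)
        mask = scar_mask(s, (64, 64))
        assert abs(mask.sum() - 64 * 64 / 2) <= 64  # within one row

    def test_line_outside_domain_gives_single_region(self):
        s = make_scenario(theta=0.3, beta=2.9, gamma=2.0, lam=3.0,
                          fast_axis="horizontal", d_max=3.5)
        d = rasterise_field(s, (32, 32))
        assert np.unique(d[..., 0]).size == 1

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(2)
        s = sample_scenario(rng)
        d = rasterise_field(s, (48, 48))
        healthy = np.isclose(d[..., 0], s.d0)
        scar = np.isclose(d[..., 0], s.d0_scar)
        assert np.all(healthy | scar)
        assert healthy.sum() + scar.sum() == 48 * 48


class TestInterpolation:
    def test_identity_on_shared_nodes(self):
        rng = np.random.default_rng(4)
        fld = generate_initial_field(SpectrumConfig(f_0=8, gen_resolution=64), rng)
        out = interpolate_to_nodes(fld, 64)
        np.testing.assert_allclose(out, fld.values, atol=1e-12)

    def test_constant_field_preserved(self):
        const = np.full((33, 33), 2.5)
        out = interpolate_to_mesh(const, (20, 20))
        np.testing.assert_allclose(out, 2.5)

    def test_linear_ramp_reproduced_exactly(self):
        # bilinear interpolation reproduces affine functions
        n = 17
        x = np.linspace(-2, 2, n)
        X, Y = np.meshgrid(x, x, indexing="ij")
        ramp = 0.7 * X - 1.3 * Y + 0.1
        xc, yc = cell_centres((24, 24))
        Xc, Yc = np.meshgrid(xc, yc, indexing="ij")
        expect = 0.7 * Xc - 1.3 * Yc + 0.1
        np.testing.assert_allclose(interpolate_to_mesh(ramp, (24, 24)),
                                   expect, atol=1e-12)
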