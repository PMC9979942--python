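"""Pixel-wise prediction: fluxes, wavenumber statistics, error model,
likelihood, full-frame prediction and maximum-likelihood refinement."""

import numpy as np
import pytest

from stillsx.beam import BeamModel
from stillsx.crystal import CrystalModel, excited_reflections
from stillsx.pattern import (
    ErrorModel,
    PixelPrediction,
    _collect_pairs,
    _pack_pattern_params,
    expected_reading,
    expected_wavenumber,
    fit_pattern,
    outlier_logpdf,
    pattern_loglikelihood,
    pixel_flux,
    pixel_loglikelihood,
    pixel_variance,
    predict_pattern,
    wavenumber_variance,
)
from stillsx.simulate import (
    SimulationConfig,
    default_beam,
    default_detector,
    simulate_crystals,
    true_intensities,
)


@pytest.fixture(scope="module")
def toy():
    """One crystal, pink-ish beam, small detector and truth intensities."""
    cfg = SimulationConfig(n_crystals=1, seed=5, bandwidth=2e-3)
    rng = np.random.default_rng(5)
    beam = default_beam(cfg)
    crystal = simulate_crystals(cfg, rng)[0]
    truth = true_intensities(cfg, rng)
    det = default_detector(n_px=64, distance_m=0.05)
    return cfg, beam, crystal, truth, det


class TestPixelFlux:
    def test_zero_structure_factors_give_zero(self, toy):
        cfg, beam, crystal, truth, det = toy
        zeros = {k: 0.0 for k in truth}
        f = pixel_flux(crystal, beam, det.panels[0], 32, 32, zeros, d_min=cfg.d_min)
        assert f == 0.0

    def test_linearity_in_intensity_and_flux(self, toy):
        cfg, beam, crystal, truth, det = toy
        panel = det.panels[0]
        hkls = sorted(excited_reflections(crystal, beam, 4.0, cfg.d_min))
        args = dict(hkl_list=hkls, d_min=cfg.d_min)
        f1 = pixel_flux(crystal, beam, panel, 20, 20, truth, **args)
        doubled = {k: 2 * v for k, v in truth.items()}
        assert pixel_flux(crystal, beam, panel, 20, 20, doubled, **args) == pytest.approx(
            2 * f1, rel=1e-12
        )
        beam2 = BeamModel(nu0=beam.nu0, bandwidth=beam.bandwidth,
                          divergence=beam.divergence, flux=3 * beam.flux)
        assert pixel_flux(crystal, beam2, panel, 20, 20, truth, **args) == pytest.approx(
            3 * f1, rel=1e-12
        )

    def test_missing_intensity_policy(self, toy):
        cfg, beam, crystal, truth, det = toy
        hkls = sorted(excited_reflections(crystal, beam, 3.0, cfg.d_min))
        with pytest.raises(KeyError):
            pixel_flux(crystal, beam, det.panels[0], 20, 20, {},
                       hkl_list=hkls, missing="error")
        assert pixel_flux(crystal, beam, det.panels[0], 20, 20, {},
                          hkl_list=hkls, missing="skip") == 0.0


class TestWavenumberStats:
    def test_monochromatic_limit(self, toy):
        cfg, _, crystal, truth, det = toy
        beam = BeamModel(nu0=1.0 / 0.13)
        hkl = next(iter(truth))
        assert expected_wavenumber(crystal, beam, det.panels[0], 30, 30, hkl) == beam.nu0
        assert wavenumber_variance(crystal, beam, det.panels[0], 30, 30, hkl) == 0.0

    def test_variance_bounded_by_source(self, toy):
        cfg, beam, crystal, truth, det = toy
        for hkl in list(truth)[:20]:
            v = wavenumber_variance(crystal, beam, det.panels[0], 25, 40, hkl)
            assert 0 <= v <= (beam.nu0 * beam.bandwidth) ** 2 + 1e-15

    def test_rejection_sampling_oracle(self, rng):
        """Accepted-photon wavenumber stats: draw nu from the source,
        weight by the (divergence-marginalized) peak overlap of
        delta_k = nu (w - w_in)."""
        nu0 = 7.7
        crystal = CrystalModel(R=0.1 * np.eye(3), shape_cov=(3e-3) ** 2 * np.eye(3),
                               mosaicity=1e-3)
        hkl = (4, 1, 7)
        x = crystal.peak_position(hkl)
        # orient the beam so this reflection satisfies the diffraction
        # condition: w_in . x = -|x|^2 / (2 nu0) puts x on the Ewald sphere
        u = x / np.linalg.norm(x)
        t = np.cross(u, [1.0, 0.0, 0.0])
        t /= np.linalg.norm(t)
        c_in = -np.linalg.norm(x) / (2 * nu0)
        w_in = c_in * u + np.sqrt(1 - c_in**2) * t
        beam = BeamModel(nu0=nu0, bandwidth=5e-3, divergence=2e-4, w_in=w_in)
        k = beam.nu0 * beam.w_in + x
        w = k / np.linalg.norm(k)
        # slightly off the optimal direction to exercise the shift
        w = w + np.array([2e-4, 0, 0])
        w /= np.linalg.norm(w)
        from stillsx.crystal import peak_cov_at
        from stillsx.pattern import _wavenumber_stats

        nu = beam.nu0 * (1 + beam.bandwidth * rng.standard_normal(2_000_000))
        delta_cov = peak_cov_at(crystal, x) + (beam.nu0 * beam.divergence) ** 2 * (
            np.eye(3) - np.outer(beam.w_in, beam.w_in)
        )
        v = w - beam.w_in
        d = nu[:, None] * v[None, :] - x[None, :]
        weight = np.exp(-0.5 * np.einsum("ni,ij,nj->n", d, np.linalg.inv(delta_cov), d))
        mc_mean = np.sum(weight * nu) / weight.sum()
        mc_var = np.sum(weight * (nu - mc_mean) ** 2) / weight.sum()
        mean, var = _wavenumber_stats(crystal, beam, w, x)
        assert mean == pytest.approx(mc_mean, rel=0.5e-2)
        assert var == pytest.approx(mc_var, rel=2e-2)


class TestReadingAndVariance:
    def test_reading_product_form(self):
        assert expected_reading(0.0, 7.7, 1e-8, 2.0) == 0.0
        r1 = expected_reading(5.0, 7.7, 1e-8, 1.0)
        assert expected_reading(5.0, 7.7, 1e-8, 2.0) == pytest.approx(2 * r1)

    def test_pure_poisson_limit(self):
        em = ErrorModel(alpha=1.0, beta=0.0)
        nu, g = 7.7, 2.0
        r = 1000.0
        # monochromatic: var = g * r * nu = g^2 * N * nu^2
        assert pixel_variance(em, r, nu, 0.0, gain_g=g) == pytest.approx(g * r * nu)

    def test_constant_relative_error_limit(self):
        em = ErrorModel(alpha=0.0, beta=4e-4)
        for r in (10.0, 1e3, 1e6):
            assert np.sqrt(pixel_variance(em, r, 7.7, 0.0)) / r == pytest.approx(0.02)

    def test_polychromatic_photon_sampling_oracle(self, rng):
        """Compound-Poisson reading: N ~ Poisson, photon energies ~ Normal;
        empirical variance matches the error-model counting term."""
        em = ErrorModel(alpha=1.0, beta=0.0)
        g, nu, sig_nu, lam = 1.7, 7.7, 0.15, 50.0
        reps = 200_000
        n = rng.poisson(lam, reps)
        total = np.zeros(reps)
        active = n > 0
        total[active] = [
            g * np.sum(nu + sig_nu * rng.standard_normal(k)) for k in n[active]
        ]
        model = pixel_variance(em, g * lam * nu, nu, sig_nu**2, gain_g=g)
        assert total.var() == pytest.approx(model, rel=2e-2)


class TestPixelLikelihood:
    def test_outlier_density_normalized(self):
        xs = np.linspace(-2e5, 2e5, 2_000_001)
        mass = np.trapezoid(np.exp(outlier_logpdf(xs, 3.0)), xs)
        # the log^-2 tail converges slowly; the residual mass beyond the
        # grid is the analytic remainder ln(2)/ln(X/scale + 2)
        t = (2e5 / 3.0) + 2.0
        tail = np.log(2.0) / np.log(t)
        assert mass + tail == pytest.approx(1.0, abs=1e-3)

    def test_maximized_at_expected_value(self):
        pred = PixelPrediction(100.0, 25.0, 7.7, 0.0, 1.0)
        em = ErrorModel(alpha=1.0, beta=0.0, epsilon_outlier=1 / 16)
        center = pixel_loglikelihood(100.0, pred, em)
        for m in (80.0, 95.0, 105.0, 120.0):
            assert pixel_loglikelihood(m, pred, em) < center

    def test_heavy_tail_bounds_extreme_outliers(self):
        pred = PixelPrediction(100.0, 25.0, 7.7, 0.0, 1.0)
        em = ErrorModel(alpha=1.0, beta=0.0, epsilon_outlier=1 / 16)
        m = 100.0 + 1e6 * 5.0
        ll = pixel_loglikelihood(m, pred, em)
        assert np.isfinite(ll)
        assert ll >= np.log(em.epsilon_outlier) + outlier_logpdf(m, em.outlier_scale)

    def test_mixture_density_normalized(self):
        pred = PixelPrediction(50.0, 16.0, 7.7, 0.0, 1.0)
        em = ErrorModel(alpha=1.0, beta=0.0, epsilon_outlier=1 / 16, outlier_scale=10.0)
        xs = np.unique(np.concatenate([
            np.linspace(-4e4, 4e4, 8001),       # outlier body
            np.linspace(-400.0, 500.0, 90001),  # fine grid under the Gaussian
        ]))
        dens = np.exp([pixel_loglikelihood(x, pred, em) for x in xs])
        mass = np.trapezoid(dens, xs)
        t = (4e4 / 10.0) + 2.0
        tail = em.epsilon_outlier * np.log(2.0) / np.log(t)
        assert mass + tail == pytest.approx(1.0, abs=1e-3)


class TestPredictPattern:
    def test_empty_excited_set_returns_background(self):
        crystal = CrystalModel(R=0.1 * np.eye(3), shape_cov=1e-12 * np.eye(3))
        beam = BeamModel(nu0=1.0 / 0.13)
        det = default_detector(n_px=16)
        bg = {"panel0": np.full((16, 16), 7.0)}
        out = predict_pattern(crystal, beam, det, {}, background=bg,
                              sigma_cutoff=1e-3, d_min=2.0)
        np.testing.assert_array_equal(out["panel0"], bg["panel0"])

    def test_ellipse_contains_reflection_flux(self, toy):
        """Each projected reflection keeps >= 99% of its flux inside the
        4-sigma detector ellipse (compared against an 8-sigma footprint)."""
        cfg, beam, crystal, truth, det = toy
        hkls = sorted(excited_reflections(crystal, beam, 3.0, cfg.d_min))
        checked = 0
        for hkl in hkls:
            f2 = truth.get(tuple(hkl))
            if not f2:
                continue
            one = {tuple(hkl): f2}
            tight = predict_pattern(crystal, beam, det, one, sigma_cutoff=3.0,
                                    d_min=cfg.d_min, sigma_ellipse=4.0)["panel0"].sum()
            wide = predict_pattern(crystal, beam, det, one, sigma_cutoff=3.0,
                                   d_min=cfg.d_min, sigma_ellipse=8.0)["panel0"].sum()
            if wide > 1e-6:
                assert tight >= 0.99 * wide
                checked += 1
        assert checked >= 3

    def test_flux_conserved_under_smoothing(self):
        """Analytic smoothing redistributes flux among pixels without
        changing the frame total (<= 0.1%).

        The reference is the unsmoothed density sampled at pixel centers,
        which is itself accurate only when spots span a few pixels, so the
        toy uses a broad reciprocal peak shape.
        """
        rng = np.random.default_rng(21)
        from scipy.spatial.transform import Rotation

        q = Rotation.random(random_state=rng).as_matrix()
        crystal = CrystalModel(R=q @ (0.1 * np.eye(3)),
                               shape_cov=(8e-3) ** 2 * np.eye(3))
        beam = BeamModel(nu0=1.0 / 0.13, bandwidth=1e-3)
        det = default_detector(n_px=128, distance_m=0.1)
        truth = {k: 1000.0 for k in true_intensities(
            SimulationConfig(n_crystals=1, seed=21, d_min=1.4),
            np.random.default_rng(21))}
        kw = dict(sigma_cutoff=3.0, d_min=1.4, sigma_ellipse=8.0)
        smoothed = predict_pattern(crystal, beam, det, truth, oversample=1, **kw)
        unsmoothed = predict_pattern(crystal, beam, det, truth, oversample=4, **kw)
        a, b = smoothed["panel0"].sum(), unsmoothed["panel0"].sum()
        assert a > 0
        assert a == pytest.approx(b, rel=1e-3)

    def test_pink_beam_spots_elongate_with_bandwidth(self, toy):
        """The projected detector ellipse of a reflection becomes more
        anisotropic (radially stretched) as the bandwidth grows."""
        from stillsx.pattern import _touched_pixels

        cfg, beam0, crystal, truth, det = toy
        hkls = sorted(excited_reflections(crystal, beam0, 2.0, cfg.d_min))
        assert hkls
        panel = det.panels[0]

        def anisotropy(bw, hkl):
            beam = BeamModel(nu0=beam0.nu0, bandwidth=bw)
            touched = _touched_pixels(crystal, beam, panel, hkl, 4.0)
            if touched is None:
                return None
            cov2 = touched[3]
            lam = np.linalg.eigvalsh(cov2)
            return lam[1] / max(lam[0], 1e-12)

        checked = 0
        for hkl in hkls[:6]:
            ratios = [anisotropy(bw, hkl) for bw in (1e-4, 5e-3, 2.5e-2)]
            if any(r is None for r in ratios):
                continue
            assert ratios[0] < ratios[1] < ratios[2]
            checked += 1
        assert checked >= 2


class TestFitPattern:
    def test_gradient_matches_finite_differences(self, toy):
        """Exact forward-mode gradient of the pattern likelihood vs central
        differences with curvature-appropriate steps, every parameter."""
        cfg, beam, crystal, truth, det = toy
        bg = {"panel0": np.full((64, 64), 10.0)}
        imgs = predict_pattern(crystal, beam, det, truth, background=bg,
                               sigma_cutoff=4.0, d_min=cfg.d_min)
        em = ErrorModel(alpha=1.0, beta=1e-4, epsilon_outlier=1 / 16)
        panel = det.panels[0]
        hkls = sorted(excited_reflections(crystal, beam, 4.0, cfg.d_min))
        pairs = _collect_pairs(crystal, beam, panel, truth, hkls, 1, 5.0)
        meas, bgf = imgs["panel0"].ravel() * 1.02, bg["panel0"].ravel()
        th = _pack_pattern_params(crystal, em)
        _, g = pattern_loglikelihood(th, pairs, meas, bgf, beam, panel.gain_g, em)
        scales = np.ones(21)
        scales[:9] = 1e-3 * np.abs(th[:9]).max()
        scales[9:15] = [0.3 if k in (0, 2, 5) else 1e-3 for k in range(6)]
        scales[15:21] = [0.3, 0.3, 0.2, 0.02, 0.3, 0.3]
        for i in range(21):
            h = 1e-4 * scales[i]
            tp, tm = th.copy(), th.copy()
            tp[i] += h
            tm[i] -= h
            fp, _ = pattern_loglikelihood(tp, pairs, meas, bgf, beam, panel.gain_g, em)
            fm, _ = pattern_loglikelihood(tm, pairs, meas, bgf, beam, panel.gain_g, em)
            fd = (fp - fm) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_self_consistency_recovery(self, toy):
        """Refit of a self-generated noiseless image from a perturbed start
        recovers the well-determined parameters (cell, scale) to 0.1%."""
        cfg, beam, crystal, truth, det = toy
        bg = {"panel0": np.full((64, 64), 10.0)}
        imgs = predict_pattern(crystal, beam, det, truth, background=bg,
                               sigma_cutoff=4.0, d_min=cfg.d_min)
        em = ErrorModel(alpha=1.0, beta=1e-6, epsilon_outlier=0.0)
        rng = np.random.default_rng(7)
        pert = CrystalModel(R=crystal.R * (1 + 2e-3 * rng.standard_normal((3, 3))),
                            shape_cov=crystal.shape_cov,
                            mosaicity=crystal.mosaicity,
                            strain=crystal.strain,
                            scale_a=crystal.scale_a * 1.02,
                            b_factor=crystal.b_factor + 0.01)
        fit, em_out, diags = fit_pattern(
            imgs, det, pert, beam, truth, background=bg, em=em,
            d_min=cfg.d_min, sigma_cutoff=4.0,
            fixed=("shape", "mosaicity", "strain", "error_model"), maxiter=400,
        )
        assert diags["loglik"] >= diags["loglik_start"]
        assert np.abs(fit.R - crystal.R).max() / np.abs(crystal.R).max() < 1e-3
        assert abs(fit.scale_a - crystal.scale_a) / crystal.scale_a < 1e-3
        # fixed groups stay at their initial values
        assert fit.mosaicity == pytest.approx(pert.mosaicity, rel=1e-12)
        assert fit.strain == pytest.approx(pert.strain, rel=1e-12)
        np.testing.assert_allclose(fit.shape_cov, pert.shape_cov, rtol=1e-10)
        assert em_out.alpha == pytest.approx(em.alpha, rel=1e-12)
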