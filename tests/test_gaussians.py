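"""Closed-form Gaussian algebra against brute-force numerical oracles."""

import numpy as np
import pytest
from scipy.special import roots_legendre

from stillsx.gaussians import (
    DegenerateCovarianceError,
    GaussianKernel,
    GaussianMixture,
    coherent_amplitude_overlap,
    convolve,
    correlated_difference_cov,
    evaluate,
    integrate_product_coherent,
    integrate_product_incoherent,
    product,
    project_1d,
    symmetric_sqrtm,
)

from conftest import random_kernel, random_psd


def tensor_grid_integral(f, center, half, n=90):
    """Gauss-Legendre tensor-product integral of f over a centred 3-D box."""
    x, w = roots_legendre(n)
    pts = center[None, :] + half * np.stack(
        np.meshgrid(x, x, x, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    wts = (w[:, None, None] * w[None, :, None] * w[None, None, :]).ravel()
    return float(np.sum(f(pts) * wts) * half**3)


def kernel_density(k, pts):
    d = pts - k.mean
    s = np.linalg.inv(k.cov)
    maha = np.einsum("ni,ij,nj->n", d, s, d)
    norm = np.sqrt(np.linalg.det(2 * np.pi * k.cov))
    return k.weight * np.exp(-0.5 * maha) / norm


class TestEvaluate:
    def test_standard_normal_at_mean(self):
        k = GaussianKernel(1.0, np.zeros(3), np.eye(3))
        assert evaluate(k, np.zeros(3)) == pytest.approx((2 * np.pi) ** -1.5)

    def test_weight_scaling_at_mean(self, rng):
        k = random_kernel(rng)
        k2 = GaussianKernel(2 * k.weight, k.mean, k.cov)
        expected = 2 * k.weight / np.sqrt(np.linalg.det(2 * np.pi * k.cov))
        assert evaluate(k2, k.mean) == pytest.approx(expected)
        assert evaluate(k2, k.mean) == pytest.approx(2 * evaluate(k, k.mean))

    def test_total_mass_equals_weight(self, rng):
        """Grid quadrature of the density over a wide box recovers the weight."""
        k = random_kernel(rng, weight_scale=3.0)
        half = 8.0 * np.sqrt(np.max(np.linalg.eigvalsh(k.cov)))
        mass = tensor_grid_integral(lambda p: np.array([evaluate(k, q) for q in p]),
                                    k.mean, half, n=61)
        assert mass == pytest.approx(k.weight, rel=1e-3)

    def test_singular_covariance_raises_with_direction(self):
        cov = np.diag([1.0, 1.0, 0.0])
        k = GaussianKernel(1.0, np.zeros(3), cov)
        with pytest.raises(DegenerateCovarianceError) as err:
            evaluate(k, np.zeros(3))
        assert err.value.null_direction is not None
        assert abs(err.value.null_direction @ np.array([0, 0, 1.0])) > 0.99


class TestProduct:
    def test_identical_standard_kernels(self):
        k = GaussianKernel(1.0, np.zeros(3), np.eye(3))
        p = product(k, k)
        np.testing.assert_allclose(p.mean, 0.0, atol=1e-14)
        np.testing.assert_allclose(p.cov, np.eye(3) / 2, atol=1e-14)

    def test_pointwise_oracle(self, rng):
        """product(a, b) evaluates to evaluate(a) * evaluate(b) everywhere."""
        for _ in range(10):
            a, b = random_kernel(rng), random_kernel(rng)
            p = product(a, b)
            for x in rng.standard_normal((10, 3)) * 2:
                assert evaluate(p, x) == pytest.approx(
                    evaluate(a, x) * evaluate(b, x), rel=1e-10
                )

    def test_shifted_pair_closed_form(self):
        a = GaussianKernel(1.0, np.zeros(3), np.eye(3))
        b = GaussianKernel(1.0, np.array([2.0, 0, 0]), np.eye(3))
        p = product(a, b)
        np.testing.assert_allclose(p.mean, [1.0, 0, 0], atol=1e-14)
        np.testing.assert_allclose(p.cov, np.eye(3) / 2, atol=1e-14)
        assert p.weight == pytest.approx(np.exp(-1.0) * (4 * np.pi) ** -1.5)

    def test_weight_linearity(self, rng):
        a, b = random_kernel(rng), random_kernel(rng)
        a2 = GaussianKernel(2 * a.weight, a.mean, a.cov)
        assert product(a2, b).weight == pytest.approx(2 * product(a, b).weight)


class TestConvolve:
    def test_identity_element(self, rng):
        a = random_kernel(rng)
        c = convolve(a, GaussianKernel(1.0, np.zeros(3), np.zeros((3, 3))))
        np.testing.assert_allclose(c.mean, a.mean)
        np.testing.assert_allclose(c.cov, a.cov, atol=1e-15)
        assert c.weight == pytest.approx(a.weight)

    def test_isotropic_variances_add(self):
        a = GaussianKernel(1.0, np.zeros(3), 2.0 * np.eye(3))
        b = GaussianKernel(1.0, np.ones(3), 3.0 * np.eye(3))
        c = convolve(a, b)
        np.testing.assert_allclose(c.cov, 5.0 * np.eye(3))
        np.testing.assert_allclose(c.mean, np.ones(3))

    def test_commutative_associative(self, rng):
        a, b, c = (random_kernel(rng) for _ in range(3))
        ab = convolve(a, b)
        ba = convolve(b, a)
        np.testing.assert_allclose(ab.mean, ba.mean, atol=1e-12)
        np.testing.assert_allclose(ab.cov, ba.cov, atol=1e-12)
        left = convolve(convolve(a, b), c)
        right = convolve(a, convolve(b, c))
        np.testing.assert_allclose(left.cov, right.cov, atol=1e-12)
        np.testing.assert_allclose(left.mean, right.mean, atol=1e-12)
        assert left.weight == pytest.approx(right.weight, rel=1e-12)

    def test_grid_convolution_oracle(self, rng):
        """1-D marginals of the convolution match direct grid convolution."""
        a, b = random_kernel(rng), random_kernel(rng)
        c = convolve(a, b)
        e = np.array([1.0, 0, 0])
        # marginals along e are 1-D Gaussians
        xs = np.linspace(-30, 30, 6001)
        dx = xs[1] - xs[0]

        def marginal(k):
            m, v, w = k.mean @ e, e @ k.cov @ e, k.weight
            return w * np.exp(-0.5 * (xs - m) ** 2 / v) / np.sqrt(2 * np.pi * v)

        direct = np.convolve(marginal(a), marginal(b), mode="same") * dx
        analytic = marginal(c)
        assert np.max(np.abs(direct - analytic)) < 1e-4


class TestCorrelatedDifference:
    def test_identical_covariances_cancel(self, rng):
        cov = random_psd(rng)
        np.testing.assert_allclose(correlated_difference_cov(cov, cov), 0.0, atol=1e-14)

    def test_scalar_rule_embedded(self):
        out = np.diag([4.0, 0, 0])
        inn = np.diag([1.0, 0, 0])
        res = correlated_difference_cov(out, inn)
        np.testing.assert_allclose(res, np.diag([1.0, 0, 0]), atol=1e-12)

    def test_commuting_pair_eigenvalue_rule_and_sampling(self, rng):
        """Shared eigenbasis: eigenvalue-wise (sqrt(lo) - sqrt(li))^2,
        cross-checked by sampling correlated Gaussian pairs."""
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        lo = rng.uniform(0.5, 3.0, 3)
        li = rng.uniform(0.1, 2.0, 3)
        cov_out = (q * lo) @ q.T
        cov_in = (q * li) @ q.T
        res = correlated_difference_cov(cov_out, cov_in)
        expected = (q * (np.sqrt(lo) - np.sqrt(li)) ** 2) @ q.T
        np.testing.assert_allclose(res, expected, atol=1e-12)
        z = rng.standard_normal((1_000_000, 3))
        diff = z @ (symmetric_sqrtm(cov_out) - symmetric_sqrtm(cov_in)).T
        emp = np.cov(diff.T)
        assert np.abs(emp - expected).max() < 0.01 * np.abs(expected).max()

    def test_result_is_psd(self, rng):
        for _ in range(20):
            r = correlated_difference_cov(random_psd(rng), random_psd(rng))
            assert np.linalg.eigvalsh(r).min() >= -1e-12


class TestOverlapIntegrals:
    def test_standard_pair_incoherent(self):
        k = GaussianKernel(1.0, np.zeros(3), np.eye(3))
        assert integrate_product_incoherent(k, k) == pytest.approx((4 * np.pi) ** -1.5)

    def test_translation_invariance(self, rng):
        a, b = random_kernel(rng), random_kernel(rng)
        shift = rng.standard_normal(3)
        a2 = GaussianKernel(a.weight, a.mean + shift, a.cov)
        b2 = GaussianKernel(b.weight, b.mean + shift, b.cov)
        assert integrate_product_incoherent(a, b) == pytest.approx(
            integrate_product_incoherent(a2, b2), rel=1e-12
        )

    def test_symmetric_and_positive(self, rng):
        a, b = random_kernel(rng), random_kernel(rng)
        ab = integrate_product_incoherent(a, b)
        assert ab > 0
        assert ab == pytest.approx(integrate_product_incoherent(b, a), rel=1e-14)

    def test_equals_product_weight(self, rng):
        a, b = random_kernel(rng), random_kernel(rng)
        assert integrate_product_incoherent(a, b) == pytest.approx(
            product(a, b).weight, rel=1e-14
        )

    def test_incoherent_quadrature_oracle(self, rng):
        a, b = random_kernel(rng), random_kernel(rng)
        center = 0.5 * (a.mean + b.mean)
        half = 9.0 + np.linalg.norm(a.mean - b.mean)
        val = tensor_grid_integral(
            lambda p: kernel_density(a, p) * kernel_density(b, p), center, half
        )
        assert integrate_product_incoherent(a, b) == pytest.approx(val, rel=1e-6)

    def test_coherent_quadrature_oracle(self, rng):
        """Coherent = (integral of the amplitude product)^2."""
        a, b = random_kernel(rng), random_kernel(rng)
        center = 0.5 * (a.mean + b.mean)
        half = 12.0 + np.linalg.norm(a.mean - b.mean)
        amp = tensor_grid_integral(
            lambda p: np.sqrt(kernel_density(a, p) * kernel_density(b, p)),
            center, half,
        )
        assert integrate_product_coherent(a, b) == pytest.approx(amp**2, rel=1e-6)

    def test_coherent_incoherent_scale_factor(self, rng):
        """For single kernels the ratio is the closed-form
        (8 pi)^(3/2) sqrt(det A det B / det(A+B)), independent of the means."""
        for _ in range(20):
            a, b = random_kernel(rng), random_kernel(rng)
            ratio = integrate_product_coherent(a, b) / integrate_product_incoherent(a, b)
            expected = (8 * np.pi) ** 1.5 * np.sqrt(
                np.linalg.det(a.cov) * np.linalg.det(b.cov)
                / np.linalg.det(a.cov + b.cov)
            )
            assert ratio == pytest.approx(expected, rel=1e-10)

    def test_identical_standard_coherent_is_unity(self):
        k = GaussianKernel(1.0, np.zeros(3), np.eye(3))
        # amplitude sqrt(phi) integrates its square to 1
        assert integrate_product_coherent(k, k) == pytest.approx(1.0, rel=1e-12)

    def test_mixture_interference(self, rng):
        """Two-kernel mixtures: amplitudes add before squaring, so the
        coherent result differs from the sum of pairwise incoherent terms
        and matches quadrature of |sum of amplitudes|^2."""
        ka = [random_kernel(rng, mean_scale=0.5) for _ in range(2)]
        kb = [random_kernel(rng, mean_scale=0.5) for _ in range(2)]
        a, b = GaussianMixture(ka), GaussianMixture(kb)
        coh = integrate_product_coherent(a, b)
        inc = integrate_product_incoherent(a, b)
        assert coh != pytest.approx(inc, rel=1e-3)
        amp = sum(coherent_amplitude_overlap(x, y) for x in ka for y in kb)
        amp_quad = tensor_grid_integral(
            lambda p: (np.sqrt(kernel_density(ka[0], p)) + np.sqrt(kernel_density(ka[1], p)))
            * (np.sqrt(kernel_density(kb[0], p)) + np.sqrt(kernel_density(kb[1], p))),
            np.zeros(3), 14.0, n=120,
        )
        assert amp == pytest.approx(amp_quad, rel=1e-5)
        assert coh == pytest.approx(amp_quad**2, rel=1e-4)

    def test_mixture_incoherent_distributes(self, rng):
        ka = [random_kernel(rng) for _ in range(2)]
        kb = [random_kernel(rng) for _ in range(3)]
        total = integrate_product_incoherent(GaussianMixture(ka), GaussianMixture(kb))
        pairwise = sum(integrate_product_incoherent(x, y) for x in ka for y in kb)
        assert total == pytest.approx(pairwise, rel=1e-12)


class TestProject1d:
    def test_isotropic(self, rng):
        k = GaussianKernel(1.5, rng.standard_normal(3), 2.5 * np.eye(3))
        w = rng.standard_normal(3)
        w /= np.linalg.norm(w)
        mean, var, weight = project_1d(k, w)
        assert var == pytest.approx(2.5)
        assert weight == pytest.approx(1.5)
        assert mean == pytest.approx(float(w @ k.mean))

    def test_eigenvector_projection(self, rng):
        cov = random_psd(rng)
        lam, vec = np.linalg.eigh(cov)
        k = GaussianKernel(1.0, np.zeros(3), cov)
        for i in range(3):
            _, var, _ = project_1d(k, vec[:, i])
            assert var == pytest.approx(lam[i], rel=1e-10)

    def test_sampling_oracle(self, rng):
        k = random_kernel(rng)
        w = rng.standard_normal(3)
        w /= np.linalg.norm(w)
        mean, var, _ = project_1d(k, w)
        samples = rng.multivariate_normal(k.mean, k.cov, size=1_000_000) @ w
        assert samples.mean() == pytest.approx(mean, abs=3.5e-3 * np.sqrt(var))
        assert samples.var() == pytest.approx(var, rel=1e-2)

    def test_rejects_non_unit_direction(self, rng):
        k = random_kernel(rng)
        with pytest.raises(ValueError):
            project_1d(k, np.array([1.0, 1.0, 0.0]))
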