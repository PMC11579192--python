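"""Tests of the quadratic basis, SSIM map, and (weighted) bias fitting."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from esfcm import (
    Volume,
    apply_bias_correction,
    build_basis,
    fit_bias_ols,
    fit_bias_wls,
    gradient_volume,
    mean_ssim_cost,
    predict_image,
    ssim_map,
    weights_from_ssim,
)


def monomial_row(x, y, z):
    return [1, x, y, z, x * x, y * y, z * z, x * y, x * z, y * z]


class TestBasis:
    def test_center_and_corner_rows(self):
        basis = build_basis((3, 3, 3), np.ones((3, 3, 3), bool))
        assert basis.A.shape == (27, 10)
        assert np.allclose(basis.A[13], [1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        assert np.allclose(basis.A[0], [1, -1, -1, -1, 1, 1, 1, 1, 1, 1])

    def test_matches_brute_force_on_random_mask(self, rng):
        mask = np.zeros((8, 8, 8), bool)
        idx = rng.choice(512, size=50, replace=False)
        mask.flat[idx] = True
        basis = build_basis((8, 8, 8), mask)
        rows = []
        for x, y, z in np.argwhere(mask):
            cx, cy, cz = (2 * v / 7 - 1 for v in (x, y, z))
            rows.append(monomial_row(cx, cy, cz))
        assert np.allclose(basis.A, rows)

    def test_too_small_mask_errors(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, :3] = True
        with pytest.raises(ValueError, match="at least 10"):
            build_basis((4, 4, 4), mask)

    def test_full_column_rank(self, rng):
        mask = rng.uniform(size=(6, 6, 6)) > 0.5
        basis = build_basis((6, 6, 6), mask)
        assert np.linalg.matrix_rank(basis.A) == 10


class TestPredictImage:
    def test_hard_and_convex_combinations(self):
        mu = np.array([[1.0, 0.5], [0.0, 0.5]])
        L = predict_image(np.array([120.0, 0.0]), mu)
        assert L[0] == pytest.approx(120.0)
        mu2 = np.array([[0.5], [0.5]])
        assert predict_image(np.array([0.0, 100.0]), mu2)[0] == pytest.approx(50.0)

    def test_matches_brute_force(self, rng):
        V = rng.uniform(0, 200, 3)
        mu = rng.dirichlet(np.ones(3), size=30).T
        L = predict_image(V, mu)
        for j in range(30):
            assert L[j] == pytest.approx(sum(V[i] * mu[i, j] for i in range(3)))


class TestGradient:
    def test_constant_volume_zero(self):
        vol = Volume(data=np.full((5, 5, 5), 9.0))
        assert np.allclose(gradient_volume(vol), 0.0)

    def test_linear_field_exact(self):
        x = np.arange(6, dtype=float)
        data = np.broadcast_to(2 * x[:, None, None], (6, 6, 6)).copy()
        assert np.allclose(gradient_volume(Volume(data=data)), 2.0)

    def test_spacing_aware(self):
        x = np.arange(6, dtype=float)
        data = np.broadcast_to(2 * x[:, None, None], (6, 6, 6)).copy()
        g = gradient_volume(Volume(data=data, spacing=(2.0, 1.0, 1.0)))
        assert np.allclose(g, 1.0)

    def test_matches_brute_force_differences(self, random_volume):
        g = gradient_volume(random_volume)
        d = random_volume.data
        # interior voxel, central differences along each axis
        i, j, k = 3, 2, 4
        gx = (d[i + 1, j, k] - d[i - 1, j, k]) / 2
        gy = (d[i, j + 1, k] - d[i, j - 1, k]) / 2
        gz = (d[i, j, k + 1] - d[i, j, k - 1]) / 2
        assert g[i, j, k] == pytest.approx(np.sqrt(gx**2 + gy**2 + gz**2))
        # boundary voxel, one-sided along the first axis
        gx0 = d[1, j, k] - d[0, j, k]
        gy0 = (d[0, j + 1, k] - d[0, j - 1, k]) / 2
        gz0 = (d[0, j, k + 1] - d[0, j, k - 1]) / 2
        assert g[0, j, k] == pytest.approx(np.sqrt(gx0**2 + gy0**2 + gz0**2))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        a = rng.uniform(0, 1, size=(10, 10, 10))
        assert np.allclose(ssim_map(a, a).values, 1.0)

    def test_symmetry(self, rng):
        a = rng.uniform(0, 1, size=(9, 9, 9))
        b = rng.uniform(0, 1, size=(9, 9, 9))
        assert np.allclose(ssim_map(a, b).values, ssim_map(b, a).values)

    def test_bounded(self, rng):
        a = rng.normal(size=(9, 9, 9))
        b = -a + rng.normal(scale=0.1, size=(9, 9, 9))
        v = ssim_map(a, b).values
        assert np.all(v >= -1.0) and np.all(v <= 1.0)

    def test_zero_variance_closed_form(self):
        a = np.ones((9, 9, 9))
        b = np.full((9, 9, 9), 3.0)
        expected = (2 * 1 * 3 + 0.0001) / (1 + 9 + 0.0001)  # second factor = c2/c2
        assert np.allclose(ssim_map(a, b).values, expected, atol=1e-12)

    def test_degenerate_zeros_stabilized(self):
        z = np.zeros((8, 8, 8))
        assert np.allclose(ssim_map(z, z).values, 1.0)

    def test_matches_skimage_in_interior(self, rng):
        a = rng.uniform(0, 1, size=(12, 12, 12))
        b = rng.uniform(0, 1, size=(12, 12, 12))
        ours = ssim_map(a, b, window=7).values
        _, ref = structural_similarity(
            a, b, win_size=7, data_range=1.0, gaussian_weights=False,
            use_sample_covariance=False, full=True,
        )
        pad = 3
        core = (slice(pad, -pad),) * 3
        assert np.allclose(ours[core], ref[core], atol=1e-10)


class TestBiasFits:
    @pytest.fixture
    def basis(self, rng):
        return build_basis((8, 8, 8), np.ones((8, 8, 8), bool))

    def test_exact_polynomial_recovered(self, basis, rng):
        beta_star = rng.standard_normal(10)
        L = rng.uniform(0, 10, 512)
        I = L + basis.A @ beta_star
        beta = fit_bias_ols(basis, I, L)
        assert np.max(np.abs(beta - beta_star)) < 1e-8

    def test_zero_residual_gives_zero(self, basis, rng):
        L = rng.uniform(0, 10, 512)
        assert np.max(np.abs(fit_bias_ols(basis, L, L))) < 1e-10

    def test_ols_matches_normal_equations(self, basis, rng):
        I = rng.uniform(0, 100, 512)
        L = rng.uniform(0, 100, 512)
        beta = fit_bias_ols(basis, I, L)
        A = basis.A
        expected = np.linalg.solve(A.T @ A, A.T @ (I - L))
        assert np.allclose(beta, expected, atol=1e-6)

    def test_residual_orthogonality(self, basis, rng):
        I = rng.uniform(0, 100, 512)
        L = rng.uniform(0, 100, 512)
        beta = fit_bias_ols(basis, I, L)
        r = (I - L) - basis.A @ beta
        scale = np.abs(I - L).sum()
        assert np.max(np.abs(basis.A.T @ r)) < 1e-6 * scale

    def test_wls_uniform_weights_equals_ols(self, basis, rng):
        I = rng.uniform(0, 100, 512)
        L = rng.uniform(0, 100, 512)
        ols = fit_bias_ols(basis, I, L)
        wls = fit_bias_wls(basis, np.full(512, 0.37), I, L)
        assert np.allclose(wls, ols, atol=1e-10)

    def test_wls_matches_weighted_normal_equations(self, basis, rng):
        I = rng.uniform(0, 100, 512)
        L = rng.uniform(0, 100, 512)
        w = rng.uniform(0.01, 1.0, 512)
        beta = fit_bias_wls(basis, w, I, L)
        A, W = basis.A, np.diag(w)
        expected = np.linalg.solve(A.T @ W @ A, A.T @ W @ (I - L))
        assert np.allclose(beta, expected, atol=1e-6)

    def test_zero_weights_restrict_support(self, rng):
        mask = np.ones((8, 8, 8), bool)
        basis = build_basis((8, 8, 8), mask)
        region = np.zeros(512, bool)
        region[rng.choice(512, size=200, replace=False)] = True
        I = rng.uniform(0, 100, 512)
        L = rng.uniform(0, 100, 512)
        wls = fit_bias_wls(basis, region.astype(float), I, L)
        # OLS on the region alone
        sub = basis.A[region]
        expected = np.linalg.lstsq(sub, (I - L)[region], rcond=None)[0]
        assert np.allclose(wls, expected, atol=1e-8)

    def test_all_zero_weights_error(self, basis, rng):
        with pytest.raises(ValueError, match="all-zero"):
            fit_bias_wls(basis, np.zeros(512), rng.uniform(size=512),
                         rng.uniform(size=512))


class TestWeightsAndCorrection:
    @pytest.mark.parametrize("s,expected", [(1.0, 0.0), (-1.0, 1.0), (0.0, 0.5)])
    def test_neglected_transform(self, s, expected):
        from esfcm.bias_correction import SSIMMap
        w = weights_from_ssim(SSIMMap(values=np.full((3, 3, 3), s)))
        assert np.allclose(w, expected)

    def test_important_transform_is_opposite(self):
        from esfcm.bias_correction import SSIMMap
        smap = SSIMMap(values=np.linspace(-1, 1, 27).reshape(3, 3, 3))
        assert np.allclose(
            weights_from_ssim(smap, "neglected") + weights_from_ssim(smap, "important"),
            1.0,
        )

    def test_zero_coefficients_identity(self, rng):
        vol = Volume(data=rng.uniform(0, 10, (6, 6, 6)))
        basis = build_basis(vol.shape, vol.mask)
        fit = apply_bias_correction(vol, basis, np.zeros(10))
        assert np.array_equal(fit.filtered.data, vol.data)

    def test_planted_field_removed_exactly(self, rng):
        clean = rng.uniform(0, 10, (6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        basis = build_basis((6, 6, 6), mask)
        beta_star = rng.standard_normal(10)
        biased = clean.copy()
        biased[mask] += basis.A @ beta_star
        fit = apply_bias_correction(Volume(data=biased), basis, beta_star)
        assert np.allclose(fit.filtered.data, clean, atol=1e-12)

    def test_correction_outside_mask_untouched(self, rng):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        vol = Volume(data=rng.uniform(0, 10, (6, 6, 6)), mask=mask)
        basis = build_basis(vol.shape, mask)
        fit = apply_bias_correction(vol, basis, rng.standard_normal(10))
        assert np.array_equal(fit.filtered.data[~mask], vol.data[~mask])
        assert not np.allclose(fit.filtered.data[mask], vol.data[mask])

    def test_idempotent_on_polynomial_residual(self, rng):
        mask = np.ones((8, 8, 8), bool)
        basis = build_basis((8, 8, 8), mask)
        L = rng.uniform(0, 10, 512)
        beta_star = rng.standard_normal(10)
        I = L + basis.A @ beta_star
        fit = apply_bias_correction(Volume(data=I.reshape(8, 8, 8)), basis,
                                    fit_bias_ols(basis, I, L))
        second = fit_bias_ols(basis, fit.filtered.data[mask], L)
        assert np.max(np.abs(second)) < 1e-8


class TestMeanSSIMCost:
    def test_uniform_map(self):
        from esfcm.bias_correction import SSIMMap
        mask = np.ones((4, 4, 4), bool)
        assert mean_ssim_cost(SSIMMap(values=np.ones((4, 4, 4))), mask) == 1.0

    def test_masked_mean_matches_brute_force(self, rng):
        from esfcm.bias_correction import SSIMMap
        values = rng.uniform(-1, 1, (6, 6, 6))
        mask = rng.uniform(size=(6, 6, 6)) > 0.4
        cost = mean_ssim_cost(SSIMMap(values=values), mask)
        assert cost == pytest.approx(values[mask].sum() / mask.sum())

    def test_empty_mask_errors(self):
        from esfcm.bias_correction import SSIMMap
        with pytest.raises(ValueError, match="empty"):
            mean_ssim_cost(SSIMMap(values=np.ones((3, 3, 3))),
                           np.zeros((3, 3, 3), bool))
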