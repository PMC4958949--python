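"""Variational reconstruction: energies, EL gradients, descent behaviour."""

import numpy as np
import pytest

from conftest import fd_gradient, naive_simulate
from dicrecon.forward import add_noise, simulate_dic
from dicrecon.kernels import Kernel, ShearSpec, make_gaussian_derivative
from dicrecon.variational import (
    FeineigleParams,
    VariationalParams,
    data_energy,
    el_data_term,
    el_tv_term,
    energy,
    estimate_background_mask,
    reconstruct_feineigle,
    reconstruct_proposed,
    tv_energy,
)

SCHEMES = ("bilinear", "piecewise_constant", "kernel_form")


class TestEnergy:
    def test_exact_fit_has_zero_energy(self, square_phantom, dirac_diag):
        g = simulate_dic(square_phantom, dirac_diag)
        total, data, tv = energy(square_phantom, g, dirac_diag, lambda_tv=0.0)
        assert total == pytest.approx(0.0, abs=1e-18)

    def test_constant_image_has_zero_tv(self, rng, dirac_diag):
        g = rng.normal(size=(16, 16))
        _, _, tv = energy(np.full((16, 16), 2.5), g, dirac_diag, lambda_tv=1.0)
        assert tv == pytest.approx(0.0, abs=1e-12)

    def test_data_term_matches_bruteforce_residual(self, rng, gauss_x):
        i = rng.normal(size=(16, 16))
        g = rng.normal(size=(16, 16))
        _, data, _ = energy(i, g, gauss_x, lambda_tv=0.3)
        expected = float(np.sum((naive_simulate(i, gauss_x.values) - g) ** 2))
        assert data == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self, dirac_x):
        with pytest.raises(ValueError, match="mismatch"):
            energy(np.zeros((8, 8)), np.zeros((9, 9)), dirac_x, 0.1)


class TestEulerLagrangeGradients:
    """The module's master oracle: each scheme's descent direction is the
    exact negative gradient of that scheme's discrete energy."""

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_data_term_matches_finite_differences(self, rng, gauss_x, scheme):
        i = rng.normal(size=(8, 8))
        g = rng.normal(size=(8, 8))
        analytic = -el_data_term(i, g, gauss_x, scheme)
        numeric = fd_gradient(lambda x: data_energy(x, g, gauss_x, scheme), i)
        rel = np.abs(analytic - numeric).max() / np.abs(numeric).max()
        assert rel < 1e-4

    def test_tv_term_matches_finite_differences(self, rng):
        i = rng.normal(size=(8, 8))
        eps = 1e-2
        analytic = -el_tv_term(i, eps)
        numeric = fd_gradient(lambda x: tv_energy(x, eps), i)
        rel = np.abs(analytic - numeric).max() / np.abs(numeric).max()
        assert rel < 1e-4

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_exact_solution_is_stationary(self, square_phantom, dirac_x, scheme):
        # for the grid-aligned Dirac-difference kernel all three schemes
        # represent the forward model exactly, so the true phantom is a
        # stationary point of the data energy
        g = simulate_dic(square_phantom, dirac_x)
        grad = el_data_term(square_phantom, g, dirac_x, scheme)
        assert np.abs(grad[3:-3, 3:-3]).max() < 1e-8

    def test_exact_solution_is_stationary_kernel_form_diagonal(
        self, square_phantom, dirac_diag
    ):
        # the kernel-side scheme uses the true PSF, so stationarity holds
        # even for the sub-pixel diagonal kernel
        g = simulate_dic(square_phantom, dirac_diag)
        grad = el_data_term(square_phantom, g, dirac_diag, "kernel_form")
        assert np.abs(grad[3:-3, 3:-3]).max() < 1e-8

    def test_schemes_agree_on_smooth_images(self, rng, gauss_x):
        from scipy.ndimage import gaussian_filter

        i = gaussian_filter(rng.normal(size=(32, 32)), 4.0)
        g = np.zeros_like(i)
        fields = [
            el_data_term(i, g, gauss_x, s)[4:-4, 4:-4].ravel() for s in SCHEMES
        ]
        for a in range(3):
            for b in range(a + 1, 3):
                assert np.corrcoef(fields[a], fields[b])[0, 1] > 0.95

    def test_constant_image_has_zero_tv_descent(self):
        assert np.allclose(el_tv_term(np.full((12, 12), 3.0), 1e-3), 0.0)

    def test_tv_preserves_large_edges_relative_to_laplacian(self):
        from scipy.ndimage import laplace

        eps = 1e-3
        img = np.zeros((32, 32))
        img[:, 16:] = 100.0  # amplitude >> tv_eps
        tv_resp = el_tv_term(img, eps)
        lap_resp = laplace(img, mode="mirror")
        edge = (slice(None), slice(15, 17))
        assert np.abs(tv_resp[edge]).max() * 10 <= np.abs(lap_resp[edge]).max()

    def test_piecewise_constant_requires_shear_symmetric_kernel(self, rng):
        v = rng.normal(size=(5, 5))
        v -= v.mean()
        k = Kernel(values=v, shear=ShearSpec(1, 0), kind="custom")
        with pytest.raises(ValueError, match="axis symmetry"):
            el_data_term(np.zeros((8, 8)), np.zeros((8, 8)), k, "piecewise_constant")


class TestReconstructProposed:
    def test_recovers_square_phantom(self, square_phantom, dirac_diag):
        from dicrecon.evaluate import pearson

        g = simulate_dic(square_phantom, dirac_diag)
        recon, _ = reconstruct_proposed(g, dirac_diag)
        assert pearson(recon, square_phantom) > 0.95

    def test_zero_image_yields_flat_reconstruction(self, dirac_diag):
        recon, _ = reconstruct_proposed(
            np.zeros((16, 16)), dirac_diag,
            VariationalParams(lambda_tv=0.5, max_iter=50),
        )
        assert np.ptp(recon) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_energy_trace_monotone_nonincreasing(self, square_phantom, dirac_diag, scheme):
        g = simulate_dic(square_phantom, dirac_diag)
        _, trace = reconstruct_proposed(
            g, dirac_diag, VariationalParams(max_iter=200, scheme=scheme)
        )
        assert np.all(np.diff(trace.total) <= 1e-10)

    def test_kernel_form_and_bilinear_reconstructions_agree(self, square_phantom, gauss_x):
        from dicrecon.evaluate import pearson

        g = simulate_dic(square_phantom, gauss_x)
        ra, _ = reconstruct_proposed(
            g, gauss_x, VariationalParams(max_iter=800, scheme="kernel_form"))
        rb, _ = reconstruct_proposed(
            g, gauss_x, VariationalParams(max_iter=800, scheme="bilinear"))
        assert pearson(ra, rb) > 0.98

    def test_output_is_nonnegative(self, square_phantom, dirac_diag):
        g = simulate_dic(square_phantom, dirac_diag)
        recon, _ = reconstruct_proposed(
            g, dirac_diag, VariationalParams(max_iter=100))
        assert recon.min() >= 0.0


class TestBackgroundMask:
    def test_flat_image_is_all_background(self):
        assert np.all(estimate_background_mask(np.full((16, 16), 0.5)) == 1.0)

    def test_mask_is_binary(self, square_phantom, dirac_diag):
        m = estimate_background_mask(simulate_dic(square_phantom, dirac_diag))
        assert set(np.unique(m)) <= {0.0, 1.0}

    def test_object_edges_are_foreground(self, square_phantom, dirac_diag):
        g = simulate_dic(square_phantom, dirac_diag)
        m = estimate_background_mask(g)
        # the bipolar edge response of the square must be masked out
        edges = np.abs(g) > 0.5 * np.abs(g).max()
        assert (m[edges] == 0.0).mean() > 0.9


class TestFeineigle:
    def test_zero_image_is_fixed_point(self):
        g = np.zeros((16, 16))
        p = FeineigleParams(mask=np.ones((16, 16)), background_value=0.0, max_iter=30)
        recon, trace = reconstruct_feineigle(g, p, shear=ShearSpec(1, 0))
        assert np.allclose(recon, 0.0, atol=1e-15)
        assert trace.total[0] == pytest.approx(0.0, abs=1e-18)

    def test_energy_trace_monotone(self, square_phantom, dirac_diag):
        g = simulate_dic(square_phantom, dirac_diag)
        _, trace = reconstruct_feineigle(
            g, FeineigleParams(max_iter=200), shear=dirac_diag.shear
        )
        assert np.all(np.diff(trace.total) <= 1e-10)

    def test_perpendicular_penalty_reduces_streak_variance(self, square_phantom, dirac_diag):
        from dicrecon._linops import grad_x, grad_y

        g = add_noise(simulate_dic(square_phantom, dirac_diag), 20.0, seed=2)
        mask = estimate_background_mask(g)
        n = dirac_diag.shear.normal

        def perp_var(recon):
            d_n = n.u * grad_x(recon) + n.v * grad_y(recon)
            return float(np.var(d_n[mask == 1.0]))

        with_pen, _ = reconstruct_feineigle(
            g, FeineigleParams(lambda1=0.5, mask=mask, max_iter=400),
            shear=dirac_diag.shear)
        without, _ = reconstruct_feineigle(
            g, FeineigleParams(lambda1=0.0, mask=mask, max_iter=400),
            shear=dirac_diag.shear)
        assert perp_var(with_pen) < perp_var(without)

    def test_mismatched_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            reconstruct_feineigle(
                np.zeros((8, 8)), FeineigleParams(mask=np.ones((4, 4)))
            )
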