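"""Kernel construction: symmetries, zero-sum invariant, integral form, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicrecon.kernels import (
    Kernel,
    ShearSpec,
    load_kernel,
    make_dirac_difference,
    make_gaussian_derivative,
    make_integral_kernel,
    shear_difference,
    write_kernel,
)


class TestShearSpec:
    def test_normalizes_to_unit_length(self):
        s = ShearSpec(3.0, 4.0)
        assert s.u**2 + s.v**2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ShearSpec(0.0, 0.0)

    def test_normal_is_perpendicular(self):
        s = ShearSpec.from_degrees(30.0)
        n = s.normal
        assert s.u * n.u + s.v * n.v == pytest.approx(0.0, abs=1e-12)


class TestGaussianDerivative:
    def test_odd_even_symmetry_along_x_shear(self):
        k = make_gaussian_derivative(0.5, ShearSpec(1, 0), half_width=2).values
        assert np.allclose(k, -k[:, ::-1], atol=1e-15)  # odd in x
        assert np.allclose(k, k[::-1, :], atol=1e-15)  # even in y

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        sigma=st.floats(0.3, 2.0),
        angle=st.floats(0.0, 360.0),
    )
    def test_sums_to_zero_for_any_sigma_and_shear(self, sigma, angle):
        k = make_gaussian_derivative(sigma, ShearSpec.from_degrees(angle))
        assert abs(k.values.sum()) < 1e-12

    def test_matches_closed_form_directional_derivative(self):
        """Entrywise match to a numerical directional derivative of the
        closed-form Gaussian (oriented so correlation differentiates the
        image along +shear, i.e. the sampled function is -d/du Gauss)."""
        sigma, hw = 0.5, 2
        shear = ShearSpec(1, 0)
        k = make_gaussian_derivative(sigma, shear, half_width=hw)

        def gauss(x, y):
            return np.exp(-(x**2 + y**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)

        h = 1e-6
        c = np.arange(-hw, hw + 1, dtype=float)
        xx, yy = np.meshgrid(c, c)
        oracle = -(gauss(xx + h * shear.u, yy + h * shear.v)
                   - gauss(xx - h * shear.u, yy - h * shear.v)) / (2 * h)
        assert np.allclose(k.values, oracle, atol=1e-8)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            make_gaussian_derivative(-1.0, ShearSpec(1, 0))

    def test_window_smaller_than_three_sigma_rejected(self):
        with pytest.raises(ValueError):
            make_gaussian_derivative(2.0, ShearSpec(1, 0), half_width=3)


class TestDiracDifference:
    def test_integer_offset_places_exact_unit_impulses(self):
        k = make_dirac_difference(ShearSpec(1, 0), offset=1.0)
        v = k.values
        assert v.shape == (3, 3)
        assert v[1, 2] == 1.0 and v[1, 0] == -1.0
        assert np.count_nonzero(v) == 2

    def test_kills_constant_images(self, dirac_diag):
        from dicrecon.forward import simulate_dic

        out = simulate_dic(np.full((16, 16), 3.7), dirac_diag)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_close_to_gaussian_derivative_sigma_half(self):
        shear = ShearSpec(1, 0)
        dirac = make_dirac_difference(shear, offset=1.0)
        gauss = make_gaussian_derivative(0.5, shear)
        d = gauss.half_width
        emb = np.zeros_like(gauss.values)
        lo = d - dirac.half_width
        emb[lo : lo + 3, lo : lo + 3] = dirac.values
        r = np.corrcoef(emb.ravel(), gauss.values.ravel())[0, 1]
        assert r > 0.9

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(0.0, 360.0), offset=st.floats(0.5, 2.5))
    def test_subpixel_deposits_sum_to_zero(self, angle, offset):
        k = make_dirac_difference(ShearSpec.from_degrees(angle), offset=offset)
        assert abs(k.values.sum()) < 1e-12

    def test_offset_beyond_window_rejected(self):
        with pytest.raises(ValueError):
            make_dirac_difference(ShearSpec(1, 0), offset=3.0, half_width=2)


class TestIntegralKernel:
    @pytest.mark.parametrize("angle", [0.0, 45.0, 90.0, 180.0])
    def test_shear_difference_reproduces_psf(self, angle):
        shear = ShearSpec.from_degrees(angle)
        for psf in (
            make_dirac_difference(shear, offset=1.0),
            make_gaussian_derivative(0.5, shear),
        ):
            k0 = make_integral_kernel(psf)
            keff = shear_difference(k0)
            da, db = keff.half_width, psf.half_width
            m = max(da, db)
            a = np.zeros((2 * m + 1, 2 * m + 1))
            a[m - da : m + da + 1, m - da : m + da + 1] = keff.values
            b = np.zeros_like(a)
            b[m - db : m + db + 1, m - db : m + db + 1] = psf.values
            assert np.abs(a - b).max() < 1e-12

    def test_random_zero_sum_kernels_recovered_on_window_interior(self, rng):
        shear = ShearSpec(1, 0)
        for d in (1, 2, 3, 4):
            v = rng.normal(size=(2 * d + 1, 2 * d + 1))
            v -= v.mean()
            psf = Kernel(values=v, shear=shear, kind="custom")
            keff = shear_difference(make_integral_kernel(psf))
            m = keff.half_width
            center = keff.values[m - d : m + d + 1, m - d : m + d + 1]
            assert np.abs(center - v).max() < 1e-12

    def test_boundary_first_differences_vanish(self, dirac_diag, gauss_x):
        for psf in (dirac_diag, gauss_x):
            v = make_integral_kernel(psf).values
            for edge in (v[0], v[-1], v[:, 0], v[:, -1]):
                assert np.abs(np.diff(edge)).max() < 1e-12
            # differences crossing the boundary ring vanish too
            assert np.abs(v[0] - v[1]).max() < 1e-12
            assert np.abs(v[:, 0] - v[:, 1]).max() < 1e-12

    def test_zero_psf_gives_zero_kernel(self):
        psf = Kernel(values=np.zeros((3, 3)), shear=ShearSpec(1, 0))
        assert np.all(make_integral_kernel(psf).values == 0.0)

    def test_non_dc_free_psf_rejected(self):
        psf = Kernel(values=np.ones((3, 3)), shear=ShearSpec(1, 0))
        with pytest.raises(ValueError, match="derivative-type"):
            make_integral_kernel(psf)


class TestKernelIO:
    def test_csv_round_trip(self, tmp_path, dirac_x):
        p = tmp_path / "k.csv"
        np.savetxt(p, dirac_x.values, delimiter=",")
        k = load_kernel(p)
        assert k.half_width == 1
        assert np.array_equal(k.values, dirac_x.values)

    def test_even_side_rejected(self, tmp_path):
        p = tmp_path / "k.txt"
        np.savetxt(p, np.ones((4, 4)))
        with pytest.raises(ValueError, match="odd"):
            load_kernel(p)

    def test_float_tiff_round_trip_identity(self, tmp_path, gauss_x):
        p = tmp_path / "k.tif"
        k32 = Kernel(values=gauss_x.values.astype(np.float32).astype(float),
                     shear=gauss_x.shear)
        write_kernel(k32, p)
        back = load_kernel(p)
        assert np.array_equal(back.values, k32.values)

    def test_text_round_trip(self, tmp_path, gauss_x):
        p = tmp_path / "k.txt"
        write_kernel(gauss_x, p)
        back = load_kernel(p)
        assert np.allclose(back.values, gauss_x.values, rtol=0, atol=1e-16)
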