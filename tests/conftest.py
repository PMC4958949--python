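"""Shared fixtures: small kernels, phantoms, and brute-force oracles."""

import numpy as np
import pytest

from dicrecon.kernels import (
    Kernel,
    ShearSpec,
    make_dirac_difference,
    make_gaussian_derivative,
)


def naive_simulate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Brute-force forward model: per-pixel double sum with mirror padding."""
    d = kernel.shape[0] // 2
    padded = np.pad(img, d, mode="reflect")
    out = np.zeros_like(img, dtype=float)
    ny, nx = img.shape
    for y in range(ny):
        for x in range(nx):
            acc = 0.0
            for e in range(2 * d + 1):
                for xi in range(2 * d + 1):
                    acc += kernel[e, xi] * padded[y + e, x + xi]
            out[y, x] = acc
    return out


def fd_gradient(energy_fn, img: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of a scalar energy."""
    grad = np.zeros_like(img)
    for idx in np.ndindex(img.shape):
        up = img.copy()
        up[idx] += h
        dn = img.copy()
        dn[idx] -= h
        grad[idx] = (energy_fn(up) - energy_fn(dn)) / (2 * h)
    return grad


def dog_kernel(sigma_narrow=0.7, sigma_wide=3.0, half_width=9, shear=None) -> Kernel:
    """Zero-sum difference-of-Gaussians kernel with nonvanishing non-DC
    spectrum (unlike directional-derivative kernels, which are zero on the
    whole frequency line perpendicular to the shear)."""
    if shear is None:
        shear = ShearSpec.from_degrees(45.0)
    c = np.arange(-half_width, half_width + 1, dtype=float)
    xx, yy = np.meshgrid(c, c)
    r2 = xx**2 + yy**2
    narrow = np.exp(-r2 / (2 * sigma_narrow**2))
    narrow /= narrow.sum()
    wide = np.exp(-r2 / (2 * sigma_wide**2))
    wide /= wide.sum()
    return Kernel(values=narrow - wide, shear=shear, kind="custom")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def shear_x():
    return ShearSpec(1.0, 0.0)


@pytest.fixture(scope="session")
def shear_diag():
    return ShearSpec.from_degrees(45.0)


@pytest.fixture(scope="session")
def dirac_x(shear_x):
    return make_dirac_difference(shear_x, offset=1.0)


@pytest.fixture(scope="session")
def dirac_diag(shear_diag):
    return make_dirac_difference(shear_diag, offset=1.0)


@pytest.fixture(scope="session")
def gauss_x(shear_x):
    return make_gaussian_derivative(0.5, shear_x)


@pytest.fixture(scope="session")
def square_phantom():
    img = np.zeros((48, 48))
    img[14:34, 14:34] = 1.0
    return img
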