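"""Fourier-domain DIC reconstruction baselines: Hilbert, Wiener, Yin.

All three operate on the periodic spectrum of the image.  The kernel is
embedded at the image size with its centre at the (0, 0) frequency-origin
pixel, so its transfer function ``H = conj(F K)`` matches the spatial
correlation model exactly for content away from the image borders.

* The Hilbert transform multiplies the spectrum by ``-i * sgn(s)`` where
  ``s`` is the signed projection of the frequency vector onto the shear
  direction (the signum axis is therefore perpendicular to the shear in the
  image plane).  It is a pure phase filter — an isometry on zero-mean
  images — that converts the bipolar edge doublets of DIC into single-signed
  ridges without deconvolving the PSF.
* Wiener filtering divides by the kernel spectrum, regularized by a constant
  noise-to-signal ratio:  ``I = F^-1[ conj(H) G / (|H|^2 + ns_ratio) ]``.
* The Yin inverse filter replaces the constant by a smoothness plus sparsity
  regularizer: ``|H|^2 + smooth * |A|^2 + sparse`` with ``A`` the spectrum of
  the 5-point discrete Laplacian.  (The original multi-shear formulation is
  reduced to the single-image case: the shear of a microscope cannot be
  changed between exposures.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import Kernel, ShearSpec

__all__ = [
    "WienerParams",
    "YinParams",
    "hilbert_reconstruct",
    "wiener_reconstruct",
    "yin_reconstruct",
]

LAPLACIAN_5PT = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class WienerParams:
    ns_ratio: float = 1e-3  # noise-to-signal regularizer N/S

    def __post_init__(self) -> None:
        if self.ns_ratio < 0:
            raise ValueError("ns_ratio must be >= 0")


@dataclass
class YinParams:
    smooth_weight: float = 1e-3
    sparse_weight: float = 1e-4

    def __post_init__(self) -> None:
        if self.smooth_weight < 0 or self.sparse_weight < 0:
            raise ValueError("weights must be >= 0")


def _embed_transfer(values: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Transfer function of centred cross-correlation with ``values``."""
    ny, nx = shape
    ky, kx = values.shape
    if ky > ny or kx > nx:
        raise ValueError("kernel larger than image")
    emb = np.zeros(shape)
    emb[:ky, :kx] = values
    emb = np.roll(emb, shift=(-(ky // 2), -(kx // 2)), axis=(0, 1))
    # correlation convention: g = I (star) K  =>  G = conj(F K) * F I
    return np.conj(np.fft.fft2(emb))


def hilbert_reconstruct(
    g: np.ndarray, shear: ShearSpec, invert: bool = False
) -> np.ndarray:
    """2D Hilbert transform of the DIC image along the shear direction."""
    g = np.asarray(g, dtype=float)
    ny, nx = g.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    s = shear.u * fx + shear.v * fy
    mult = -1j * np.sign(s)  # sign(0) = 0: the DC term is dropped
    if invert:
        mult = -mult
    return np.real(np.fft.ifft2(mult * np.fft.fft2(g)))


def wiener_reconstruct(
    g: np.ndarray, k: Kernel, p: WienerParams | None = None
) -> np.ndarray:
    """Wiener deconvolution of the DIC image by the kernel spectrum."""
    if p is None:
        p = WienerParams()
    g = np.asarray(g, dtype=float)
    h = _embed_transfer(k.values, g.shape)
    power = np.abs(h) ** 2
    if p.ns_ratio == 0 and np.any(power < 1e-300):
        raise ValueError(
            "ns_ratio=0 with zeros in the kernel spectrum: unregularized division"
        )
    rec = np.fft.ifft2(np.conj(h) * np.fft.fft2(g) / (power + p.ns_ratio))
    return np.real(rec)


def yin_reconstruct(
    g: np.ndarray, k: Kernel, p: YinParams | None = None
) -> np.ndarray:
    """Inverse filtering with Laplacian-smoothness and sparsity regularizers."""
    if p is None:
        p = YinParams()
    g = np.asarray(g, dtype=float)
    h = _embed_transfer(k.values, g.shape)
    power = np.abs(h) ** 2
    a = _embed_transfer(LAPLACIAN_5PT, g.shape)
    denom = power + p.smooth_weight * np.abs(a) ** 2 + p.sparse_weight
    if np.any(denom < 1e-300):
        raise ValueError("all regularizer weights zero with spectral zeros in K")
    rec = np.fft.ifft2(np.conj(h) * np.fft.fft2(g) / denom)
    return np.real(rec)
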