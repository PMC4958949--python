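"""PSF / kernel construction for the linear DIC image-formation model.

The linear model treats a DIC micrograph as the local correlation of the
optical-path-length map with a derivative-type (zero-sum) kernel oriented
along the instrument's shear axis.  This module builds the two standard
kernels (first derivative of a Gaussian, difference of two Dirac deltas),
their integral form ``K0`` used by the kernel-side variational scheme, and
reads/writes kernels as text matrices or float TIFF.

Conventions (shared by every module):

* arrays are indexed ``(row, col) = (y, x)``; x increases rightward, y
  downward; the window origin is the centre pixel;
* kernels are oriented so that *cross-correlation* with an image computes the
  image's directional derivative along ``+shear`` (e.g. the Dirac-difference
  kernel has +1 at ``+offset*u`` and -1 at ``-offset*u``, which yields
  ``I(p + u) - I(p - u)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ShearSpec",
    "Kernel",
    "make_gaussian_derivative",
    "make_dirac_difference",
    "make_integral_kernel",
    "load_kernel",
    "write_kernel",
]


@dataclass(frozen=True)
class ShearSpec:
    """Unit shear vector u = [u v]^T with u^2 + v^2 = 1."""

    u: float
    v: float

    def __post_init__(self) -> None:
        n = math.hypot(self.u, self.v)
        if n == 0:
            raise ValueError("shear vector must be nonzero")
        if abs(n - 1.0) > 1e-12:
            object.__setattr__(self, "u", self.u / n)
            object.__setattr__(self, "v", self.v / n)

    @classmethod
    def from_degrees(cls, angle_deg: float) -> "ShearSpec":
        a = math.radians(angle_deg)
        return cls(math.cos(a), math.sin(a))

    @property
    def normal(self) -> "ShearSpec":
        """Unit vector perpendicular to the shear."""
        return ShearSpec(-self.v, self.u)


DEFAULT_SHEAR = ShearSpec.from_degrees(45.0)


@dataclass(frozen=True)
class Kernel:
    """A finite kernel on the window W = [-d, d] x [-d, d]."""

    values: np.ndarray
    shear: ShearSpec
    kind: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("kernel values must be a 2D array")
        if v.shape[0] % 2 == 0 or v.shape[1] % 2 == 0:
            raise ValueError("kernel side must be odd")
        object.__setattr__(self, "values", v)

    @property
    def half_width(self) -> int:
        return self.values.shape[0] // 2

    @property
    def is_derivative_type(self) -> bool:
        return abs(float(self.values.sum())) < 1e-12


def _window_grid(half_width: int) -> tuple[np.ndarray, np.ndarray]:
    c = np.arange(-half_width, half_width + 1, dtype=float)
    return np.meshgrid(c, c)  # xx (cols), yy (rows)


def make_gaussian_derivative(
    sigma: float, shear: ShearSpec = DEFAULT_SHEAR, half_width: int | None = None
) -> Kernel:
    """Directional first derivative of an isotropic Gaussian along the shear.

    ``half_width`` defaults to ``ceil(3*sigma)`` (and must be at least that,
    so the window captures the kernel's support and the zero-sum invariant
    holds).  The sign follows the package convention: correlation with the
    returned kernel estimates the image derivative along ``+shear``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    min_hw = max(1, math.ceil(3 * sigma))
    if half_width is None:
        half_width = min_hw
    if half_width < min_hw:
        raise ValueError(f"half_width must be >= ceil(3*sigma) = {min_hw}")
    xx, yy = _window_grid(half_width)
    proj = shear.u * xx + shear.v * yy
    gauss = np.exp(-(xx**2 + yy**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    values = proj / sigma**2 * gauss
    return Kernel(values=values, shear=shear, kind="gaussian_derivative")


def make_dirac_difference(
    shear: ShearSpec = DEFAULT_SHEAR, offset: float = 1.0, half_width: int | None = None
) -> Kernel:
    """Difference of two Dirac deltas at ``+/- offset`` along the shear.

    Integer grid positions receive exact +/-1; sub-pixel positions are
    realized by bilinear interpolation over the four nearest grid cells, so
    the kernel still sums to zero exactly.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if half_width is None:
        half_width = max(1, math.ceil(offset * max(abs(shear.u), abs(shear.v), 1e-12)))
        half_width = max(half_width, math.ceil(offset))
    px, py = offset * shear.u, offset * shear.v
    if max(abs(px), abs(py)) > half_width + 1e-12:
        raise ValueError("offset larger than half_width")
    side = 2 * half_width + 1
    values = np.zeros((side, side))

    def _deposit(x: float, y: float, w: float) -> None:
        x0, y0 = math.floor(x), math.floor(y)
        fx, fy = x - x0, y - y0
        for iy, wy in ((y0, 1 - fy), (y0 + 1, fy)):
            for ix, wx in ((x0, 1 - fx), (x0 + 1, fx)):
                if wx * wy != 0.0:
                    values[iy + half_width, ix + half_width] += w * wx * wy

    _deposit(px, py, +1.0)
    _deposit(-px, -py, -1.0)
    return Kernel(values=values, shear=shear, kind="dirac_difference")


def _shear_step(shear: ShearSpec) -> tuple[int, int]:
    """Grid step (ex, ey) nearest to the shear direction (8-neighbour)."""
    m = max(abs(shear.u), abs(shear.v))
    ex = int(round(shear.u / m)) if m > 0 else 1
    ey = int(round(shear.v / m)) if m > 0 else 0
    if ex == 0 and ey == 0:
        ex = 1
    return ex, ey


def make_integral_kernel(psf: Kernel) -> Kernel:
    """The integral form ``K0`` of a derivative-type kernel.

    ``K0`` is the discrete antiderivative of the PSF along the shear
    direction: its forward difference along the (grid-quantized) shear step
    reproduces the PSF on the interior of the window.  The window is enlarged
    by a margin and the outermost two rings are tapered to zero so that all
    first differences on the boundary vanish — the discrete analogue of a
    kernel with zero boundary derivatives, which is what licenses moving the
    derivative from the image onto the kernel in the variational scheme.
    """
    if not psf.is_derivative_type:
        raise ValueError(
            "psf must be derivative-type (sum to 0); the shear integral of a "
            "kernel with nonzero DC does not close on a finite window"
        )
    ex, ey = _shear_step(psf.shear)
    d = psf.half_width
    d0 = d + 3
    side = 2 * d0 + 1
    pad = d0 - d
    emb = np.zeros((side, side))
    emb[pad : pad + 2 * d + 1, pad : pad + 2 * d + 1] = psf.values

    # exclusive cumulative sum along lines parallel to (ex, ey):
    # S[p] = sum of emb over p - k*(ex,ey), k >= 1  =>  S[p + e] - S[p] = emb[p]
    s = _accumulate_along(emb, ex, ey)

    # taper: force the two outermost rings to zero (windowed rim).
    idx = np.maximum(
        np.abs(np.arange(side) - d0)[None, :], np.abs(np.arange(side) - d0)[:, None]
    )
    taper = np.ones((side, side))
    taper[idx >= d0 - 1] = 0.0
    s = s * taper
    return Kernel(values=s, shear=psf.shear, kind="integral_K0")


def _accumulate_along(emb: np.ndarray, ex: int, ey: int) -> np.ndarray:
    """Exclusive cumulative sum of ``emb`` along direction ``(ex, ey)``."""
    side = emb.shape[0]
    # traversal order: predecessors (p - e) are visited before p
    ys = range(side) if ey >= 0 else range(side - 1, -1, -1)
    out = np.zeros_like(emb)
    for y in ys:
        xs = range(side) if ex >= 0 else range(side - 1, -1, -1)
        for x in xs:
            py, px = y - ey, x - ex
            if 0 <= py < side and 0 <= px < side:
                out[y, x] = out[py, px] + emb[py, px]
    return out


def shear_difference(k0: Kernel) -> Kernel:
    """Forward difference of ``K0`` along the shear step (inverse of
    :func:`make_integral_kernel` on the window interior), cropped to the
    minimal centred odd window containing its support."""
    ex, ey = _shear_step(k0.shear)
    v = k0.values
    side = v.shape[0]
    shifted = np.zeros_like(v)
    ysrc = slice(max(ey, 0), side + min(ey, 0))
    ydst = slice(max(-ey, 0), side + min(-ey, 0))
    xsrc = slice(max(ex, 0), side + min(ex, 0))
    xdst = slice(max(-ex, 0), side + min(-ex, 0))
    shifted[ydst, xdst] = v[ysrc, xsrc]
    diff = shifted - v
    return Kernel(values=_crop_centered(diff), shear=k0.shear, kind="custom")


def _crop_centered(values: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Crop to the smallest centred odd-sided window containing all entries
    with magnitude > tol (keeps at least 3x3)."""
    side = values.shape[0]
    c = side // 2
    nz = np.argwhere(np.abs(values) > tol)
    if nz.size == 0:
        return values[c : c + 1, c : c + 1].copy()
    r = int(np.max(np.abs(nz - c)))
    r = max(r, 1)
    return values[c - r : c + r + 1, c - r : c + r + 1].copy()


def load_kernel(path, shear: ShearSpec = DEFAULT_SHEAR) -> Kernel:
    """Read a kernel from a text matrix (whitespace/comma delimited) or TIFF."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        values = np.asarray(tifffile.imread(path))
    else:
        try:
            values = np.loadtxt(path)
        except ValueError:
            values = np.loadtxt(path, delimiter=",")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.ndim != 2:
        raise ValueError("kernel file must contain a 2D array")
    if values.shape[0] % 2 == 0 or values.shape[1] % 2 == 0:
        raise ValueError("kernel side must be odd")
    return Kernel(values=values, shear=shear, kind="custom")


def write_kernel(kernel: Kernel, path) -> None:
    """Write a kernel as a float TIFF or a whitespace-delimited text matrix."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, kernel.values.astype(np.float32))
    else:
        np.savetxt(path, kernel.values)
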