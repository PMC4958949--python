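"""Matrix-free linear operators shared by the forward model and the solvers.

Every spatial-domain operator in the package is a composition of

* ``P`` — mirror (reflect, no edge repeat) padding, and
* ``C`` — valid cross-correlation with a small kernel,

and gradients of quadratic energies need the *exact* discrete adjoint
``(C P)^T = P^T C^T``.  ``C^T`` is full convolution; ``P^T`` folds the padded
border back onto its source pixels.  Implementing the adjoint this way (rather
than approximating it with another mirror-padded convolution) is what lets the
finite-difference oracles in the test suite hold to machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "correlate_mirror",
    "adjoint_correlate_mirror",
    "grad_x",
    "grad_y",
    "grad_x_T",
    "grad_y_T",
]

# central-difference stencils, correlation convention: out[p] = sum K[s] in[p+s]
_DX = np.array([[-0.5, 0.0, 0.5]])
_DY = _DX.T


def correlate_mirror(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Cross-correlate ``img`` with ``kernel`` under mirror boundary handling.

    ``out[y, x] = sum_{eta, xi} kernel[eta, xi] * img[y + eta, x + xi]`` with
    the kernel window centred on the output pixel and out-of-range samples
    reflected (numpy ``reflect`` / ndimage ``mirror`` convention).
    """
    img = np.asarray(img, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape[0] > img.shape[0] or kernel.shape[1] > img.shape[1]:
        raise ValueError(
            f"kernel {kernel.shape} larger than image {img.shape}"
        )
    return ndimage.correlate(img, kernel, mode="mirror")


def _fold_indices(n: int, d: int) -> np.ndarray:
    # index map of reflect padding: padded[i] = x[idx[i]]
    return np.pad(np.arange(n), d, mode="reflect")


def adjoint_correlate_mirror(res: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`correlate_mirror` (same kernel).

    Satisfies ``<correlate_mirror(x, K), r> == <x, adjoint_correlate_mirror(r, K)>``
    for all ``x``, ``r`` to rounding error.
    """
    res = np.asarray(res, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    dy = kernel.shape[0] // 2
    dx = kernel.shape[1] // 2
    full = signal.convolve2d(res, kernel, mode="full")
    ny, nx = res.shape
    ri = _fold_indices(ny, dy)
    ci = _fold_indices(nx, dx)
    # fold rows, then columns (reflect padding is separable in the index map)
    rows = np.zeros((ny, full.shape[1]))
    np.add.at(rows, ri, full)
    out = np.zeros((ny, nx))
    np.add.at(out.T, ci, rows.T)
    return out


def grad_x(img: np.ndarray) -> np.ndarray:
    """Central-difference d/dx (x rightward, columns), mirror boundary."""
    return correlate_mirror(img, _DX)


def grad_y(img: np.ndarray) -> np.ndarray:
    """Central-difference d/dy (y downward, rows), mirror boundary."""
    return correlate_mirror(img, _DY)


def grad_x_T(img: np.ndarray) -> np.ndarray:
    return adjoint_correlate_mirror(img, _DX)


def grad_y_T(img: np.ndarray) -> np.ndarray:
    return adjoint_correlate_mirror(img, _DY)
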