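"""Image reading/writing for the command-line surface.

TIFF and PNG in, float arrays out: 8/16-bit integer data are scaled to
[0, 1]; floating-point TIFF passes through bit-exactly.  Multi-channel
inputs are reduced to luminance with a logged warning (DIC data is
single-channel by nature).
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger("dicrecon")

__all__ = ["read_image", "write_image"]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path) -> np.ndarray:
    """Read a single-channel image as a float array."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = np.asarray(tifffile.imread(path))
    elif path.lower().endswith(".png"):
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
    else:
        raise ValueError(f"unsupported image format: {path}")
    if arr.ndim == 3:
        log.warning("multi-channel image %s reduced to luminance", path)
        arr = arr[..., :3].astype(float) @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / float(info.max)
    return arr.astype(float, copy=False)


def write_image(arr: np.ndarray, path, preview_png: bool = False) -> None:
    """Write a float array as 32-bit float TIFF (or 16-bit min-max PNG)."""
    path = str(path)
    arr = np.asarray(arr, dtype=float)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, arr.astype(np.float32))
    elif path.lower().endswith(".png"):
        import imageio.v3 as iio

        lo, hi = float(arr.min()), float(arr.max())
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))
        with open(path + ".scale.txt", "w") as fh:
            fh.write(f"min {lo}\nmax {hi}\n")
    else:
        raise ValueError(f"unsupported image format: {path}")
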