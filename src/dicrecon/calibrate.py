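"""Optical-path-length calibration against a reference bead.

A reconstruction is proportional to optical path length only up to an
unknown scale (and background offset).  Imaging an object of known geometry
and refractive index — a polystyrene microbead in index oil — fixes the
scale: line profiles through the bead centre are taken in four directions
(horizontal, vertical, both diagonals), averaged, and fitted affinely to the
theoretical phase profile of a sphere.  The fitted scale converts a unit
intensity change into physical path length for any other object imaged under
the same settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .evaluate import pearson

__all__ = [
    "CalibrationResult",
    "extract_profiles",
    "fit_scale",
    "apply_calibration",
    "find_bead_center",
]


@dataclass
class CalibrationResult:
    scale: float
    offset: float
    correlation: float
    averaged_profile: np.ndarray
    theoretical_profile: np.ndarray


def extract_profiles(
    recon: np.ndarray, center: tuple[float, float], length: int
) -> np.ndarray:
    """Average of four centre-line profiles (horizontal, vertical, diagonals).

    ``center`` is ``(x, y)`` in pixel coordinates; each profile has
    ``length`` samples spaced one pixel apart physically (diagonal lines are
    resampled by linear interpolation at the same physical spacing), centred
    on ``center``.
    """
    recon = np.asarray(recon, dtype=float)
    cx, cy = center
    ny, nx = recon.shape
    t = np.arange(length, dtype=float) - (length - 1) / 2.0
    dirs = [(1.0, 0.0), (0.0, 1.0), (np.sqrt(0.5), np.sqrt(0.5)), (np.sqrt(0.5), -np.sqrt(0.5))]
    profiles = []
    for dx, dy in dirs:
        xs = cx + t * dx
        ys = cy + t * dy
        if xs.min() < 0 or xs.max() > nx - 1 or ys.min() < 0 or ys.max() > ny - 1:
            raise ValueError("profile line exceeds the image bounds")
        profiles.append(ndimage.map_coordinates(recon, [ys, xs], order=1))
    return np.mean(profiles, axis=0)


def fit_scale(
    measured: np.ndarray, theoretical: np.ndarray, fit_offset: bool = True
) -> CalibrationResult:
    """Least-squares fit ``theoretical ~ scale * measured + offset``.

    With ``fit_offset=False`` only the scale is fitted (offset fixed at 0),
    for settings where the background level is already anchored.
    """
    measured = np.asarray(measured, dtype=float)
    theoretical = np.asarray(theoretical, dtype=float)
    if measured.shape != theoretical.shape:
        raise ValueError("profiles must have equal length")
    if np.ptp(measured) == 0 or np.ptp(theoretical) == 0:
        raise ValueError("constant profile; fit undefined")
    if fit_offset:
        A = np.stack([measured, np.ones_like(measured)], axis=1)
    else:
        A = measured[:, None]
    coef, *_ = np.linalg.lstsq(A, theoretical, rcond=None)
    scale = float(coef[0])
    offset = float(coef[1]) if fit_offset else 0.0
    return CalibrationResult(
        scale=scale,
        offset=offset,
        correlation=pearson(measured, theoretical),
        averaged_profile=measured,
        theoretical_profile=theoretical,
    )


def apply_calibration(recon: np.ndarray, cal: CalibrationResult) -> np.ndarray:
    """Convert reconstructed intensities to optical path length units."""
    return cal.scale * np.asarray(recon, dtype=float) + cal.offset


def find_bead_center(recon: np.ndarray) -> tuple[float, float]:
    """Centroid of the Otsu-thresholded normalized reconstruction (x, y)."""
    from skimage.filters import threshold_otsu

    r = np.clip(np.asarray(recon, dtype=float), 0, None)
    if np.ptp(r) == 0:
        raise ValueError("cannot locate a bead in a constant image")
    m = r >= threshold_otsu(r)
    cy, cx = ndimage.center_of_mass(m)
    return float(cx), float(cy)
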