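"""Linear DIC image formation and synthetic phantom generation.

The forward model: a DIC micrograph ``G`` is the local correlation of the
optical-path-length map ``I`` with a derivative-type kernel ``K`` on the
window ``W = [-d, d]^2``,

    G(x, y) = sum_{(xi, eta) in W} K(eta, xi) * I(y + eta, x + xi),

with mirror (reflect) boundary handling.  Because ``K`` sums to zero the model
responds only to optical-path-length *differences* along the shear axis —
constant regions map to the (zero) background, edges to bipolar bright/dark
flanks, which is exactly the familiar shadow-cast DIC appearance under
positive bias (up to the constant bias offset, which carries no information
and is omitted).

The phantom generator emulates the kind of benchmark the method is evaluated
on when no real micrographs are at hand: 20 ground-truth images of simple
geometric shapes (ellipse, rectangle, pentagon, triangle, cross) and their
rotated versions, 15 strictly two-valued and 5 with graded intensities, each
paired with its simulated DIC image, plus a spherical-bead phase phantom for
calibration.  Shapes are rasterized by exact pixel-centre inclusion tests
(no antialiasing) so the two-valued images contain exactly two grey levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._linops import correlate_mirror
from .kernels import DEFAULT_SHEAR, Kernel, ShearSpec, make_dirac_difference

__all__ = [
    "simulate_dic",
    "add_noise",
    "generate_shape_set",
    "bead_phantom",
    "PhantomSet",
    "default_shape_config",
    "write_phantom_set",
]

DEFAULT_IMAGE_SIZE = 128  # the benchmark never states a size; chosen for desk-scale runs


def simulate_dic(truth: np.ndarray, psf: Kernel) -> np.ndarray:
    """Simulate a DIC image: correlate the OPL map with the DIC kernel."""
    truth = np.asarray(truth, dtype=float)
    if not np.all(np.isfinite(truth)):
        raise ValueError("truth image contains non-finite values")
    return correlate_mirror(truth, psf.values)


def add_noise(g: np.ndarray, snr_db: float | None, seed: int) -> np.ndarray:
    """Add white Gaussian noise at the given SNR (dB, variance-referenced).

    Noise variance is ``var(g) / 10**(snr_db / 10)``; the SNR is referenced to
    the signal's variance rather than its mean square because DIC images carry
    a large uninformative DC bias.  ``snr_db=None`` (or ``inf``) returns the
    input unchanged.  Deterministic given ``seed``.
    """
    g = np.asarray(g, dtype=float)
    if snr_db is None or math.isinf(snr_db):
        return g.copy()
    var = float(np.var(g))
    if var == 0:
        raise ValueError("SNR undefined for a constant image")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(var / 10 ** (snr_db / 10))
    return g + rng.normal(0.0, sigma, size=g.shape)


# ---------------------------------------------------------------------------
# shape rasterization (pixel-centre inclusion tests; exact two-valued output)
# ---------------------------------------------------------------------------


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    return x - c, y - c


def _rot(x, y, angle_deg):
    a = math.radians(angle_deg)
    return x * math.cos(a) + y * math.sin(a), -x * math.sin(a) + y * math.cos(a)


def _ellipse_mask(size, a, b, angle_deg):
    x, y = _grid(size)
    xr, yr = _rot(x, y, angle_deg)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _rect_mask(size, w, h, angle_deg):
    x, y = _grid(size)
    xr, yr = _rot(x, y, angle_deg)
    return (np.abs(xr) <= w / 2) & (np.abs(yr) <= h / 2)


def _regular_polygon_mask(size, n_sides, radius, angle_deg):
    x, y = _grid(size)
    xr, yr = _rot(x, y, angle_deg)
    inside = np.ones(xr.shape, dtype=bool)
    # convex polygon = intersection of half-planes through edge midpoints
    apothem = radius * math.cos(math.pi / n_sides)
    for k in range(n_sides):
        phi = 2 * math.pi * k / n_sides
        inside &= xr * math.cos(phi) + yr * math.sin(phi) <= apothem
    return inside


def _cross_mask(size, arm_w, arm_l, angle_deg):
    x, y = _grid(size)
    xr, yr = _rot(x, y, angle_deg)
    h = (np.abs(xr) <= arm_l / 2) & (np.abs(yr) <= arm_w / 2)
    v = (np.abs(xr) <= arm_w / 2) & (np.abs(yr) <= arm_l / 2)
    return h | v


def default_shape_config(size: int = DEFAULT_IMAGE_SIZE) -> dict:
    """Default phantom inventory: 20 images = 5 binary base shapes x 3
    rotations (15 two-valued) + 5 multi-level base shapes."""
    s = size
    binary = [
        ("ellipse", [0.0, 30.0, 60.0], lambda a: _ellipse_mask(s, 0.30 * s, 0.18 * s, a)),
        ("rectangle", [0.0, 25.0, 50.0], lambda a: _rect_mask(s, 0.50 * s, 0.28 * s, a)),
        ("pentagon", [0.0, 24.0, 48.0], lambda a: _regular_polygon_mask(s, 5, 0.30 * s, a)),
        ("triangle", [0.0, 40.0, 80.0], lambda a: _regular_polygon_mask(s, 3, 0.34 * s, a)),
        ("cross", [0.0, 22.5, 45.0], lambda a: _cross_mask(s, 0.16 * s, 0.56 * s, a)),
    ]
    return {"size": s, "binary": binary, "n_multilevel": 5}


@dataclass
class PhantomSet:
    """Index-aligned ground truths and simulated DIC images with labels."""

    ground_truths: list[np.ndarray]
    dic_images: list[np.ndarray]
    labels: list[dict]
    psf: Kernel
    noise_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ground_truths) != len(self.dic_images):
            raise ValueError("ground truths and DIC images must be index-aligned")

    def __len__(self) -> int:
        return len(self.ground_truths)


def _multilevel_images(size: int) -> list[tuple[str, np.ndarray]]:
    """Five graded-intensity phantoms (values span a range, not just {0, 1})."""
    x, y = _grid(size)
    out = []

    m = _ellipse_mask(size, 0.32 * size, 0.20 * size, 15.0)
    ramp = np.clip((x / (0.64 * size)) + 0.5, 0.0, 1.0)
    out.append(("ramp_ellipse", np.where(m, 0.2 + 0.8 * ramp, 0.0)))

    img = np.zeros((size, size))
    for lvl, frac in zip((0.25, 0.5, 0.75, 1.0), (0.46, 0.34, 0.22, 0.10)):
        img[_rect_mask(size, frac * size, frac * size, 10.0)] = lvl
    out.append(("step_pyramid", img))

    r = np.hypot(x, y)
    m = r <= 0.30 * size
    out.append(("radial_disk", np.where(m, 1.0 - r / (0.30 * size), 0.0)))

    m = _regular_polygon_mask(size, 5, 0.30 * size, 36.0)
    diag = np.clip(((x + y) / (0.9 * size)) + 0.5, 0.0, 1.0)
    out.append(("ramp_pentagon", np.where(m, 0.1 + 0.9 * diag, 0.0)))

    outer = r <= 0.34 * size
    inner = r <= 0.20 * size
    img = np.zeros((size, size))
    img[outer] = 0.5
    img[inner] = 1.0
    out.append(("two_level_annulus", img))
    return out


def generate_shape_set(
    config: dict | None = None,
    seed: int = 0,
    psf: Kernel | None = None,
    noise_db: float | None = None,
) -> PhantomSet:
    """Generate the synthetic benchmark: 20 ground truths (15 two-valued, 5
    multi-level) and their simulated DIC images.

    The default PSF is the difference of two Dirac deltas one pixel from the
    origin — a close approximation of the first derivative of a Gaussian with
    sigma = 0.5 — which is the standard generated PSF for this benchmark.
    ``noise_db`` (e.g. 20) adds white Gaussian noise to every DIC image;
    ``None`` keeps the set noise-free.  Fully deterministic given ``seed``.
    """
    if config is None:
        config = default_shape_config()
    if psf is None:
        psf = make_dirac_difference(DEFAULT_SHEAR, offset=1.0)
    binary = config["binary"]
    if not binary:
        raise ValueError("shape list is empty")
    size = config["size"]

    truths: list[np.ndarray] = []
    labels: list[dict] = []
    for name, angles, builder in binary:
        for angle in angles:
            truths.append(builder(angle).astype(float))
            labels.append({"base_shape": name, "rotation_deg": float(angle), "mode": "binary"})
    for name, img in _multilevel_images(size)[: config["n_multilevel"]]:
        truths.append(img)
        labels.append({"base_shape": name, "rotation_deg": 0.0, "mode": "multilevel"})

    dics = []
    for i, t in enumerate(truths):
        g = simulate_dic(t, psf)
        if noise_db is not None:
            g = add_noise(g, noise_db, seed=seed * 100003 + i)
        dics.append(g)
    return PhantomSet(
        ground_truths=truths, dic_images=dics, labels=labels, psf=psf,
        noise_db=noise_db, seed=seed,
    )


def bead_phantom(
    radius_um: float, delta_n: float, pixel_um: float, size: int
) -> np.ndarray:
    """Optical-path-length map of a spherical bead in an index-matched medium.

    The OPL at in-plane radius ``rho`` is the chord length through the sphere
    times the refractive-index difference:

        OPL(rho) = delta_n * 2 * sqrt(radius^2 - rho^2)   for rho <= radius,

    and 0 outside, sampled at pixel centres (units of ``radius_um``).
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if radius_um >= pixel_um * size / 2:
        raise ValueError("bead does not fit in the image")
    x, y = _grid(size)
    rho = np.hypot(x, y) * pixel_um
    chord = np.where(rho <= radius_um, 2.0 * np.sqrt(np.maximum(radius_um**2 - rho**2, 0.0)), 0.0)
    return delta_n * chord


def write_phantom_set(pset: PhantomSet, out_dir) -> None:
    """Write a phantom set as float TIFFs plus a YAML manifest."""
    import pathlib

    import tifffile
    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (t, g) in enumerate(zip(pset.ground_truths, pset.dic_images)):
        tifffile.imwrite(out / f"gt_{i:03d}.tif", t.astype(np.float32))
        tifffile.imwrite(out / f"dic_{i:03d}.tif", g.astype(np.float32))
    tifffile.imwrite(out / "psf.tif", pset.psf.values.astype(np.float32))
    manifest = {
        "labels": pset.labels,
        "seed": pset.seed,
        "snr_db": pset.noise_db,
        "shear": {"u": pset.psf.shear.u, "v": pset.psf.shear.v},
        "count": len(pset),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
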