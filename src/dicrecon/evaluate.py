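"""Quantitative evaluation of reconstructions.

Grayscale ground truth: negative reconstruction values are clipped (they are
physically meaningless path lengths), both images are min-max normalized to
[0, 1] independently, and the mean squared error is computed.  Binary
(hand-segmentation) ground truth: the reconstruction is thresholded at every
unique value and the ROC curve (false positive rate vs true positive rate)
is traced; the area under it (AUC) summarizes reconstruction quality without
committing to any single threshold.  Ties are counted as foreground, which
together with trapezoidal integration makes the AUC identical to the
Mann-Whitney U statistic (probability that a random foreground pixel outranks
a random background pixel, ties worth one half).

The benchmark driver weighs every base shape equally regardless of how many
rotated variants it has: MSEs of rotations are averaged first, then the
across-shape mean is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ROCResult",
    "normalize_pair",
    "mse",
    "roc_auc",
    "pearson",
    "benchmark",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def normalize_pair(
    recon: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Clip negatives of ``recon``, then min-max scale each image to [0, 1]."""

    def _scale(img, name):
        lo, hi = float(img.min()), float(img.max())
        if hi == lo:
            raise ValueError(f"{name} image is constant; normalization undefined")
        return (img - lo) / (hi - lo)

    recon = np.clip(np.asarray(recon, dtype=float), 0.0, None)
    truth = np.asarray(truth, dtype=float)
    return _scale(recon, "reconstruction"), _scale(truth, "truth")


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared pixel difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation over all pixels."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def roc_auc(recon: np.ndarray, mask: np.ndarray) -> ROCResult:
    """Threshold-sweep ROC of a grayscale reconstruction against a binary mask.

    Foreground = pixels ``>= threshold``; the sweep runs over every unique
    reconstruction value plus a sentinel above the maximum (giving the (0, 0)
    corner) — with the minimum itself yielding (1, 1).  AUC is the
    trapezoidal area under (FPR, TPR).
    """
    recon = np.asarray(recon, dtype=float).ravel()
    mask = np.asarray(mask).ravel().astype(bool)
    n_pos = int(mask.sum())
    n_neg = int((~mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("mask must contain both classes")
    uniq = np.unique(recon)
    thresholds = np.concatenate([uniq, [uniq[-1] + 1.0]])[::-1]  # high -> low
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    # vectorized sweep: counts of positives/negatives at or above each threshold
    order = np.argsort(recon, kind="stable")
    sorted_vals = recon[order]
    sorted_pos = mask[order].astype(float)
    cum_pos = np.concatenate([[0.0], np.cumsum(sorted_pos)])
    total = recon.size
    for i, t in enumerate(thresholds):
        idx = np.searchsorted(sorted_vals, t, side="left")
        above = total - idx
        pos_above = cum_pos[-1] - cum_pos[idx]
        tpr[i] = pos_above / n_pos
        fpr[i] = (above - pos_above) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def benchmark(
    pset,
    algorithms: dict[str, Callable[[np.ndarray], np.ndarray]],
    metric: str = "mse",
    masks: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Run reconstruction algorithms over a phantom set and tabulate quality.

    ``algorithms`` maps a name to a callable taking the DIC image and
    returning a reconstruction.  ``metric`` is ``"mse"`` (against grayscale
    ground truth, after :func:`normalize_pair`) or ``"auc"`` (against binary
    masks; ``masks`` defaults to thresholded ground truths).  Returns a tidy
    DataFrame with columns algorithm, image, base_shape, metric, value, plus
    per-algorithm summary rows (``image = "mean"``) in which rotated variants
    of a base shape are averaged before base shapes are averaged equally.
    """
    if metric not in ("mse", "auc"):
        raise ValueError(f"unknown metric {metric!r}")
    rows = []
    for name in algorithms:
        if not callable(algorithms[name]):
            raise ValueError(f"algorithm {name!r} is not callable")
    for name, algo in algorithms.items():
        for idx, (g, truth, label) in enumerate(
            zip(pset.dic_images, pset.ground_truths, pset.labels)
        ):
            recon = algo(g)
            if metric == "mse":
                a, b = normalize_pair(recon, truth)
                value = mse(a, b)
            else:
                m = masks[idx] if masks is not None else (truth > truth.min())
                value = roc_auc(np.clip(recon, 0, None), m).auc
            rows.append(
                {
                    "algorithm": name,
                    "image": idx,
                    "base_shape": label["base_shape"],
                    "metric": metric,
                    "value": value,
                }
            )
    df = pd.DataFrame(rows)
    # two-level weighting: rotations first, then base shapes equally
    summaries = []
    for name, sub in df.groupby("algorithm", sort=False):
        per_shape = sub.groupby("base_shape", sort=False)["value"].mean()
        summaries.append(
            {
                "algorithm": name,
                "image": "mean",
                "base_shape": "all",
                "metric": metric,
                "value": float(per_shape.mean()),
            }
        )
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
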