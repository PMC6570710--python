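"""Depth-prediction evaluation: L1, relative L1, RMSE, per-image max error.

All metrics compare ground-truth and predicted depth maps in decoded
cm-space. Dataset-level reports aggregate per-image values as
mean +/- population standard deviation across images, one row per model,
with the relative error in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricReport",
    "l1_error",
    "relative_l1_error",
    "rmse",
    "max_pixel_l1",
    "evaluate_pairs",
    "evaluate_model",
]


@dataclass
class MetricReport:
    mean_l1: float  # cm
    std_l1: float
    mean_rel_l1: float  # %
    std_rel_l1: float
    mean_rmse: float  # cm
    std_rmse: float
    mean_max_l1: float  # cm
    n_images: int

    def as_dict(self):
        return {
            "mean_l1_cm": self.mean_l1,
            "std_l1_cm": self.std_l1,
            "mean_rel_l1_pct": self.mean_rel_l1,
            "std_rel_l1_pct": self.std_rel_l1,
            "mean_rmse_cm": self.mean_rmse,
            "std_rmse_cm": self.std_rmse,
            "mean_max_l1_cm": self.mean_max_l1,
            "n_images": self.n_images,
        }


def _pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return x, y


def l1_error(x, y):
    """Mean over pixels of |x - y| (cm)."""
    x, y = _pair(x, y)
    return float(np.mean(np.abs(x - y)))


def relative_l1_error(x, y, eps=1e-3):
    """100 * mean over pixels with x >= eps of |x - y| / x (percent).

    Pixels shallower than ``eps`` cm are excluded from the average — the
    ratio is undefined at zero ground-truth depth, which rendered contact
    points can produce exactly.
    """
    x, y = _pair(x, y)
    mask = x >= eps
    if not mask.any():
        raise ValueError("all ground-truth pixels below eps")
    return float(100.0 * np.mean(np.abs(x[mask] - y[mask]) / x[mask]))


def rmse(x, y):
    """sqrt(mean((x - y)^2)) over all pixels (cm)."""
    x, y = _pair(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def max_pixel_l1(x, y):
    """Largest per-pixel absolute error (cm)."""
    x, y = _pair(x, y)
    return float(np.max(np.abs(x - y)))


def evaluate_pairs(predict_fn, pairs, eps=1e-3) -> MetricReport:
    """Per-image metrics for ``predict_fn(rgb) -> depth_cm`` over (rgb, depth) pairs.

    Aggregates across images as mean +/- population std; relative error in %.
    """
    if not pairs:
        raise ValueError("empty evaluation split")
    per = {"l1": [], "rel": [], "rmse": [], "max": []}
    for c, x in pairs:
        y = predict_fn(c)
        per["l1"].append(l1_error(x, y))
        per["rel"].append(relative_l1_error(x, y, eps=eps))
        per["rmse"].append(rmse(x, y))
        per["max"].append(max_pixel_l1(x, y))
    return MetricReport(
        mean_l1=float(np.mean(per["l1"])),
        std_l1=float(np.std(per["l1"])),
        mean_rel_l1=float(np.mean(per["rel"])),
        std_rel_l1=float(np.std(per["rel"])),
        mean_rmse=float(np.mean(per["rmse"])),
        std_rmse=float(np.std(per["rmse"])),
        mean_max_l1=float(np.mean(per["max"])),
        n_images=len(pairs),
    )


def evaluate_model(trainer, manifest_rows, split="test", domain="synthetic", noise_seed=0):
    """Table-style report for one trained model on a manifest split."""
    from .gan_core import _load_split

    pairs = _load_split(manifest_rows, split, domain=domain)
    if not pairs:
        raise ValueError(f"no rows with split={split!r}, domain={domain!r}")
    return evaluate_pairs(lambda c: trainer.predict(c, noise_seed=noise_seed), pairs)
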