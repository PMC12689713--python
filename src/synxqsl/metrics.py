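"""Map-quality metrics over labelled masks: signed errors, SNR, CNR, SSIM.

Definitions used throughout the phantom benchmark:

* signed-error statistics: err = estimate - truth over a mask; reported
  as (RMS, min, max);
* SNR of a uniform region: mean / SD inside the region; for a multi-region
  label map the per-region SNRs are averaged (constant regions have
  infinite SNR and are excluded from the average);
* CNR between a foreground and a background mask:
  ``|mu_fg - mu_bg| / sqrt(sd_fg^2 + sd_bg^2)`` (pooled-SD form — there is
  no single canonical CNR; the same definition is applied to every method
  so rankings are comparable);
* SSIM: slice-wise 2D structural similarity (Gaussian window, sd 1.5,
  K1=0.01, K2=0.03, dynamic range taken from the truth map), averaged
  over the mask.  Backed by scikit-image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = [
    "signed_error_stats",
    "snr",
    "snr_per_region",
    "cnr",
    "ssim",
    "wilcoxon_errors",
    "MetricsReport",
]


def signed_error_stats(
    est: np.ndarray, truth: np.ndarray, mask: np.ndarray
) -> tuple[float, float, float]:
    """(RMS, min, max) of est - truth over a non-empty mask."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if est.shape != truth.shape or est.shape != mask.shape:
        raise ValueError("est, truth and mask must share one shape")
    if not mask.any():
        raise ValueError("empty mask")
    err = est[mask] - truth[mask]
    return (
        float(np.sqrt(np.mean(err * err))),
        float(err.min()),
        float(err.max()),
    )


def snr_per_region(map_: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Per-region mean/SD; constant regions map to ``inf``."""
    map_ = np.asarray(map_, dtype=float)
    labels = np.asarray(labels)
    out: dict[int, float] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        vals = map_[labels == lab]
        sd = vals.std()
        out[int(lab)] = float("inf") if sd == 0 else float(abs(vals.mean()) / sd)
    return out


def snr(map_: np.ndarray, labels: np.ndarray) -> float:
    """Mean of per-region SNRs over a label map (or a single boolean mask).

    Regions flagged infinite (zero SD) are excluded from the average; if
    every region is constant the result is ``inf``.
    """
    labels = np.asarray(labels)
    if labels.dtype == bool:
        labels = labels.astype(np.int32)
    per = snr_per_region(map_, labels)
    if not per:
        raise ValueError("no non-zero region labels")
    finite = [v for v in per.values() if np.isfinite(v)]
    if not finite:
        return float("inf")
    return float(np.mean(finite))


def cnr(map_: np.ndarray, fg_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """|mu_fg - mu_bg| / sqrt(sd_fg^2 + sd_bg^2); symmetric in fg/bg."""
    map_ = np.asarray(map_, dtype=float)
    fg = np.asarray(fg_mask, dtype=bool)
    bg = np.asarray(bg_mask, dtype=bool)
    if not fg.any() or not bg.any():
        raise ValueError("foreground and background masks must be non-empty")
    a, b = map_[fg], map_[bg]
    denom = np.sqrt(a.std() ** 2 + b.std() ** 2)
    if denom == 0:
        raise ValueError("both regions have zero variance; CNR undefined")
    return float(abs(a.mean() - b.mean()) / denom)


def ssim(
    est: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Masked mean SSIM between two 3D maps, computed slice-wise in 2D."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape or est.ndim != 3:
        raise ValueError("expected two 3D maps of equal shape")
    if mask is None:
        mask = np.ones(est.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    data_range = float(truth.max() - truth.min())
    if data_range == 0:
        raise ValueError("constant truth map; SSIM dynamic range undefined")
    total = 0.0
    count = 0
    for z in range(est.shape[2]):
        m = mask[:, :, z]
        if not m.any():
            continue
        _, smap = structural_similarity(
            truth[:, :, z],
            est[:, :, z],
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=data_range,
            full=True,
        )
        total += float(smap[m].sum())
        count += int(m.sum())
    return total / count


def wilcoxon_errors(err_a: np.ndarray, err_b: np.ndarray) -> float:
    """p-value of the Wilcoxon signed-rank test on paired absolute errors."""
    res = stats.wilcoxon(np.abs(np.ravel(err_a)), np.abs(np.ravel(err_b)))
    return float(res.pvalue)


@dataclass
class MetricsReport:
    """Tidy benchmark report.

    ``errors`` holds one row per (method, parameter, S0 level) with the
    signed-error statistics; ``maps`` one row per (method, parameter) with
    the per-map RMSE / SNR / CNR / SSIM.
    """

    errors: pd.DataFrame
    maps: pd.DataFrame

    def to_csv(self, prefix) -> None:
        self.errors.to_csv(f"{prefix}_errors.csv", index=False)
        self.maps.to_csv(f"{prefix}_maps.csv", index=False)
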