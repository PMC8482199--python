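"""Contrast and coefficient-of-variation metrics for reproducibility studies.

The WM-GM contrast is C = (S_WM - S_GM)/(S_WM + S_GM) over class-mean
signals.  Reproducibility across repeated sessions (or subjects) is
summarized by the per-voxel coefficient of variation, CV = sd/mean with the
sample (n-1) standard deviation, mapped over an aligned volume stack and
averaged within tissue classes or manually drawn ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import Mask, Volume

__all__ = ["contrast", "cv", "cv_map", "roi_summary", "ContrastReport"]

# Voxels whose stack mean falls below this fraction of the masked median
# mean are flagged and set to 0 in the CV map.
CV_MEAN_FLOOR_FRACTION = 1e-6


@dataclass
class ContrastReport:
    mean_wm: float
    mean_gm: float
    n_wm: int
    n_gm: int

    @property
    def c(self) -> float:
        return (self.mean_wm - self.mean_gm) / (self.mean_wm + self.mean_gm)


def contrast(wm_values, gm_values) -> float:
    """Normalized class-mean difference (S_WM - S_GM)/(S_WM + S_GM)."""
    wm = np.asarray(wm_values, dtype=float)
    gm = np.asarray(gm_values, dtype=float)
    if wm.size == 0 or gm.size == 0:
        raise ValueError("empty class vector")
    m_wm, m_gm = wm.mean(), gm.mean()
    if m_wm + m_gm == 0:
        raise ZeroDivisionError("both class means are zero")
    return (m_wm - m_gm) / (m_wm + m_gm)


def cv(values) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m == 0:
        raise ZeroDivisionError("zero mean")
    return float(v.std(ddof=1) / m)


def cv_map(stack, mask: Mask | None = None):
    """Per-voxel CV across an aligned stack of volumes.

    Returns ``(cv_vol, flags)``; voxels outside the mask or with near-zero
    stack mean are flagged (uint8 = 1) and set to 0.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 volumes")
    first = stack[0]
    for v in stack[1:]:
        if v.shape != first.shape:
            raise ValueError(f"grid mismatch: {v.shape} vs {first.shape}")
    if mask is None:
        mask = Mask.full(first.shape)
    if mask.data.shape != first.shape:
        raise ValueError("mask grid mismatch")

    data = np.stack([v.data for v in stack], axis=0)
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)

    inside = mask.data
    med = np.median(np.abs(mean[inside])) if inside.any() else 0.0
    floor = CV_MEAN_FLOOR_FRACTION * med
    valid = inside & (np.abs(mean) > floor)

    out = np.zeros(first.shape)
    np.divide(sd, mean, out=out, where=valid)
    flags = (~valid).astype(np.uint8)
    return first.like(out, units=""), first.like(flags, units="flags")


def roi_summary(cv_vol: Volume, rois: dict) -> pd.DataFrame:
    """Mean +/- sample SD of the CV within each ROI, in percent.

    ``rois`` maps names to Masks.  Returns a DataFrame with columns
    roi, n_voxels, cv_mean_pct, cv_sd_pct.
    """
    rows = []
    for name, roi in rois.items():
        if roi.data.shape != cv_vol.shape:
            raise ValueError(f"ROI {name!r}: grid mismatch")
        vals = cv_vol.data[roi.data]
        if vals.size == 0:
            raise ValueError(f"ROI {name!r} is empty")
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        rows.append({"roi": name, "n_voxels": int(vals.size),
                     "cv_mean_pct": 100.0 * vals.mean(),
                     "cv_sd_pct": 100.0 * sd})
    return pd.DataFrame(rows)
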