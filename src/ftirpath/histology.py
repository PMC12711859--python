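"""Threshold-based immunohistochemistry burden quantification.

Inputs are single-channel positivity maps (0-255 or 0-1; positive staining
= high intensity).  Burden is the percent of ROI pixels at or above a fixed
per-stain threshold, averaged over the ten grid-sampled ROIs of a slide.
Thresholds are explicit config values for reproducibility, not adaptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roi import ROI

__all__ = [
    "StainImage",
    "DEFAULT_THRESHOLDS",
    "read_stain_image",
    "percent_area",
    "slide_mean_burden",
]

STAINS = ("tau_AT8", "TDP43", "beta_amyloid", "PLP")

# package defaults on the 0-255 scale; override per study in the config
DEFAULT_THRESHOLDS = {s: 128.0 for s in STAINS}


@dataclass
class StainImage:
    pixels: np.ndarray  # 2-D intensity grid
    stain: str
    case_id: str = ""

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ValueError("stain image must be a 2-D single-channel grid")
        if not np.all(np.isfinite(p)) or p.min() < 0:
            raise ValueError("stain image intensities must be finite and >= 0")
        if self.stain not in STAINS:
            raise ValueError(f"unknown stain {self.stain!r}; expected one of {STAINS}")
        self.pixels = p


def read_stain_image(path: str, stain: str, case_id: str = "") -> StainImage:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # accept greyscale stored with a trailing channel axis
        if arr.shape[2] != 1:
            raise ValueError("stain images must be single-channel")
        arr = arr[..., 0]
    return StainImage(arr, stain, case_id)


def percent_area(img: StainImage, roi: ROI, threshold: float) -> float:
    """100 x (ROI pixels with intensity >= threshold) / (ROI pixel count)."""
    rows, cols = roi.pixel_indices(img.pixels.shape)
    if rows.size == 0:
        raise ValueError(f"ROI {roi.label}: empty")
    positive = np.count_nonzero(img.pixels[rows, cols] >= threshold)
    return 100.0 * positive / rows.size


def slide_mean_burden(records: pd.DataFrame | list[dict]) -> float:
    """Mean percent_area over the ROIs of one case/stain slide."""
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("no burden records to average")
    return float(df["percent_area"].mean())
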