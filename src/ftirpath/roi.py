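"""ROI extraction and averaging, hyperspectral intensity maps, and
grey/white-matter ratios.

Coordinate convention: (row, col), 0-based, row 0 = top; rectangles are
half-open [r0, r1) x [c0, c1).  ROI "matching" across modalities is by
shared (case_id, roi_label) keys, mirroring manual alignment; no image
registration is performed.

Per-ROI quantities are computed on the ROI-mean spectrum (spectra are
averaged first to suppress pixel noise, then preprocessed and quantified).
Intensity maps use baseline-corrected but non-normalized absorbance, so
grey/white contrast is preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import BandDefinition, BandLibrary, RatioDefinition, integrate_band, quantify_spectrum
from .spectral import (
    HyperspectralCube,
    PreprocessConfig,
    Spectrum,
    preprocess_pipeline,
    rubber_band_baseline,
)

__all__ = [
    "ROI",
    "ROISet",
    "roi_mean_spectrum",
    "intensity_map",
    "quantify_rois",
    "gm_wm_ratio",
    "gm_wm_pair_ratios",
    "read_roiset_json",
    "write_roiset_json",
]

GM = "GM"
WM = "WM"


@dataclass(frozen=True)
class ROI:
    """A labelled pixel region, either an axis-aligned rectangle
    [r0, r1) x [c0, c1) or an explicit pixel list."""

    label: str
    tissue_class: str  # "GM" | "WM"
    rect: tuple[int, int, int, int] | None = None  # r0, c0, r1, c1
    pixels: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.tissue_class not in (GM, WM):
            raise ValueError(f"ROI {self.label}: tissue_class must be GM or WM")
        if (self.rect is None) == (self.pixels is None):
            raise ValueError(f"ROI {self.label}: give exactly one of rect/pixels")
        if self.rect is not None:
            r0, c0, r1, c1 = self.rect
            if not (r0 < r1 and c0 < c1):
                raise ValueError(f"ROI {self.label}: empty rectangle")

    def pixel_indices(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        h, w = shape
        if self.rect is not None:
            r0, c0, r1, c1 = self.rect
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValueError(f"ROI {self.label}: rectangle outside cube bounds")
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                                 indexing="ij")
            return rr.ravel(), cc.ravel()
        px = np.asarray(self.pixels, dtype=int)
        if px.size == 0:
            raise ValueError(f"ROI {self.label}: no pixels")
        if px[:, 0].min() < 0 or px[:, 0].max() >= h or \
           px[:, 1].min() < 0 or px[:, 1].max() >= w:
            raise ValueError(f"ROI {self.label}: pixels outside cube bounds")
        # canonical (row, col) order so aggregates are permutation-invariant
        order = np.lexsort((px[:, 1], px[:, 0]))
        px = px[order]
        return px[:, 0], px[:, 1]

    def n_pixels(self, shape: tuple[int, int]) -> int:
        rows, _ = self.pixel_indices(shape)
        return rows.size


@dataclass
class ROISet:
    case_id: str
    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self):
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique within a case")

    def by_class(self, tissue_class: str) -> list[ROI]:
        return [r for r in self.rois if r.tissue_class == tissue_class]


def write_roiset_json(rs: ROISet, path: str) -> None:
    doc = {
        "comment": "coordinates are (row, col), 0-based, row 0 = top; "
                   "rect = [r0, c0, r1, c1], half-open",
        "case_id": rs.case_id,
        "rois": [
            {"label": r.label, "tissue_class": r.tissue_class,
             **({"rect": list(r.rect)} if r.rect is not None
                else {"pixels": [list(p) for p in r.pixels]})}
            for r in rs.rois
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_roiset_json(path: str) -> ROISet:
    with open(path) as fh:
        doc = json.load(fh)
    rois = []
    for r in doc["rois"]:
        rois.append(ROI(
            r["label"], r["tissue_class"],
            rect=tuple(r["rect"]) if "rect" in r else None,
            pixels=tuple(tuple(p) for p in r["pixels"]) if "pixels" in r else None,
        ))
    return ROISet(doc["case_id"], rois)


# ---------------------------------------------------------------------------
# operations


def roi_mean_spectrum(cube: HyperspectralCube, roi: ROI) -> Spectrum:
    """Channel-wise arithmetic mean over the ROI's valid pixels."""
    rows, cols = roi.pixel_indices((cube.height, cube.width))
    ok = cube.valid_mask[rows, cols]
    if not np.any(ok):
        raise ValueError(f"ROI {roi.label}: all pixels are masked")
    rows, cols = rows[ok], cols[ok]
    mean = np.asarray(cube.data[rows, cols], dtype=float).mean(axis=0)
    return Spectrum(cube.axis, mean, ("raw",),
                    meta={"roi": roi.label, "tissue_class": roi.tissue_class,
                          "n_pixels": int(rows.size)})


def intensity_maps(cube: HyperspectralCube, bands: Sequence[BandDefinition],
                   cfg: PreprocessConfig | None = None) -> dict[str, np.ndarray]:
    """Per-pixel band areas (AU * cm-1) on baseline-corrected spectra for
    several bands in one baseline pass.  Masked pixels are NaN."""
    cfg = cfg or PreprocessConfig()
    out = {b.name: np.full((cube.height, cube.width), np.nan) for b in bands}
    template = cube.pixel_spectrum(0, 0)
    # excision once on the template to get the retained-channel mask
    from .spectral import excise_region

    work = template
    for lo, hi in cfg.excise_windows:
        work = excise_region(work, lo, hi)
    keep = np.isin(cube.axis.values, work.wavenumbers)
    rows, cols = np.nonzero(cube.valid_mask)
    for r, c in zip(rows, cols):
        s = Spectrum(work.axis, np.asarray(cube.data[r, c], float)[keep],
                     ("raw",), work.segments)
        _, corrected = rubber_band_baseline(s)
        for b in bands:
            out[b.name][r, c] = integrate_band(corrected, b)
    return out


def intensity_map(cube: HyperspectralCube, band: BandDefinition,
                  cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Per-pixel band area map for a single band (see ``intensity_maps``)."""
    return intensity_maps(cube, [band], cfg)[band.name]


def quantify_rois(cube: HyperspectralCube, roiset: ROISet, lib: BandLibrary,
                  ratios: Sequence[RatioDefinition],
                  cfg: PreprocessConfig | None = None) -> pd.DataFrame:
    """One table row per ROI: mean spectrum -> preprocess -> areas/ratios/peaks.

    Per-ROI failures are logged into an ``error`` column and leave the
    quantity columns missing rather than aborting the whole table.
    """
    cfg = cfg or PreprocessConfig()
    records = []
    for roi in roiset.rois:
        rec: dict = {"case_id": roiset.case_id, "roi_label": roi.label,
                     "tissue_class": roi.tissue_class}
        try:
            mean = roi_mean_spectrum(cube, roi)
            rec["n_pixels"] = mean.meta["n_pixels"]
            pre = preprocess_pipeline(mean, cfg)
            rec.update(quantify_spectrum(pre, lib, ratios))
        except ValueError as exc:
            rec["error"] = str(exc)
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    if "error" not in df.columns:
        df["error"] = ""
    return df


def gm_wm_ratio(quant: pd.DataFrame, quantity: str) -> pd.Series:
    """Per-case ratio of the GM-ROI mean to the WM-ROI mean of a quantity."""
    if quantity not in quant.columns:
        raise KeyError(f"unknown quantity {quantity!r}")
    out = {}
    for case_id, sub in quant.groupby("case_id"):
        gm = sub.loc[sub["tissue_class"] == GM, quantity].dropna()
        wm = sub.loc[sub["tissue_class"] == WM, quantity].dropna()
        if gm.empty or wm.empty:
            raise ValueError(
                f"case {case_id}: needs at least one GM and one WM ROI with "
                f"{quantity!r} defined"
            )
        out[case_id] = float(gm.mean() / wm.mean())
    return pd.Series(out, name=f"gm_wm_{quantity}")


def gm_wm_pair_ratios(quant: pd.DataFrame, quantity: str) -> pd.DataFrame:
    """Per matched GM/WM ROI pair ratios (pairing by rank order of labels
    within each tissue class), for distribution-level comparisons."""
    rows = []
    for case_id, sub in quant.groupby("case_id"):
        gm = sub[sub["tissue_class"] == GM].sort_values("roi_label")
        wm = sub[sub["tissue_class"] == WM].sort_values("roi_label")
        for i, ((_, g), (_, w)) in enumerate(zip(gm.iterrows(), wm.iterrows())):
            rows.append({"case_id": case_id, "pair": i,
                         "gm_roi": g["roi_label"], "wm_roi": w["roi_label"],
                         quantity: g[quantity] / w[quantity]})
    return pd.DataFrame(rows)
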