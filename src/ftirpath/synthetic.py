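"""Synthetic four-case FTIR study generator with closed-form ground truth.

Emulates the study design: four FFPE brain-tissue cases (CONTROL, FTLD_TDP,
FTLD_TDP_AD, AD), each imaged as a hyperspectral cube with a grey-matter and
a white-matter territory, 10 + 10 matched ROIs of 1,000 pixels, and matched
immunohistochemistry burden tables.  Every per-pixel spectrum is a sum of
Gaussian absorption bands (per-tissue amplitude, per-case center shifts) on
an affine baseline plus i.i.d. Gaussian noise, so all downstream quantities
have closed-form ground truth.

Programmed case contrasts (direction only, mirroring the study's findings):

* beta-sheet (1625 cm-1) second-derivative intensity high in both FTLD
  cases, highest in grey-matter FTLD_TDP_AD;
* CH2 asymmetric stretch at 2918 cm-1 in the control, shifted to 2923 cm-1
  in all three disease cases; alpha-helix shifted 1652 -> 1660 cm-1 in
  FTLD_TDP_AD only;
* grey/white lipid and amide-I intensity ratios lower in every disease case
  than in the control;
* amide I/II elevated in disease (highest in FTLD_TDP_AD grey matter);
* TDP-43 burden high in the FTLD cases only, tau (AT8) high in FTLD_TDP_AD
  and AD only, with burden linearly coupled to amide I/II ground truth so
  the pooled FTIR-histology Spearman correlations are positive.

Effect sizes are chosen so the directional contrasts are significant with
the exact Mann-Whitney test at n = 10 ROIs per group; they are not
estimates of real effect magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bands import BandLibrary, RatioDefinition, default_band_library, default_ratios
from .roi import GM, WM, ROI, ROISet
from .spectral import HyperspectralCube, Spectrum, WavenumberAxis

__all__ = [
    "CASE_IDS",
    "BandParams",
    "SyntheticCaseSpec",
    "StudyLayout",
    "GroundTruth",
    "StainCoupling",
    "default_grid",
    "default_study_specs",
    "default_couplings",
    "case_template_spectrum",
    "generate_cube",
    "generate_burden",
    "generate_stain_image",
]

CASE_IDS = ("CONTROL", "FTLD_TDP", "FTLD_TDP_AD", "AD")

GRID_LO = 950.0
GRID_HI = 3900.0
GRID_STEP = 1.0


def default_grid() -> np.ndarray:
    """Default synthetic axis: 950..3900 cm-1 at 1 cm-1 spacing.

    1 cm-1 puts every literature peak used here (1625, 1652, 1660, 1680,
    1695, 1740, 2850, 2918, 2923, 3010 cm-1) exactly on-grid, so
    grid-resolution peak checks are exact.
    """
    return np.arange(GRID_LO, GRID_HI + GRID_STEP / 2, GRID_STEP)


@dataclass(frozen=True)
class BandParams:
    center: float   # cm-1
    sigma: float    # cm-1
    amp_gm: float   # AU
    amp_wm: float   # AU

    def amp(self, tissue: str) -> float:
        return self.amp_gm if tissue == GM else self.amp_wm


@dataclass
class SyntheticCaseSpec:
    case_id: str
    band_table: dict[str, BandParams]
    baseline: tuple[float, float]  # offset AU, slope AU per cm-1 (vs nu-950)
    noise_sd: float
    shift_table: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.case_id not in CASE_IDS:
            raise ValueError(f"unknown case_id {self.case_id!r}")
        for name, bp in self.band_table.items():
            if bp.amp_gm < 0 or bp.amp_wm < 0:
                raise ValueError(f"band {name}: amplitudes must be >= 0")
            if bp.sigma < 2 * GRID_STEP:
                raise ValueError(f"band {name}: sigma must be >= 2 grid steps")

    def center(self, band: str) -> float:
        return self.band_table[band].center + self.shift_table.get(band, 0.0)


@dataclass(frozen=True)
class StudyLayout:
    """Cube geometry: GM territory on top, WM below, ROIs sampled inside.

    64 x 64 pixels by default (configurable up to the instrument's
    128 x 128) with 25 x 40 = 1,000-pixel ROI rectangles; random ROIs may
    overlap, as randomly selected regions on a slide do.
    """

    height: int = 64
    width: int = 64
    gm_rows: tuple[int, int] = (0, 32)
    wm_rows: tuple[int, int] = (32, 64)
    roi_shape: tuple[int, int] = (25, 40)
    n_per_class: int = 10

    def territory(self, tissue: str) -> tuple[int, int]:
        return self.gm_rows if tissue == GM else self.wm_rows

    def validate(self) -> None:
        rh, rw = self.roi_shape
        for tissue in (GM, WM):
            r0, r1 = self.territory(tissue)
            if r1 - r0 < rh or self.width < rw:
                raise ValueError(
                    f"{tissue} territory cannot hold a {rh}x{rw} ROI"
                )


# ---------------------------------------------------------------------------
# case roster


_SIGMA = {
    "alpha_helix": 7.0, "beta_sheet": 5.0, "unordered": 4.0,
    "beta_high_1680": 5.0, "beta_high_1695": 4.0, "amide_II": 16.0,
    "PO2": 12.0, "PO2_sym": 11.0, "CH2_sym": 7.0, "CH2_asym": 8.0,
    "CH3": 8.0, "olefinic": 5.0, "carboxyl": 9.0,
}

_CENTER = {
    "alpha_helix": 1652.0, "beta_sheet": 1625.0, "unordered": 1645.0,
    "beta_high_1680": 1680.0, "beta_high_1695": 1695.0, "amide_II": 1545.0,
    "PO2": 1240.0, "PO2_sym": 1080.0, "CH2_sym": 2850.0, "CH2_asym": 2918.0,
    "CH3": 2960.0, "olefinic": 3010.0, "carboxyl": 1740.0,
}

# (amp GM, amp WM) per band per case
_AMPLITUDES: dict[str, dict[str, tuple[float, float]]] = {
    "CONTROL": {
        "alpha_helix": (0.85, 0.60), "beta_sheet": (0.10, 0.10),
        "unordered": (0.09, 0.07), "beta_high_1680": (0.06, 0.05),
        "beta_high_1695": (0.04, 0.03), "amide_II": (0.60, 0.42),
        "PO2": (0.28, 0.24), "PO2_sym": (0.20, 0.17),
        "CH2_sym": (0.38, 0.62), "CH2_asym": (0.55, 0.95),
        "CH3": (0.22, 0.38), "olefinic": (0.050, 0.080),
        "carboxyl": (0.060, 0.100),
    },
    "FTLD_TDP": {
        "alpha_helix": (0.55, 0.55), "beta_sheet": (0.45, 0.40),
        "unordered": (0.09, 0.07), "beta_high_1680": (0.10, 0.08),
        "beta_high_1695": (0.06, 0.05), "amide_II": (0.48, 0.34),
        "PO2": (0.13, 0.11), "PO2_sym": (0.12, 0.10),
        "CH2_sym": (0.24, 0.52), "CH2_asym": (0.36, 0.80),
        "CH3": (0.15, 0.33), "olefinic": (0.065, 0.080),
        "carboxyl": (0.110, 0.160),
    },
    "FTLD_TDP_AD": {
        "alpha_helix": (0.50, 0.55), "beta_sheet": (0.60, 0.42),
        "unordered": (0.04, 0.03), "beta_high_1680": (0.20, 0.20),
        "beta_high_1695": (0.09, 0.07), "amide_II": (0.42, 0.30),
        "PO2": (0.11, 0.09), "PO2_sym": (0.10, 0.08),
        "CH2_sym": (0.20, 0.42), "CH2_asym": (0.30, 0.66),
        "CH3": (0.12, 0.28), "olefinic": (0.070, 0.085),
        "carboxyl": (0.130, 0.180),
    },
    "AD": {
        "alpha_helix": (0.75, 0.60), "beta_sheet": (0.14, 0.12),
        "unordered": (0.05, 0.04), "beta_high_1680": (0.07, 0.05),
        "beta_high_1695": (0.05, 0.03), "amide_II": (0.52, 0.38),
        "PO2": (0.16, 0.14), "PO2_sym": (0.13, 0.11),
        "CH2_sym": (0.26, 0.50), "CH2_asym": (0.40, 0.86),
        "CH3": (0.17, 0.34), "olefinic": (0.040, 0.048),
        "carboxyl": (0.045, 0.095),
    },
}

_BASELINES = {
    "CONTROL": (0.12, 2.0e-5),
    "FTLD_TDP": (0.15, 2.5e-5),
    "FTLD_TDP_AD": (0.18, 3.0e-5),
    "AD": (0.10, 1.5e-5),
}

# disease peak shifts (cm-1): CH2 asym 2918 -> 2923 in all disease cases,
# alpha-helix 1652 -> 1660 in the mixed-pathology case only
_SHIFTS = {
    "CONTROL": {},
    "FTLD_TDP": {"CH2_asym": 5.0},
    "FTLD_TDP_AD": {"CH2_asym": 5.0, "alpha_helix": 8.0},
    "AD": {"CH2_asym": 5.0},
}

DEFAULT_NOISE_SD = 0.005  # AU per pixel per channel


def default_study_specs(seed: int = 0,
                        noise_sd: float = DEFAULT_NOISE_SD) -> list[SyntheticCaseSpec]:
    """The four study cases with the default amplitude/shift tables."""
    specs = []
    for case in CASE_IDS:
        table = {
            name: BandParams(_CENTER[name], _SIGMA[name], *_AMPLITUDES[case][name])
            for name in _CENTER
        }
        specs.append(SyntheticCaseSpec(
            case_id=case, band_table=table, baseline=_BASELINES[case],
            noise_sd=noise_sd, shift_table=dict(_SHIFTS[case]), seed=seed,
        ))
    return specs


def _case_rng(spec: SyntheticCaseSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        [spec.seed, CASE_IDS.index(spec.case_id), stream]
    )


# ---------------------------------------------------------------------------
# closed-form model


def model_absorbance(spec: SyntheticCaseSpec, tissue: str,
                     x: np.ndarray) -> np.ndarray:
    """Band model (no baseline, no noise) evaluated at wavenumbers x."""
    y = np.zeros_like(np.asarray(x, float))
    for name, bp in spec.band_table.items():
        c = spec.center(name)
        y += bp.amp(tissue) * np.exp(-((x - c) ** 2) / (2 * bp.sigma ** 2))
    return y


def model_second_derivative(spec: SyntheticCaseSpec, tissue: str,
                            x: np.ndarray) -> np.ndarray:
    """Analytic d2/dnu2 of the band model."""
    x = np.asarray(x, float)
    y = np.zeros_like(x)
    for name, bp in spec.band_table.items():
        c = spec.center(name)
        u = (x - c) / bp.sigma
        y += (bp.amp(tissue) / bp.sigma ** 2) * (u ** 2 - 1.0) * np.exp(-u ** 2 / 2)
    return y


def model_window_area(spec: SyntheticCaseSpec, tissue: str,
                      lo: float, hi: float) -> float:
    """Exact integral of the band model over [lo, hi] (erf closed form)."""
    total = 0.0
    for name, bp in spec.band_table.items():
        c = spec.center(name)
        total += bp.amp(tissue) * bp.sigma * np.sqrt(2 * np.pi) * (
            norm.cdf((hi - c) / bp.sigma) - norm.cdf((lo - c) / bp.sigma)
        )
    return float(total)


def case_template_spectrum(spec: SyntheticCaseSpec, tissue: str,
                           grid: np.ndarray | None = None) -> Spectrum:
    """Noise-free per-pixel template (bands + affine baseline)."""
    x = default_grid() if grid is None else np.asarray(grid, float)
    off, slope = spec.baseline
    y = model_absorbance(spec, tissue, x) + off + slope * (x - x[0])
    return Spectrum(WavenumberAxis(x), y, ("raw",),
                    meta={"case_id": spec.case_id, "tissue_class": tissue,
                          "synthetic_template": True})


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Closed-form expectations for one synthetic case.

    ``component_areas`` are isolated-band areas a*sigma*sqrt(2*pi);
    ``window_areas`` integrate the full model over each library band window
    (what the pipeline measures); ``deriv_depths``/``peak_positions`` come
    from the analytic model second derivative on the grid; ``ratios`` follow
    the ratio definitions on the windowed/model quantities.
    """

    case_id: str
    component_areas: dict[str, dict[str, float]]
    window_areas: dict[str, dict[str, float]]
    deriv_depths: dict[str, dict[str, float]]
    peak_positions: dict[str, dict[str, float]]
    ratios: dict[str, dict[str, float]]
    burden_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def compute_ground_truth(spec: SyntheticCaseSpec,
                         lib: BandLibrary | None = None,
                         ratios: Sequence[RatioDefinition] | None = None,
                         grid: np.ndarray | None = None) -> GroundTruth:
    lib = lib or default_band_library()
    ratios = ratios if ratios is not None else default_ratios()
    x = default_grid() if grid is None else np.asarray(grid, float)
    comp: dict[str, dict[str, float]] = {}
    wins: dict[str, dict[str, float]] = {}
    depths: dict[str, dict[str, float]] = {}
    peaks: dict[str, dict[str, float]] = {}
    rvals: dict[str, dict[str, float]] = {}
    for tissue in (GM, WM):
        comp[tissue] = {
            name: float(bp.amp(tissue) * bp.sigma * np.sqrt(2 * np.pi))
            for name, bp in spec.band_table.items()
        }
        d2 = model_second_derivative(spec, tissue, x)
        wins[tissue] = {}
        depths[tissue] = {}
        peaks[tissue] = {}
        for band in lib:
            lo, hi = band.window
            wins[tissue][band.name] = model_window_area(spec, tissue, lo, hi)
            if band.mode == "deriv_peak":
                idx = np.nonzero((x >= lo) & (x <= hi))[0]
                k = idx[np.argmin(d2[idx])]
                peaks[tissue][band.name] = float(x[k])
                depths[tissue][band.name] = float(abs(d2[k]))
        rvals[tissue] = {}
        for r in ratios:
            if r.basis == "area":
                num = wins[tissue][r.numerator]
                den = wins[tissue][r.denominator]
            else:
                num = depths[tissue][r.numerator]
                den = depths[tissue][r.denominator]
            rvals[tissue][r.name] = num / den if abs(den) > 1e-12 else float("nan")
    return GroundTruth(spec.case_id, comp, wins, depths, peaks, rvals)


# ---------------------------------------------------------------------------
# cube / ROI / burden generation


def _sample_rois(layout: StudyLayout, rng: np.random.Generator) -> list[ROI]:
    rois = []
    rh, rw = layout.roi_shape
    for tissue in (GM, WM):
        r0, r1 = layout.territory(tissue)
        for i in range(layout.n_per_class):
            rr = int(rng.integers(r0, r1 - rh + 1))
            cc = int(rng.integers(0, layout.width - rw + 1))
            rois.append(ROI(f"{tissue}_{i + 1:02d}", tissue,
                            rect=(rr, cc, rr + rh, cc + rw)))
    return rois


def _check_roi_in_territory(roi: ROI, layout: StudyLayout) -> None:
    r0, r1 = layout.territory(roi.tissue_class)
    rr0, _, rr1, _ = roi.rect
    if rr0 < r0 or rr1 > r1:
        raise ValueError(
            f"ROI {roi.label} lies outside the {roi.tissue_class} territory"
        )


def generate_cube(spec: SyntheticCaseSpec,
                  layout: StudyLayout | None = None,
                  lib: BandLibrary | None = None,
                  artifact_rect: tuple[int, int, int, int] | None = None,
                  ) -> tuple[HyperspectralCube, ROISet, GroundTruth]:
    """Simulate one case: cube + ROI layout + closed-form ground truth.

    Deterministic given (spec, layout): the random stream is keyed by
    (spec.seed, case index) and consumed in a fixed order (ROI placement,
    then noise).
    """
    layout = layout or StudyLayout()
    layout.validate()
    x = default_grid()
    frac = (np.array([spec.center(b) for b in spec.band_table])
            - x[0]) % GRID_STEP
    if not np.all(np.minimum(frac, GRID_STEP - frac) < 1e-9):
        raise ValueError("band centers (incl. shifts) must lie on the grid")
    rng = _case_rng(spec, stream=0)
    rois = _sample_rois(layout, rng)
    for roi in rois:
        _check_roi_in_territory(roi, layout)
    off, slope = spec.baseline
    base = off + slope * (x - x[0])
    data = np.empty((layout.height, layout.width, x.size), dtype=np.float32)
    for tissue in (GM, WM):
        r0, r1 = layout.territory(tissue)
        template = (model_absorbance(spec, tissue, x) + base).astype(np.float32)
        data[r0:r1] = template[None, None, :]
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape,
                                                    dtype=np.float32)
    mask = np.ones((layout.height, layout.width), dtype=bool)
    if artifact_rect is not None:
        ar0, ac0, ar1, ac1 = artifact_rect
        mask[ar0:ar1, ac0:ac1] = False
    cube = HyperspectralCube(WavenumberAxis(x), data, mask,
                             meta={"case_id": spec.case_id, "seed": spec.seed})
    truth = compute_ground_truth(spec, lib)
    return cube, ROISet(spec.case_id, rois), truth


@dataclass(frozen=True)
class StainCoupling:
    """Linear link from a ground-truth FTIR ratio to stain percent area.

    percent_area(ROI) = intercept(case, tissue) + slope * ratio_truth
                        + N(0, noise_sd), clipped to [0, 100].
    ``intercept`` is a scalar or a {case: (gm, wm)} mapping; ``ratio`` may
    be None for stains not coupled to a spectral index (slope ignored).
    """

    stain: str
    ratio: str | None
    slope: float
    noise_sd: float
    intercept: float | Mapping[str, tuple[float, float]] = 0.0

    def intercept_for(self, case_id: str, tissue: str) -> float:
        if isinstance(self.intercept, Mapping):
            pair = self.intercept[case_id]
            return pair[0] if tissue == GM else pair[1]
        return float(self.intercept)


# target slide-mean burden (%): (GM, WM) per case; Fig-2-style pattern
_BURDEN_TARGETS = {
    "TDP43": {"CONTROL": (0.4, 0.3), "FTLD_TDP": (28.0, 20.0),
              "FTLD_TDP_AD": (30.0, 22.0), "AD": (0.9, 0.6)},
    "tau_AT8": {"CONTROL": (0.4, 0.3), "FTLD_TDP": (1.2, 0.8),
                "FTLD_TDP_AD": (30.0, 18.0), "AD": (26.0, 3.0)},
    "beta_amyloid": {"CONTROL": (0.1, 0.1), "FTLD_TDP": (2.0, 0.5),
                     "FTLD_TDP_AD": (18.0, 6.0), "AD": (15.0, 5.0)},
    "PLP": {"CONTROL": (12.0, 55.0), "FTLD_TDP": (11.0, 52.0),
            "FTLD_TDP_AD": (8.0, 45.0), "AD": (11.0, 50.0)},
}


def default_couplings(specs: Sequence[SyntheticCaseSpec] | None = None,
                      lib: BandLibrary | None = None) -> list[StainCoupling]:
    """Study couplings: pathology stains track amide I/II (slope > 0) around
    the per-case target means; amyloid and myelin are uncoupled."""
    specs = specs or default_study_specs()
    truths = {s.case_id: compute_ground_truth(s, lib) for s in specs}

    def _intercepts(stain: str, ratio: str, slope: float):
        out = {}
        for case, (g, w) in _BURDEN_TARGETS[stain].items():
            rt = truths[case].ratios
            out[case] = (g - slope * rt[GM][ratio], w - slope * rt[WM][ratio])
        return out

    return [
        StainCoupling("TDP43", "amide_I_II", 5.0, 2.0,
                      _intercepts("TDP43", "amide_I_II", 5.0)),
        StainCoupling("tau_AT8", "amide_I_II", 5.0, 2.0,
                      _intercepts("tau_AT8", "amide_I_II", 5.0)),
        StainCoupling("beta_amyloid", None, 0.0, 1.0,
                      {c: v for c, v in _BURDEN_TARGETS["beta_amyloid"].items()}),
        StainCoupling("PLP", None, 0.0, 2.5,
                      {c: v for c, v in _BURDEN_TARGETS["PLP"].items()}),
    ]


def generate_burden(spec: SyntheticCaseSpec, roiset: ROISet,
                    couplings: Sequence[StainCoupling],
                    truth: GroundTruth | None = None) -> pd.DataFrame:
    """Per-ROI stain burden table matched to the ROI layout by label keys."""
    truth = truth or compute_ground_truth(spec)
    rng = _case_rng(spec, stream=1)
    rows = []
    for coupling in couplings:
        for roi in roiset.rois:
            tissue = roi.tissue_class
            val = coupling.intercept_for(spec.case_id, tissue)
            if coupling.ratio is not None:
                val += coupling.slope * truth.ratios[tissue][coupling.ratio]
            if coupling.noise_sd > 0:
                val += rng.normal(0.0, coupling.noise_sd)
            rows.append({
                "case_id": spec.case_id, "roi_label": roi.label,
                "tissue_class": tissue, "stain": coupling.stain,
                "percent_area": float(np.clip(val, 0.0, 100.0)),
            })
    return pd.DataFrame(rows)


def recovery_errors(seeds: Sequence[int],
                    lib: BandLibrary | None = None,
                    ratios: Sequence[RatioDefinition] | None = None,
                    noise_sd: float = DEFAULT_NOISE_SD) -> np.ndarray:
    """Absolute relative errors of pipeline-recovered band areas and ratios
    against closed-form ground truth, over full default studies at the
    given seeds.  One entry per (seed, case, tissue, quantity)."""
    from .roi import quantify_rois

    lib = lib or default_band_library()
    ratios = ratios if ratios is not None else default_ratios()
    errs = []
    for seed in seeds:
        for spec in default_study_specs(seed=seed, noise_sd=noise_sd):
            cube, roiset, truth = generate_cube(spec, lib=lib)
            quant = quantify_rois(cube, roiset, lib, ratios)
            for tissue in (GM, WM):
                sub = quant[quant["tissue_class"] == tissue]
                for band in lib:
                    gt = truth.window_areas[tissue][band.name]
                    meas = sub[f"area_{band.name}"].mean()
                    errs.append(abs(meas - gt) / abs(gt))
                for r in ratios:
                    gt = truth.ratios[tissue][r.name]
                    meas = sub[f"ratio_{r.name}"].mean()
                    errs.append(abs(meas - gt) / abs(gt))
    return np.asarray(errs)


def generate_stain_image(shape: tuple[int, int], roiset: ROISet,
                         burden: pd.DataFrame, stain: str,
                         threshold: float = 128.0,
                         seed: int = 0) -> np.ndarray:
    """Synthetic single-channel positivity map whose per-ROI percent area at
    ``threshold`` reproduces the burden table (to rounding of pixel counts).

    Overlapping ROIs are painted in label order, so exact agreement is
    guaranteed only for non-overlapping layouts; used for round-trip tests
    of the threshold quantification.
    """
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=np.uint8)
    sub = burden[burden["stain"] == stain].set_index("roi_label")
    for roi in roiset.rois:
        rows, cols = roi.pixel_indices(shape)
        pct = float(sub.loc[roi.label, "percent_area"])
        n_pos = int(round(pct / 100.0 * rows.size))
        pick = rng.choice(rows.size, size=n_pos, replace=False)
        img[rows, cols] = max(0, int(threshold) - 28)  # background below threshold
        img[rows[pick], cols[pick]] = 255
    return img
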