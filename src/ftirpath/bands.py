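"""Declarative band library, band-area integration, functional-group ratios
and second-derivative peak analysis.

Band positions follow the standard mid-infrared assignments for tissue:
amide I 1600-1700 and amide II 1500-1600 cm-1 (protein backbone), amide-I
secondary-structure sub-bands (beta-sheet ~1625, unordered ~1645, alpha-helix
~1652, high-wavenumber beta ~1680/1695), asymmetric phosphate ~1240,
symmetric phosphate ~1080, total lipids 2800-3000 (CH2 2850/2920, CH3
~2960), olefinic =C-H ~3010 and carbonyl C=O ~1740 cm-1.  Windows not fixed
by convention are editable defaults in the library config.

Absorption maxima appear as second-derivative minima, so a "peak" on the
derivative branch is the most negative channel inside the band window.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .spectral import PreprocessResult, Spectrum, second_derivative

__all__ = [
    "BandDefinition",
    "BandLibrary",
    "RatioDefinition",
    "PeakReport",
    "default_band_library",
    "default_ratios",
    "load_band_config",
    "integrate_band",
    "compute_ratios",
    "detect_peak",
    "detect_shift",
    "quantify_spectrum",
]

AREA = "area"
DERIV_PEAK = "deriv_peak"
DERIV_MAG = "deriv_peak_magnitude"

UNDEFINED_DENOMINATOR = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    name: str
    window: tuple[float, float]
    assignment: str = ""
    nominal_peak: float | None = None
    mode: str = AREA

    def __post_init__(self):
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"band {self.name}: window lo must be < hi")
        if self.nominal_peak is not None and not lo <= self.nominal_peak <= hi:
            raise ValueError(f"band {self.name}: nominal peak outside window")
        if self.mode not in (AREA, DERIV_PEAK):
            raise ValueError(f"band {self.name}: unknown mode {self.mode!r}")


@dataclass(frozen=True)
class RatioDefinition:
    name: str
    numerator: str
    denominator: str
    basis: str = AREA

    def __post_init__(self):
        if self.basis not in (AREA, DERIV_MAG):
            raise ValueError(f"ratio {self.name}: unknown basis {self.basis!r}")


class BandLibrary:
    """Named collection of band definitions."""

    def __init__(self, bands: Sequence[BandDefinition]):
        self._bands: dict[str, BandDefinition] = {}
        for b in bands:
            if b.name in self._bands:
                raise ValueError(f"duplicate band name {b.name!r}")
            self._bands[b.name] = b

    def __getitem__(self, name: str) -> BandDefinition:
        try:
            return self._bands[name]
        except KeyError:
            raise KeyError(f"unknown band {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._bands

    def __iter__(self):
        return iter(self._bands.values())

    def __len__(self):
        return len(self._bands)

    def names(self):
        return list(self._bands)

    def validate_ratios(self, ratios: Sequence[RatioDefinition]) -> None:
        for r in ratios:
            for ref in (r.numerator, r.denominator):
                if ref not in self:
                    raise KeyError(
                        f"ratio {r.name!r} references unknown band {ref!r}"
                    )


def default_band_library() -> BandLibrary:
    """The study band set.  Windows without a conventional definition are
    package defaults and can be overridden through the config file."""
    return BandLibrary([
        BandDefinition("amide_I", (1600.0, 1700.0), "amide I (protein backbone C=O)"),
        BandDefinition("amide_II", (1500.0, 1600.0), "amide II (N-H bend / C-N stretch)"),
        BandDefinition("alpha_helix", (1645.0, 1665.0), "alpha-helix amide I sub-band",
                       1652.0, DERIV_PEAK),
        BandDefinition("beta_sheet", (1610.0, 1640.0), "beta-sheet amide I sub-band",
                       1625.0, DERIV_PEAK),
        BandDefinition("unordered", (1640.0, 1650.0), "unordered/random-coil shoulder",
                       1645.0, DERIV_PEAK),
        BandDefinition("beta_high_1680", (1670.0, 1690.0), "high-wavenumber beta",
                       1680.0, DERIV_PEAK),
        BandDefinition("beta_high_1695", (1688.0, 1702.0), "high-wavenumber beta",
                       1695.0, DERIV_PEAK),
        BandDefinition("PO2", (1220.0, 1260.0), "asymmetric phosphate stretch",
                       1240.0, AREA),
        BandDefinition("PO2_sym", (1060.0, 1100.0), "symmetric phosphate stretch",
                       1080.0, AREA),
        BandDefinition("total_lipids", (2800.0, 3000.0), "C-H stretching region"),
        BandDefinition("CH2_sym", (2840.0, 2870.0), "CH2 symmetric stretch",
                       2850.0, DERIV_PEAK),
        BandDefinition("CH2_asym", (2900.0, 2936.0), "CH2 asymmetric stretch",
                       2920.0, DERIV_PEAK),
        BandDefinition("CH3", (2950.0, 2975.0), "CH3 stretch", 2960.0, AREA),
        BandDefinition("olefinic", (3000.0, 3020.0), "olefinic =C-H stretch",
                       3010.0, AREA),
        BandDefinition("carboxyl", (1725.0, 1755.0), "carbonyl C=O stretch",
                       1740.0, AREA),
    ])


def default_ratios() -> list[RatioDefinition]:
    """The seven study ratios.

    Area basis where the bands are separable windows; second-derivative
    peak-magnitude basis where the quantities are overlapping amide-I
    sub-bands that raw-area windows cannot separate.
    """
    return [
        RatioDefinition("amide_I_II", "amide_I", "amide_II", AREA),
        RatioDefinition("alpha_unordered", "alpha_helix", "unordered", DERIV_MAG),
        RatioDefinition("alpha_PO2", "alpha_helix", "PO2", AREA),
        RatioDefinition("olefinic_lipids", "olefinic", "total_lipids", AREA),
        RatioDefinition("carboxyl_lipids", "carboxyl", "total_lipids", AREA),
        RatioDefinition("CH3_lipids", "CH3", "total_lipids", AREA),
        RatioDefinition("alpha_beta", "alpha_helix", "beta_sheet", DERIV_MAG),
    ]


def load_band_config(path: str) -> tuple[BandLibrary, list[RatioDefinition]]:
    """Read a TOML or YAML band/ratio config.

    Layout::

        [band.amide_I]
        window = [1600, 1700]
        assignment = "amide I"
        peak = 1650          # optional
        mode = "area"        # or "deriv_peak"

        [ratio.amide_I_II]
        num = "amide_I"
        den = "amide_II"
        basis = "area"       # or "deriv_peak_magnitude"
    """
    if path.endswith((".yml", ".yaml")):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    bands = []
    for name, spec in (doc.get("band") or {}).items():
        bands.append(BandDefinition(
            name,
            tuple(float(v) for v in spec["window"]),
            spec.get("assignment", ""),
            float(spec["peak"]) if "peak" in spec else None,
            spec.get("mode", AREA),
        ))
    ratios = []
    for name, spec in (doc.get("ratio") or {}).items():
        ratios.append(RatioDefinition(name, spec["num"], spec["den"],
                                      spec.get("basis", AREA)))
    lib = BandLibrary(bands)
    lib.validate_ratios(ratios)
    return lib, ratios


# ---------------------------------------------------------------------------
# operations


def _window_channels(s: Spectrum, band: BandDefinition) -> np.ndarray:
    """Indices of channels inside the band window; the window must sit
    entirely inside one contiguous segment (never across an excised gap)."""
    lo, hi = band.window
    wn = s.wavenumbers
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(
            f"band {band.name}: window [{lo:g}, {hi:g}] lies outside the axis"
        )
    for a, b in s.segments:
        if wn[a] <= lo and hi <= wn[b - 1]:
            idx = np.nonzero((wn >= lo) & (wn <= hi))[0]
            if idx.size and a <= idx[0] and idx[-1] < b:
                return idx
    raise ValueError(
        f"band {band.name}: window [{lo:g}, {hi:g}] spans an excised gap"
    )


def integrate_band(s: Spectrum, band: BandDefinition) -> float:
    """Trapezoidal area under the absorbance curve over the band window
    (AU * cm-1).  Non-negative for baseline-corrected input."""
    idx = _window_channels(s, band)
    if idx.size < 2:
        raise ValueError(f"band {band.name}: fewer than 2 channels in window")
    return float(np.trapezoid(s.absorbance[idx], s.wavenumbers[idx]))


@dataclass(frozen=True)
class PeakReport:
    band: str
    position: float  # cm-1, grid channel of the second-derivative minimum
    depth: float     # |second derivative| at that channel


def detect_peak(sd: Spectrum, band: BandDefinition,
                edge_exclude: int | None = None) -> PeakReport:
    """Locate the absorption peak as the second-derivative minimum.

    ``sd`` must be a (possibly normalized) second-derivative spectrum.
    Positions are reported at grid resolution; ties break to the lowest
    wavenumber.  Channels within ``edge_exclude`` of a segment edge are
    skipped (default: the Savitzky-Golay half-window recorded on ``sd``).
    """
    if band.mode != DERIV_PEAK:
        raise ValueError(f"band {band.name} is not a deriv_peak band")
    idx = _window_channels(sd, band)
    if idx.size < 3:
        raise ValueError(f"band {band.name}: window has fewer than 3 channels")
    if edge_exclude is None:
        edge_exclude = (int(sd.meta.get("sg_window", 5)) - 1) // 2
    if edge_exclude:
        keep = np.ones(idx.size, dtype=bool)
        for a, b in sd.segments:
            keep &= (idx >= a + edge_exclude) & (idx < b - edge_exclude) | (
                (idx < a) | (idx >= b)
            )
        if not np.any(keep):
            raise ValueError(
                f"band {band.name}: window contains only segment-edge channels"
            )
        idx = idx[keep]
    vals = sd.absorbance[idx]
    k = int(np.argmin(vals))  # argmin returns the first = lowest wavenumber
    return PeakReport(band.name, float(sd.wavenumbers[idx[k]]),
                      float(abs(vals[k])))


def detect_shift(sd_case: Spectrum, sd_ref: Spectrum,
                 band: BandDefinition) -> float:
    """Peak shift (cm-1) of case vs reference; positive = toward higher
    wavenumber."""
    if sd_case.axis != sd_ref.axis:
        raise ValueError("shift detection requires spectra on a shared axis")
    return detect_peak(sd_case, band).position - detect_peak(sd_ref, band).position


def _deriv_magnitude(sd: Spectrum, band: BandDefinition) -> float:
    return detect_peak(sd, band).depth


def compute_ratios(corrected: Spectrum, lib: BandLibrary,
                   ratios: Sequence[RatioDefinition],
                   derivative: Spectrum | None = None) -> dict[str, float]:
    """Functional-group ratios on one spectrum.

    Area-basis ratios integrate the baseline-corrected branch; peak-magnitude
    ratios read second-derivative depths (``derivative`` is computed from
    ``corrected`` with default settings when not supplied).  A denominator
    below 1e-12 yields NaN (undefined), never +/-inf.
    """
    lib.validate_ratios(ratios)
    need_deriv = any(r.basis == DERIV_MAG for r in ratios)
    if need_deriv and derivative is None:
        derivative = second_derivative(corrected)
    out: dict[str, float] = {}
    cache_area: dict[str, float] = {}
    cache_depth: dict[str, float] = {}
    for r in ratios:
        if r.basis == AREA:
            num = cache_area.setdefault(
                r.numerator, integrate_band(corrected, lib[r.numerator]))
            den = cache_area.setdefault(
                r.denominator, integrate_band(corrected, lib[r.denominator]))
        else:
            num = cache_depth.setdefault(
                r.numerator, _deriv_magnitude(derivative, lib[r.numerator]))
            den = cache_depth.setdefault(
                r.denominator, _deriv_magnitude(derivative, lib[r.denominator]))
        out[r.name] = float("nan") if abs(den) < UNDEFINED_DENOMINATOR else num / den
    return out


def quantify_spectrum(pre: PreprocessResult, lib: BandLibrary,
                      ratios: Sequence[RatioDefinition]) -> dict[str, float]:
    """One flat record of band areas, ratios and peak positions for a
    preprocessed spectrum: ``area_<band>``, ``ratio_<name>``,
    ``peak_<band>`` and ``depth_<band>`` columns."""
    row: dict[str, float] = {}
    for band in lib:
        row[f"area_{band.name}"] = integrate_band(pre.corrected, band)
        if band.mode == DERIV_PEAK:
            rep = detect_peak(pre.derivative, band)
            row[f"peak_{band.name}"] = rep.position
            row[f"depth_{band.name}"] = rep.depth
    row.update({f"ratio_{k}": v for k, v in
                compute_ratios(pre.corrected, lib, ratios,
                               pre.derivative).items()})
    return row
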