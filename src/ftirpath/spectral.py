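"""Spectrum/cube data model and mid-infrared preprocessing operators.

The preprocessing chain mirrors common practice for FTIR microspectroscopy
of tissue sections: excision of the atmospheric CO2 band (2250-2400 cm-1),
rubber-band (lower convex hull) baseline correction, Savitzky-Golay second
differentiation (polynomial order 2, window 5 points) and vector
normalization.  Band areas are read from the baseline-corrected branch;
peak positions and shifts from the normalized second-derivative branch.

Axes are stored ascending in cm-1.  A spectrum may consist of several
contiguous segments after excision; every segment-aware operator (hull
baseline, differentiation, integration) treats segments independently and
never interpolates across an excised gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "HyperspectralCube",
    "PreprocessConfig",
    "PreprocessResult",
    "excise_region",
    "rubber_band_baseline",
    "second_derivative",
    "vector_normalize",
    "preprocess_pipeline",
]

WN_MIN = 400.0
WN_MAX = 8000.0


class WavenumberAxis:
    """A strictly monotonic sampling grid in cm-1, stored ascending."""

    __slots__ = ("values",)

    def __init__(self, values: Iterable[float]):
        v = np.asarray(values, dtype=float)
        if v.ndim != 1:
            raise ValueError("wavenumber axis must be one-dimensional")
        if v.size < 5:
            raise ValueError("wavenumber axis needs at least 5 channels")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavenumber axis contains non-finite values")
        d = np.diff(v)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):
            v = v[::-1].copy()
        else:
            raise ValueError("wavenumber axis must be strictly monotonic")
        if v[0] < WN_MIN or v[-1] > WN_MAX:
            raise ValueError(
                f"wavenumbers must lie within [{WN_MIN:g}, {WN_MAX:g}] cm-1"
            )
        self.values = v
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __repr__(self) -> str:
        return (
            f"WavenumberAxis({self.values[0]:g}..{self.values[-1]:g} cm-1, "
            f"{self.values.size} channels)"
        )


def _default_segments(n: int) -> tuple[tuple[int, int], ...]:
    return ((0, n),)


def infer_segments(values: np.ndarray, gap_factor: float = 1.5):
    """Split an ascending axis into contiguous segments at spacing jumps.

    Used when loading spectra whose excision history is unknown (e.g. CSV
    exports); freshly built spectra carry their segment bounds explicitly.
    """
    d = np.diff(values)
    step = np.median(d)
    cuts = np.nonzero(d > gap_factor * step)[0]
    bounds = []
    start = 0
    for c in cuts:
        bounds.append((start, c + 1))
        start = c + 1
    bounds.append((start, values.size))
    return tuple(bounds)


@dataclass
class Spectrum:
    """A single absorbance trace on a wavenumber axis.

    ``provenance`` is an ordered tuple of processing tags (``raw``,
    ``baseline_corrected``, ``second_derivative``, ``normalized`` ...);
    ``segments`` holds half-open index ranges of contiguous axis pieces.
    """

    axis: WavenumberAxis
    absorbance: np.ndarray
    provenance: tuple[str, ...] = ("raw",)
    segments: tuple[tuple[int, int], ...] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.axis, WavenumberAxis):
            self.axis = WavenumberAxis(self.axis)
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 1 or a.size != len(self.axis):
            raise ValueError("absorbance length must equal axis length")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        self.absorbance = a
        if self.segments is None:
            self.segments = _default_segments(len(self.axis))

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.axis.values

    def with_absorbance(self, values: np.ndarray, tag: str | None = None) -> "Spectrum":
        prov = self.provenance + (tag,) if tag else self.provenance
        return Spectrum(self.axis, np.asarray(values, float), prov,
                        self.segments, dict(self.meta))

    def segment_slices(self):
        return [slice(a, b) for a, b in self.segments]

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis, self.absorbance.copy(), self.provenance,
                        self.segments, dict(self.meta))


@dataclass
class HyperspectralCube:
    """H x W image of spectra sharing one axis, with a validity mask.

    ``valid_mask`` is False on artifact / off-tissue pixels; masked pixels
    are excluded from every aggregate downstream.
    """

    axis: WavenumberAxis
    data: np.ndarray  # H x W x K
    valid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.axis, WavenumberAxis):
            self.axis = WavenumberAxis(self.axis)
        d = np.asarray(self.data)
        if d.ndim != 3 or d.shape[2] != len(self.axis):
            raise ValueError("cube data must be H x W x K with K = axis length")
        self.data = d
        if self.valid_mask is None:
            self.valid_mask = np.ones(d.shape[:2], dtype=bool)
        else:
            m = np.asarray(self.valid_mask, dtype=bool)
            if m.shape != d.shape[:2]:
                raise ValueError("valid_mask shape must match cube H x W")
            self.valid_mask = m

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def pixel_spectrum(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, np.asarray(self.data[row, col], float),
                        ("raw",), meta={"row": row, "col": col})


# ---------------------------------------------------------------------------
# operators


def excise_region(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Remove all channels with lo <= wavenumber <= hi (e.g. the CO2 band).

    The result keeps a gap in the axis; nothing is interpolated across it.
    Idempotent, and a no-op when the window misses the axis entirely.
    """
    if not lo < hi:
        raise ValueError("excision window requires lo < hi")
    wn = s.wavenumbers
    keep = (wn < lo) | (wn > hi)
    if not np.any(keep):
        raise ValueError("excision would produce an empty spectrum")
    if np.all(keep):
        return s.copy()
    # remap segment bounds through the boolean keep vector
    pos = np.cumsum(keep) - 1  # new index of each kept channel
    new_bounds = []
    for a, b in s.segments:
        seg_keep = keep[a:b]
        if not np.any(seg_keep):
            continue
        kept_idx = np.nonzero(seg_keep)[0] + a
        # the excision may split this segment in two
        breaks = np.nonzero(np.diff(kept_idx) > 1)[0]
        start = 0
        for br in breaks:
            new_bounds.append((pos[kept_idx[start]], pos[kept_idx[br]] + 1))
            start = br + 1
        new_bounds.append((pos[kept_idx[start]], pos[kept_idx[-1]] + 1))
    return Spectrum(WavenumberAxis(wn[keep]), s.absorbance[keep],
                    s.provenance + (f"excised[{lo:g},{hi:g}]",),
                    tuple(new_bounds), dict(s.meta))


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Andrew monotone-chain lower hull of (x, y) with x strictly ascending."""
    idx: list[int] = []
    for i in range(x.size):
        while len(idx) >= 2:
            i1, i2 = idx[-2], idx[-1]
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (
                x[i] - x[i1]
            )
            if cross <= 0.0:  # i2 on or above the chord i1 -> i
                idx.pop()
            else:
                break
        idx.append(i)
    return idx


def rubber_band_baseline(s: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Rubber-band baseline: the lower convex hull of each contiguous segment.

    Returns ``(baseline, corrected)`` with ``corrected = absorbance -
    baseline``.  The hull is anchored at both segment endpoints, so the
    corrected trace is >= 0 everywhere and exactly 0 at hull vertices.
    Single pass; correcting an already-corrected spectrum is a no-op to
    numerical precision.
    """
    if len(s.axis) < 2:
        raise ValueError("baseline correction needs at least 2 channels")
    wn = s.wavenumbers
    base = np.empty_like(s.absorbance)
    for sl in s.segment_slices():
        x, y = wn[sl], s.absorbance[sl]
        if x.size == 1:
            base[sl] = y
            continue
        hull = _lower_hull_indices(x, y)
        base[sl] = np.interp(x, x[hull], y[hull])
    baseline = s.with_absorbance(base, None)
    baseline.provenance = s.provenance + ("baseline",)
    corrected = s.with_absorbance(s.absorbance - base, "baseline_corrected")
    return baseline, corrected


def second_derivative(s: Spectrum, window: int = 5, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay second derivative d2A/dnu2 (AU * cm^2).

    Requires a uniformly spaced axis (per segment, relative tolerance 1e-6).
    Edge channels come from evaluating the edge-fitted polynomial; peak
    searches downstream exclude them.  Output is divided by the grid step
    squared, so values are true second derivatives independent of spacing.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    wn = s.wavenumbers
    out = np.empty_like(s.absorbance)
    for sl in s.segment_slices():
        x, y = wn[sl], s.absorbance[sl]
        if x.size < window:
            raise ValueError(
                f"segment of {x.size} channels is shorter than the "
                f"Savitzky-Golay window ({window})"
            )
        d = np.diff(x)
        h = d.mean()
        if np.max(np.abs(d - h)) > 1e-6 * h:
            raise ValueError(
                "axis is not uniformly spaced; resample the spectrum onto a "
                "uniform grid before differentiation"
            )
        out[sl] = savgol_filter(y, window, polyorder, deriv=2, delta=h,
                                mode="interp")
    res = s.with_absorbance(out, "second_derivative")
    res.meta["sg_window"] = window
    res.meta["sg_polyorder"] = polyorder
    return res


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale the trace to unit Euclidean norm (shape-only comparison)."""
    norm = float(np.linalg.norm(s.absorbance))
    if norm <= 0.0:
        raise ValueError("cannot normalize null spectrum")
    return s.with_absorbance(s.absorbance / norm, "normalized")


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the fixed preprocessing order.

    excise_windows: closed cm-1 intervals removed before anything else
        (default: the atmospheric CO2 band).
    sg_window / sg_polyorder: Savitzky-Golay second-derivative settings.
    normalize: whether the derivative branch is vector normalized over the
        full retained spectrum (the shape-only convention used here).
    """

    excise_windows: tuple[tuple[float, float], ...] = ((2250.0, 2400.0),)
    sg_window: int = 5
    sg_polyorder: int = 2
    normalize: bool = True


@dataclass
class PreprocessResult:
    corrected: Spectrum          # branch A: feeds band-area integration
    derivative: Spectrum         # branch B: feeds peak position analysis
    baseline: Spectrum


def preprocess_pipeline(s: Spectrum, cfg: PreprocessConfig | None = None) -> PreprocessResult:
    """Excision -> rubber-band baseline -> [A: corrected | B: SG d2 -> norm]."""
    cfg = cfg or PreprocessConfig()
    work = s
    for lo, hi in cfg.excise_windows:
        work = excise_region(work, lo, hi)
    baseline, corrected = rubber_band_baseline(work)
    deriv = second_derivative(corrected, cfg.sg_window, cfg.sg_polyorder)
    if cfg.normalize:
        deriv = vector_normalize(deriv)
    return PreprocessResult(corrected=corrected, derivative=deriv,
                            baseline=baseline)
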