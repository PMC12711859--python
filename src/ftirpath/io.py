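"""File interfaces: ENVI-style hyperspectral cubes, CSV spectra and cubes.

Cube format: a plain-ASCII ``.hdr`` carrying samples/lines/bands and the
wavelength list (cm-1), next to a ``.dat`` holding float32 little-endian
band-sequential (BSQ) values.  The long-format CSV alternative has one row
per (pixel_y, pixel_x, wavenumber, absorbance).  All wavenumbers in file
interfaces are cm-1, absorbance dimensionless.
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd

from .spectral import HyperspectralCube, Spectrum, WavenumberAxis, infer_segments

__all__ = [
    "write_envi_cube",
    "read_envi_cube",
    "write_cube_csv",
    "read_cube_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
]


def write_envi_cube(cube: HyperspectralCube, path_stem: str) -> tuple[str, str]:
    """Write ``<stem>.hdr`` + ``<stem>.dat`` (float32 LE, BSQ).

    The validity mask is stored as an extra trailing band named ``mask`` is
    not standard ENVI, so instead invalid pixels are recorded in the header
    as a ``masked pixels`` list of ``row,col`` pairs.
    """
    h, w, k = cube.data.shape
    hdr = path_stem + ".hdr"
    dat = path_stem + ".dat"
    bsq = np.ascontiguousarray(
        np.transpose(cube.data, (2, 0, 1)).astype("<f4")
    )
    bsq.tofile(dat)
    wl = ", ".join(f"{v:.6g}" for v in cube.axis.values)
    masked = np.argwhere(~cube.valid_mask)
    lines = [
        "ENVI",
        "description = {ftirpath hyperspectral absorbance cube}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {k}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = cm-1",
        "wavelength = {" + wl + "}",
    ]
    if masked.size:
        pairs = ", ".join(f"{r}:{c}" for r, c in masked)
        lines.append("masked pixels = {" + pairs + "}")
    with open(hdr, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return hdr, dat


def _parse_hdr(text: str) -> dict:
    # collapse {...} blocks onto one line, then read key = value pairs
    text = re.sub(r"\{([^}]*)\}", lambda m: "{" + " ".join(m.group(1).split()) + "}",
                  text, flags=re.S)
    out = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        out[key.strip().lower()] = val.strip()
    return out


def read_envi_cube(path_stem: str) -> HyperspectralCube:
    hdr = path_stem + ".hdr" if not path_stem.endswith(".hdr") else path_stem
    stem = hdr[:-4]
    with open(hdr) as fh:
        fields = _parse_hdr(fh.read())
    h = int(fields["lines"])
    w = int(fields["samples"])
    k = int(fields["bands"])
    if int(fields.get("data type", 4)) != 4:
        raise ValueError("only float32 (data type 4) cubes are supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    wl = fields["wavelength"].strip("{}").replace(",", " ").split()
    axis = WavenumberAxis([float(v) for v in wl])
    raw = np.fromfile(stem + ".dat", dtype="<f4")
    if raw.size != h * w * k:
        raise ValueError("cube .dat size does not match header dimensions")
    data = np.transpose(raw.reshape(k, h, w), (1, 2, 0)).astype(float)
    mask = np.ones((h, w), dtype=bool)
    if "masked pixels" in fields:
        for pair in fields["masked pixels"].strip("{}").replace(",", " ").split():
            r, c = pair.split(":")
            mask[int(r), int(c)] = False
    return HyperspectralCube(axis, data, mask)


def write_cube_csv(cube: HyperspectralCube, path: str) -> None:
    """Long-format CSV: pixel_y, pixel_x, wavenumber, absorbance (valid pixels)."""
    h, w, k = cube.data.shape
    rows, cols = np.nonzero(cube.valid_mask)
    wn = cube.axis.values
    df = pd.DataFrame({
        "pixel_y": np.repeat(rows, k),
        "pixel_x": np.repeat(cols, k),
        "wavenumber": np.tile(wn, rows.size),
        "absorbance": cube.data[rows, cols].ravel(),
    })
    df.to_csv(path, index=False)


def read_cube_csv(path: str) -> HyperspectralCube:
    df = pd.read_csv(path)
    need = {"pixel_y", "pixel_x", "wavenumber", "absorbance"}
    if not need.issubset(df.columns):
        raise ValueError(f"cube CSV must have columns {sorted(need)}")
    wn = np.sort(df["wavenumber"].unique())
    axis = WavenumberAxis(wn)
    h = int(df["pixel_y"].max()) + 1
    w = int(df["pixel_x"].max()) + 1
    data = np.zeros((h, w, wn.size))
    mask = np.zeros((h, w), dtype=bool)
    ch = np.searchsorted(wn, df["wavenumber"].to_numpy())
    data[df["pixel_y"].to_numpy(), df["pixel_x"].to_numpy(), ch] = (
        df["absorbance"].to_numpy()
    )
    mask[df["pixel_y"].to_numpy(), df["pixel_x"].to_numpy()] = True
    return HyperspectralCube(axis, data, mask)


def write_spectrum_csv(s: Spectrum, path: str) -> None:
    pd.DataFrame({"wavenumber": s.wavenumbers,
                  "absorbance": s.absorbance}).to_csv(path, index=False)


def read_spectrum_csv(path: str) -> Spectrum:
    df = pd.read_csv(path)
    if not {"wavenumber", "absorbance"}.issubset(df.columns):
        raise ValueError("spectrum CSV needs a 'wavenumber,absorbance' header")
    wn = df["wavenumber"].to_numpy(float)
    ab = df["absorbance"].to_numpy(float)
    order = np.argsort(wn)
    wn, ab = wn[order], ab[order]
    segs = infer_segments(wn)
    return Spectrum(WavenumberAxis(wn), ab, ("raw",), segs)
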