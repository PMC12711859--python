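"""Preprocess every ROI-mean spectrum and quantify band areas, ratios and
second-derivative peaks; derive the grey/white intensity ratios.

Reads the study written by 01_generate_study.py (or regenerates it from the
seed if absent) and writes results/roi_quant.csv, results/gm_wm_ratios.csv
and results/peaks.csv.
"""

import argparse
import os

import pandas as pd

from ftirpath import io as fio
from ftirpath.bands import default_band_library, default_ratios
from ftirpath.pipeline import _peak_table
from ftirpath.roi import gm_wm_ratio, quantify_rois, read_roiset_json
from ftirpath.synthetic import CASE_IDS, default_study_specs, generate_cube

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--data-dir", default="scratch/study_data")
parser.add_argument("--results", default="results")
args = parser.parse_args()
os.makedirs(args.results, exist_ok=True)

lib, ratios = default_band_library(), default_ratios()
tables = []
for case, spec in zip(CASE_IDS, default_study_specs(seed=args.seed)):
    stem = os.path.join(args.data_dir, case)
    if os.path.exists(stem + ".hdr"):
        cube, roiset = fio.read_envi_cube(stem), read_roiset_json(stem + "_rois.json")
    else:
        cube, roiset, _ = generate_cube(spec)
    tables.append(quantify_rois(cube, roiset, lib, ratios))
quant = pd.concat(tables, ignore_index=True)
quant.to_csv(os.path.join(args.results, "roi_quant.csv"), index=False)
print(f"quantified {len(quant)} ROIs "
      f"({quant['n_pixels'].iloc[0]} px each) -> roi_quant.csv")

gm_wm = pd.DataFrame({
    "gm_wm_lipids": gm_wm_ratio(quant, "area_total_lipids"),
    "gm_wm_amide_I": gm_wm_ratio(quant, "area_amide_I"),
})
gm_wm.to_csv(os.path.join(args.results, "gm_wm_ratios.csv"))
print("\ngrey/white intensity ratios (lipids 2800-3000, amide I 1600-1700):")
print(gm_wm.round(3))
ctrl = gm_wm.loc["CONTROL"]
reduced = (gm_wm.drop("CONTROL") < ctrl).all(axis=1)
print(f"\nall disease cases below control: {reduced.all()}")

peaks = _peak_table(quant)
peaks.to_csv(os.path.join(args.results, "peaks.csv"), index=False)
print("\ncase-mean peak positions (cm-1):")
print(peaks.set_index(["case_id", "tissue_class"])[
    ["peak_beta_sheet", "peak_alpha_helix", "peak_CH2_sym", "peak_CH2_asym"]
].round(1))
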