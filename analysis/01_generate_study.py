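"""Generate the four-case synthetic FTIR study.

Writes the hyperspectral cubes (ENVI), ROI layouts (JSON) and ground-truth
ledgers to scratch/study_data (binary, not part of the deliverable tables),
and the matched histology burden table to results/burden.csv.
"""

import argparse
import os

import pandas as pd

from ftirpath import io as fio
from ftirpath.roi import write_roiset_json
from ftirpath.synthetic import default_couplings, default_study_specs, generate_burden, generate_cube

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--data-dir", default="scratch/study_data")
parser.add_argument("--results", default="results")
args = parser.parse_args()

os.makedirs(args.data_dir, exist_ok=True)
os.makedirs(args.results, exist_ok=True)

specs = default_study_specs(seed=args.seed)
couplings = default_couplings(specs)
burdens = []
for spec in specs:
    cube, roiset, truth = generate_cube(spec)
    stem = os.path.join(args.data_dir, spec.case_id)
    fio.write_envi_cube(cube, stem)
    write_roiset_json(roiset, stem + "_rois.json")
    truth.to_json(stem + "_ground_truth.json")
    burdens.append(generate_burden(spec, roiset, couplings, truth))
    print(f"{spec.case_id}: {cube.height}x{cube.width} cube, "
          f"{len(roiset.rois)} ROIs "
          f"({roiset.rois[0].n_pixels((cube.height, cube.width))} px each)")

burden = pd.concat(burdens, ignore_index=True)
burden.to_csv(os.path.join(args.results, "burden.csv"), index=False)
means = burden.groupby(["case_id", "stain"])["percent_area"].mean().unstack()
print("\nslide-mean burden (% area):")
print(means.round(1))
print(f"\nwrote {args.data_dir}/<case>.hdr/.dat and "
      f"{args.results}/burden.csv ({len(burden)} rows)")
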