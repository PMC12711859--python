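"""Inferential layer: disease-vs-control Mann-Whitney comparisons of the
functional-group ratios and pooled/per-case Spearman correlations between
FTIR indices and stain burden.

Reads results/roi_quant.csv and results/burden.csv (from scripts 01/02)
and writes results/comparisons.csv and results/correlations.csv.
"""

import argparse
import os

import pandas as pd

from ftirpath.pipeline import DEFAULT_CORRELATION_PAIRS, _comparison_table
from ftirpath.stats import correlate_ftir_histology

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--results", default="results")
parser.add_argument("--alpha", type=float, default=0.05)
args = parser.parse_args()

quant = pd.read_csv(os.path.join(args.results, "roi_quant.csv"))
burden = pd.read_csv(os.path.join(args.results, "burden.csv"))

comparisons = _comparison_table(quant, args.alpha, args.seed)
comparisons.to_csv(os.path.join(args.results, "comparisons.csv"), index=False)
sig = comparisons[comparisons["significant"]]
print(f"Mann-Whitney disease vs control: {len(sig)}/{len(comparisons)} "
      f"significant at alpha={args.alpha}")
amide = comparisons[comparisons["quantity"].str.startswith("ratio_amide_I_II")]
print("\namide I/II comparisons (U > 50 means disease elevated):")
print(amide[["quantity", "group_a", "u_statistic", "p_two_sided"]]
      .to_string(index=False))

rows = []
for scope in ("global", "per_group"):
    rows += [r.as_dict() for r in correlate_ftir_histology(
        quant, burden, DEFAULT_CORRELATION_PAIRS, scope=scope,
        alpha=args.alpha, seed=args.seed)]
correlations = pd.DataFrame(rows)
correlations.to_csv(os.path.join(args.results, "correlations.csv"),
                    index=False)
glob = correlations[(correlations["scope"] == "global")]
print("\npooled Spearman correlations (FTIR index vs stain burden):")
print(glob[["x_name", "y_name", "tissue_class", "n", "rho", "p_two_sided",
            "significant"]].round(4).to_string(index=False))
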