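# ftirpath

FTIR hyperspectral imaging analysis of FFPE brain tissue: preprocessing of
per-pixel mid-infrared spectra, functional-group band quantification and
diagnostic ratios, second-derivative structural peak analysis, matched
grey/white-matter ROI statistics, and correlation of spectroscopic indices
with immunohistochemical protein burden.

The pipeline targets a four-case neuropathology contrast — control,
frontotemporal lobar degeneration with phosphorylated TDP-43 inclusions
(FTLD[TDP]), FTLD[TDP] with Alzheimer co-pathology, and Alzheimer's
disease — and ships a synthetic-study generator with closed-form ground
truth, so every stage is testable end-to-end without any external data.
It is written for spectroscopists and digital-pathology researchers who
want the numerics of this kind of study (rubber-band baselines,
Savitzky–Golay derivatives, band ratios, exact small-sample rank tests)
as a reusable, verified library rather than a GUI workflow.

## The analysis in brief

Per pixel, absorbance A(ν) on a 950–3900 cm⁻¹ grid is processed as

1. excision of the atmospheric CO₂ band (2250–2400 cm⁻¹);
2. rubber-band baseline correction: subtract the lower convex hull of the
   spectrum (per contiguous segment, endpoint-anchored);
3. Savitzky–Golay second derivative d²A/dν² (order 2, window 5 points),
   then vector normalization to unit Euclidean norm.

Band areas (trapezoid over the corrected branch) and second-derivative
peak positions/depths yield the study's indices: amide I/II,
α-helix/unordered, α-helix/PO₂, olefinic/lipids, carboxyl/lipids,
CH₃/lipids and α-helix/β-sheet, plus peak shifts such as the CH₂
asymmetric stretch 2918 → 2923 cm⁻¹ and α-helix 1652 → 1660 cm⁻¹.
ROI-level inference uses the exact Mann–Whitney U test (full null
distribution at n ≤ 10 per group) and Spearman correlations with exact or
permutation p-values at small n. Histological burden is percent area above
a fixed threshold, ten ROIs per slide.

## Worked example

Run the numbered analysis drivers from the repository root (each is a thin
script over the library; `--seed` controls the synthetic study):

```sh
python analysis/01_generate_study.py   # cubes + ROIs + burden tables
python analysis/02_quantify_rois.py    # per-ROI areas/ratios/peaks
python analysis/03_intensity_maps.py   # per-pixel lipid/amide maps (slow)
python analysis/04_statistics.py       # comparisons + correlations
```

`02_quantify_rois.py` prints, for the default seed:

```
grey/white intensity ratios (lipids 2800-3000, amide I 1600-1700):
             gm_wm_lipids  gm_wm_amide_I
AD                  0.489          1.256
CONTROL             0.590          1.357
FTLD_TDP            0.456          1.069
FTLD_TDP_AD         0.457          1.090

all disease cases below control: True
```

i.e. every disease case shows reduced grey-to-white lipid and amide-I
intensity ratios relative to the control, the map-level signature of
combined lipid and protein redistribution. `04_statistics.py` then prints
the inferential layer, e.g.

```
amide I/II comparisons (U > 50 means disease elevated):
ratio_amide_I_II_GM    FTLD_TDP        100.0     0.000011
```

an exact Mann–Whitney p (the most extreme value attainable at n = 10/10 is
2/184,756 ≈ 1.1·10⁻⁵) showing grey-matter amide I/II elevated in
FTLD[TDP] over control, and

```
amide_I_II  TDP43  GM  40  0.8487  0.0000  True
```

the pooled 40-ROI grey-matter Spearman correlation between the amide I/II
ratio and TDP-43 burden (ρ = 0.85, p < 10⁻¹¹): protein-structure indices
rise with histological pathology load.

The same study is available as a CLI:
`ftirpath run --synthetic --seed 7 --out results/study` (also
`generate`, `preprocess`, `quantify`, `stats` subcommands; see
`ftirpath --help`).

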