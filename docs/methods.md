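# Methods

`ftirpath` re-implements, as a tested pipeline, a mid-infrared (FTIR)
hyperspectral analysis of formalin-fixed paraffin-embedded (FFPE) human
brain tissue contrasting four neuropathological cases — a control, two
frontotemporal lobar degeneration cases with phosphorylated TDP-43
inclusions (one with Alzheimer co-pathology), and an Alzheimer's disease
case — and correlating the spectroscopic indices with immunohistochemical
protein burden. This note documents the model, the numerical choices, and
what the synthetic study does and does not establish.

## Spectral model and preprocessing

Each pixel of a hyperspectral cube holds an absorbance trace A(ν) on a
strictly monotonic wavenumber grid (cm⁻¹), stored ascending, spanning
950–3900 cm⁻¹ by default. Preprocessing follows a fixed order:

1. **CO₂ excision.** Channels in 2250–2400 cm⁻¹ are removed. The axis
   keeps a gap; nothing is interpolated across it, and any band window
   spanning a gap is an error. Interpolated values in the excised region
   would be fabricated data.
2. **Rubber-band baseline.** The baseline is the lower convex hull of the
   (ν, A) point set of each contiguous segment (Andrew monotone chain),
   linearly interpolated between hull vertices and anchored at the segment
   endpoints. Corrected = A − baseline is ≥ 0 and exactly 0 at hull
   vertices; the operation is idempotent and single-pass (no iterative
   hull refinement — the canonical rubber-band definition, deterministic).
3. **Second derivative.** Savitzky–Golay, polynomial order 2, window 5
   points, divided by the squared grid step so values are true d²A/dν²
   (AU·cm²) independent of spacing. The axis must be uniform per segment
   (relative tolerance 1e−6). Edge channels are the evaluation of the
   edge-fitted polynomial (`mode="interp"`); peak searches exclude the
   (window−1)/2 edge channels of each segment to avoid spurious edge
   minima.
4. **Vector normalization.** The derivative trace is scaled to unit
   Euclidean norm over the full retained spectrum, so only spectral shape
   is compared. Whether normalization should span the full spectrum or
   only the amide region is a genuinely open choice; full-spectrum is the
   default and the region is configurable. Ratios of derivative depths
   within one spectrum are invariant to this choice.

Branch A (baseline-corrected absorbance) feeds band-area integration and
the intensity maps; branch B (normalized second derivative) feeds peak
position, depth and shift analysis. Absorption maxima appear as
second-derivative minima.

## Band library and ratios

Band windows follow standard tissue assignments: amide I 1600–1700 and
amide II 1500–1600 cm⁻¹; amide-I secondary-structure sub-bands (β-sheet
~1625, unordered ~1645, α-helix ~1652, high-wavenumber β ~1680 and ~1695);
asymmetric phosphate 1220–1260 (symmetric ~1080 also present); total
lipids 2800–3000 with CH₂ symmetric/asymmetric peaks at 2850/2920 and CH₃
~2960; olefinic =C–H 3000–3020; carbonyl C=O 1725–1755 cm⁻¹. Windows with
no fixed convention are package defaults, editable in a TOML/YAML config.
The asymmetric phosphate band is the default denominator of the
α-helix/PO₂ ratio; the symmetric band is available in the library.

Areas are trapezoidal integrals over the window on the corrected branch.
Peaks are the most negative derivative channel in the window, reported at
grid resolution (no sub-channel interpolation, so exact-position checks
are meaningful; parabolic refinement can be added behind a config flag);
ties break to the lowest wavenumber.

Seven ratios are computed per spectrum. Amide I/II, α-helix/PO₂,
olefinic/lipids, carboxyl/lipids and CH₃/lipids use band areas, which is
meaningful where the windows are separable. α-helix/unordered and
α-helix/β-sheet use second-derivative peak magnitudes, because the
overlapping amide-I sub-bands cannot be separated by raw-area windows;
this matches common biospectroscopy practice. Olefinic/lipid could equally
use peak height; area is the default because it is less sensitive to noise
at the weak 3010 cm⁻¹ band. A denominator below 1e−12 yields a missing value (never ±inf),
excluded pairwise from statistics.

## ROI analysis

Regions of interest are labelled GM (grey matter) or WM (white matter)
rectangles (half-open, (row, col) 0-based) or pixel sets; the study layout
is 10 GM + 10 WM ROIs of ~1,000 pixels per case. Spectra are averaged over
the ROI's valid pixels first (channel-wise mean, permutation-invariant by
canonical pixel ordering), then preprocessed and quantified — averaging
before quantification suppresses pixel noise and mirrors how
representative ROI profiles are built in practice. Matching across
modalities is by shared (case, ROI-label) keys; no image registration.
Masked (artifact/off-tissue) pixels are excluded from every aggregate; a
masked pixel's stored values have provably zero influence.

Per-pixel intensity maps integrate a band on the baseline-corrected (not
normalized) spectrum of every valid pixel — normalization would erase the
grey/white intensity contrast the maps display. A flat spectrum is its own
lower hull, so a constant cube maps to zero; maps carry band signal, not
offsets. The grey/white ratio of a quantity is the GM-ROI mean divided by
the WM-ROI mean per case.

## Statistics

Two-group comparisons use the Mann–Whitney U test (two-sided; U from
midranks). With both groups ≤ 10 and no ties, p is exact from the full
null distribution of U, computed by the standard count recursion —
equivalent to enumerating all label assignments, which the tests verify by
brute force. Ties at small n switch to a seeded Monte-Carlo permutation
test (10⁵ draws); larger samples use the normal approximation with tie and
continuity correction. Spearman's ρ is the Pearson correlation of
midranks; p is exact by full permutation enumeration for n ≤ 8, seeded
Monte-Carlo for 9 ≤ n ≤ 10, and the t approximation for n > 10. α = 0.05,
two-sided, with no multiple-testing adjustment by default (a
Benjamini–Hochberg helper exists but is off), matching the conventional
reporting this pipeline reproduces.

Burden correlation pools all cases' ROIs per tissue class ("global" scope,
n = 40 at the default design) or stratifies by case ("per-group"); strata
with fewer than 3 complete pairs are flagged insufficient rather than
computed.

## Histology quantification

Stain burden is the percent of ROI pixels at or above a fixed per-stain
intensity threshold on a single-channel positivity map, averaged over the
ten ROIs of a slide. Thresholds are explicit configuration values (default
128 on a 0–255 scale), not adaptive: reproducibility is preferred over
optimality, and the upstream color deconvolution of DAB/hematoxylin images
is out of scope — inputs are already positivity maps.

## Synthetic study design

The generator emulates the study at desk scale. Per-pixel spectra are sums
of Gaussian bands (per-tissue amplitudes, per-case center shifts) on an
affine baseline plus i.i.d. Gaussian noise (default SD 0.005 AU per
channel — a realistic pixel-level noise floor for FPA imaging after
48-scan co-addition). Cubes are 64×64 pixels (configurable up to the
instrument's 128×128 format) split into a GM and a WM territory, with
10+10 randomly placed 25×40-pixel ROIs (= 1,000 pixels; random ROIs may
overlap, as randomly sampled slide regions do). The default grid is 950 to
3900 cm⁻¹ at 1 cm⁻¹ spacing: 1 cm⁻¹ puts every literature peak position
used in the contrasts (1625, 1652, 1660, 1680, 1695, 1740, 2850, 2918,
2923, 3010 cm⁻¹) exactly on-grid, so grid-resolution peak assertions are
exact. Instrument spectral resolution does not fix digital point spacing.

Programmed case contrasts (direction only): elevated β-sheet (1625)
derivative intensity in both FTLD cases, strongest in mixed-pathology grey
matter; CH₂-asymmetric 2918 → 2923 cm⁻¹ shift in all disease cases;
α-helix 1652 → 1660 cm⁻¹ shift in the mixed-pathology case only; reduced
grey/white lipid and amide-I intensity ratios in every disease case;
elevated amide I/II in disease; elevated carboxyl/lipids in the FTLD cases
only. TDP-43 burden is high in the FTLD cases, tau (AT8) in the
mixed-pathology and AD cases, β-amyloid in the amyloid-bearing cases, and
myelin (PLP) mildly reduced in mixed pathology; pathology stains are
linearly coupled (plus noise) to the amide I/II ground truth per ROI, so
pooled FTIR–histology correlations are positive by construction. Effect
sizes are chosen so the directional contrasts are significant with the
exact Mann–Whitney test at n = 10 ROIs per group; they are design values,
not estimates of real effect magnitudes.

Ground truth is closed-form: isolated-band areas a·σ·√(2π); windowed
areas as the exact (erf) integral of the full model over each library
window, including overlap tails — this is the quantity the pipeline
actually measures, so it is the recovery reference; derivative depths and
peak positions from the analytic second derivative of the full model on
the grid. The analytic-depth reference deliberately omits Savitzky–Golay
smoothing, which biases measured depths by a few percent at σ = 4–7 cm⁻¹
(the bias partially cancels in depth ratios); recovery is therefore judged
on the median absolute relative error over all recovered quantities.

Two modelling realities are worth stating. First, a weak unordered
shoulder 7 cm⁻¹ from a strong α-helix band has no independent
second-derivative minimum at any amplitude pairing — the α band's positive
derivative lobe swamps it. The generator keeps the unordered amplitude
below 0.1 AU and chooses σ = 4 cm⁻¹, which places the shoulder's
third-derivative zero at the α-helix center so the 1652 position stays
exact; the α/unordered ratio is then a stable window-depth measure rather
than a two-peak separation, and its ground truth is model-evaluated the
same way. Second, at 1 cm⁻¹ spacing with default noise, single-ROI
(1,000-pixel) peak positions can wobble by one channel; case-level
positions (noise-free templates, pooled-territory profiles, per-case
medians) are exact and are what the acceptance checks assert.

What the synthetic study does not emulate: Mie/resonant-Mie scattering,
paraffin residue, water vapor, detector nonlinearity, instrument line
shapes (bands are Gaussian, not Voigt), spatial texture within tissue
classes, or biological within-case variability beyond pixel noise.
Passing tests therefore demonstrate correctness of the numerics and the
pipeline's ability to recover known structure — not robustness to real
FFPE-tissue artifacts.

## Problem sizes and determinism

The test suite and the acceptance script run the full four-case study
(64×64×2951 cubes) in seconds per case; parameter recovery uses 20
independent seeds and statistical calibration 2,000 null replicates. All
randomness flows from explicit integer seeds: cubes use a stream keyed by
(seed, case index) consumed in fixed order (ROI placement, then noise),
burden tables a parallel stream, so every table is bit-reproducible for a
given seed and configuration.

## Known limitations

* Amide-I sub-band quantities are window measures, not curve-fit
  components; full deconvolution is deliberately out of scope.
* The rubber-band hull under a noisy pixel spectrum hangs slightly below
  the true baseline, positively biasing per-pixel map areas by O(noise);
  ROI-mean quantification is unaffected in practice because averaging
  precedes baseline correction.
* Absolute concentrations (Beer–Lambert calibration) are not estimated;
  all quantities are relative.
* Grey/white "matching" is by label, as in manually aligned ROI studies;
  no registration or automated segmentation is provided.
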