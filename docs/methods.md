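# Methods

This note documents the models, parameter choices and numerical
conventions behind `hemoscape`, and what the synthetic-data experiments do
and do not establish about real brain-slice data.

## Study design being emulated

Organotypic brain-slice cultures are exposed to 200 μM of one of five
conditions — vehicle control (Ctrl), heme bound to albumin (HemeAlb), the
heme–hemopexin complex (HemeHpx), cell-free hemoglobin (Hb), or the
hemoglobin–haptoglobin complex (HbHp) — and separate slice batches are
consumed by five readouts: ⁵⁸Fe heme-iron deposition (ppb, ICP-MS), lipid
peroxidation (control-centred MDA equivalents, μM g⁻¹ protein), a
transcriptional heme-stress score and an Nrf2/heme-metabolism score (both
arbitrary variance-stabilized units), and the pseudocytometric apoptotic
neuron fraction. Because the assays are destructive, the integration step
works on bootstrap pseudoslices rather than per-slice vectors.

## Synthetic readout pools

Only per-condition summary statistics (mean ± SD, n) are published for the
per-slice pools, so pools are drawn from a normal distribution truncated to
each readout's valid range (iron ≥ 0; cell-death fraction in [0, 1]; MDA
and scores unbounded). Two refinements:

* **Moment matching.** The published mean ± SD are the *sample* statistics
  of the real pools. Generated pools are therefore affinely rescaled to
  match them exactly (then re-clipped to the valid range; the clip is
  active only when a matched value would leave the range and perturbs the
  moments marginally). Without this, pool means wobble by sd/√n — noise the
  original analysis, which resampled fixed empirical pools, never had; with
  cell-death SDs of 12–25 percentage points and between-condition gaps as
  small as 3 points, that wobble can reorder conditions.
* **Pool sizes** equal the published per-assay n (6 for iron, 13–21 for
  MDA, 13–18 for cell death, 8 per condition for the transcript scores,
  taken from the lower end of the published 8–19 range).

Two preset cells are not published and are flagged `assumed=True` alongside
the transcript-score rows: the control iron value (proxied by the
"near-baseline" heme-Hpx level, 0.056 ± 0.004 ppb) and the control
cell-death n (16, mid-range of the published 13–18).

The transcript-score presets are arbitrary VST units chosen once to encode
the published ordinal structure — heme-stress: HemeHpx < Ctrl < HemeAlb <
Hb < HbHp (means −0.2, 0, 1.0, 1.3, 1.6); heme-metabolism: elevated
essentially only for HbHp (means 0, 0.2, −0.1, 0.4, 1.5) — with SD 0.5.
Effect sizes of 2–3 within-condition SDs for the driving contrasts are
consistent with the clearly separated score box plots and the dominant
heme-metabolism PC2 loading reported for the original data.

## Fluorescence image generator

Non-overlapping disk cells (radius 6 px) on a flat background, three
uint16 channels (nuclei, NeuN, Casp3). Two populations are mixed at a known
fraction (round-half-up): viable cells at (NeuN 3000, Casp3 300), apoptotic
at (300, 3000), per-cell intensities N(μ, 0.1 μ), per-pixel noise with SD
5% of the cell intensity. Placement is rejection sampling with a minimum
center distance of 2r + 2; infeasible packings raise an explicit error
rather than silently truncating. In log₁₀ space the populations are ~20 SD
apart — deliberately far above the ≥ 4 SD separation the classifier tests
assume, so fraction-recovery tests probe the pipeline, not the noise
model. Not modeled: PSF, autofluorescence, overlapping or irregular cells,
z-structure; passing tests therefore show the segmentation/classification
logic is correct, not that it is robust to real microscopy artifacts.

## Count-matrix generator

Genes × samples negative-binomial counts, var = μ + αμ² with dispersion
α = 0.1, lognormal baseline abundances scaled to a 2 × 10⁶ library, 8
samples per condition, 2000 genes. Two disjoint programs (100 heme-stress,
80 heme-metabolism genes) receive per-condition log2 fold changes; defaults
encode the same ordinal structure as the score presets (stress: −0.3, 0,
1.5, 2.0, 2.5; metab: 0, 0.2, 0, 0.3, 2.0). A fully-null design (all zero)
is legal for calibration runs; otherwise the ordinal structure is enforced
at construction.

## Pseudocytometry

Segmentation is Otsu thresholding on the nuclei channel, 8-connected
components, and a minimum-area filter (default 20 px) — no watershed,
because the synthetic fixtures are non-overlapping and the original
pipeline's operators are unspecified. Features are log₁₀(intensity + 1)
(pseudocount for zero-intensity safety). Classification is k-means with
k = 2, k-means++ initialization, 10 restarts, fixed seed; features are
processed in a canonical sort order so results are invariant to cell
ordering. The cluster with higher mean log Casp3 is labeled apoptotic
(ties broken toward lower log NeuN). Clustering is per image by default;
pooling across images is available by concatenating cell lists before
classification.

## Biochemistry

MDA: c(μM) = ΔA₅₃₂₋₆₀₀ / (ε · l) × 1000 × d with ε = 156 mM⁻¹ cm⁻¹,
path length 1 cm, dilution d defaulting to 10 (100 μL homogenate in a
1000 μL reaction). Negative ΔA passes through: the published control MDA
values are negative, which is consistent with a control-centred
normalization; that centring (subtract the batch control mean) is provided
as an explicit, documented step rather than guessed into the conversion.
LDH release is reported as percent of the Triton X-100 full-lysis signal.

## Gene scores

The variance-stabilizing transform is median-of-ratios size-factor
normalization followed by log2(x + 1); all-zero genes pass through as
zeros. Differential expression is a per-gene Welch t-test on VST values
with Benjamini–Hochberg adjustment — a deliberately minimal, clearly named
stand-in for DESeq2/apeglm, adequate here because only the *construction*
of the score sets needs exercising; its calibration (type-I error ≈ 5% on
a 2000-gene null, > 90% power at log2fc = 2 with 8 per group) is checked
by the test suite. The heme-response set is the top 50 genes by log2 fold
change among those with adj. p < 0.05 and positive fold change, ties
broken lexicographically; ranking by fold change (not p) is a documented
choice, configurable via the function arguments. Scores are unweighted
per-sample means over the set's VST rows; the named curated sets
(NRF2 targets, heme metabolism, iron transport) are supplied as external
GMT files since their membership is catalog-defined.

## Bootstrap PCA

One seeded RNG stream consumed in fixed (condition-major, replicate,
readout) order makes the pseudoslice matrix bit-reproducible. Z-scaling is
global across all 1250 rows (a single matrix-level operation), divisor
n − 1; zero-variance columns are an error naming the readout. PCA is
computed by SVD of the scaled matrix, equivalent to the covariance
eigendecomposition (the test suite checks this equivalence against an
explicit eigendecomposition oracle and the 2-variable closed form
(1 ± ρ)/2). PCA signs are arbitrary, so components are oriented to fix the
⁵⁸Fe loading on PC1 and the heme-metabolism loading on PC2 non-negative; a
zero anchor loading leaves the component untouched, and applied flips are
recorded.

Centroids are per-condition means of the PC1/PC2 scores with 2.5–97.5
percentile intervals over that condition's pseudoslices. The attractor rule
is interval-based and deterministic: the control is Baseline; a condition
whose PC1 interval lies entirely above the control's is Toxic; failing
that, a PC2 interval entirely above the control's is Adaptive; everything
else (treated but control-like, or protective) is Sequestered. Toxic takes
precedence by construction. On the synthetic presets HbHp separates from
control on *both* axes — the residual iron burden and elevated stress score
push its PC1 interval clear of the control's — so the rule labels it Toxic
even though its dominant displacement is adaptive (largest PC2 centroid by
a wide margin). The original study's verbal map calls this state adaptive;
with pseudoslice-distribution intervals the precedence rule is the
conservative reading, and the centroid table carries the full geometry for
either interpretation.

## Problem sizes and expected results

Default analysis scale: B = 250 (1250 × 5 matrix), 2000 genes × 40
samples, 100-cell 512 × 512 image fields (2 per condition in the pipeline,
20 in the fraction-recovery experiment), pool sizes as published. At this
scale the full pipeline runs in seconds on one core.

Passing tests establish: exact design dimensions (1250 × 5; top-50 set);
exact unit conversions; classifier recovery of known mixing fractions under
clean two-population separation; PCA algebra against independent oracles;
and stable qualitative reproduction of the published biplot structure on
the preset summaries (damage readouts co-loading on PC1, heme-metabolism
dominating PC2, free toxins extreme on PC1, HbHp extreme on PC2, heme-Hpx
nearest control, across 10 pool/bootstrap seeds). They do *not* establish
the published variance percentages (64.6%/27.7%) or loading values, which
depend on the unpublished empirical score pools; the synthetic analogs land
near PC1 ≈ 52%, PC2 ≈ 27%.

## Known limitations

* The normal-truncated, moment-matched pools erase any skew or outlier
  structure the real per-slice distributions had; bootstrap-PCA results on
  real pools will differ in detail.
* The DE stand-in has no dispersion shrinkage and will lose power against
  DESeq2 at small n or low counts.
* The image model omits every real-microscopy artifact; segmentation
  parameters (Otsu, min-area) are not tuned for real tile scans.
* The attractor rule is one defensible formalization of a verbal
  description; alternative precedence (adaptation before toxicity) changes
  the HbHp label, as discussed above.
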