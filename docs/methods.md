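# Methods

`plaquemap` re-implements, as a tested library, a correlative chemical
imaging analysis of amyloid-beta (Aβ) plaque polymorphism: fluorescence
(LCO) microscopy quantification and CNN morphotype classification of
plaques, guided extraction and preprocessing of MALDI-MSI spectra at
single-plaque ROIs, spatial segmentation of MSI datacubes, and the
multivariate/univariate statistics that link plaque morphotype (diffuse,
cored, coarse-grained, cotton-wool, vascular/CAA) to Aβ peptide
signatures. Because the post-mortem tissue data behind such studies are
not redistributable, a synthetic-cohort generator with known ground truth
stands in for them; every pipeline stage is therefore testable as a
parameter-recovery problem.

## Peptide panel

Peptides are named `Abeta<start>[pE]-<end>` over the canonical Aβ1-42
sequence `DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA`; C-termini are
restricted to 40 or 42. Masses use **average** residue masses (Expasy
table) because linear-mode TOF at m/Δm = 1000 does not resolve isotopes;
observed m/z is [M+H]+ with a 1.008 Da proton. N-terminal pyroglutamate
(pE) is modelled as water loss (−18.0153 Da) for Glu starts and ammonia
loss (−17.0305 Da) for Gln starts. The default nine-peptide panel
(Aβ1-40, 1-42, 2-42, 3pE-40, 3pE-42, 4-40, 4-42, 5-42, 11pE-42) spans
3319–4515 m/z, inside the 1500–6000 Da acquisition window; computed
Aβ1-42 [M+H]+ is 4515.05, within one FWHM of the instrument's 4515.6
calibration anchor.

## Synthetic cohorts

The generator is a pure function of (parameters, seed); its defaults are
the study conditions.

**Geometry** (per morphotype template): cored plaques (CP) 30–50 µm with
a bright compact core (0.3 × diameter) and weaker corona; coarse-grained
plaques (CGP) 50–100 µm, 3–8 dense granules, no corona; diffuse plaques
(DP) 50–90 µm low-contrast textured blobs; cotton-wool plaques (CWP)
50–100 µm uniform blobs; CAA as 10–20 µm annuli on vessel paths.
Microscopy renders at 0.5 µm/px (20× widefield scale) into an LCO channel
plus a co-localised tau-neurite (PHF-1-like) channel whose planted
amplitude is CGP > CP > DP = 0.

**Peptide profiles**: each morphotype carries a relative-abundance vector
chosen once so that every contrast the analysis is meant to detect has a
planted fold ≥ 2 in the reported direction — CP above DP for Aβ1-40,
Aβ3pE-42 and Aβ11pE-42 (fold 3; Aβ1-42 marginal at 1.3); CGP above CP for
the x-40 species (1-40 ×2.5, 3pE-40 and 4-40 ×4) and below CP for the
x-42 species (~×2); CAA above CGP for Aβ1-40/3pE-40 and below for x-42 —
while the remaining peptides are planted *equal* so recovery experiments
have true negatives (Aβ2-42 and, for CP-vs-DP, also 3pE-40/4-40/4-42/5-42).
Aβ1-40 is core-enriched (×3) inside cored plaques.

**Spectra**: pixel or ROI spectra are sums of unit-apex Gaussians at each
peptide's m/z with FWHM = m/z / 1000, plus a matrix-cluster baseline
b(m) = b₀·exp(−(m−1500)/λ), λ = 1200 Da, plus additive detector noise
(σ = 0.02). Abundances carry multiplicative log-normal noise with
σ_log = √ln(1+CV²). The baseline amplitude default is b₀ = 4, which
makes the 9-peptide panel ≈ 2% of the total ion count — the regime in
which TIC normalisation is meaningful (in real tissue MALDI the matrix
background dominates TIC; a generator in which the analyte panel is a
large TIC fraction would make TIC normalisation itself distort
between-class comparisons). ROI-level spectra are sampled at 0.25 Da,
emulating a linear-TOF digitizer; full datacubes default to 1–2 Da bins
to bound memory and are used for segmentation and determinism checks, not
for fold-change quantification (see Limitations).

**Cohort structure**: groups CUAP (cognitively unimpaired amyloid
positive), sAD and fAD with default sizes 5/12/6. Noise is hierarchical:
per-patient peptide multipliers at the inter-patient CV (18%), per-plaque
multipliers at the intra-patient CV (16%), per-measurement multipliers at
the technical CV (10%). Plaque counts per patient are Poisson around
group-dependent means (CUAP/sAD/fAD: DP 6/5/1, CP 2/4/6, CGP 0/2/4, CAA
0/1/1) chosen once at the ~10–15 plaques/patient scale; only the ordering
(DP: CUAP ≈ sAD > fAD; CP increasing CUAP→fAD; CGP absent in CUAP and
fAD > sAD; CAA absent in CUAP) is study-anchored — absolute loads are
free simulator parameters. CUAP patients never receive CGP or CAA
deposits.

## Microscopy quantification

Channels are processed as grayscale: background subtraction by grayscale
morphological opening with a 50 µm disk (a rolling-ball equivalent;
decomposed footprint for speed), thresholding of the LCO channel by Li &
Lee's minimum-cross-entropy method, 8-connected components with a 100 µm²
minimum area (below any plaque of interest; the smallest CP ≈ 30 µm ≈
700 µm²). Per-ROI fluorescence is **summed** intensity over the ROI
divided by its area in µm² — the sum convention makes the constant-image
case exact and is stated because "intensity per µm²" is otherwise
ambiguous. Batch connected-component capture replaces interactive
per-object ROI selection.

## CNN morphotype classifier

Patches are resized bilinearly to 120 × 120, converted to grayscale
(channel mean), and contrast-stretched by mapping the 1st/99th intensity
percentiles to [0, 1]; constant patches map to zeros. Augmentation:
rotation ±20°, horizontal/vertical flips (p = 0.5 each), isotropic scale
0.9–1.1, re-cropped/padded to 120 × 120 (ranges are package choices; only
the transform families are prescribed).

The network is 3 blocks of {3×3 conv (32/64/128) → batch-norm → ReLU →
2×2 max-pool} → dense 128 → dropout 0.5 → softmax over {CGP, CP, DP},
trained with Adam (lr 0.001, decay ×0.96 every 10 epochs), categorical
cross-entropy, batch 32 — the smallest stack that meets the synthetic
accuracy bar on one CPU. Layers, backprop and Adam are implemented in
numpy (`plaquemap.nn`) with im2col convolutions; batch-norm seeds its
running statistics from the first batch so short trainings evaluate
sensibly. Default epochs 30 with early stop on validation loss (patience
5) or perfect validation accuracy; acceptance runs use 14 epochs.

Training is stratified three-fold cross-validation: member *f* trains on
folds ≠ *f* with augmentation and validates on fold *f*; each sample
validates exactly once; the ensemble predicts by averaging member softmax
outputs, with argmax ties resolved by the fixed order CGP < CP < DP. The
train/test split is stratified with per-class round-half-up (e.g. class
counts 42/208/135 at 20% give a 77-patch test set; the achieved counts
are returned rather than forcing any particular total). Evaluation
reports the confusion matrix, accuracy and per-class precision/recall/F1;
a never-predicted class yields precision `None` with a warning.
`reconstruct_confusion` searches all 3×3 integer matrices with a given
total and trace for those reproducing a printed metrics panel after
two-decimal rounding (off-diagonal mass enumerated exactly, diagonals
pruned per class).

## MSI spectral chain

Per ROI: member-pixel spectra are averaged, then

1. square-root transform (variance stabilisation),
2. Savitzky-Golay smoothing, half-window 10 **bins** (full window 21),
   cubic; edges by polynomial interpolation so polynomials up to the
   filter order are reproduced exactly,
3. SNIP baseline, 100 iterations, decreasing-window variant with the LLS
   transform log(log(√(v+1)+1)+1),
4. baseline subtraction with **difference-of-squares back-transform**:
   signal = smoothed² − baseline², exact for peaks that add on a
   baseline — a plain subtraction on the sqrt scale would compress a
   planted fold of 3 to √3,
5. TIC normalisation, scaling by the **raw** spectrum's total ion count
   (the acquisition-level TIC); normalising by the baseline-subtracted
   signal's own sum would turn abundances into compositions and shrink
   all fold changes,
6. MAD noise (×1.4826, σ-consistent) on the processed signal,
7. SNR > 2 peak gate per panel peptide (below-noise peptides recorded as
   0 with a flag), and trapezoidal AUC over ±1 FWHM (m/z / 1000) around
   each peptide, widened to ≥ 1.5 bins on coarse grids.

Steps 4 and 5 are the two numerical choices that make the chain
fold-faithful; with them the noise-free planted ratios are recovered to
< 1% and the 10%-CV Monte-Carlo ratio for a planted fold of 3 lands
within [2.2, 3.8].

## Spatial segmentation

Pixels are clustered on TIC-normalised spectra (optionally smoothed with
a per-bin 2-D Gaussian — none/weak/medium/strong = σ 0/0.5/1/2 px,
"medium = 1 px" being an explicit guess for an undisclosed tool setting —
and binned to 1 Da) under Euclidean distance. Bisecting k-means splits
the leaf with the largest within-cluster sum of squares (ties to the
lower node id) via 2-means with 10 seeded restarts until the requested
leaf count; the split sequence defines nested dendrogram cuts. The number
of clusters is exposed as a parameter because the reference workflow cut
dendrograms interactively. Single-ion images integrate a trapezoidal AUC
window per pixel.

## Registration and plaque loads

Microscopy→MSI mapping is a similarity transform (scale, rotation,
translation — shear is not expected between two images of one physical
section), fitted from landmark pairs by the closed-form least-squares
(Umeyama) solution; reflections are rejected. ROI masks map through the
transform and rasterise onto 10 µm MSI pixels by 5×5 supersampling with a
50% coverage rule (symmetric, area-preserving in expectation); clipped or
empty footprints warn. Plaque loads are per-type counts, % area fraction
of the analysed tissue area, and counts per mm².

## Statistics

Autoscaling: column-wise mean 0 / SD 1 (n−1), constant columns dropped
with a warning. OPLS-DA (two classes, y ∈ {+1, −1} centred): each
orthogonal component is w_o ∝ p − (wᵀp)w estimated NIPALS-style and
deflated, then one predictive component on the deflated X; R2X counts
predictive + orthogonal reconstruction, R2Y the y-fit, and Q2 comes from
stratified 7-fold cross-validation (1 − PRESS/SS); defaults n_orth = 1,
folds = 7. VIP over the predictive component satisfies Σ VIP² = p.
HCA is Ward (D2) on Euclidean distances of autoscaled rows.
Kruskal-Wallis uses the tie-corrected H; Dunn's post hoc compares pooled
mean ranks with tie-corrected variance, two-sided p multiplied by the
number of comparisons (capped at 1). Two-group batches use Mann-Whitney U
(exact null when both groups ≤ 8 without ties, normal approximation with
continuity/tie correction otherwise) or Wilcoxon signed-rank when paired,
with Benjamini-Hochberg step-up adjustment across the batch. Pearson
correlations are pairwise-complete; CV summaries are 100·sd/mean per
group, cumulated as the mean over peptides and groups. Plaques are pooled
across patients as independent observations — mirroring the source
workflow despite the nesting — and results carry a `pooling` flag saying
so.

## Parameter-recovery experiments

`plaquemap.experiments.recovery_experiment` asks, across 50 seeds: with
the CV hierarchy (10/16/18%), 12 patients and 10 plaques per type, does
the chain + statistics detect the planted discriminators (Dunn-adjusted
p < 0.05) and only those, and does the VIP ranking place every planted
discriminator above every planted-equal peptide? Detection, true-negative
and VIP-ranking rates are reported per contrast (CP-vs-DP, CGP-vs-CP).
Under the defaults all three rates are ≥ 90%.

## Problem sizes

Desk-scale defaults keep everything on one CPU: ROI-level simulation at
0.25 Da over 1500–6000 (18 001 bins); datacubes at 1–2 Da on 0.3–0.8 mm
fields (40–80 px grids); classifier runs at 100 patches/class, 14 epochs,
3 folds; recovery at 50 seeds × 360 ROI spectra; pipeline determinism on
a 3-patient cohort. The acceptance script reruns all of these from
scratch.

## What the synthetic data do and do not show

The generator reproduces the *statistical shape* of the problem —
morphotype-specific geometry and contrast, peptide fold structure,
instrument peak width, baseline decay, hierarchical CVs, cohort
imbalance — but not: real plaque texture and histology, m/z calibration
drift between sections, isotope fine structure, matrix/ion-suppression
heterogeneity within tissue, or the unknown true overlap between
morphotype chemistries. Passing tests therefore demonstrate that the
implementation recovers known structure under the modelled noise, not
that the biological conclusions would replicate on new tissue.

## Known limitations

- At coarse m/z binning (≥ 1 Da) the prescribed 21-bin Savitzky-Golay
  window is much wider than the ~4 Da peaks; its undershoot lobes
  interact with SNIP's large clipping windows and can couple peptides
  ~200 Da apart. Quantification therefore uses the 0.25 Da grid; coarse
  cubes serve segmentation only.
- TIC normalisation is compositional: if the analyte panel were a large
  share of TIC, between-class fold changes would distort. The generator
  keeps the panel at ~2% of TIC, matching the assumption's domain of
  validity.
- The CNN is trained on synthetic morphology; its accuracy bound says
  nothing about stain variability, section artefacts or imaging setups.
- Pooling plaques within patients makes univariate p-values
  anticonservative for patient-level claims; a mixed-effects treatment is
  deliberately out of scope.
- Registration assumes landmarks; there is no automatic intensity-based
  alignment, no deformable registration, no m/z recalibration across
  sections.
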