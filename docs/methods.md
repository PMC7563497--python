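# Methods

This note documents the models, numerical choices and open design decisions
behind glycobarcode, and what the synthetic-data tests do and do not show.

## Peak alignment

Peaks from all runs are pooled and clustered greedily: visiting peaks in
descending area order (ties broken by rt, then m/z, so the result is
independent of input table order), a peak joins the nearest existing
consensus feature within the tolerances (0.5 min rt, 0.08 Da m/z; distances
scaled by the tolerances) or seeds a new feature at its own position.
Seeding by descending area anchors each consensus at its most intense
observation, which is robust to position jitter in weak peaks. A sample
contributes at most one peak per feature — the nearest wins — and unmatched
cells are imputed as 0 area (absence is treated as no signal, not as missing
data). Candidate features are found through (rt, m/z) bucket hashing, so
alignment is near-linear in the number of peaks. Tests validate the clusters
against a brute-force single-linkage oracle on jittered data with separation
beyond, and jitter below half of, the tolerances — the regime in which the
two algorithms provably agree and recovery is unambiguous.

## Feature filtering

Three steps, applied in order, with per-step removal counts reported:

1. **Reproducibility.** CV of the QC-pool replicate areas ≤ 0.50. CV is the
   sample standard deviation (ddof = 1) divided by the mean; an all-zero QC
   profile gives infinite CV and is removed (it could not be ratio-normalized
   anyway). The CV is computed over QC replicates only, per standard
   metabolomics practice.
2. **Reliability.** Median vendor-reported S/N ≥ 5. S/N is taken from the
   input peak tables when present (it is an instrument/vendor quantity, not
   re-estimated from spectra); when absent the step is skipped with a logged
   warning.
3. **Ion curation.** Rule-based removal of redundant ions, all rules
   individually switchable:
   - *isotopes*: feature B co-elutes with A (|Δrt| ≤ 0.5 min), sits
     1.003355/z Da above it (z ∈ {1,2,3}, ±0.08 Da) and has the smaller
     reference area (mean over QC replicates);
   - *adducts*: same pattern with a configurable delta-mass list; the
     defaults are negative-mode offsets (Na−H +21.9819, 2Na−2H +35.9767,
     formate +46.0055, acetate +59.0133), matching negative-mode
     electrospray acquisition of sialylated glycopeptides;
   - *fragments*: co-eluting features whose areas correlate across samples
     at Pearson r ≥ 0.95 keep only their highest-m/z member; features are
     visited from high to low m/z and already-flagged partners are ignored,
     so an isotope flagged in the previous rule cannot displace its parent.

   The rules are this package's own; random m/z placement makes occasional
   chance collisions unavoidable (~0.5 % of true features at 300 features in
   a 2200 Da window), which is why the curation tests allow < 1 % true loss.

The filter is idempotent: re-applying it removes nothing.

## QC-pool normalization

Expression is the ratio of a sample's area to the mean area of the QC
injections bracketing it in run order (the nearest preceding and following
QC; at the ends of the sequence, whichever side exists). QC pools are
injected in pairs around every block of 20 patient runs, so a sample is
normalized by its own batch's pair, absorbing between-batch intensity drift.
Without run-order information the mean over all QC replicates is used.
Features with a zero QC mean in any bracket are dropped with a warning. A
sample identical to the QC pool maps to all-1 values, and the ratio is
invariant to rescaling any feature's areas jointly in samples and QC.

## Barcode encoding

**Grid.** 41 columns × 42 rows for the study's 1712 features (1722 cells, 10
blanks). For other feature counts, nrows = ⌈√n⌉ and ncols = ⌈n/nrows⌉,
overridable.

**Rt layout** sorts features by elution time (ties by m/z) and fills the
grid row-major from top-left; its blanks are the trailing row-major cells at
the bottom-right. It serves as a structure-free control: elution order is
unrelated to expression similarity.

**PCA layout** unit-variance scales and zero-centers each feature over the
samples (zero-variance features are mapped to all-0 rather than left
unscaled), takes a two-component principal decomposition, sorts features
ascending by the first loading, cuts them into consecutive groups of nrows
(41 groups of 42 at study scale; the last group may be short, leaving the
blanks at the bottom of the last column), and sorts each group by the second
loading. Column = group, row = within-group rank, so co-expressed features
become vertical neighbors. Each component's sign is canonicalized (largest
absolute loading made positive) so layouts are reproducible across
linear-algebra backends; loading-sort ties break by feature index. A matrix
of rank < 2 after scaling raises an error naming the deficiency. The layout
is fitted on the full cohort matrix — the original analysis likewise derived
loadings from all samples, and the decomposition never sees labels.

**Brightness.** The published description states only that strong expression
renders dark and blanks white; the exact mapping here is this package's own:
v = 255·(1 − (clamp(log2 r, −c, c) + c)/2c) with clip c = 2, so a ratio of
1 (sample = QC) is mid-gray (128), ≥ 4× saturates to black, ≤ 0.25× to
white. The log-symmetric map treats up- and down-regulation evenly on the
ratio scale; rounding is half-up.

**Marker coloring.** CA125 attenuates red and HE4 attenuates green:
f(x) = clamp(1 − log10(1 + x/x₀)/s, 0, 1) with reference points x₀ at the
clinical cutoffs (CA125 35 U/mL, HE4 70 pmol/L) and slope s = 2, both
configurable. Blue is never modified, and zero markers are the identity.
Blank cells are white in the monochrome barcode and therefore carry pure
marker color — a high-marker serum renders blue-dominant. Only the
qualitative directions are taken from the published description; the exact
transform is a documented stand-in.

**Rendering** upscales the cell grid to a square raster (default 227 px)
with nearest-neighbor interpolation, which preserves the blocky structure
and invents no colors; PNG output is lossless and byte-deterministic.

## Network and training

The full architecture reproduces the classical AlexNet stack layer by layer
(input 227×227×3 with zero-centering; conv 96@11×11 stride 4; cross-channel
normalization over 5 channels; 3×3/2 max pool; grouped conv 2×128@5×5 pad 2;
norm; pool; conv 384@3×3; grouped 2×192@3×3; grouped 2×128@3×3; pool; FC
4096; dropout 0.5; FC 4096; dropout 0.5; FC n_classes; softmax), verified in
tests by its shape trace (conv1 → 55×55×96, pool5 → 6×6×256) and parameter
arithmetic (conv1 = 96·(11·11·3)+96 = 34 944). In transfer mode the final
fully connected / softmax / classification stage is freshly initialized and
every earlier layer is frozen — pretrained parameters are bit-identical
before and after training, asserted in tests. Pretrained weights are a
user-supplied plug-in (nothing is downloaded); without them only fresh mode
is available, and the published transfer-vs-fresh comparison is out of reach
because it also requires the undeposited patient cohort.

Layers run on a compact numpy engine written for this package (grouped/
strided convolution via im2col, local response normalization, overlapping
max pooling, dropout, softmax cross-entropy) with finite-difference-checked
backward passes. All randomness — He-normal initialization, batch order,
dropout masks — flows from one seeded generator, so training is
bit-reproducible; a non-finite loss aborts with a divergence error.

Training defaults are the study's: batch size 5, 30 epochs, initial learning
rate 1e-4, SGD with momentum (0.9, the usual toolbox default; the study
names the optimizer but not the momentum) or Adam. Zero-centering subtracts
per-channel means computed on the training split from the raw 8-bit values.
Loss is two-class cross-entropy. No data augmentation.

A **reduced architecture** (64×64×3 input; conv 8@5×5 stride 2; 3×3/2 pool;
conv 16@3×3 pad 1; pool; FC 64; dropout 0.5; FC 2) exposes the identical
interface and is used for desk-scale training throughout the tests — it is
selected explicitly by `arch="reduced"`, never silently. One fit on ~70
64-pixel barcodes takes a few seconds on one CPU.

## Evaluation

Splits are stratified: each class contributes round(0.4·n) samples to the
test set, which reproduces the published test-set arithmetic (97 + 254 →
39 + 102 = 141); stratification is not stated in the text but is forced by
that arithmetic, and an unstratified option exists. ROC-AUC is the
normalized Mann-Whitney statistic (ties count one half), computed via
scikit-learn and cross-checked in tests against exhaustive pair enumeration.
Confusion metrics at cutoff 0.5 (score ties count as positive — the
convention is unstated in the source, and ≥ is adopted) are reported as
integer percents, rounded half-up to match the published table. Repeated
holdout draws n_repeats splits with seeds seed+0…seed+n−1; the confusion
table comes from a designated repeat (default: the last), since how the
published single table relates to the ten repeats is not stated. The
rank-sum comparison is two-sided Mann-Whitney: exact null distribution when
both lists have ≤ 12 values and no ties, otherwise the tie-corrected normal
approximation without continuity correction (identical lists give p = 1
exactly).

## Synthetic cohorts

Feature values are multiplicative: log values are a·z_block + b·ε with a
per-sample latent factor per block, b = √ln(1+CV²) from the idiosyncratic
noise CV (default 0.2, typical of QC-ratio LC-MS data), and a chosen so the
within-block log correlation equals block_corr (default 0.7, 8 blocks);
values are rescaled to unit mean so the non-EOC class sits at the QC level.
Differentially expressed features (default 5 %) are multiplied by
2^effect_size (default 1.0) in EOC samples and are concentrated in one block
by default, mimicking a coherent aberrant-glycosylation signal (an option
scatters them). Markers are log-normal with class-mean separation δ =
Φ⁻¹(AUC)·σ·√2 from the binormal identity; non-EOC locations (CA125 median
13 U/mL, σ_log 0.7; HE4 median 45 pmol/L, σ_log 0.35) are typical of healthy
sera. Calibration is verified empirically: the mean empirical marker AUC
over 50 cohort draws sits within ±0.01 of target. Consensus rt is uniform on
the 1–14 min gradient window and m/z uniform on 800–3000 Da.

Peak tables multiply cohort ratios by per-feature log-normal base
intensities (~10⁵), add position jitter (defaults 0.1 min, 0.01 Da — well
below half the alignment tolerances), and insert QC-pool injections with 5 %
replicate noise in bracketing pairs. Contamination can inject isotopes
(+1.003355 Da, 0.4× area), adducts (0.3× area), high-CV junk and low-S/N
features, all recorded as ground truth.

**What passing these tests does not show about real data:** the generator
has no retention-time drift or warping, no missing peaks, no heteroscedastic
or intensity-dependent noise, no correlated marker–glycopeptide structure,
and its block covariance is a free modeling knob, not an estimate of real
glycopeptide covariance. The published patient-cohort AUCs (0.881 PCA
transferred, 0.954 multicolored) are therefore not reproducible here: they
require the undeposited 351-patient dataset and pretrained weights. What the
scaled-down experiments do establish is directional: on block-structured
cohorts with planted signal, the PCA layout outperforms elution order, and
marker coloring outperforms monochrome, with multicolor PCA mean test AUC
well above 0.8 at 60 + 60 samples over ten repeats.

## Problem sizes used in tests

The test suite and acceptance script train the reduced network only:
variant comparisons use a 60 + 60-sample, 1712-feature cohort with ten
holdout repeats; curation checks use 30 samples × 300 features with 60
injected isotopes; the null control permutes labels on a 60-sample,
200-feature cohort over five seeds. These sizes were chosen so the full
suite completes in a couple of minutes on one CPU while leaving each
property comfortably away from its decision boundary.

## Known limitations

- Alignment is greedy; pathological peak clouds straddling tolerance
  boundaries can split differently than single-linkage clustering (the
  tests compare the two only in the well-separated regime).
- The brightness and coloring formulas are stand-ins for unpublished ones;
  only their directions are source-backed.
- The numpy engine is CPU-only and unbatched across workers; full-scale
  AlexNet training is possible but slow, and is not exercised by tests.
- Batch bracketing assumes QC injections are interleaved in run order; runs
  without run-order metadata fall back to a global QC mean.
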