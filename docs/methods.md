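# Methods

This note documents the models, procedures and numerical choices behind
`pathomil`, in the order data flows through the pipeline.

## Problem setting

Advanced high-grade serous ovarian carcinoma is treated with debulking
surgery (primary, PDS, or interval, IDS) followed by platinum-based
chemotherapy. Two outcomes matter clinically: whether the tumor is
platinum-sensitive (relapse ≥ 6 months after completing chemotherapy,
encoded as class 1) and the progression-free survival (PFS) time. The
package predicts both from digitized H&E whole-slide images (WSIs) fused
with clinical covariates, using weakly supervised multiple-instance
learning: the label attaches to a slide (a bag of tile feature vectors),
never to individual tiles.

## WSI preprocessing

Tissue segmentation works on the HSV saturation channel: median filter
(kernel `median_kernel = 7`), binarization at a fixed threshold
(`sat_threshold = 8` on the 0–255 scale) or Otsu's method, then morphological
closing with a square structuring element of side `close_kernel = 4`.
Two artifact filters then zero out pixels: the *white filter* removes bright
background glass (saturation < 15 **and** HSV value ≥ 200) and the *black
filter* removes pen marks and over-stained regions (RGB mean < 50). The
white/black cutoffs are conventional artifact bounds, exposed in
`SegmentationParams`, since no canonical values exist. For pyramidal slides
the mask is computed at the coarsest level whose longest side is ≤ 4096 px,
which bounds memory without affecting tile-level decisions; flat images are
segmented at native resolution.

Tiles are 256×256 px at level 0 (0.25 µm/px under a 40× objective, i.e.
64 µm of tissue per edge), stride 256 (no overlap), enumerated row-major.
A tile is kept by the *four-point rule*: four probes at `center ±
tile_size/4` in x and y are mapped into mask space; `four_pt_any` (default)
keeps the tile if at least one probe hits tissue, `four_pt_all` requires all
four. The rule is configurable because "mostly inside tissue" admits both
readings; `any` is permissive and suits the whole-tissue (no manual ROI)
philosophy of the pipeline.

Kept tiles are resized to 224×224 with bicubic interpolation (per-channel
float resampling, avoiding 8-bit re-quantization), scaled to [0, 1], and
standardized per channel. The channel statistics belong to the chosen
encoder; the ImageNet values (0.485, 0.456, 0.406)/(0.229, 0.224, 0.225) are
the fallback.

## Feature bags and encoders

Tile encoders are pluggable behind `EncoderContract` (a deterministic map
from normalized tiles to D-vectors). Pretrained pathology foundation models
plug in here; none ship with the package. The bundled `SyntheticEncoder`
projects 12 per-channel summary statistics (mean, std, min, max × RGB)
through a fixed seeded Gaussian matrix — deterministic, fast, and
sufficient to exercise every downstream code path. Bags persist to HDF5
(float32 `features` N×D, int32 `coords` N×2, identifying attributes).

## Network

Instance features are projected once, hᵢ′ = ReLU(W·hᵢ + b), into an
embedding of width `attention_hidden` (default 256; the desk-scale
experiments use 64). Gated attention scores each instance,

    aᵢ = wᵀ(tanh(V hᵢ′) ⊙ σ(U hᵢ′)),   αᵢ = softmaxᵢ(aᵢ),

and the slide embedding is M_WSI = Σᵢ αᵢ hᵢ′. The weighted sum is taken in
the projected space (hᵢ′ rather than raw hᵢ): the downstream fusion then
sees the same space the attention scored, and the choice is recorded here
because the raw-space alternative is equally defensible.

Two attention networks exist, selected by the surgery route (PDS/IDS);
the projection, instance classifier, fusion and output heads are shared.
Updates are naturally confined to the active route: parameters that receive
no gradient in a step are not touched by the optimizer (including weight
decay).

Clinical covariates C (z-scored continuous + one-hot categorical, fixed
order with a schema hash stored in checkpoints) fuse through a learned
vector-valued gate:

    g = σ(f_gate([M_WSI ; C])),   M_fused = g ⊙ (W_w M_WSI) + (1−g) ⊙ (W_c C),

a convex element-wise combination whose endpoints are testable: g ≡ 1
ignores the clinical branch, g ≡ 0 ignores imaging. The gate is
vector-valued (one weight per fusion dimension) rather than scalar — the
richer of the two readings of an unspecified dimensionality, and the one
that lets different embedding coordinates lean on different modalities.

Heads: classification is dual-output (softmax over
resistant/sensitive); survival is a single linear output, the risk score r̂
(unsquashed). The instance classifier is a single shared affine map on hᵢ′
(the single-branch variant; one-classifier-per-class is the other lineage
option).

## Losses

Classification: L_total = L_bag + λ·L_inst with λ = 0.9. L_bag is
cross-entropy of the slide prediction. L_inst is the clustering loss: rank
instances by α, give the top-k the bag label and the bottom-k the
complementary label (k = 8, reduced to ⌊N/2⌋ for small bags, minimum 1),
and average the instance classifier's cross-entropy over those 2k
instances.

Survival: the negative mean Cox partial log-likelihood over a batch,

    L = −(1/B) Σᵢ δᵢ [ r̂ᵢ − log Σ_{j: tⱼ ≥ tᵢ} exp(r̂ⱼ) ],

with risk sets formed inside the batch and tied times handled by the
inclusive comparison (Breslow convention; Efron is out of scope). A batch
with no events contributes zero loss (with a warning). The implementation
shifts by max r̂ for overflow safety; a brute-force risk-set enumeration
oracle agrees to ≤ 1e−9 over randomized batches.

## Training

Training is slide-level: every slide inherits its patient's label and
survival outcome, and each slide is one optimization example. Patient-level
aggregation (mean or median of slide scores) happens only at evaluation.

* Classification: Adam, lr 5e-5, weight decay 1e-4, dropout 0.5 on the
  attention and fusion modules, one update per slide.
* Survival: Adam, lr 2e-4, weight decay 1e-5, dropout 0.25, step LR
  scheduler (step 10, γ = 0.5; the scheduler's constants are package
  defaults, exposed in config). The default batch scheme is shuffled
  minibatch risk sets of 32 slides. A full-cohort scheme (complete risk
  sets, one update per epoch) is available, but with the 50-epoch cap it
  allows only ~50 optimizer steps and demonstrably underfits
  (held-out C ≈ 0.51 vs ≈ 0.81 for minibatches on the reference synthetic
  cohort); since the loss is defined per batch either way, minibatching is
  the default.

Both tasks run at most 50 epochs with early stopping, patience 5, on the
validation metric: patient-level AUC (classification) or patient-level
Harrell C (survival). Best-epoch weights are restored. Improvement counting
starts after a 10-epoch warm-up so a lucky first epoch cannot end training
degenerately; within the monitored phase the no-improvement counter never
exceeds the patience. Splits are patient-level simple random
0.65/0.20/0.15 (optional label stratification, off by default). The
multi-seed protocol trains 10 independent trials (seeds 0–9 by default) and
summarizes metrics as mean ± 1.96·sd/√n.

All randomness — initialization, shuffling, dropout — flows from one
integer seed; two runs with the same seed produce bit-identical histories.

## Evaluation statistics

* ROC-AUC: rank statistic (ties 1/2), patient-level bootstrap CI
  (1000 resamples default).
* Threshold metrics (precision/recall/F1/specificity) at score > 0.5 by
  default; the operating threshold is a config knob, not a learned value.
* Harrell C: comparable pairs per Harrell's rule, risk ties 0.5.
* Time-dependent AUC: the IPCW cumulative/dynamic estimator at a horizon,
  censoring weights from the Kaplan–Meier estimate of the censoring
  distribution. The estimator choice is recorded in output metadata; with
  no censoring it collapses to the plain ROC-AUC against the
  event-by-horizon indicator.
* Kaplan–Meier: product-limit with Greenwood log-log intervals; the median
  is the earliest time with Ŝ ≤ 0.5 and is reported "not reached" when the
  curve never crosses 0.5 (mirrored as an open upper CI bound).
* Tertile stratification: cutpoints are the 1/3 and 2/3 linear-interpolation
  quantiles of *training* risk scores, frozen, and applied unchanged
  elsewhere; assignment is score ≤ q1 → low, ≤ q2 → intermediate, else
  high. The quantile convention matters for group counts and is fixed here.
* Baseline tests: Pearson chi-square without continuity correction
  (categorical) and tie-corrected Kruskal–Wallis (continuous). Fisher's
  exact test is deliberately not implemented: the bundled development-cohort
  table is reproduced by the plain chi-square, which therefore suffices as
  the single categorical test.
* Paired bootstrap comparison of two models' AUC/C: patient-level
  resampling, percentile CI, two-sided p = 2·min(P(Δ*≤0), P(Δ*≥0)).

## Synthetic cohorts

`simulate_cohort` emulates the multimodal structure the pipeline consumes:
each patient contributes 2 primary + 1 metastatic slide (bags of 50–200
standard-normal instances in D = 64 dimensions), clinical covariates echoing
a typical baseline table (binary stage-like and cytoreduction-like
variables, a log-normal CA-125-like marker, a 3-level categorical), a
Bernoulli response label, and exponential survival with independent
exponential censoring whose rate is solved by bisection to hit the target
censoring fraction (0.3) in expectation.

Half the patients are signal carriers: round(π·N) instances per slide
(π = 0.2) are shifted by μ·u (μ = 2.0, u a fixed seeded unit direction);
metastatic slides carry 1.25·π (capped at 1) so the third slide is
informative under median aggregation. The patient latent score combines the
realized planted fraction (coefficient 20), the clinical effects and
N(0, 0.25²) noise; labels are Bernoulli(σ(6·s_centered)) and hazards are
0.05·exp(β_s·s_centered) per month with β_s = 1. The two scale constants
were calibrated once so the generator meets its own design contract — the
oracle score (projection of the mean bag feature onto u) separates labels
with AUC ≥ 0.95 at n = 300, and the true latent score attains Harrell
C ≈ 0.83, leaving genuine headroom for a trained model to reach C ≥ 0.8 —
and are frozen. Randomness is split per patient
(`default_rng([seed, patient_index])`), so enlarging a cohort never
perturbs existing patients.

What the generator does *not* emulate: real tile-feature geometry
(foundation-model features are neither isotropic nor Gaussian), staining
and scanner variation, spatial correlation between neighboring tiles,
informative censoring, and covariate–image correlation beyond the shared
latent score. Passing recovery tests therefore demonstrates that the
architecture, losses and training procedure can extract a planted
instance-level signal and calibrate risk groups — not that the pipeline
reaches any particular performance on clinical data.

`simulate_tissue_image` paints saturated ellipses (plus optional pure-black
patches) on a white canvas and returns the exact ground-truth mask, giving
the segmentation/tiling stage a geometric oracle.

## Desk-scale experiment sizes

The reference experiments (tests and `scripts/acceptance.py`) use
300 patients, D = 64, attention/fusion width 64, and 10 seeds for null and
stratification replications; a strong-effect classification run fits in
about half a minute on one CPU. The stratification experiment assigns all
held-out patients (validation + test, ≈ 35 per risk group) because KM
medians over ~15-patient groups are dominated by sampling noise.

## Known limitations

* The NumPy autodiff engine is single-threaded and eager; it is sized for
  desk-scale bags, not gigapixel cohorts with 1536-dimensional features.
* Survival training assumes non-informative censoring; the Cox loss uses
  Breslow tie handling only.
* Instance pseudo-labels assume the complementary class for low-attention
  instances, which is a heuristic of the clustering-loss lineage; for
  strongly imbalanced bags it can mislabel background in positive bags.
* The heatmap renderer assumes non-overlapping tiles (stride ≥ tile size)
  when claiming order invariance.
* `openslide` is not a dependency; pyramidal formats are supported only
  through the in-memory `SlideImage` interface (levels as downsampled
  arrays), and flat PNG/TIFF/JPEG through Pillow.
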