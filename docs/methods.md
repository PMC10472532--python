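# Methods

`oxicam` implements a contactless SpO₂-from-video pipeline: skin color
signals are extracted from hand video by chroma-based segmentation,
windowed into short segments, and regressed to blood oxygen saturation
either by optophysiology-inspired convolutional networks or by the
classical ratio-of-ratios calibration. A Bayesian two-group comparison
with a region of practical equivalence (ROPE) supports group analyses
(skin tone, hand side). Because real hand-video datasets with breath-hold
references are rarely shareable, the package carries a synthetic
optophysiological generator that serves as ground truth for every stage.

## Optophysiological signal model

Hemoglobin absorbs light differently depending on oxygenation: the
extinction of deoxygenated hemoglobin (Hb) exceeds that of oxygenated
hemoglobin (HbO₂) strongly in the red band, weakly in blue, and hardly at
all in green. The generator realizes this with per-channel relative
extinction constants (red 3.0/0.5, green 1.0/1.0, blue 1.6/1.1 for
Hb/HbO₂). These are *simulator constants* chosen to honor the qualitative
band ordering, not literature values. The skin color signal per channel c
is

    x_c(t) = DC_c · (1 + PI · m_c(S(t)) · p(t)) + n(t),
    m_c(S) = ε_Hb[c] · (1 − S/100) + ε_HbO₂[c] · (S/100),

with DC_c the baseline reflectance (0–255; scaled down for darker
Fitzpatrick tones and for the back of the hand), PI the perfusion index
(default 0.02 — a typical AC/DC modulation depth for reflectance
photoplethysmography), p(t) a zero-mean unit-amplitude pulse waveform at
the heart rate (raised-cosine systolic bump by default; a pure sine is
available for closed-form tests), and n(t) Gaussian sensor noise (default
SD 0.3 intensity units, the scale left after spatially averaging a few
thousand skin pixels plus residual lighting flicker). Palm-down
recordings additionally get a slow 1% multiplicative drift (sunlight/
shadow variation on the hairier, darker dorsum).

The ratio-of-ratios RR(S) = (AC/DC)_red / (AC/DC)_blue equals
m_red(S)/m_blue(S) exactly (the waveform cancels) and is strictly
decreasing in S on [85, 100], which is what makes the affine calibration
S ≈ a − b·RR workable.

### Breath-hold trajectories

Reference SpO₂ traces follow a protocol of alternating normal breathing
(30–40 s) and full-exhalation breath holds (30–40 s), three cycles per
recording. Measured saturation responds with a 15 s lag (circulatory
transit to the finger probe) and relaxes toward the target with a 10 s
first-order time constant, dipping 5–10 percentage points below the 98%
baseline — deep enough to fall below 90% in most recordings. The lag and
time constant are unvalidated defaults: the protocol itself is standard,
but no quantitative desaturation-response model was available, so a
lagged first-order relaxation was chosen as the simplest shape with the
right qualitative features. Values are clipped to [70, 100].

## Skin extraction

Frames are converted to YCbCr with the full-range BT.601 (JPEG) matrix —
the dialect is centralized in one constant pair so it can be switched —
and the Cr (red-chroma) histogram of each frame is split by Otsu's
method, implemented over the 256-bin histogram with exhaustive evaluation
of every cut and ties broken toward the lowest bin. The Otsu class with
the higher mean Cr is taken as skin (skin chroma is red-shifted relative
to typical backgrounds). The threshold is recomputed per frame by default
(robust to lighting drift); a fixed-from-first-frame mode exists. Skin
fractions outside [0.02, 0.98] set an implausibility flag. The R, G, B
means over the mask form the skin color signal. No morphological cleanup
is applied by default.

## Windowing, labels, and splits

Signals are cut into 10 s windows (3×300 samples at 30 fps) with a 0.2 s
stride — 5 windows per second, matching the 5 Hz rate to which the 1 Hz
reference is resampled with a generalized-cross-validated smoothing
spline. CNN windows are labeled with the reference at the window *end*
(causal, as in live monitoring; center-anchoring is available). The
ratio-of-ratios baseline instead uses *window-mean* labels on
center-anchored windows: AC/DC is a symmetric statistic of the whole
window, so its natural regression target is the window-average
saturation — end-anchoring would fold the desaturation transient into
the calibration as a systematic phase error.

Standardization is global per channel from training-set statistics
(per-segment z-scoring was rejected because it would erase the AC/DC
amplitude information the task depends on). Training data are
rebalanced by sampling with replacement, weighting each window inversely
to the population of its 1%-wide label bin (breath-hold labels pile up
near the normal range). Splits are structural: participant-specific mode
trains on cycles 1–2 of session 1, validates on cycle 3, tests on
session 2; leave-one-participant-out holds out all recordings of one
subject. Windows are assigned to a role only if they lie entirely inside
the role's time intervals, so train and validation can never share
overlapping segments.

## Regressors

The channel combination layer computes V = σ(W·U + b·1ᵀ): a linear map
across color channels applied pointwise along time, with a ReLU (or
identity, in the linear ablation). Three arrangements are provided:

* **model1** — mixing first: channel layers 3→16→12→7, then three
  conv(+optional batch-norm)+ReLU+max-pool(2) blocks (16, 8, 4 filters,
  kernel 7) and a 200-unit dense head (~32 000 parameters).
* **model2** — features first: an independent conv stack per color
  channel (8, 4 filters; no sharing), channel layers 12→10→8→7 on the
  pooled features, and a 20-unit head (~12 000 parameters).
* **model3** — interleaved: four conv+pool blocks with decreasing filter
  counts (64, 32, 16, 8) and a 2000-unit head (~312 000 parameters).

Exact filter counts and head widths are free choices; they were set to
land near the three variants' characteristic parameter-count magnitudes
(tens of thousands / ~ten thousand / hundreds of thousands) that
distinguish the designs. Ablations of model1 replace the mixing stack by
one linear channel combination (`linear_mix`) or the conv extractor by
dense layers (`dense_features`).

The networks, backward passes, and the Adam optimizer are implemented in
numpy (`oxicam.nn`); backpropagation is verified against central-difference
numerical gradients in the test suite. Training minimizes RMSE, keeps the
checkpoint of the epoch with the lowest validation loss, and is fully
seeded (initialization, shuffling, dropout), so runs are bit-reproducible.
One wrinkle is resolved deliberately: model selection always uses the
*lowest* validation loss (a "highest validation RMSE" selection rule would
keep the worst instance and is treated as an obvious slip). The scalar
head's bias is initialized to the training-label mean — labels live near
95–100% and Adam would otherwise spend most of a short budget closing
that offset. Default optimizer settings: Adam, lr 1e-3, batch 64, up to
300 epochs with early-stopping patience 30. Hyperparameter search is a
successive-halving (HyperBand-style) loop over random configurations
(learning rate, filter counts, kernel size, head widths, dropout,
batch-norm), keeping the best third per round with a tripled epoch
budget.

Experiment drivers use reduced problem sizes chosen as the package's
default desk-scale conditions: 3-subject cohorts, 40 epochs with dropout
0.3 and batch normalization (both selected on validation loss, the same
criterion the original tuning procedure optimizes). At these settings
every variant reaches a median held-out correlation near 0.9 on the
synthetic cohort.

### Ratio-of-ratios baseline

DC is the window mean; AC is √2 × RMS of the 0.5–4 Hz band-passed
component (3rd-order Butterworth, zero-phase), i.e. the amplitude of an
equivalent sinusoid — band-passed RMS was preferred over peak-to-peak for
noise robustness, and the band covers 30–240 bpm. The calibration
SpO₂ = a − b·RR is fitted by least squares on labeled windows and
predictions are clipped to (0, 100]. Red/blue is the default channel
pair; red/green is selectable.

## Postprocessing and metrics

Per-window predictions form a 5 Hz trace; values above 100% are clipped,
then a centered 10 s (50-sample) moving average with shrinking edge
windows is applied (shrinking windows avoid padding bias at the ends).
Per recording we report Pearson correlation (undefined for constant
traces — flagged as NaN), MAE, and RMSE over the time overlap with the
reference; groups are summarized by median and IQR with
linear-interpolation quantiles (stated because IQRs are not reproducible
otherwise). A random-guess null predictor draws uniformly between a
reference's minimum and maximum at 5 Hz and is smoothed identically; its
median correlation across many synthetic references is ≈ 0.

## Bayesian group comparison

Group comparisons use a BEST-style model: per-group Student-t likelihoods
with separate means and scales and a shared normality parameter, under
broad data-scaled priors (μ_j ~ Normal(pooled mean, 1000·pooled SD),
σ_j ~ Uniform(pooled SD/1000, 1000·pooled SD), ν−1 ~ Exponential(mean
29)). The posterior is sampled with an affine-invariant ensemble sampler
(emcee, 32 walkers), extending the chain until the effective sample size
of the mean difference reaches the target (default 1000) and its
split-chain R-hat drops below 1.05. The ROPE is Cohen's standardized
[−0.1, 0.1] scaled by a user-supplied data SD (0.3 for correlation-valued
metrics gives [−0.03, 0.03]); the equal-means hypothesis is accepted if
more than 95% of the posterior mass of μ_a − μ_b falls inside the ROPE,
rejected below 2.5%, and otherwise reported as undecided with the
fraction as the certainty quantifier.

## What the synthetic generator does and does not show

The generator reproduces the protocol structure, the extinction-ordering
physics of the AC/DC ratios, skin-tone and hand-side differences in
baseline reflectance, subject-specific heart rates, sensor noise, and
slow drift. It deliberately omits motion artifacts, photorealistic hand
appearance, melanin-specific radiative transfer, and — importantly —
channel-dependent pulse waveform shapes and phases: all three color
channels share one perfectly coherent pulse.

That last simplification has a real consequence for interpretability
experiments. For a *single linear* channel combination followed by an
amplitude-sensitive readout, the optimal weights in this simulator form a
pulse-cancellation direction, and the SpO₂-*insensitive* green channel is
the ideal cancellation reference: subtracting green removes the common
pulse exactly and leaves the red channel's oxygen-dependent amplitude
residual. Planted-direction controls confirm this (a red-minus-green
initialization reaches a held-out correlation of ~0.7 where a red/blue
"sensitivity" direction reaches ~0.06). Weight-visualization runs on this
generator therefore tend to show red/green rather than red/blue
dominance. On real skin video the blue channel is empirically the
dominant partner of red, which suggests that waveform decoherence and
channel-specific noise — absent here by design — are what demote the
green channel in practice. Passing or failing the weight-direction check
on synthetic data is thus informative about the simulator, not about
real recordings.

## Numerical choices and degenerate inputs

* Otsu thresholding requires ≥ 2 populated bins and raises a degenerate-
  input error otherwise; fp-level ties resolve toward the lowest bin.
* Thresholds computed on the rounded Cr histogram are applied to the
  rounded Cr image, so bin-boundary pixels cannot straddle the decision.
* Segments shorter than one window produce an empty set with a warning;
  an empty skin mask fails with the frame index named.
* Generated intensities are clipped to [0, 255] and clipping is logged.
* AC/DC computation requires ≥ 5 s windows and positive DC.
* Constant traces make Pearson correlation undefined: NaN plus a warning,
  excluded (and counted) in group summaries.
* The reported problem sizes for tests and the acceptance script
  (3-subject cohorts, 40-epoch budgets, 20 weight-visualization
  instances, ~10⁴ posterior draws) are the package's desk-scale defaults.
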