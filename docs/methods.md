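# Methods

This note documents the models, conventions and numerical choices behind
`dopaquant`, and what its synthetic-data tests do and do not establish about
real recordings and images.

## Trace quantification

**Units and sampling.** Traces are uniformly sampled; amperometric defaults
are 10 kHz sampling with currents in nA and dopamine concentrations in µM.
Acquisition hardware low-pass filters at 400 Hz; the package treats that
filter as a property of the recording and does not re-filter during analysis.
A zero-phase Butterworth low-pass (`lowpass_filter`) is available for
conditioning synthetic data to resemble filtered acquisitions.

**Calibration.** Electrodes are calibrated by ordinary least squares of
plateau current against the dopamine ladder (0, 1, 5, 10, 20 µM is the
conventional series). An electrode is usable when the slope is positive and
r² ≥ 0.98 (configurable); this encodes the "only linear electrodes are used"
acceptance rule as a concrete, adjustable gate.

**Baselines.** Peak amplitude and AUC subtract the mean of a pre-stimulus
baseline window; the default window used throughout the examples and tests is
~50–100 ms ending a few ms before onset. Raw (non-subtracted) values are
available by passing `baseline_window=None`. Whether AUC should be
baseline-subtracted is genuinely open in practice; subtraction is the default
here because it makes the metric invariant to electrode offset drift.

**Rise time.** The 20–80% rise time takes the baseline-corrected peak after
onset as 100%, locates the *first upward* crossings of 20% and 80% with
linear interpolation between bracketing samples (sub-sample resolution, ties
broken toward the earlier sample), and is exactly 0.6·d for a linear ramp of
duration d. The metric is invariant to amplitude scaling and baseline offset.

**AUC.** Trapezoidal integration with interpolated window endpoints, so the
integral is exactly additive over adjacent windows and exactly linear in
amplitude. The standard train window is 2.935 s from the first stimulus.

**Trains.** Per-stimulus amplitudes are measured within each inter-stimulus
window relative to the trace value one sample before that stimulus (local
baseline). This prevents double-counting when responses summate on a slow
decay; it slightly underestimates amplitudes when a response has not fully
risen before the next onset. Normalization divides by a caller-supplied
reference first amplitude (e.g. the control-group mean).

**Artefact blanking.** Stimulus artefacts are removed by replacing samples in
[onset, onset + 1 ms] (configurable) with linear interpolation between the
flanking retained samples. The blanking method is a package choice; the
windowed AUC after blanking matches artefact-free generation to well under
1%.

**DAT block.** The before/after comparison reports area_drug − area_baseline
and area_drug / area_baseline over a common window. A non-positive baseline
area leaves the fold undefined (reported as None), never infinite.

**KCl responses** are quantified from the start of the puff to 200 s after
its end (default 10 s puff), peak and trapezoidal AUC, baseline from a
pre-puff window.

**Microdialysis.** Values are divided by the mean concentration of a
designated reference series (e.g. the control group) over the 76–120 min
window, inclusive; the log copy is the natural log of the normalized values
and is refused when any normalized value is non-positive.

## Synthetic transients

The release transient is a peak-normalized difference of exponentials
c(t) = A·k·(e^(−t/τ_decay) − e^(−t/τ_rise)) with k set so max c = A. This is
a deliberately generic kinetic form — the quantification code never assumes
it, which keeps recovery tests fair. Uptake block is emulated by multiplying
τ_decay by `clearance_scale` (blocking reuptake slows clearance; no explicit
uptake model is attempted). Defaults: τ_rise 1 ms, τ_decay 40 ms, µM-scale
amplitudes — the regime of fast striatal dopamine transients. Stimulus
artefacts are single-sample current spikes at onsets; noise is additive
Gaussian in the concentration domain, propagated through the calibration map.
Ground truth (per-stimulus peak and rise time, windowed AUC) is computed by
dense numerical evaluation of the kinetic form at 25× the acquisition rate,
independent of the analysis code path; the truth AUC matches the closed-form
integral to well within 0.1%.

Recovery tests average four noisy sweeps per recording before extracting
metrics, mirroring standard sweep-averaged quantification. With 2%-of-peak
noise per sweep this holds the max-statistic bias of the peak estimate under
2%; without averaging the bias of "max of signal + noise" is roughly
σ·√(2 ln N_eff) and can exceed 3% — a property of the estimator, not a bug.

## 3D volume pipeline

**Conventions.** Voxel order (z, y, x), 0-based indices, physical coordinates
in µm from the volume origin; default voxel size 0.125 µm in z (the standard
SIM z step) and 0.04 µm laterally (typical of reconstructed SIM; the lateral
size is an assumption, configurable everywhere).

**Segmentation.** Otsu thresholds are computed on a 256-bin histogram of the
channel's observed range without rescaling (`skimage.filters.threshold_otsu`);
the mask is strictly-greater-than. Connected components use 26-connectivity
(8 in 2D). Size filters are inclusive on both bounds. Filtering order is
threshold → label → size-filter on both channels; overlap classification is
evaluated against the size-filtered axon mask. Note that Otsu assumes a
meaningfully bimodal histogram: on volumes where foreground occupies ≪1% of
voxels and noise is strong, the threshold can split the noise mode instead —
ROIs should contain signal, as they do in practice.

**Skeletonization.** The axon mask is Gaussian-smoothed (default σ = 1 voxel
per axis), re-binarized at 0.5, and thinned to a one-voxel curve skeleton by
sequential simple-point deletion: a voxel is removed only if its 26-bit
neighborhood pattern is *simple* (removal preserves the number of 26-connected
object components and 6-connected background components — the
Bertrand/Malandain characterization) and it is not a curve endpoint; deletion
proceeds in six directional subiterations, each restricted to voxels with
object material behind them so one-voxel-thick structures cannot erode
lengthwise. Patterns are memoized, keeping the pure-Python implementation
fast on tubular masks.

**Length measurement.** Skeleton length is *not* the sum of per-voxel steps:
a 26-adjacency graph with anisotropic physical edge weights is reduced to a
spanning tree, leaf spurs shorter than 0.3 µm hanging off junctions are
pruned (thinning artifacts of bumpy tube surfaces), and each maximal path is
measured as a polyline resampled every 4 voxels, summing chords. Chord
resampling removes the staircase bias that per-step summation incurs on
oblique lines (up to ~20% at SIM anisotropies). On rendered tubes of radius
0.25 µm the recovered length is within ~6% of the true centerline length
across straight, L-shaped, diagonal and oblique geometries; thinning erodes
roughly one radius at each tube end, which is the dominant residual for short
segments.

**Cluster metrics.** In-axon classification is strictly greater than 40%
voxel overlap ("positive association"); density divides the in-axon count by
the ROI volume by default, with the axon-marker volume available as an
alternative normalizer (`density_per_th_volume`). Mean volume of an empty set
is reported as missing, not zero.

**Shuffle null.** Each object's voxel set is rigidly translated (no rotation)
by an integer-voxel displacement drawn uniformly from a box (default
1×1×1 µm³) centered on its original centroid; out-of-bounds draws are
redrawn. Per round the in-axon classification and cluster metrics are
recomputed; the null is the mean over rounds (default 1000). With
structureless masks the mean shuffled in-axon fraction equals the mask
fraction to within Monte-Carlo error; with clusters planted inside axons and
smaller than the extra-axonal population, shuffling lowers in-axon density
and raises mean in-axon volume — the diagnostic direction for genuine
intra-axonal clustering.

## Synthetic volumes

Axon centerlines are fixed-step random walks (default step 0.5 µm) with
Gaussian angular jitter, clipped at the volume boundary; tubes of fixed
radius (default 0.25 µm) are rendered around them by exact point-to-segment
distance on voxel centers. Intra-axonal clusters follow a Poisson process
along arclength, centered on the centerline; extra-axonal clusters follow a
Poisson process in the axon complement, realized by redrawing positions until
the whole ellipsoid avoids the axon mask (thinning a spatial Poisson
process). Cluster ellipsoids are mildly anisotropic (axis ratios 0.75–1.3)
with requested volumes drawn uniformly from a configurable range; the truth
records both the requested analytic volume and the rendered voxel volume —
recovery is asserted against the rendered volume, which is the only quantity
a voxel-level pipeline can match exactly. Placement enforces a minimum
centroid separation of two maximal radii on a best-effort basis: the Poisson
*count* is always honored (a biased count would corrupt rate-recovery tests),
so extremely crowded scenes may contain touching clusters. PSF blur is an
anisotropic Gaussian; noise is additive Gaussian only — no Poisson shot
noise, no SIM reconstruction artifacts (documented limitation: passing tests
show metric correctness on clean geometry, not robustness to reconstruction
artifacts). Truth always describes the pre-blur, pre-noise scene.

Cluster-recovery test conditions use cluster volumes of 0.005–0.02 µm³ with
PSF σ = (0.06, 0.03, 0.03) µm: blur must remain small relative to cluster
size or the blur-dilated masks cross the upper size bound (0.04 µm³) and the
paper-style size filter removes them — with these conditions the in-axon
count is recovered exactly at 5% noise. The extra-axonal cluster rate
(0.8/µm³) keeps the cluster channel's foreground fraction high enough for
Otsu bimodality, consistent with dense striatal active-zone labeling.

## Synaptosome pipeline

Rolling-ball background subtraction is implemented as grayscale opening with
a disk of the stated physical radius (1 µm default) followed by subtraction
and clipping at zero — a standard approximation of the classical rolling
ball that is exact for flat backgrounds and conservative for slow gradients.
Detection applies Otsu, 8-connected labeling, inclusive area bounds
(0.2–1 µm²) and a strict bounding-box extent ratio max(x,y)/min(x,y) < 1.5.
Bassoon/TH co-positivity is decided by pixel overlap relative to the smaller
object at a 20% threshold (the co-positivity criterion is not standardized;
the Syt1 criterion is reused and configurable); matching is one-to-one
greedy by best overlap, and the categories partition the union of filtered
objects. Syt1 positivity requires Syt1 pixels to cover 20–100% of the
category object's pixels — coverage is measured relative to the category
object, so a large Syt1 blob covering a small punctum counts as positive
while a tiny speck does not.

The field generator plants non-overlapping round puncta per category with
Bernoulli Syt1 labels; positives receive a co-centered Syt1 punctum (100%
coverage), negatives none. Planted fractions are therefore recovered exactly
on noiseless fields — this validates the category/criterion logic, not
robustness to overlapping or partially colocalized puncta.

## Reproducibility

All randomness derives from a master seed through named substreams
(SHA-256 of the stage name spawns a `numpy` SeedSequence key), so stages are
independently rerunnable and bit-identical. Volumes and images are written as
plain multichannel TIFF with sizes and channel names in the image description
(the OME writer embeds a per-file UUID, which would break byte-identical
reruns; OME-TIFF is still accepted on read). Reports sort rows and fix float
formatting, making CSV/JSON outputs deterministic.

## Problem sizes

The test suite and acceptance script run on volumes of roughly
28×140×140 voxels (3.5 × 11 × 11 µm³), 512² px fields of 300 puncta, and
3.3 s traces at 10 kHz, with 1000 shuffle rounds where the null is exercised
— sizes chosen so the full parameter-recovery battery completes in about a
minute while every statistical check retains comfortable power.
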