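# Methods

This note records the models, parameter choices and numerical decisions
behind `topodecode`, in the order data flows through the package.

## Synthetic experiment model

The simulator emulates a goal-directed planar reaching study: 12
subjects, 128-channel EEG at 1024 Hz, 416 trials per subject (208
self-executed "active", 208 robot-guided "passive"), targets appearing
in four orthogonal directions (balanced: 52 per direction among active
trials), successive movements at least 2 s apart (default inter-onset
gap 2.5 s plus up to 0.3 s jitter).  Cursor kinematics are generated
with the EEG on a common clock.

**Planted signal.** Every trial carries a movement-related cortical
potential: zero until `onset_lead` before movement onset, a monotone
cosine ramp to a negative peak 50 ms after onset, and a cosine recovery
to baseline 1 s later.  Defaults: lead 0.25 s, peak −8 µV (active) /
−4 µV (passive).  The wave is weighted over sensors with a Gaussian
scalp patch (σ = 0.5 layout units ≈ 2–3 inter-sensor spacings) centred
on the left motor region (sensor D18, the montage position closest to
10–20 C3; subjects are modelled right-handed, so the pattern is
contralateral).  Active trials with slower reaction times build the
ramp up later: the effective lead is
`0.25 + 0.3·(E[RT] − RT)` s, clipped below at 80 ms, so pre-movement
epochs carry reaction-time information in their *timing*, and the
population-average lead remains 0.25 s.  Each direction adds an
execution-locked negative component (peak −5 µV around 0.3 s after
onset) over its own patch: left/right movements over the contralateral
motor region, up/down over midline fronto-central (≈FCz) and
centro-parietal (≈CPz) patches.

**Variability and noise.** Amplitudes scale lognormally per subject
(σ = 0.15) and per trial (σ = 0.10).  Background noise is per-channel
1/f ("pink") noise, synthesized in the frequency domain (power
flattened below 0.5 Hz), 10 µV RMS.  Blinks arrive as a Poisson
process (15/min), each a gamma-shaped positive transient (~80 µV at
the frontal pole, Gaussian scalp decay from ≈Fpz).  All draws come
from one seed; identical (config, seed) reproduce recordings bitwise.

**Reaction times** follow an equal-weight two-mode lognormal mixture
(medians 0.25 s and 0.55 s, σ = 0.18), truncated by redraw to
[0.15, 0.8] s, plus 2% outliers placed uniformly just outside those
bounds — so the configured outlier probability is exactly the expected
fraction outside the retention window.  The movement itself is a bell
(raised-cosine) speed profile, 0.35 m/s peak, 0.6 s duration, aligned
so the 0.05 m/s threshold crossing falls exactly at stimulus + RT; a
return stroke brings the cursor back between trials.

**What the simulator does not model:** volume conduction from dipole
sources (patterns are planted directly in sensor space), muscle/line
noise, channel dropouts, non-stationary drifts, or cross-subject
montage misalignment.  Tests passing on this generator show the
pipeline recovers what it assumes — sensor-space class structure under
1/f noise and ocular artifacts — not that it handles every failure
mode of real recordings.

## Preprocessing

* Bandpass 0.1–40 Hz: MNE's default windowed-FIR, zero phase, applied
  to the continuous recording.
* ICA cleanup: FastICA (16 components) fit on a temporally decimated
  copy (≤100k samples); components whose time course correlates with
  the frontal-channel average above 0.7 in magnitude are subtracted via
  their back-projection (a rank-limited subtraction, so untouched
  components pass through exactly).  On this simulator's Gaussian 1/f
  background the FastICA fixed point has no stable rotation for most
  components and the iteration cap is routinely reached; the blink
  component, which is heavy-tailed, is resolved regardless, so the
  default policy is to warn and proceed.  A strict mode raises a
  diagnostic error with the iteration count instead.
* Movement onset = first cursor-speed crossing of 0.05 m/s within
  1.5 s of the stimulus; RT outside [0.15, 0.8] s is discarded.  The
  fast/slow threshold is the per-subject median of retained RTs
  (label fast ⇔ RT < median).  RT labels exist for active trials only
  (reaction time is undefined for robot-initiated movement), and the
  RT dataset takes a seeded random half of the retained active trials,
  matching a study in which concurrent reaction labels cover only part
  of the experiment (~50 trials/class at full scale).
* Epochs are cut relative to movement onset — (−0.5, 0) s for RT,
  (−0.5, 0.5) s for active/passive, (−0.5, 1.5) s for directions —
  resampled 1024 → 250 Hz by polyphase filtering, then z-scored per
  channel per trial over time.  Normalizing *after* resampling makes
  the output moments exactly 0/1; a guard test bounds the interior
  difference against the opposite order at the sub-percent level for
  these band-limited signals (polyphase edge ripple dominates the
  residual).

## Spatial map

Sensors are sorted front-to-back into 13 bands (two bands of 9 at the
frontal and occipital extremes, eleven of 10 between), each band
ordered left→right; over-full bands drop their laterally outermost
sensor.  This yields the 13 × 9 grid with 11 peripheral sensors
removed.  The assignment ships as an editable CSV asset and is
re-validated on load; the exact identity of the dropped set is an
approximation derived from the standard montage geometry.  A
quantitative check holds on the shipped asset: for 98.3% of mapped
sensors the nearest mapped neighbour in layout space lies within
Chebyshev distance 2 on the grid (test threshold 95%).

## Decoder

Five learnable layers.  Three 3-D convolutions, kernel 3 × 4 × 5
(rows × cols × time), with 'same' zero padding on the spatial axes and
valid convolution in time — a 9-column grid cannot survive three valid
4-wide kernels, so spatial padding is forced; pooling (1, 1, 2) after
each (temporal only, keeping the full scalp grid visible).  The fourth
layer is a 2-D convolution, kernel 3 × 5 in the (row, time) plane with
weights shared across grid columns, consuming the 3-D feature stack as
its input channels — 2-D weights at full spatial resolution, which is
also what keeps Grad-CAM maps localizable in both grid axes.  Pooling
(2, 2) over (rows, time) follows, then a dense softmax layer.  Each
convolution is followed by ReLU then batch normalization then pooling.
Filter counts default to 4/8/8 and 16 — sized for single-core
training — and are configurable.  Valid temporal convolution with this
pooling schedule supports T ∈ {125, 250, 500}.

Weights use He (variance-scaling) initialization from a seeded
generator.  Training minimizes mean cross-entropy with Adam
(lr 10⁻³, batch 64, 60 epochs by default); there is no dropout,
weight decay or schedule — batch normalization is the only
regularizer.  The implementation is plain numpy with JIT-compiled
direct convolution kernels; every layer has an explicit backward pass,
verified against central finite differences (≤10⁻⁴ relative error on a
float64 model), and training is bit-reproducible for a fixed seed (the
`deterministic_mode` flag documents this contract; nothing in the
stack is nondeterministic to begin with).  An optional stacked
channels × time baseline of matching depth (`build_model_2d`) is
provided for representation comparisons.

## ERP statistics

The cluster permutation test thresholds pointwise two-sample
pooled-variance t statistics at a two-sided `point_alpha` (default
0.05), groups suprathreshold points into clusters connected through
sensor adjacency and temporal contiguity (positive and negative
separately), scores each cluster by its summed t, and compares
observed masses against the permutation null of the maximum |mass|
under trial relabelling.  P-values use the add-one rule
p = (1 + #{null ≥ obs}) / (n_perm + 1); defaults n_perm = 1000.
Permutation t-maps are computed in vectorized blocks and clusters via
sparse connected components, which keeps a 500-permutation test on
20+20 trials × 10 channels × 50 samples around 0.2 s; MNE's
implementation of the same test serves as an independent oracle in the
test suite (observed cluster masses agree exactly).  Adjacency comes
either from layout distance (default radius 0.45 layout units, ~1.5×
the montage spacing) or from the 8-neighbourhood of the grid.

The MRCP is the 1–4 Hz band of the trial-averaged waveform (order-1
zero-phase Butterworth; filtering and averaging commute, and the low
order limits distortion of the slow ramp).  Onset detection must
respect a property of that band: the 1 Hz high-pass differentiates the
slow ramp, producing a positive lobe before the negativity, so the
waveform's *value* crosses any baseline-derived threshold only ~0.1 s
before movement even for a ramp that departs at 0.25 s.  The onset is
therefore slope-defined: the channel and its negative peak are chosen
inside the post-baseline interior of the epoch (the baseline period
and a 50 ms right edge are excluded — zero-phase filter transients
live at the edges), and from the point of steepest descent the onset
walk runs back while the Savitzky–Golay-smoothed downward slope
(120 ms window, order 2) stays above 5% of its maximum.  An onset is
only reported if the peak lies below `onset_k = 2` baseline standard
deviations (baseline = first 150 ms of the epoch) and the descent
lasts ≥ 50 ms; a flat epoch yields none.  On noise-free templates this
recovers a 0.25 s lead as 0.22 s (the residual bias is the filter's);
on full-scale simulated subjects the recovered lead is 0.19–0.25 s.

The raw-epoch baseline flattens each trial to a channels·time vector
and fits L2-regularized multinomial logistic regression (C = 1),
evaluated leave-one-subject-out.

## Validation protocols and metrics

Leave-one-subject-out trains on all subjects but one and tests on the
held-out one (one accuracy per subject; fold seeds derived from the
base seed).  Subject-specific and all-data protocols use stratified
4:1 train/test splits — stratification is a deliberate strengthening
of a plain random split, protecting small runs from empty classes —
with 10 random partitions averaged in the all-data case.  Reports
carry per-fold accuracies, their mean and population standard
deviation, a row-normalized percentage confusion matrix over pooled
predictions, and macro F1 (unweighted mean of per-class F1).

## Grad-CAM

Maps come from a `cam_resolution` variant of the architecture that
shrinks the pooling windows (one temporal pool instead of three, none
after the 2-D stage) and is retrained, keeping ~0.5 ms-scale time
resolution in the final feature maps.  For a trial and target class,
the gradient of the class *score* (pre-softmax logit) w.r.t. the 2-D
convolution's post-ReLU feature maps is averaged over space and time
into one weight per feature channel; the weighted feature-map sum is
rectified, upsampled to 13 × 9 × T (multilinear; nearest-neighbour
selectable) and max-normalized.  Per-class maps average over
validation trials and re-normalize.  Max-normalization makes maps
invariant to positive rescaling of the class score (tested exactly);
the pre-normalization mean is kept on each map so that class-contrast
comparisons (weaker plants → weaker activations) remain possible.

`localization_score` quantifies Fig-style alignment against a known
planted region: the fraction of the top-5% saliency mass (ties
included, so a uniform map scores the mask's volume fraction) lying
inside the region.  In the planted-recovery experiments the region is
sized like the simulator's scalp patches (≈5 × 5 grid cells × 240 ms);
with much smaller plants the map's argmax still falls inside the
region but the decoder's receptive-field halo spreads the top-mass
over neighbouring cells, which is a property of the architecture, not
of the saliency method.

## Scaled-down study sizes

Default tests and the bundled experiments run reduced problem sizes
chosen once: unit fixtures use 16–48-trial subjects; the decode-sanity
experiment uses 4 subjects × 100 trials, T = 125 (the active/passive
task on a symmetric (−0.25, 0.25) s window), a 2/4/4 + 8-filter
decoder and 20 training epochs; cluster-test calibration uses 20
trials/condition on 10 channels × 50 samples with 500 permutations and
200 repeats.  The acceptance script alone runs full 416-trial
subjects.  Accuracy expectations under these sizes are validated
against chance via binomial bounds rather than against any fixed
percentage.

## Known limitations

* Sensor-space simulation only; no forward model, so source-level
  claims are out of reach by design.
* The planted classes are fixed additive spatiotemporal templates in
  near-Gaussian noise, so the Bayes decision rule for the synthetic
  decoding tasks is close to linear in the flattened epoch.  A
  regularized linear model is therefore a near-ceiling reference on
  synthetic data; a decoder's advantage over such a baseline on real
  recordings draws on nonlinear and nonstationary EEG structure that
  this generator deliberately does not model, and should not be
  expected to reproduce here.  The decode-sanity test asserts both
  bars (above chance and above the linear baseline) and the second one
  documents exactly this gap when it fails.
* The grid asset's dropped-sensor set is one valid solution of the
  stated constraints, not a reconstruction of a published table.
* FastICA on near-Gaussian backgrounds does not converge in the
  fixed-point sense; blink removal works regardless (see above), but
  component indices are less stable across seeds than on real EEG.
* The decoder is CPU-sized; at the default filter counts it trains a
  full-scale subject fold in minutes, not seconds, and no GPU path is
  provided.
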