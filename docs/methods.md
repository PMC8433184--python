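# Methods

## The phenotyping model

One incubator is one independent observation. Its 200 × 200 px
brightfield patch series is reduced to a state label and transition
frames by a fixed decision order; every step is a deterministic function
of (patch series, classifier weights, configuration):

1. **Occupancy.** The patch classifier votes over the first
   `persistence_frames` frames; a majority of non-embryo labels means
   `Empty` and the protocol stops.
2. **Alive/dead.** The mobility function `m[t] = mean |p[t+1] − p[t]|`
   (mean *absolute* pixel difference — a signed mean of a deforming but
   mass-conserving embryo would cancel to ≈0 and could not produce a
   step at twitch onset) is median-filtered; if its population variance
   is below the dead threshold the embryo is `Dead`. Variance of the
   mobility trace is the only alive/dead criterion.
3. **Hatch.** The first frame opening a run of ≥ `persistence_frames`
   consecutive `Empty` classifications. No such run before the end of
   the recording ⇒ the late-hatching path.
4. **Twitch.** On the *reduced* mobility trace — the filtered trace
   cropped at the hatch frame, or the full (noncropped) trace for late
   hatchers — the twitch is the first upward crossing of the trace
   through its own mean: the first pair index `i ≥ 1` with
   `v[i] ≥ mean` and `v[i−1] < mean` (earliest index wins; ties on the
   boundary count as crossed). Pair `i` compares frames `i` and `i+1`,
   so the reported twitch frame is `i + 1`. A trace with no crossing
   (alive by variance, yet featureless) yields `Unclear` with no twitch
   time; in practice this requires a non-constant trace that never dips
   below its mean, which the variance rule all but excludes.
5. **Bean.** The first persistent `PreBean → Bean` label switch starting
   before the twitch frame. If no persistent `PreBean` run precedes the
   first persistent `Bean` run — the embryo was already folded at the
   start, or never clearly reached the bean stage — bean timing is
   unresolvable and the embryo is `Unclear`; otherwise it is `Normal`
   (hatch seen) or `LateHatching` (hatch not seen).

Stage intervals are exact products: `(frame_b − frame_a) ×
frame_interval` minutes, with 0-based frame indices throughout.

### Dead-threshold calibration

The dead threshold self-calibrates per run as 3× the 95th percentile of
the trace variances of incubators the classifier calls empty — an empty
trap carries the same sensor noise as a dead embryo but no motion, so it
bounds the static regime from above. The configured
`dead_variance_fallback` (default 0.01 intensity², for imagery scaled
like the synthetic renderer's) acts both as the value used when a run
has no empty incubator and as a floor on the calibrated value: a
noise-free recording calibrates to exactly zero, which no variance is
strictly below. An absolute `dead_variance_threshold` in the
configuration overrides calibration entirely; it should sit well above
the noise-only trace variance (≈ `Var(|d|)/N_pixels`, i.e. ~1.6 × 10⁻⁴
at noise σ = 3 on 40 000-pixel patches) and below the variance induced
by twitching (≥ 0.04 in the renderer's regime).

## The stage classifier

Patches are downscaled to 48 × 48, min–max normalised to [0, 1]
(illumination varies across lanes; the normalisation removes the gain
term), flattened, and passed through a fully connected network (one
ReLU hidden layer of 64 units, softmax over the three classes). Training
runs through scikit-learn's MLP with the L-BFGS solver — full-batch,
deterministic given the seed, and markedly more stable than SGD at this
data size (hundreds of patches per class). A stratified 20 % split is
held out and its accuracy stored on the model; minority classes are
oversampled to the majority count before fitting (the resampling
analogue of inverse-frequency loss weighting — real annotated sets are
imbalanced). The fitted weights are frozen into a pure-NumPy forward
pass, so inference has no training-library dependence, is bit-reproducible,
and serialises to a single checkpoint (zip of a JSON header plus weight
arrays, class order included).

`persistence_frames` (default 3) debounces transition detection: one
misclassified frame must not create or destroy a transition. Three
frames equal 15 min of wall time at the 5-min interval — short against
the hour-scale stage durations.

## Fluorescence quantification

`I_SBR = I_ROI / I_BG` per frame. The incubator mask is built once from
an embryo-free brightfield patch: Otsu's threshold separates the dark
trap walls, the wall outline is dilated (disk radius 5 px, bridging the
gate opening), holes are filled, the outline is eroded back and the wall
band subtracted, leaving the interior; the mask is then extended by
`mask_dilation_radius` (default 2 px) to cover the embryo boundary.
`I_ROI` is the *nonzero median* of the masked GFP patch — robust to the
unmasked openings around the embryo outline; `I_BG` is the *mean* of the
background window spanning the full patch width over the top 7 µm
(20 rows at 0.35 µm/px; the window is 10 % of the patch area by
construction, distinct from the ~4 % unmasked openings inside the trap).
The two statistics are deliberately different. Because each frame is
normalised by its own background window, `I_SBR` is exactly invariant to
global intensity scaling, which is the point of the ratio: lamp drift
cancels. Population profiles average `I_SBR` across embryos per frame
with hatch dropout (an embryo contributes until its hatch frame) and
report SEM, flagged at n = 1.

## The synthetic chip renderer

The generator emulates the imaging geometry, not embryo morphology: a
bright background (level 180) with dark rectangular trap walls (level
60, 6 px thick, 64 × 44 px outer extent, an 8 px gate opening), six
traps per field of view at a 210 px pitch by default, 0.35 µm/px, and a
70 µm patch = 200 px. The embryo is a textured ellipse (~52 × 32 px,
granular smoothed-noise texture); the bean stage adds a bright crescent
of inner structure along the major axis. Hatching renders the trap empty
from the hatch frame on (the larva leaves); dead embryos are
bit-identical across frames before noise; `Unclear` embryos are rendered
already folded at frame 0, so no pre-bean→bean transition is observable.
Gaussian sensor noise (σ default 3 intensity levels, chosen so classifier
accuracy saturates) is added independently per frame. The GFP channel
renders embryo pixels at `fluo_ratio` × a flat background (level 100).

Twitching is a rigid jitter of the embryo sprite: a fixed-radius
(`jitter_amplitude`, default 3 px) random-angle walk with an angular
step of at least 45° per frame, plus a ±5° rotation. The minimum angular
step guarantees consecutive poses differ by ≥ 0.77 × amplitude, so the
mobility trace steps up cleanly at the twitch frame — muscle twitching
does not pause — rather than flickering near zero as i.i.d. offsets
occasionally would.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: optics (no point-spread function,
no defocus), debris and partially clogged traps, embryo orientation
variability and rolling, gradual morphological change within stages,
photobleaching, stage drift, and the real appearance of the bean fold
(the crescent is a learnability device, not morphology). Classifier
accuracies reported here are accuracies on this rendering, not on
micrographs; the pipeline logic (state machine, trace analysis, Eq.-style
normalisation) is what the synthetic ground truth validates.

## Numerical choices

- Mobility differences are computed in float64; unsigned imagery is
  promoted before subtraction so differences cannot underflow.
- Median filtering uses edge replication and preserves trace length;
  window default 5 pairs (25 min), enough to kill single-frame spikes
  (e.g. the bean-transition appearance change) without smearing the
  twitch step by more than one pair.
- Mean-crossing tie rule: `v[i] ≥ mean` with strict `v[i−1] < mean`,
  earliest index.
- Trace variance is the population variance (ddof = 0); interval SEMs
  use the sample standard deviation (ddof = 1) over Normal embryos.
- Incubator detection auto-thresholds Canny hysteresis at 10 %/30 % of
  the frame's intensity span (σ = 2 px smoothing), filters components to
  [0.3, 3] × the expected trap area and aspect in [0.5, 4], and refines
  each centroid to the centre of the dark wall pixels in a local window
  (the filled-component centroid drifts when embryo edges merge with the
  outline). A uniform frame returns an empty location list, not an error.
- Border crops shift inward so the full 200 px square always fits; no
  padding enters patch statistics.
- Clustergram rows are z-scored with the population SD across a
  label-sorted column frame (floating-point reductions are
  evaluation-order dependent; sorting makes the matrix exactly
  permutation invariant); constant rows are defined as all zeros and
  ordered after the clustered rows; row/column order comes from
  average-linkage hierarchical clustering under correlation distance
  with a deterministic tie-break by label.
- Per-incubator failures inside `phenotype_chip` become records with the
  `error` field set instead of aborting the batch — one debris-filled
  trap must not kill a run.

## Problem sizes

The test suite and the acceptance script run at desk scale: classifier
training sets of 300 patches per class; cohorts of 64 embryos as 8
fields of view × 8 incubators × 100 frames (8 h 20 min of simulated
time at 5 min/frame); 20 fields of view for detection accuracy; 1,000
random traces for the twitch-detection oracle; 50 random cohorts for the
summary oracle. A full acceptance run takes about a minute on one CPU.

## Known limitations

- The dead/alive rule needs the full recording: an embryo that would
  have twitched after the recording ends is indistinguishable from a
  dead one (flagged by requiring complete series, as the protocol
  assumes a 12 h observation).
- The bean call depends on the classifier having seen both pre-bean and
  bean appearances; heavily deformed embryos (as under osmotic stress)
  degrade bean timing before they degrade the mobility-based calls.
- `I_ROI` as a nonzero median assumes the embryo fills the majority of
  the (dilated) incubator mask; a small embryo in a large trap would
  bias `I_SBR` toward 1.
- Stage positions are assumed fixed for a run; incubator drift requires
  explicit re-detection.
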