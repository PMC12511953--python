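# Methods

`stereotrack` detects *small-displacement stereotypies* — purposeless,
repetitive movements such as head shaking or tight circling performed by
cage-confined animals — from per-frame bounding-box detections. In that
regime the animal's centroid barely moves, so trajectory analysis carries
almost no signal; what does change rhythmically is the *shape* of a box
fitted tightly to the animal's contour. The pipeline therefore tracks each
individual, converts its box sequence into an aspect-ratio time series, and
searches that series for bounded stretches of periodic oscillation.

## Pipeline model

**Tracking.** Tracking-by-detection with a constant-velocity Kalman filter
over the state (cx, cy, a, h, v_cx, v_cy, v_a, v_h), where a = w/h is the
box aspect ratio — deliberately the same quantity analysed downstream, so
the tracker and the behavior analysis share one definition. Association is
two-stage: detections with confidence ≥ τ_high are matched first (Hungarian
algorithm, cost 1 − IoU) against all live track predictions; remaining
detections with τ_low ≤ conf < τ_high are then matched against
still-unmatched tracks. The second stage is what holds identities through
partial occlusions, when the detector still fires but scores low. Noise
covariances follow the SORT/ByteTrack convention (position stds
proportional to box height, weights 1/20 and 1/160). Defaults: τ_high = 0.5,
τ_low = 0.1, stage IoU gates 0.2/0.3, max_age = 30 frames, min_hits = 3.
Confirmed tracks are reported with their full history; frames a track
coasted through are filled by linear interpolation between observed boxes
(never extrapolated), a standard offline post-processing step that keeps
the amplitude series gap-free through brief dropouts.

**Amplitude.** Per track, the ratio r_t = w_t/h_t is interpolated with a
natural cubic spline through the observed frames and evaluated on the
uniform 1/fps grid. Gaps up to `max_gap_s` (default 1.0 s) are bridged by
the spline and recorded; longer gaps split the track into separate series —
bridging longer detector dropouts would fabricate amplitude structure.
Stretches with fewer than 4 observations cannot support a cubic spline and
are dropped with a logged warning. The ratio orientation (w/h vs h/w) is a
config flag (`invert_ratio`) for sensitivity analysis; an optional
moving-average pre-smoother exists but is off by default, so the spline
interpolates rather than smooths.

**Segmentation.** Stereotypy is intermittent: quiescent stretches of the
ratio signal lack fluctuations, while stereotypic stretches oscillate
around the *same* baseline. Segments therefore differ mainly in variance,
not in mean, and a mean-shift-only changepoint cost cannot see an episode
at all. Each series is cut by recursive binary segmentation under the
Gaussian maximum-likelihood cost C(i, j) = n·log(RSS/n) (sensitive to both
mean and variance changes); a split is accepted when it lowers the cost by
more than a BIC-style penalty (default 3·log n, three parameters per
split: location, mean, variance) and both halves are at least `min_len_s`
(default 2.0 s) long. The penalty is unitless because the cost is a log
likelihood.

**Fluctuation regimes and span merging.** Binary segmentation applied to a
long-period oscillation legitimately keeps cutting at internal turning
points — consecutive half-cycles have different means — leaving fragments
that are individually too short to exhibit a full cycle. Episode assembly
therefore first classifies each segment by fluctuation level: a segment is
*active* when its variance exceeds `active_factor` (default 3) times a
robust noise variance estimated from the series' first differences
(differencing cancels the slow oscillation; the MAD-based scale is
insensitive to the episodes themselves). Adjacent active segments merge
into one span, and periodicity is judged on spans. Quiescent segments are
never tested. For a quiescent segment of ≥ 50 samples the probability of
its empirical variance exceeding 3× the true noise variance is
negligible (χ² tail ≈ 1e−10), so the classification adds no false alarms.

**Periodicity judgment.** A span is periodic when its variance exceeds
`var_floor` (default 1e−4) and its autocorrelation function

    ACF(k) = Σ_{i=k+1..n} (y_i − ȳ)(y_{i−k} − ȳ) / Σ_{i=1..n} (y_i − ȳ)²

(full-series mean and denominator, so |ACF| ≤ 1 by Cauchy–Schwarz) has a
local maximum at some lag within `lag_range_s` (default 0.4–6.0 s,
bracketing the plausible stereotypy cycle range) with value ≥ `theta_acf`
(default 0.3). For white noise of n samples the ACF standard error is
≈ 1/√n, so at the series lengths involved (hundreds of samples) a 0.3
threshold is many standard errors out and false positives are rare; the
specificity test holds the rate under 5% across 200 pure-noise tracks.

**Cycle estimation.** The cycle time is 1/f*, with f* the positive
frequency of maximal magnitude in the DFT of the mean-removed span. The raw
bin resolution is 1/(span length), which for cycle times of a few seconds
inside episodes of 4–19 s produces period errors of order T²/(2D) — up to
a second — so the peak is refined by parabolic interpolation of the
log-magnitude of the three bins around it, the standard single-tone
frequency estimator. When the period divides the span length exactly the
neighbour bins hold only numerical noise; interpolation is skipped and the
estimate is exact. If the refined cycle exceeds the span duration (under
one resolved cycle), the ACF peak lag is used instead, which keeps the
invariant cycle ≤ duration. Zero-padding is available (`fft_zero_pad`) but
off by default. Spans judged periodic become episodes; adjacent episodes
with cycle times within `merge_tol` = 25% merge (stereotypy cycles drift).
Per individual the report carries the episode list — mean cycle time,
total duration, and also the benchmark-style estimate duration/⌊cycles⌉
emitted for comparison — or the explicit marker *none*.

## Evaluation stack

Detection metrics use greedy confidence-ordered matching at a fixed IoU
threshold (default 0.5) and all-point PR interpolation for AP — exact on
small test sets, unlike 11-point sampling. Identity metrics (IDF1/IDP/IDR)
use a single global one-to-one identity assignment maximising correctly
identified detections, found by the Hungarian algorithm and verified in
tests against exhaustive bijection enumeration. CLEAR metrics
(MOTA = 1 − (FN + FP + IDSW)/GT, Recall) use per-frame Hungarian matching
with carry-over preference for the previous frame's correspondence;
identity switches are counted against the most recent previous match.
Behavior accuracy is the MAE of per-individual mean cycle time and total
duration over individuals episodic in both reports; none/episode
disagreements are reported as confusion counts, not folded into the MAE.

## Detector-side operators

The geometry and attention modules reproduce the detector-side math as
deterministic, framework-free operators so it is exactly testable without
a trained network. MPDIoU = IoU − (d1² + d2²)/(w² + h²) penalises IoU by
the squared distances between corresponding box corners, normalised by the
squared *image* size (passed explicitly, never inferred); its complement is
the regression loss. The SimAM operator computes the energy
y = (x − u)²/(4(Σ(x − u)²/n + λ)) + 0.5 per 2×2 spatial quadrant of each
channel plane (split at floor(H/2), floor(W/2); λ = 1e−4 guards
single-element quadrants) and gates the input by sigmoid(y). The
three-branch cooperative attention implements, per branch, a layout
rotation (C↔W, C↔H, or identity), mean-pool squeeze, 1-D same-padded
(reflect) excitation convolution with injectable weights (identity delta by
default), sigmoid gating, and inverse rotation; the three branch outputs
are averaged. These are inference-only: the surrounding detector would
learn the weights, and training is out of scope here.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes:
mean-reverting centroid walks (scatter well under 10% of the box diagonal —
the small-displacement regime), a fixed per-individual box height, and an
aspect ratio at baseline 0.8 with N(0, 0.03²) jitter, overridden during
episodes by a sinusoid of peak-to-peak amplitude 0.4 with period drawn
uniformly from 0.9–4.3 s and duration from 4–19 s, at 25 fps for 60 s.
Detection corruption adds independent box dropout, N(0, σ_d²) corner
jitter, a confidence model dipping from mean 0.85 to 0.3 inside designated
occlusion windows, and Poisson-rate spurious low-confidence boxes.
Randomness derives one SeedSequence substream per individual and role, so
adding an individual never perturbs the others. Triangle and sawtooth
episode waveforms are available for robustness checks; the sinusoid is the
default because the FFT cycle estimator presumes a dominant tone.

What the generator does **not** emulate: appearance (no pixels at all),
crossing or heavily overlapping individuals, detector failure modes that
correlate across frames or individuals, amplitude waveform drift within an
episode, and non-sinusoidal quasi-periodicity. Passing tests therefore
demonstrate correctness of the algorithmic chain under the stated signal
model, not detector-grade performance on real video.

## Reference benchmark and problem sizes

The packaged benchmark (`stereotrack.benchmark`) runs 20 such sequences
(one individual each; sequence i seeded as seed·10⁶ + i) through the
episode pipeline and reports the MAE of recovered cycle times and episode
durations. A sequence whose episode goes undetected contributes its full
generating duration to the duration error and is excluded from (but
counted alongside) the cycle error. Tests and the acceptance script run
the suite at this size; the tracker robustness check uses a 3-individual,
60 s scene with 5% dropout and one occlusion window per individual, and
the specificity check uses 200 pure-noise 60 s series.

## Known limitations

* Aspect ratio is a scalar proxy: stereotypies that leave the box shape
  invariant (e.g. pure rotation of a radially symmetric posture) are
  invisible to it.
* Episodes shorter than about 1.5 cycles rarely clear the ACF threshold —
  with the full-series denominator, ACF(T) ≈ (n − k)/n at best — and are
  reported as *none*; this is visible in the benchmark as occasional
  undetected episodes.
* The tracker has no appearance model; identity preservation relies on
  motion continuity and fails if individuals overlap for longer than the
  coasting age.
* Changepoint boundaries are maximum-likelihood point estimates without
  uncertainty; duration errors inherit boundary error from both ends.
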