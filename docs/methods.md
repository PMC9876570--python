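# Methods

This note documents the models, estimators and numerical choices behind
`ripplecortex`, and what the synthetic-data tests do and do not establish
about real recordings.

## Ripple detection

The LFP (analysis rate 1 kHz) is convolved with a bank of real Morlet
(Gabor) kernels spanning 110–250 Hz in 10 Hz steps, each with 7 cycles and
unit gain at its own center frequency; by linearity the bank is collapsed
into a single summed kernel before convolution. The ripple power trace is
the rectified filter output smoothed with an 8 ms rectangular window.
Events are seeded where power exceeds mean + `detect_k`·SD of the whole
trace, extended outward to 75 % of that threshold, screened by a minimum
supra-boundary duration, centered on the deepest trough of the
band-filtered trace, and finally events whose centers are less than 50 ms
apart are concatenated (recomputing the merged center; the merge is
idempotent). Events within 0.5 s of the recording edges are dropped so that
subsequent alignment windows always fit.

Defaults: `detect_k = 4`, `duration_threshold = 13 ms`. Both are
per-recording knobs (they were hand-tuned per animal in the experiments
this pipeline models). The 13 ms default reflects that the supra-boundary
duration of a genuine 30–100 ms ripple is much shorter than its envelope:
power only exceeds 75 % of the threshold near the envelope peak. On
generator-default sessions (band z = 6 at each center) this operating point
gives detector recall 0.99, precision 0.97, and a false-positive rate of
~0.008 events/s on ripple-free noise; a 30 ms duration threshold would cost
~40 % recall.

EMG gating: the neck EMG is rectified, smoothed (50 ms), and an event is
excluded if the smoothed amplitude exceeds a threshold anywhere within
±500 ms of its center. The default threshold is median + 8·MAD: movement
bouts sit at several times the baseline amplitude while the *expected
maximum* of ~10⁴ effectively independent smoothed baseline samples already
reaches ~5 MAD above the median, so smaller multipliers false-trigger on
quiet recordings.

## Peri-event statistics and the permutation null

Alignment produces realization matrices A(r, t) (events × lags, lag 0 at
the event center, chunks on the signal's native grid). The null model
permutes the intervals between successive event centers, keeping the first
center fixed; each of `n_perm = 200` surrogate sets has the same event
count and span as the real set. The per-lag mean and SD of the
surrogate-aligned *averages* form the null; individual chunks and averages
alike are z-scored as (x − null mean)/null SD. This calibrates the
event-aligned average: for surrogate-like event sets the z values have
lag-averaged mean ≈ 0 and SD ≈ 1 (the suite verifies 0.90–1.10 over 200
simulations). Z-scoring is invariant to rescaling of the raw signal.

Bootstrap averaging uses draw size 50 with 193 (voltage) / 270 (glutamate)
draws; both counts come from the original power analysis of the
repeated-measures design and are carried as constants, not recomputed.

## Ensemble-wise correlation and asymmetry

C(t₁, t₂) is the Pearson correlation across events between column t₁ of A
and column t₂ of B (typically B = peri-ripple MUA). Columns are
standardized with population SD, so C(A, A) has an exactly unit diagonal;
zero-variance columns yield NaN and are excluded downstream. Because each
column is centered, C measures the *residual* (noise) processes — mean
waveforms cancel exactly.

Before correlating imaging traces against MUA, the 1 kHz MUA is averaged
over one 10 ms target frame and then linearly interpolated onto the 100 Hz
imaging lag grid. The anti-alias step matters: naive point interpolation
of a rectified noise envelope discards 9 of 10 samples and can bury real
ripple-to-ripple covariability in sampling noise.

The asymmetry index is AI = (Σ C above the diagonal − Σ below) / Σ |C| off
the diagonal, within a square lag box and excluding the diagonal. With
rows indexed by A's lags and columns by B's, mass above the diagonal means
B's correlated fluctuations occur at later lags, i.e. **A leads B**; the
suite checks that an implanted ±50 ms lag flips the sign. AI is a lead/lag
*indicator*, not a causal estimate.

## SVD multiplexing

Peri-ripple stack chunks are concatenated along time and the
(time × pixels) unfolding is factorized by a thin SVD. No per-pixel mean
is removed, so the dominant global event-locked response is absorbed by
component 1. The decomposition runs on raw ΔF/F chunks: z-scoring against
the per-pixel null rescales pixels nonuniformly and measurably distorts
the spatial modes (mode recovery drops from ~0.998 to ~0.84 on synthetic
sessions), so the z-scored traces are used for feature extraction and
region traces but not as SVD input. Sign ambiguity is resolved by forcing
each spatial mode's mean to be non-negative. K = 100 components are
retained by default, mirroring the 1 vs 2–100 component split used in the
analyses this package reproduces; variance fractions are always reported
against the full spectrum, so subset fractions are additive and the
full-rank reconstruction is exact.

The deep-layer estimate is EMX − α·Ras with α = 0.5: the pan-layer signal
is treated as an even mixture of superficial and deep contributions, so
subtracting half the superficial-only signal isolates (half of) the deep
component. α is exposed as a parameter.

## Calcium analysis

Neuropil traces are scaled by 0.7 and subtracted. Deconvolution solves
the non-negative AR(1) least-squares problem (pool-adjacent-violators /
online active-set, no sparsity penalty) with g = exp(−1/(rate·τ)),
τ = 1 s; on synthetic populations the 200 ms-binned output correlates
> 0.99 with the true spike counts.

Clustering z-scores each neuron's peri-ripple mean trace (−0.5 to +0.5 s)
and scales it to unit norm, making Euclidean k-means equivalent to k-means
under correlation distance (10 replicates, ≤ 1000 iterations). Cluster 1
is the *activated* cluster, identified by the post-minus-pre contrast of
the cluster-mean trace rather than the early post window alone: with a 1 s
indicator decay, suppressed neurons still carry elevated pre-ripple calcium
into the first 200 ms. Cluster count is chosen where silhouette
(correlation distance) and Calinski–Harabasz peak; on disagreement the
silhouette winner is used and the conflict logged.

The modulation test chunks the deconvolved trace ±1 s around each ripple;
each of 1000 shuffles circularly rotates every chunk by an independent
uniform amount up to ±1 s and re-averages. The statistic is the summed
squared difference between an average and the shuffle-mean over the
(0, 200 ms] window; a neuron is significant when its true statistic
exceeds the 95th percentile of the shuffle statistics (one-sided; ties
count against significance). Direction compares the true average's mean
over (0, 200 ms] with its median over (−400, 0) ms. Calibration: type-I
error 2.5–7.5 % over 400 unmodulated neurons; power ≥ 80 % at rate-gain 3
with 50 events and 0.5 Hz baseline.

## Trace features

Baseline = mean over (−200, 0) ms; amplitude = max over (0, 200] ms minus
baseline; deactivation traces are inverted first so every feature is
reported as a positive-going activation. Onset/offset are the half-maximum
crossings of the first-difference derivative flanking its maximum within
(−200, 200) ms, with a 3-point moving average on the derivative and linear
interpolation between samples. The derivative maximum landing on the
search-window edge is an error (crossing undefined), as is a flat trace.

**Limitation** — the half-max definition is nonparametric and inherits the
derivative's noise: at single-event amplitude SNR 5 averaged over 50
events, the mean onset error is 4–6 ms but individual estimates have a
jitter tail to ~15 ms; when noise power concentrates near the pass-band
edge the derivative maximum itself can be displaced. Consumers needing
tighter onsets should average more events or smooth harder (both exposed
as parameters).

## The synthetic session generator

The generator is the test bed for every stage; its defaults describe a
quiet awake mouse (120 s default epoch; ripples ~10/min with ≥ 0.5 s
separation, durations uniform 30–100 ms; movement bouts after 28.47 % of
ripples, the published mean exclusion fraction).

* **LFP**: 1/f background plus, per ripple, a Gabor atom at 160 Hz whose
  trough sits at the event center, riding on a 50 ms half-cosine
  sharp-wave trough. The Gabor amplitude is calibrated per duration
  (dividing by the band filter's attenuation of brief bursts) and the
  background's ripple-band content is gated out under the event, so the
  band-envelope z at each center *equals* the configured SNR. A steep
  > 300 Hz noise component carries the spiking signal: its variance rises
  in a burst at each ripple and dips ~75 ms after it.
* **Coupling**: one standard-normal latent per ripple scales both the
  post-ripple MUA suppression and the aRSC imaging dip — a common
  inhibitory source — implanting genuine positive noise correlation
  between MUA and aRSC in the first ~100 ms. The burst gain varies
  independently.
* **Wide-field stacks**: spatial-mode × temporal-kernel sums. The global
  mode is smooth with mild topography; the aRSC mode is confined to the
  mask. The implanted pair is near-orthogonal in both space and time
  (small retained spatial overlap 0.08 keeps the global mode positive
  inside aRSC) — orthogonality is what makes the implants identifiable by
  SVD. Glutamate kernels: positive post-ripple alpha bump (τ = 150 ms)
  globally, negative Gaussian dip (80 ms, σ = 40 ms) in aRSC; the voltage
  flavour has a pre-ripple rise and post-ripple dip. Common-mode slow
  drift and i.i.d. pixel noise (0.5 % ΔF/F on the coarse 32×32 grid,
  i.e. heavily binned pixels) are added.
* **Calcium**: inhomogeneous-Poisson spikes at 0.5 Hz baseline with
  multiplicative box profiles (up: ×3 in (0, 200] ms, ×0.5 pre; down
  mirrored), convolved with a 1 s single-exponential indicator, plus
  0.1 ΔF/F Gaussian noise. Spike counts are retained as deconvolution
  ground truth.

What the generator does **not** emulate: hemodynamic/optical artifacts,
vascular structure and registration error in the stacks; bursting and
indicator nonlinearity in the calcium model; non-stationary behavioral
states; ripple bundling and amplitude–duration correlations. Passing the
suite therefore demonstrates correctness of the estimators under the
modelled statistical structure, not robustness to every artifact of real
preparations.

## Problem sizes

The validation runs use desk-scale sessions chosen to keep every stage's
sampling error well inside its acceptance band: 4 × ~20-event sessions
plus 50 × 20 s noise runs for the detector; 200 simulations × 200
permutations for null calibration; 200 events for the correlation
construction; 400 null and 100 modulated neurons at 1000 shuffles for the
shuffle test; 300 s (~40 ripples) for the full multiplexing session.
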