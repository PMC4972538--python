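# Methods

This note documents the models, estimators and numerical choices behind
`hippoblink`, and what the synthetic benchmarks do and do not establish
about real recordings.

## The scientific setting

During trace eyeblink conditioning a tone (CS) predicts, across a 250 ms
stimulus-free gap, an eyelid stimulation (US).  Dorsal-CA1 pyramidal cells
often appear to "respond" to the CS, but three very different mechanisms
can produce such a response.  The pipeline is organised around telling
them apart on a per-session basis:

1. a space-invariant CS response (**cs_cell**),
2. a response gated by the cell's place field regardless of behavioural
   state (**cs_place_cell**),
3. no CS response at all — only an arousal-mediated switch from
   quiet-wakefulness firing (ripple-associated bursts, place field off) to
   alert firing (place field on) (**arousal_place_cell**).

The discriminating observables are (i) the Spearman correlation between
CS-evoked counts and the place-field intensity at the delivery location,
(ii) the presence or absence of a pre/post rate change on trials delivered
while the animal is already running (hence already alert), and (iii) the
peri-CS ripple occurrence rate on sitting trials.

## Signal primitives

**Band-pass filtering** is zero-phase FIR (window method, Hamming), applied
forward–backward.  The filter family and order are package choices: the
transition band is half the low edge (capped at 40 Hz) and the tap count
follows the 3.3/Δf rule, giving ≥ 40 dB stop-band attenuation per pass.
FIR + `filtfilt` keeps the impulse response finite, so filtering artifacts
stay local — the same design value that motivates the STFT below.

**STFT.**  Every frame is an explicit slice of `window_length` seconds
(default 400 ms) multiplied by a Kaiser window and FFT-ed with 4× zero
padding; the coefficient phase is rotated to reference the frame centre, so
`arg X(t, f)` is the instantaneous phase of the matching cosine at `t`.
Because no padding or overlap-add is involved, a coefficient at time `t`
depends on samples in `t ± 200 ms` *bitwise* — the property the theta
analysis relies on to bound the influence of the high-amplitude US
transient.  Frames that would extend past the data are marked invalid, not
padded.  The Kaiser shape parameter follows the α-convention (β = πα) with
α = 1.  Hop (10 ms) and padding factor are configurable; they are estimator
resolution choices, not scientific claims.

## Behaviour

CR detection band-passes the differential EMG to 120–960 Hz and compares
RMS in three 100 ms windows per trial: baseline (−100–0 ms from CS onset),
CR (380–480 ms; the US arrives at 500 ms) and control (−580–−480 ms).  A
trial is a blink iff [CR − baseline] exceeds the within-session 95th
percentile of [control − baseline]; under a stationary null the detector
therefore fires on ~5% of trials by construction, which the calibration
tests verify.  The percentile is computed per session from valid trials
(sessions are analysed independently).  A 0–80 ms startle window is
available as a diagnostic but plays no role in detection.

Trials are labelled run/sit from speed averaged over the 500 ms before the
CS, with a deliberate hysteresis band: ≥ 8 cm/s → run, ≤ 2 cm/s → sit,
otherwise ambiguous and excluded from state-split analyses.  The sit
threshold reuses the 2 cm/s moving criterion of the rate maps; the run
threshold is a package default, configurable.  Speed comes from central
differences of 200 ms boxcar-smoothed positions.

## Place fields

Rate maps divide smoothed spike-count maps by smoothed occupancy maps
(numerator and denominator smoothed separately — standard occupancy-map
practice; kernels truncated at 4σ).  Track maps are 1-D and directional
(1 cm bins, σ = 3 cm); endbox maps are 2-D and non-directional (1 cm²
pixels, σ = 1 cm).  Only moving samples (v > 2 cm/s) contribute; the 2 s
window after every CS onset is excluded from spikes and occupancy alike so
evoked firing cannot contaminate the maps; bins under 50 ms/cm² of
occupancy are marked indeterminate and excluded from all downstream
averages.  Pre-smoothing conservation (Σ counts = spikes in moving,
non-excluded epochs) is asserted exactly in the tests.

The trial-level spatial prediction is the trajectory average of the map
over the 500 ms post-CS window, using the direction-appropriate track map
on the track and the endbox map in a box.  Spatial classification
(no_field / endbox_only / track_only / track_and_endbox) requires a
contiguous suprathreshold region of ≥ 3 valid bins — single-bin blips are
treated as noise — and is reported at both 2 Hz and 5 Hz peak thresholds
because the class counts are threshold-sensitive.

Pyramidal-cell screening: rate < 4 Hz, spike width > 0.25 ms, and > 5% of
inter-spike intervals under 10 ms, all strict inequalities.

## CS-response statistics

All counts use 500 ms windows flanking the CS onset; the 10 ms US delivery
window never contributes (spike detection there is impossible around the
electrical artifact, and the generator honours the same convention).  The
Wilcoxon signed-rank test is deliberately reported with a `heuristic` flag:
spatial tuning and state violate its i.i.d. assumption, so its p-value
ranks effect strength rather than supporting inference.  For ≤ 25 non-zero
differences the exact sign-flip null is computed by dynamic-programming
convolution over midranks (ties among count differences are ubiquitous, and
midranks keep the enumeration exact); larger samples use the normal
approximation with tie correction.

The reliability statistic truncates the Poisson double sum at the
(1 − 10⁻¹³) quantile of the pre-CS Poisson, bounding the neglected mass
below 10⁻¹²; the closed forms P(k2>0 | λ1=0) = 1 − e^(−λ2) and the
λ1 = λ2 symmetry hold to 10⁻¹⁰ and a 10⁶-draw Monte-Carlo oracle agrees
within 3 SE across a 5×5 grid of rates.  A cell that never fires after the
CS is assigned ρ = 0 by convention (its correlation is undefined, and the
convention is conservative for the positive-ρ signature).

Predicted-vs-observed rate comparisons stratify trials into a
zero-intensity stratum plus logarithmic intensity bins, with percentile
bootstrap CIs (2000 resamples) and a log-ratio discrepancy using
ε = 0.01 Hz (the floor below which rates are not meaningfully resolved).
US-window analyses reuse the same machinery but carry a caveat: the
unconditioned head movement confounds them.

## Ripples

Per channel: band-pass 80–250 Hz → 10 ms sliding RMS → peaks above
mean + 5 SD of the envelope (statistics taken over sitting epochs when
state labels exist), with event extent delimited at mean + 2 SD and
duration bounded to 20–200 ms.  Candidate frequency is the spectral peak of
a 100 ms STFT frame centred on the envelope peak; an event is kept iff that
frequency lies in 120–250 Hz and candidates coincide within ±15 ms on at
least 3 channels.  Overlapping detections merge, keeping the
longest-duration member.  Thresholds are per-channel with a global
coincidence rule; all values are configurable and recorded in output
metadata.  The 5 SD default was chosen as conventional practice and is
validated on synthetic data (≥ 90% sensitivity at the generator's default
amplitude, < 0.05 false events/s on matched noise).

## Theta

Instantaneous frequency is the 4–12 Hz spectral peak per frame, refined by
quadratic interpolation around the argmax bin; phase and amplitude are the
argument and modulus of the coefficient at the peak bin.  The transition
analysis uses one frame ending at the stimulus onset and one starting
100 ms after it (for the US: 100 ms after the US offset), so the two phase
estimates share no data; each is advanced to the gap midpoint with its own
frequency (φ → φ + 2πfΔt, wrapped).  Summaries report the Fisher–Lee
circular–circular correlation, the circular mean and resultant of
(post − pre), and the Rayleigh statistics of the post phases.  The
interpretation contract: diagonal scatter (correlation ≈ 1, shift ≈ 0) —
rhythm unaffected; horizontal band (post-R ≈ 1 independent of pre) — reset
to a fixed phase; shifted diagonal — constant phase shift.  The mean
resultant length is unweighted by default with an amplitude-weighted
variant available.

Trial LFP state: a sitting trial counts as sit_theta iff its pre-trial
(1 s, configurable) theta/delta power ratio exceeds 4 *and* its theta power
exceeds the 5th percentile of theta power in 1 s running windows.  The
theta channel is a configuration input (in real data it would be chosen
superficial to the cell layer by sharp-wave polarity, a curation step
outside this package's scope).

## Synthetic sessions

The generator is the package's testbed and embodies the arousal account
plus the two alternatives:

* **Behaviour** — an alternating renewal process: exponential endbox sit
  dwells (default mean 8 s, which makes the run/sit trial mix roughly
  balanced as in the recordings the pipeline targets) alternating with
  port-to-port traversals at a speed drawn once per run (N(35, 5) cm/s,
  floored at 10).  Sitting positions drift slowly (σ = 0.5 cm, 0.5 s
  correlation time) so sitting speed stays below the moving criterion.
  The stationary sit fraction has a closed form used as a recovery oracle.
* **Spiking** — inhomogeneous Poisson on a 1 ms grid.  Place fields are
  Gaussian bumps along the track axis (independent fields per direction),
  active while alert; quiet-state firing is near zero except inside ripple
  windows, each joined with the cell's participation probability as a
  high-rate burst.  The arousal model switches quiet → alert 50 ms after
  the CS (configurable — the transition latency and the 2 s alert duration
  are not constrained by data and are exposed as parameters) and adds
  nothing else; cs_cell adds a flat bump; cs_place_cell scales the bump by
  normalised field intensity.  A pure CS cell is modelled as
  state-independent (it is, by hypothesis, not a place cell), which is what
  makes its counts i.i.d. Poisson and its observed reliability match the
  expectation — the control condition for the reliability-gap signature.
* **LFP** — additive, not biophysical: theta sinusoid with optional
  frequency drift while running, 1/f background, Gaussian-envelope ripple
  wavelets (140–220 Hz, 40–80 ms) in quiet epochs synchronised across a
  channel subset, optional US transient.  Ripples cease inside the post-CS
  arousal window under the arousal model.  A separate single-channel
  probe generator produces unbroken / reset / constant-shift theta for the
  transition benchmarks, with the pre-stimulus phase randomised per trial.
* **EMG** — broadband noise, amplitude-gated: an unconditioned burst after
  every US and a conditioned burst in the 380–480 ms window on
  Bernoulli(p) trials, so burst energy overlaps the 120–960 Hz detection
  band.

Everything is driven by `numpy` Generators seeded from a single session
seed; identical seeds reproduce sessions bitwise.

**What the benchmarks show — and do not.**  Passing recovery tests shows
the estimators are unbiased and correctly calibrated *under the generative
model*: Gaussian fields, Poisson spiking, additive LFP, exchangeable EMG
noise.  Real recordings add non-Poisson bursting, theta phase precession
interacting with field traversal, overlapping ripple chains, electrode
drift and unit-isolation errors, none of which the generator emulates (a
precession-law spike generator exists only in the phase-precession tests).
The benchmarks therefore validate the pipeline's logic and calibration,
not the biological conclusions one would draw from any particular dataset.

## Benchmark scales

The standard benchmark session uses 100 cells and 150 trials over 1500 s
(about a minute to simulate and analyse end to end); detector calibrations
use 500 EMG trials, 1000 null cells for the signed-rank test, and 300 s of
4-channel LFP with one injected ripple every 5 s.  These sizes put the
Monte-Carlo error of every recovered quantity well inside its acceptance
band while keeping the full suite comfortably fast.

## Known limitations

* Occupancy-map division amplifies noise in thinly sampled bins; the
  50 ms/cm² validity mask controls this but makes I_place undefined on
  trials delivered in unexplored locations (such trials are excluded, as
  they must be).
* The run-threshold hysteresis leaves ambiguous trials unanalysed rather
  than guessed; sessions dominated by mid-speed behaviour will have low
  state-split power.
* The Fisher–Lee correlation is O(n²) in trials — irrelevant at session
  scale, noticeable above ~10⁴ trials.
* Multi-session aggregation is a thin concatenation; repeated observations
  of the same neuron across sessions are treated as independent units,
  with session/unit identifiers retained for downstream deduplication.
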