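# Methods

`thetanav` re-implements, as a tested and reusable pipeline, the analysis of
hippocampal-formation virtual-channel signals during an abstract grid
navigation task: oscillatory theta power and theta–gamma phase–amplitude
coupling (PAC) as functions of distance to a navigation goal, together with
the confound controls that such an analysis needs (power residualization,
aperiodic slope, evoked response, waveform asymmetry).  Because the empirical
cohort is not reproducible at desk scale, the package ships a synthetic-data
module that generates both the behavior and the signals under the
theta–gamma sequence-coding model, so every stage of the chain can be
validated by parameter recovery.

## The task model (`thetanav.task`)

Navigation happens on a 4×4 grid of visual stimuli with 4-adjacent moves.
Per trial, the goal is drawn uniformly from all cells at Manhattan distance
≥ 3 from the start, and each start is the previous trial's goal (the chain
resets at block boundaries — the design is silent there, so blocks are
treated as independent and the first trial of each block is flagged, since
its start is unknown during the cue).  Shortest paths under 4-adjacency are
monotone lattice paths, so their count is `C(d, |Δrow|)`; the suite checks
this against an exhaustive BFS oracle for all 256 ordered pairs.  On this
grid there are exactly **124** ordered start–goal pairs at distance ≥ 3 and
**592** shortest paths between them.

Behavioral metrics: *tortuosity* = steps taken / shortest distance
(correct ⇔ 1); a path is *novel* when at least one of its transitions was
never walked before **in either direction** (transitions are stored as
unordered cell pairs for this reason), and *familiarity* is the fraction of
previously-walked transitions.  The simulated agent walks a uniformly random
shortest path with probability `p_correct` (default 0.85, matching high
human accuracy on this task) and otherwise inserts a single detour, giving
tortuosity `(d+2)/d`.  Reaction/step times are log-normal plumbing; nothing
downstream depends on them statistically.

## The generative signal model (`thetanav.signals`)

One virtual channel per participant (the analogue of an ROI-averaged source
time series), sampled at 600 Hz by default.  Each epoch is driven by an item
count `n` — the number of locations remaining on the path (cue epochs: the
trial's shortest distance; move epochs: the remaining shortest distance from
the pre-press cell):

* **Theta carrier** at 4 Hz with amplitude `theta_amp_base +
  theta_amp_slope·n` (defaults 1.0 and 0.12 per step): theta power grows
  with sequence length.  A secondary high-theta carrier at 7.5 Hz with
  amplitude `theta_high_amp_slope·n` (default 0.15) carries the 6–9 Hz load
  effect; it vanishes at `n = 0` so a no-load, no-noise epoch degenerates to
  a pure sinusoid.
* **Gamma bursts**: per theta cycle, one Gaussian-windowed sinusoid per item
  (50 Hz and 100 Hz band centers, envelope SD `burst_width_cycles/(4f)`,
  random carrier phase), placed at preferred theta phases equally spaced
  across a fan `min(2π, (π/3)·n)` wide centered on the trough, each jittered
  by a wrapped-normal with concentration `κ(n) = max(0.5, 6 − 0.8·n)`.  More
  items ⇒ wider fan and lower concentration ⇒ lower measured PAC.  The
  wrapped-normal choice gives a closed-form expected resultant
  `exp(−σ²/2)`, used as an oracle in the tests.
* **Aperiodic background**: `1/f^χ` noise by exact spectral shaping of white
  noise (χ defaults to 1, SD 1), analytically normalized so the Welch
  log-log slope recovers −χ within ±0.15.
* **Confound injectors**: a phase-locked Gaussian-windowed theta transient
  (evoked response); and waveform asymmetry by a monotone piecewise-linear
  time-warp within each theta cycle so that ascending/descending durations
  are in ratio `(1+a)/(1−a)` while the period is preserved — the asymmetry
  index of the warped wave equals `a` exactly.  Burst placement inverts the
  same warp, so coupling stays locked to the observable phase.

Epoch-level hooks (`asymmetry_slope`, `noise_exponent_slope`,
`n_bursts_override`, `coupled`) let recovery and null studies vary or freeze
each property independently.  The distance-null generator
(`pipeline.null_signal_params`) freezes theta amplitude, burst count, burst
dispersion, asymmetry (at the nonzero constant 0.2) and the exponent, and
removes the phase preference entirely, so its epochs are statistically
independent of the distance labels.

What the generator does **not** emulate: sensor-level MEG physics (leakage,
artifacts), learning dynamics across the session, between-participant
effect-size heterogeneity, or the human property that incorrect trials lack
distance coding (synthetic epochs are driven by remaining distance on all
trials).  Passing recovery tests therefore show that the *pipeline* measures
what the model encodes, not that real hippocampal data behave this way.

## Spectral analysis (`thetanav.spectral`)

Time–frequency power by convolution with five-cycle complex Morlet wavelets
(`σ_t = n_cycles/2πf`, L2-normalized, truncated at ±3 SD) at 20
log-spaced frequencies from 1 to 30 Hz inclusive.  Power = |coefficient|²,
log-transformed (natural log; any base only rescales), then
baseline-corrected by subtracting the per-frequency mean log power in a
pre-event window (cue: −1.5…−0.5 s before cue onset, cropped to the 0–3 s
cue period; navigation: −1…−0.5 s before each press, cropped to ±1 s).
Samples within half a wavelet of an epoch edge are invalid (NaN) and never
enter statistics — epochs are cut long precisely so the analysis windows
avoid edges, and the code enforces this rather than trusting it.  Band power
(low theta 2–5 Hz, high theta 6–9 Hz; closed intervals on the grid
frequencies) is the mean log power over band frequencies and window samples;
the band powers entering distance regressions are deliberately **not**
baseline-corrected.  Welch PSDs (2 s Hann segments, half overlap) cover
1–150 Hz for the aperiodic control.

## Phase–amplitude coupling (`thetanav.coupling`)

Zero-phase band-pass (windowed-sinc FIR, odd length ≈ 3 cycles of the band's
low edge, applied forward-backward; Butterworth alternative for the
asymmetry control), Hilbert analytic signal, then the mean vector length

    MVL = |Σₜ aₜ·e^{iφₜ}| / Σₜ aₜ

over the valid samples of the window of interest, with θ-phase from 2–5 Hz
and gamma amplitude from one wide band-pass per band (slow 30–70 Hz, fast
70–140 Hz).  The amplitude-normalized form is primary (bounded, exactly
invariant to phase rotation and amplitude scaling); the unnormalized mean
vector `|Σ a·e^{iφ}|/N` is also reported since published estimators differ.
Because raw MVL leaks trial-wise power, each participant's epochs are
residualized by OLS of MVL on theta and gamma band power (same window, raw
powers); the residuals — zero-mean and orthogonal to both covariates by
construction — are what is regressed on distance.

Filtering is implemented in the frequency domain (squared real response of
the centered symmetric kernel = forward–backward pass), which also yields
the analytic signal in the same inverse FFT; the composed band-pass + Hilbert
path is retained and the two are cross-checked in the tests.  Half the
filter length is masked at each epoch end.  Realized stopband attenuation of
the double-pass design exceeds 40 dB one octave outside the band; tighter
transitions would require filters longer than the epochs support at theta.
A mains notch is *not* applied to synthetic data (no line noise); the flag
exists for imported recordings, with the caveat that a 48–52 Hz notch bites
the 30–70 Hz band.

## Confound controls (`thetanav.controls`)

* **Aperiodic slope**: Welch spectra averaged across all trials with the
  same distance, then an iterative robust line fit in log-log space —
  fit, flag points > 3 robust SDs (and ≥ 0.05 log₁₀ units) *above* the line
  as oscillatory peaks, refit, repeat to stability (≤ 20 iterations, flagged
  unstable otherwise).  Only the exponent (−slope) is used downstream, so
  the full Gaussian-peak decomposition is deliberately out of scope.  For
  per-participant distance regressions the averaged spectra use equalized
  trial counts per distance (first `m` in session order, `m` the smallest
  retained level), because unequal averaging makes the log spectrum noisier
  at rare distances and measurably biases the exponent-vs-distance slope;
  levels with fewer than 10 trials are dropped.
* **Evoked amplitude**: signals averaged across trials *before* the
  time-frequency transform (only phase-locked activity survives), with
  trial counts matched across distances by subsampling, repeated 100 times
  and averaged; restricted to distances ≤ 4 (5-step trials are rare).
* **Waveform asymmetry**: 2–5 Hz zero-phase Butterworth, extrema located by
  zero-crossing bracketing (exactly one peak per up–down crossing pair,
  which forbids noise-induced double extrema; edge cycles discarded), and
  per cycle AI = (ascend − descend)/(ascend + descend), averaged over ≥ 3
  cycles.  AI of a pure sinusoid is 0; it flips sign under time reversal and
  ignores scaling and offsets.  Note the estimator sees only in-band
  harmonic content: a skewed 4 Hz rhythm loses nearly all its asymmetry to
  the 2–5 Hz filter (its first harmonic is 8 Hz), so asymmetry-recovery
  studies use a 2.5 Hz carrier whose harmonic lies in-band, and the exact
  `AI = a` identity is verified on the unfiltered warped wave.

## Statistics (`thetanav.stats`, `thetanav.pipeline`)

Per participant, each per-epoch outcome is regressed (OLS) on distance to
goal — a continuous integer regressor (cue: shortest distance; navigation:
remaining shortest distance, recomputed from the current cell so incorrect
trials are well-defined) — with trial number as a nuisance against slow
drift.  The final step of each trial (goal visible) is excluded from
navigation regressions.  Condition slices: correct/incorrect on all trials;
novel/previously-traversed defined within correct trials, so the slice
counts conserve (`novel + traversed = correct`).  Per-participant distance
coefficients go into two-sided one-sample t tests (or paired t tests for
slice contrasts), with Cohen's d = mean/SD (one-sample) or
mean(diff)/SD(diff) (paired); α = 0.05; no multiple-testing correction
inside the pipeline — the report lists every test run so users can correct
externally.  Distance profiles (means per distance bin, bins 3–5, navigation
shown in descending order) are display summaries only; the inference is
always the continuous regression.  Distance-6 (corner-to-corner) trials are
generated but excluded from the profile bins; they stay in the continuous
regressions (switchable).

## Problem sizes and numerical choices

Recovery and calibration experiments simulate 23 participants × 100 trials
per cohort and 100 cohorts per condition, at a reduced problem
representation chosen to keep a full run on one CPU in minutes: 300 Hz
virtual channel (well above twice the highest gamma band edge), move epochs
of ±2 s analyzed at ±1 s, move epochs only, and single-precision FFTs (the
measured quantities are SNR-limited far above float32 resolution).  The
acceptance script uses 40 cohorts per condition.  All randomness flows from
`numpy` `SeedSequence` spawning, so every experiment is exactly reproducible
from one integer seed; fixed seed ⇒ bit-identical epochs, tables and
reports.

Known limitations: the linear forms linking distance to theta amplitude and
phase dispersion are modelling choices (the framework only fixes the
direction of the effects), exposed as parameters; the FIR mask (half filter
length per end) is a conventional bound, not an exact transient length; the
asymmetry warp assumes cycles aligned to the nominal carrier, exact for
sinusoids and approximate for broadband theta; and epochs are generated
independently per press rather than cut from one continuous trial signal,
which ignores temporal overlap between consecutive move epochs.
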