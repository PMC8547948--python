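# Methods

`echokin` analyses the sensor-motor feedback loop of echolocating toothed
whales during close prey approaches (buzzes): how the inter-click interval
(ICI), which sets the acoustic depth of field `dof = ICI * c / 2`, is
adjusted in response to sudden target movements, and with what latency.
This note documents the models, the estimators, the synthetic-data
generator that provides ground truth, and the numerical choices.

## The sensing model

An echolocator emitting clicks at interval ICI receives unambiguous echoes
only from ranges below `ICI * c / 2`; prey accelerating away can leave this
depth of field within tens of milliseconds, so the clicking rate must be
adjusted to track target range. Two analytic bandwidths frame the analysis:
information arrives at up to `1/(2*ICI)` Hz (Nyquist), while a feedback
loop with pure delay `tau` can respond at only about `1/(4*tau)` Hz. At a
2.5 ms buzz ICI and a 50 ms response latency the ratio is 40: the animal
acquires echo information some 40 times faster than it can act on it, and
at least `floor(0.05 / 0.0025) = 20` clicks are emitted per latency period.
The sound speed is taken as 1500 m/s throughout (configurable); it is the
value under which a 5 ms ICI corresponds to a 3.75 m depth of field.

## Pipeline

**Click detection** (`click_buzz`). Audio is bandpass filtered to the
species click band (harbour porpoise `pp`: 100-250 kHz; Blainville's beaked
whale `md`: 25-60 kHz) with a 4th-order zero-phase Butterworth (zero phase
keeps click and echo timing unbiased), and the Hilbert-envelope magnitude
is smoothed by a 50 µs centred moving average. The running noise floor is
the blockwise median envelope over 50 ms blocks — insensitive to the
sub-millisecond clicks themselves — rescaled from the Rayleigh median to an
RMS-equivalent level. Envelope peaks more than 15 dB (default) above the
floor, separated by at least the blanking time (1 ms `pp` / 1.5 ms `md`),
are detections. Because echoes from close targets also clear the noise
threshold, a second pass keeps only peaks within 9 dB of a running upper
quantile (80th percentile over ±12 neighbours) of detection amplitudes: the
outgoing click is recorded essentially at the source and is 16-25 dB louder
on the tag than any target echo, so this separates the two populations
without any waveform classification. On synthetic audio at ≥ 20 dB SNR the
detector's timing error is well below the 50 µs target.

The ICI convention is *forward*: `ici[k] = times[k+1] - times[k]`, the
depth of field in force once click `k` is out. Buzzes are maximal runs of
ICI below 13 ms (`pp`) or 100 ms (`md`) spanning at least 0.5 s, measured
first click to last click of the run (the unpadded convention; the span
definition is this package's choice).

**Echograms** (`echogram`). For each click the envelope is resampled onto a
uniform range axis via `r = c*tau/2`, with bin width `c/(2*f_env)` where
the envelope rate `f_env` is 100 kHz (`pp`) or 50 kHz (`md`) — 0.75 / 1.5 cm
bins, far below any kinematic scale of interest. SNR is taken per click
against the median envelope over the last 20 % of that click's segment
(beyond plausible target range). Ranges below 0.2 m are blanked (transmit
artefact), and bins coinciding with *other* clicks' direct arrivals
(±0.2 ms) are masked to 0 dB: the outgoing clicks would otherwise dominate
every segment, since the next click is always louder than the echo.

**Echo trace and escape timing.** The target trace is extracted by gated
peak tracking: global SNR maximum above 10 dB until first lock, then the
best peak within a 0.5 m gate centred on the last valid range; after 25
consecutive misses the tracker re-acquires globally so a lock onto a noise
transient cannot blind the rest of the buzz. Escape onset is found with a
continuous two-segment hinge regression `r(t) = a + b*t + d*max(t - t0, 0)`
over candidate breakpoints on the valid-click grid, reported only when the
slope increase `d` exceeds 0.25 m/s — the same speed-excess cut used to
select clear V-shaped traces. Replacing manual apex picking with this fit
keeps the ~10 ms timing accuracy while being reproducible; on clean
synthetic V traces the bias is below one median ICI.

**Event-locked statistics** (`response_stats`). `deltaICI_k =
ici[k+1] - ici[k]` is assigned to the time of click `k+1` (a change is
observable only once the later click is emitted; ties count as
non-positive). Proportions of positive deltaICI are formed in bins of
50 ms (`pp`) or 100 ms (`md`) spanning ±500 ms around the event, with the
event on a bin edge. RMS norm-jerk — the vector magnitude of the first
difference of tag acceleration times the sampling rate, unsmoothed, since
smoothing would bias latencies — uses the same bins.

**Bootstrap null.** Chance association is assessed by transplanting event
offsets between buzzes: per replicate, random ordered buzz pairs (with
replacement) donate their buzz-start-to-event offset to the receiving
buzz, the statistic is recomputed at the mock event, and replicates are
aggregated across trials. The cross-trial aggregate is the median (robust
to odd trials; a pooled-mean mode is provided as the other natural
convention). A bin is significant when more than 95 % of replicate
aggregates fall below the observed aggregate; ties are counted at half
weight (mid-p), without which the atoms of median-of-proportions
aggregates make the criterion conservative (~0.03 instead of 0.05 type-I
rate in calibration runs). Significance is per-bin and uncorrected, by
design.

**Latency estimators** (`latency`).

* *Threshold latencies* isolate strong, saccade-like responses: the first
  post-event click whose forward ICI exceeds 5 ms (depth of field past
  3.75 m), and the first post-event time at which norm-jerk, RMS-smoothed
  over a 10 ms sliding window (the window length is this package's choice),
  exceeds 300 m/s^3. Pre-event crossings are ignored; no crossing returns
  "none" rather than a number.
* *Loop-area minimisation.* Plotting prey range against depth of field
  yields counter-clockwise hysteresis loops when the response lags its
  cause. Both series are linearly interpolated to a common 200 Hz base
  (dense enough for the 5 ms advance grid; the raw click series is denser
  still), the depth-of-field series is advanced (shifted earlier) in 5 ms
  steps up to 300 ms, and the enclosed area of the trajectory closed
  last-point-to-first is computed as the absolute net shoelace sum. Loops
  of consistent lag share orientation, so the net signed area sums them;
  at the true advance the trajectory collapses onto a curve and the area
  vanishes. The minimising advance is the latency estimate; ties break to
  the smallest advance. The total area is minimised rather than per-loop
  areas individually: it is monotone in loop size and needs no loop
  segmentation.
* *Cue regression.* The RMS target acceleration over 0.5 s after motion
  onset (gravity removed as the per-axis mean over a 1 s pre-onset
  baseline; onset at 5 baseline standard deviations) is the cue; ordinary
  least squares of `1/latency` on the cue linearises the
  faster-cue/faster-response relation and returns slope, r², and a
  two-sided slope p-value.

## The synthetic trial generator

`synthetic_trials` generates the study conditions with full ground truth:
a predator closing at 1 m/s from 4 m, an escape at 2 s into a 3 s record
in which the target opens the range at 0.5 m/s net (the cut used for clear
V traces is > 0.25 m/s excess), clicks rendered as Gaussian tone bursts
(unit peak; 130 kHz / 10 cycles for `pp`, 40 kHz for `md`, ≥ 95 % of energy
in the species band) into white Gaussian noise, and echoes delayed by
`2 r/c` and attenuated by two-way spherical spreading (`40 log10 r`, the
dominant term at < 10 m ranges; absorption is negligible there and is
omitted). Echo strength is parameterised as SNR at 1 m against the in-band
Rayleigh noise floor (default 40 dB — roughly 25 dB at the 2-4 m working
ranges). An optional static reflector provides clutter for gate tests.

The ICI control law is a pure transport delay on range:
`ICI(t) = margin * 2 r(t - delay) / c`, clamped to the species buzz range,
with `margin = 1.2` so the echo always returns inside the click interval
(the functional form of wild ICI control is not known; the proportional
margin is this package's modelling choice and is the simplest law that
reproduces smooth tracking). Every ICI carries 3 % multiplicative Gaussian
jitter — cycle-to-cycle variability that any event-locked statistic must
overcome, and without which the bootstrap null is degenerate. Because
proportional tracking of a 0.5 m/s escape moves each successive ICI by
only ~2 µs (invisible under jitter), strong responses are modelled with
the saccade option: after the response delay, an over-compensating
multiplier ramps in (gain 2.5, 100 ms rise, 600 ms decay), emulating the
large ballistic outward depth-of-field adjustments that over-shoot prey
range in real chases. Null (control) trials continue the approach with no
escape and no responses; the recorded event time is causally inert.

The tag accelerometer carries a jerk transient starting at
`event + response_latency_jerk`: a constant-|jerk| triangle burst
(acceleration zigzag with slope magnitude `jerk_peak`, default 500 m/s^3,
ending on a zero crossing). This waveform is chosen over a damped
sinusoid because its RMS jerk equals its peak jerk over any fully active
window, making the 300 m/s^3 threshold semantics exact. The target
accelerometer (two horizontal axes, 500 Hz) has small fixed gravity
offsets plus a decaying two-axis oscillation at the event whose amplitude
scales with the configured pull strength.

What the generator does *not* emulate: multipath (surface/bottom bounces
beyond one optional static reflector), beam-pattern and off-axis effects,
schooling prey, coloured or non-stationary noise, clicks from non-focal
animals, and target-line artefacts (real target acceleration begins
~100 ms before the echo-visible move due to line tightening; here the
event time is the cue time). Passing tests therefore demonstrate
correctness of the estimators under the stated statistical structure, not
robustness to every artefact of field recordings.

## Problem sizes and reproducibility

All randomness flows from explicit seeds (`SimConfig.seed`, bootstrap
`rng_seed`); identical configurations give byte-identical trials. The
test suite validates latency recovery with 20 trials per injected latency
in {30, 60, 90, 120, 150} ms (median within one 5 ms grid step at high
SNR, two steps at ~15 dB trace SNR with jitter), and bootstrap calibration
with 100 independent 30-trial null cohorts at 200 replicates each (per-bin
type-I rate 0.05 ± 0.02). `scripts/acceptance.py` recomputes the same
quantities at reduced cohort sizes (3 trials per latency level, 9 for the
90 ms repeated-escape scenario, 50 null cohorts) chosen to keep a full run
around two minutes on one core while leaving each estimate's sampling
error well inside the tolerances above.

## Known limitations

* Single-target tracking only; the gate follows one trace and clutter is
  handled only through gating and click masking.
* Single-buzz loop-area estimates scatter by ±2-3 grid steps under 3 %
  ICI jitter; pooling across buzzes (median) is required for grid-step
  accuracy.
* The detector's echo-rejection pass assumes outgoing clicks are markedly
  louder than echoes, true for on-animal tags but not for far-field
  recorders.
* The bundle reader's variable naming is this package's own schema; a
  mapping shim would be needed for external archives whose internal
  netCDF layout differs.
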