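# echokin

Echo-kinetic response analysis for biosonar tag data.

Echolocating toothed whales probe their surroundings with clicks; the
inter-click interval (ICI) sets the acoustic depth of field
`dof = ICI * c / 2`, the maximum range from which an echo returns
unambiguously before the next click. When prey suddenly accelerates away
during a close approach (a *buzz*), the animal must dilate its ICI within
a fraction of a second or lose the target beyond the depth of field.
`echokin` measures that sensor-motor feedback loop from sound-and-movement
tag recordings: it detects clicks and buzzes, builds echograms, extracts
prey echo traces and times escape onsets, computes event-locked
delta-ICI and jerk statistics against bootstrap nulls, and estimates
response latencies — including by advancing the depth-of-field series
until the hysteresis loops it traces against prey range collapse.

The package is aimed at bioacousticians and sensory ecologists working
with DTAG-style recordings (hydrophone audio at hundreds of kHz plus
tri-axial accelerometry). A synthetic trial generator with full ground
truth — closing predator, escaping target, delayed ICI control law, echoes
in noise, jerk transients — drives validation end to end.

## Core quantities

* depth of field: `dof = ICI * c / 2` (5 ms ICI ↔ 3.75 m at c = 1500 m/s)
* delta-ICI response: proportion of positive `ici[k+1] - ici[k]` in 50 ms
  (porpoise) or 100 ms (beaked whale) bins around the prey escape, tested
  against a buzz-pair bootstrap null (event offsets transplanted between
  buzzes, >95 % criterion per bin)
* norm-jerk: `|d a/dt|` from tag accelerometry, RMS per bin; 300 m/s^3
  threshold for strong kinematic responses
* loop-area latency: the advance of the depth-of-field series, on a 5 ms
  grid, that minimises the area of the range-vs-dof hysteresis loops
* bandwidth ratio: information rate `1/(2 ICI)` over control rate
  `1/(4 latency)` — about 40 at a 2.5 ms ICI and 50 ms latency

## Worked example

From `examples/03_echogram_and_trace.py` — simulate a porpoise approach
(1 m/s closing from 4 m, target escape at 2 s, 90 ms response latency),
detect clicks, form the echogram, extract the echo trace, and time the
escape:

```text
echogram: 693 clicks x 640 range bins (0.75 cm per bin)
trace: 692/693 clicks valid, median range error 0.19 cm
v_apex at 2.001 s (truth event 2.000 s); slopes -1.00 -> +0.50 m/s
```

The trace follows the target to sub-centimetre accuracy; the hinge fit
recovers the escape onset (the V apex) within ~1 ms of the injected event,
with the -1 m/s approach and +0.5 m/s net opening speed read directly off
the fitted slopes. `examples/` contains one script per capability:
simulation and bundle I/O, click/buzz detection, echograms and traces,
event-locked response statistics, and latency estimation. Each prints its
numbers with a line on what they mean.

A thin CLI wraps the same functions for shell pipelines:

```sh
echokin sim --seed 4 --out trial.nc
echokin clicks trial.nc --out clicks.csv
echokin echogram trial.nc --out eg.png --trace-csv trace.csv
echokin respond trial*.nc --preset pp --nrep 1000 --seed 1 --out bins.csv
echokin latency trial*.nc --method loop --out latencies.csv
```

## Layout

* `src/echokin/trial_io.py` — streams, trial bundles, WAV/netCDF/CSV I/O
* `src/echokin/synthetic_trials.py` — ground-truth trial generator
* `src/echokin/click_buzz.py` — click detection, ICI, buzz segmentation
* `src/echokin/echogram.py` — echograms, echo traces, escape timing
* `src/echokin/response_stats.py` — event-locked stats, bootstrap nulls,
  analytic helpers
* `src/echokin/latency.py` — threshold, loop-area, and regression latency
  estimators
* `docs/methods.md` — models, assumptions, numerical choices, limitations
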