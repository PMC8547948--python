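"""Form an echogram, extract the target echo trace, and time the escape.

The echogram stacks each click's envelope segment on a range axis
(r = c*tau/2) coloured by SNR.  Gated peak tracking follows the target
echo across clicks; a two-segment hinge fit finds the V apex — the
closing-to-opening transition that marks the target's escape and serves
as the reference time for latency analysis.
"""

import numpy as np

import echokin as ek

bundle = ek.simulate_trial(ek.SimConfig(seed=7))
train = ek.detect_clicks(bundle.audio, preset="pp")
eg = ek.form_echogram(bundle.audio, train, preset="pp", max_range=5.0)
print(f"echogram: {eg.snr.shape[0]} clicks x {eg.snr.shape[1]} range bins "
      f"({100 * eg.range_bin_width:.2f} cm per bin)")

trace = ek.extract_trace(eg)
tv, rv = trace.valid_points()
err_cm = 100 * np.abs(rv - bundle.ground_truth.prey_range(tv))
print(f"trace: {trace.valid.sum()}/{len(train)} clicks valid, "
      f"median range error {np.median(err_cm):.2f} cm")

event = ek.detect_motion_onset(trace)
print(f"{event.type} at {event.time:.3f} s "
      f"(truth event {bundle.ground_truth.event_time:.3f} s); "
      f"slopes {event.pre_slope:+.2f} -> {event.post_slope:+.2f} m/s")
# The pre-slope is the -1 m/s approach; the post-slope the +0.5 m/s net
# opening rate of the escape; the apex lands within ~10 ms of the truth.
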