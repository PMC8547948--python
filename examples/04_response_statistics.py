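"""Event-locked delta-ICI proportions with a buzz-pair bootstrap null.

A cohort of strong-response trials (75 ms latency, over-compensating
"saccadic" ICI adjustment) is compared against the bootstrap null built by
transplanting event offsets between buzzes.  Bins where >95 % of null
replicates fall below the observed median proportion are flagged.
"""

import numpy as np

import echokin as ek
from echokin.click_buzz import ClickTrain

rng = np.random.default_rng(0)


def cohort(n, null):
    trials = []
    for _ in range(n):
        ev = float(rng.uniform(1.0, 2.0))
        cfg = ek.SimConfig(seed=int(rng.integers(2**31)), event_time=ev,
                           response_latency=0.075, saccade_enabled=not null)
        times, _ = ek.simulate_click_train(cfg, null=null)
        trials.append((ClickTrain(times=times), ev))
    return trials


res = ek.bootstrap_null(cohort(30, null=False), bin_width=0.05,
                        n_rep=200, rng_seed=1)
print("bin (ms)        observed  significant")
for b in range(res.bin_edges.size - 1):
    lo, hi = 1e3 * res.bin_edges[b], 1e3 * res.bin_edges[b + 1]
    mark = "*" if res.significant[b] else ""
    print(f"[{lo:+5.0f}, {hi:+5.0f})   {res.observed[b]:.2f}      {mark}")

null_res = ek.bootstrap_null(cohort(30, null=True), bin_width=0.05,
                             n_rep=200, rng_seed=2)
print(f"\nnull cohort significant bins: {int(null_res.significant.sum())}/"
      f"{null_res.significant.size}")
# Proportions hover near 0.5 before the event and rise sharply from the
# [+50, +100) ms bin on - the 75 ms injected latency made visible - while
# the null cohort shows (at most chance-level) flagged bins.
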