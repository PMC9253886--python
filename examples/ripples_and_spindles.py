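"""Detect sharp-wave ripples and sleep spindles and couple them.

Generates ten minutes of NREM with ripples on the hippocampal channel and
spindles on the cortical channel, runs both envelope detectors, and reports
rates, the ripple-to-spindle coupling summary and the IEI statistics.
"""

import numpy as np

import lfprhythms as m
from lfprhythms import events as ev

SR = 512.0
cfg = m.SimConfig(duration=600, seed=4, sample_rate=SR, state_dwell_means={"NREM": 1e9})
rec = m.synthesize(cfg)
nrem = rec.truth["state"] == "NREM"

spwr = ev.detect_spwr(rec.channels[0], SR, nrem)
spindles = ev.detect_spindles(rec.channels[1], SR, nrem)
nrem_s = float(nrem.sum())

print(f"ripples : {len(spwr):3d} detected ({len(rec.truth['events']['spwr'])} inserted), "
      f"rate {spwr.rate_per_s(nrem_s):.2f}/s, "
      f"peak frequency {spwr.peak_freq_hz.mean():.1f} Hz")
print(f"spindles: {len(spindles):3d} detected ({len(rec.truth['events']['spindle'])} inserted), "
      f"rate {spindles.rate_per_s(nrem_s):.3f}/s")

coupling = ev.couple_events(spwr, spindles, window_s=5.0)
print(f"ripple:spindle count ratio : {coupling.count_ratio:.2f}")
print(f"ripples followed by spindle: {coupling.fraction_followed_pct:.1f}% within {coupling.window_s:.0f} s")

stats = ev.burstiness_memory(spwr.ieis_s)
print(f"ripple IEI burstiness {stats.burstiness:+.3f}, memory {stats.memory:+.3f}")

# Burstiness 0 and memory 0 indicate Poisson-like event timing, as inserted;
# the coupling fraction counts ripples whose next spindle onset falls within
# the stated window.
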