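"""Measure theta-gamma phase-amplitude coupling by both matrix methods.

Synthesizes awake epochs whose gamma envelope is locked to the theta peak
(preferred phase 0 rad) at moderate depth, builds the 9 x 18 PAC matrices by
the per-cycle and the Hilbert method, and reports the recovered preferred
phase and the modulation index.
"""

import numpy as np

import lfprhythms as m
from lfprhythms import coupling as cp
from lfprhythms.filters import FilterSpec, analytic_signal, bandpass
from lfprhythms.sim import PacConfig, SpindleConfig, SpwrConfig

SR = 512.0
cfg = m.SimConfig(
    duration=112, seed=3, sample_rate=SR,
    state_dwell_means={"AWAKE": 1e9},
    pac=PacConfig(preferred_phase=0.0, coupling_depth=0.5),
    spwr=SpwrConfig(rate=0), spindle=SpindleConfig(rate=0, coupled_fraction=0),
)
x = m.synthesize(cfg).channels[0]
wlen = int(8 * SR)
epochs = [x[k * wlen : (k + 1) * wlen] for k in range(12)]

pac1 = cp.pac_matrix_cycles(epochs, SR)
pac2 = cp.pac_matrix_hilbert(epochs, SR)
print(f"preferred phase, per-cycle method : {cp.preferred_phase(pac1):+.3f} rad")
print(f"preferred phase, Hilbert method   : {cp.preferred_phase(pac2):+.3f} rad")
print(f"configured preferred phase        : +0.000 rad (theta peak)")

theta_phase = analytic_signal(bandpass(np.concatenate(epochs[:4]), FilterSpec.for_band("theta", SR)), SR).phase
gamma_amp = analytic_signal(bandpass(np.concatenate(epochs[:4]), FilterSpec(65, 85, SR)), SR).amplitude
mi = cp.modulation_index(theta_phase, gamma_amp)
print(f"modulation index (65-85 Hz band)  : {mi:.4f}")

# Both methods should place the coupling maximum at the theta peak (0 rad);
# the modulation index is the KL distance of the phase-conditioned gamma
# amplitude distribution from uniform, normalized to [0, 1].
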