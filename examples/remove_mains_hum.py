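"""Clean mains hum off a force signal and measure the attenuation.

Builds a noisy 1,000 Hz force channel contaminated with 50 Hz hum, applies
the periodic median filter, and reports the spectral attenuation at the hum
frequency next to the change in off-hum power.
"""

import numpy as np
from scipy.signal import periodogram

import posturekit as pk

rng = np.random.default_rng(0)
t = np.arange(10_000) / 1000.0
clean = 0.05 * rng.standard_normal(len(t))
contaminated = clean + 1.0 * np.sin(2 * np.pi * 50.0 * t + 0.4)

filtered = pk.periodic_median_filter(pk.Signal(contaminated, 1000.0), hum_freq=50.0)

f, p_before = periodogram(contaminated, 1000.0)
_, p_after = periodogram(filtered.samples, 1000.0)
i50 = int(np.argmin(np.abs(f - 50.0)))
off = np.ones_like(f, bool)
off[i50] = False

print(f"power at 50 Hz before/after: {p_before[i50]:.3e} / {p_after[i50]:.3e}")
print(f"attenuation at the hum bin: {10 * np.log10(p_before[i50] / p_after[i50]):.1f} dB")
print(f"off-bin power change: {10 * np.log10(p_before[off].sum() / p_after[off].sum()):.4f} dB")
# The phase-folded median estimates the hum waveform robustly, so the hum
# bin drops by tens of dB while broadband content is left untouched.
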