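"""Seeded synthesis of noise currents with a prescribed PSD.

Generates a pink-noise current as a sum of sinusoids with random phases and
verifies with a Welch periodogram that the realized spectrum follows the
model, octave by octave.
"""

import numpy as np
from scipy.signal import welch

from cablepsd import InputPSDModel, generate_noise, input_psd

model = InputPSDModel(kind="pink", s0=1e-30, f_cut=0.05)
series = generate_noise(model, dt=2.5e-4, duration=60.0, seed=12345)
f, P = welch(series.samples, fs=1 / series.dt, nperseg=len(series.samples) // 30)

print(f"{series.samples.size} samples at dt = {series.dt*1e3:.3g} ms, seed 12345")
print()
print("octave (Hz)    measured/model PSD")
for lo in (1, 4, 16, 64, 256):
    m = (f >= lo) & (f < 2 * lo)
    ratio = P[m].mean() / np.mean(np.asarray(input_psd(model, f[m])))
    print(f"{lo:5d}-{2*lo:<5d}   {ratio:8.3f}")

print()
print("Ratios near 1 confirm the synthesized trace realizes the requested")
print("1/f spectrum; rerunning with the same seed reproduces the series")
print("bit for bit.")
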