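"""Position-dependent filtering of a single current input.

Injects a unit current at X' = 0.8 L on the default ball-and-stick neuron
and prints how much of it returns through the soma membrane at different
frequencies: the dendrite acts as a frequency-dependent current divider, so
the somatic share collapses with frequency.
"""

import numpy as np

from cablepsd import DEFAULT_PARAMS, dimensionless_map, transfer_single

print("f (Hz)   |I_soma/I_in|   1/ratio")
for f in (1.0, 10.0, 100.0, 1000.0):
    point = dimensionless_map(DEFAULT_PARAMS, f)
    h = transfer_single(point, 0.8 * point.L, "soma_current").value
    print(f"{f:7.0f}   {abs(h):12.5f}   1/{1/abs(h):,.1f}")

print()
print("At 1 Hz about 1/7 of the input current crosses the soma membrane;")
print("by 1 kHz the capacitive dendritic return swallows all but ~1/3100 —")
print("this position-dependent low-pass filtering is what turns distributed")
print("white input noise into power-law output spectra.")
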