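"""Apparent power laws: local slopes and lf/if/hf regime boundaries.

The asymptotic exponents are reached only at very high frequency; what an
experiment sees at 10-1000 Hz is the local log-log slope mu(f), which is
still on its way up.  This script prints mu at experimentally relevant
frequencies and the regime boundaries (where mu crosses 10% and 90% of
alpha_inf) for the uncorrelated-dendrite soma-potential transfer.
"""

import math

import numpy as np

from cablepsd import (
    DEFAULT_PARAMS,
    asymptotic_exponent,
    regime_boundaries,
    slope_of_transfer,
)

tau = DEFAULT_PARAMS.membrane_resistance * DEFAULT_PARAMS.membrane_capacitance
W = np.logspace(-2, 8, 601)
curve = slope_of_transfer(W, "soma_potential", "unc_dend", L=1.0, b=0.2)
alpha = float(asymptotic_exponent("soma_potential", "unc_dend"))

print("f (Hz)    mu (local slope)")
for f0 in (1.0, 10.0, 100.0, 1000.0):
    W0 = 2 * math.pi * f0 * tau
    mu0 = float(np.interp(np.log(W0), np.log(W), curve.mu))
    print(f"{f0:7.0f}   {mu0:6.2f}")

rb = regime_boundaries(curve, alpha_inf=alpha)
f_lo = rb.f_lf_if / (2 * math.pi * tau)
f_hi = rb.f_if_hf / (2 * math.pi * tau)
print()
print(f"alpha_inf = {alpha}; regime boundaries at 10%/90% of alpha_inf:")
print(f"  lf->if at {f_lo:8.2f} Hz   (filtering becomes visible)")
print(f"  if->hf at {f_hi:8.2f} Hz   (slope within 10% of its asymptote)")
print()
print("Between these frequencies the PSD looks like a power law with an")
print("exponent that is still rising — an 'apparent' power law whose fitted")
print("slope depends on the fitting window.")
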