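"""Power-law inheritance from single neurons to an EEG proxy.

Computes the dipole-moment PSD of one ball-and-stick neuron under
uncorrelated white input, places a population of such neurons at random
distances/orientations from a far-field electrode, and shows that the
compound PSD inherits the single-neuron log-log slope exactly.
"""

import numpy as np

from cablepsd import (
    DipoleSource,
    PopulationSpec,
    compose_total_psd,
    default_fixture,
    local_slope,
    population_psd,
    psd_transfer,
)

params, ensemble = default_fixture()
f = np.logspace(1, 3, 60)
tr = psd_transfer(params, f, "dipole", ensemble)
S_single = compose_total_psd(tr, ensemble)

rng = np.random.default_rng(0)
sources = [
    DipoleSource.from_geometry(
        S_single, r=rng.uniform(0.01, 0.05), theta=rng.uniform(0, 1.2)
    )
    for _ in range(500)
]
S_pop = population_psd(sources, PopulationSpec(500, "UC"))

mu_single = local_slope(f, S_single).mu
mu_pop = local_slope(f, S_pop).mu
i = len(f) - 1
print(f"single-neuron dipole PSD slope at 1 kHz: {mu_single[i]:.3f}")
print(f"500-source EEG-proxy slope at 1 kHz:     {mu_pop[i]:.3f}")
print(f"max |difference| over 10-1000 Hz:        {np.abs(mu_pop - mu_single).max():.2e}")
print()
print("The forward model only scales each source by cos(theta)/(4 pi sigma r^2),")
print("so any power law shared by the single-neuron dipoles passes through")
print("to the EEG unchanged — head-model details affect amplitude, not slope.")
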