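"""From single-neuron current dipoles to population EEG-proxy PSDs.

In an infinite homogeneous isotropic Ohmic medium the far-field potential of
a current dipole ``p`` at distance ``r`` and angle ``theta`` is
``phi = p * cos(theta) / (4 pi sigma r**2)``: the geometry enters only
through a scalar weight, so the contribution of each neuron factorizes into
``g_k * p_k(t)``.  The compound PSD of ``N`` sources is then

* uncorrelated dipoles (UC): ``S_EEG = sum_k g_k**2 * S_p,k``;
* correlated dipoles (C, frequency-independent pairwise coherence 1):
  ``S_EEG = |sum_k g_k * sqrt(S_p,k)|**2``.

Either way, if all sources share a power law ``S_p ~ f**-alpha`` the
compound signal inherits the same exponent — realistic (multi-shell) head
models only change the weights ``g_k``, not this inheritance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DipoleSource",
    "PopulationSpec",
    "dipole_potential_weight",
    "population_psd",
]


def dipole_potential_weight(r: float, theta: float, sigma_ext: float = 0.3) -> float:
    """Far-field weight ``cos(theta)/(4 pi sigma r**2)`` (1/(S m)).

    ``r`` in meters, ``theta`` in radians, ``sigma_ext`` the extracellular
    conductivity (S/m, default 0.3).
    """
    if r <= 0:
        raise ValueError("distance r must be positive")
    if sigma_ext <= 0:
        raise ValueError("conductivity must be positive")
    return math.cos(theta) / (4.0 * math.pi * sigma_ext * r**2)


@dataclass(frozen=True)
class DipoleSource:
    """One neuron's dipole-moment PSD and its forward-model weight."""

    psd: np.ndarray  # (A m)^2 / Hz on the common frequency grid
    weight: float  # forward-model factor g_k (1/(S m))

    @classmethod
    def from_geometry(
        cls, psd: np.ndarray, r: float, theta: float, sigma_ext: float = 0.3
    ) -> "DipoleSource":
        return cls(psd=np.asarray(psd, dtype=float),
                   weight=dipole_potential_weight(r, theta, sigma_ext))


@dataclass(frozen=True)
class PopulationSpec:
    """Population composition: number of sources and correlation mode."""

    n_sources: int
    mode: str = "UC"  # "UC" uncorrelated dipoles, "C" correlated

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ValueError("population needs at least one source")
        if self.mode not in ("UC", "C"):
            raise ValueError(f"unknown correlation mode {self.mode!r}")


def population_psd(
    sources: Sequence[DipoleSource], spec: PopulationSpec
) -> np.ndarray:
    """Compound EEG-proxy PSD (V^2/Hz) for a population of dipole sources."""
    if len(sources) != spec.n_sources:
        raise ValueError(
            f"spec announces {spec.n_sources} sources, got {len(sources)}"
        )
    grids = {s.psd.shape for s in sources}
    if len(grids) != 1:
        raise ValueError("all sources must share one frequency grid")
    if spec.mode == "UC":
        return sum(s.weight**2 * s.psd for s in sources)
    amp = sum(s.weight * np.sqrt(s.psd) for s in sources)
    return np.abs(amp) ** 2
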