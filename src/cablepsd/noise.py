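"""Input-current noise models, time-domain synthesis and the mixed-noise
soma-potential scenario.

Input PSD models
----------------
* ``white``: constant ``s0``;
* ``pink``: ``s0 * f_ref/f`` (1/f noise, e.g. slow ion-channel noise);
* ``brown``: ``s0 * (f_ref/f)**2`` (Brownian noise);
* ``exp_synapse``: Lorentzian ``s0 / (1 + (2 pi f tau_s)**2)`` — the PSD of
  white presynaptic drive filtered through a current-based exponential
  synapse (high-frequency slope 2);
* ``alpha_synapse``: squared Lorentzian ``s0 / (1 + (2 pi f tau_s)**2)**2``
  for an alpha-function synaptic current (high-frequency slope 4);
* ``table``: log-log interpolation of a user-supplied table.

Pink and brown models need a low-frequency cutoff ``f_cut`` below which the
spectrum is held flat so that synthesized series have bounded power; ``f_ref``
fixes the frequency at which the PSD equals ``s0``.

Noise series are synthesized as sums of sinusoids with random phases (one
per FFT frequency), so their periodograms follow the model PSD by
construction and the series is reproducible bit-for-bit from its seed.

The mixed-noise scenario combines a pink ("ion-channel") and a synaptic
input population, both uncorrelated and homogeneous over a high-conductance
ball-and-stick neuron, scales each so that the band-integrated
soma-potential variance hits its target, and reports the crossover frequency
where the two component PSDs intersect together with the local slope of the
summed PSD (which approaches 3 = 2 + 1 at high frequency when the pink
component dominates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .distributed import InputEnsembleSpec, psd_transfer
from .params import DEFAULT_PARAMS, PhysicalParams
from .slopes import SlopeCurve, local_slope

__all__ = [
    "InputPSDModel",
    "NoiseSeries",
    "input_psd",
    "generate_noise",
    "mixed_noise_scenario",
    "MixedNoiseResult",
]

_KINDS = ("white", "pink", "brown", "exp_synapse", "alpha_synapse", "table")


@dataclass(frozen=True)
class InputPSDModel:
    """Parametric model of the input-current PSD.

    ``s0`` is the PSD amplitude (A^2/Hz) at the reference frequency
    ``f_ref`` (white/pink/brown) or at zero frequency (synapse models).
    ``tau_s`` is the synaptic time constant (s).  ``f_cut`` bounds the
    pink/brown divergence at low frequency.
    """

    kind: str
    s0: float = 1e-30  # 1 fA^2/Hz, the default white-noise amplitude
    tau_s: float = 1e-3
    f_ref: float = 1.0
    f_cut: float = 0.1
    table: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown input PSD kind {self.kind!r}")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.kind in ("exp_synapse", "alpha_synapse") and self.tau_s <= 0:
            raise ValueError("synaptic time constant must be positive")
        if self.kind == "table" and self.table is None:
            raise ValueError("table model requires (f, s) arrays")

    def __call__(self, f):
        return input_psd(self, f)


def input_psd(model: InputPSDModel, f):
    """Evaluate the input-current PSD (A^2/Hz) at frequencies ``f`` (Hz)."""
    f = np.asarray(f, dtype=float)
    if model.kind in ("pink", "brown") and np.any(f <= 0):
        raise ValueError("pink/brown input PSD undefined at f <= 0")
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    if model.kind == "white":
        out = np.full_like(f, model.s0)
    elif model.kind == "pink":
        fe = np.maximum(f, model.f_cut)
        out = model.s0 * model.f_ref / fe
    elif model.kind == "brown":
        fe = np.maximum(f, model.f_cut)
        out = model.s0 * (model.f_ref / fe) ** 2
    elif model.kind == "exp_synapse":
        out = model.s0 / (1.0 + (2.0 * math.pi * f * model.tau_s) ** 2)
    elif model.kind == "alpha_synapse":
        out = model.s0 / (1.0 + (2.0 * math.pi * f * model.tau_s) ** 2) ** 2
    else:  # table
        ft, st = model.table
        out = np.exp(
            np.interp(np.log(np.maximum(f, ft[0])), np.log(ft), np.log(st))
        )
    return out if out.ndim else float(out)


@dataclass
class NoiseSeries:
    """A synthesized noise current trace (A) with its generation metadata."""

    dt: float
    duration: float
    samples: np.ndarray
    seed: int
    frequencies: np.ndarray


def generate_noise(
    model: InputPSDModel, dt: float, duration: float, seed: int
) -> NoiseSeries:
    """Synthesize a noise current as a sum of sinusoids with random phases.

    One sinusoid per discrete frequency ``k/duration`` with amplitude
    ``sqrt(2 * s(f_k) * df)``, assembled through an inverse real FFT.  The
    result is deterministic given the seed and its Welch periodogram matches
    the model PSD.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 100 * dt:
        raise ValueError("duration must cover at least 100 samples")
    n = int(round(duration / dt))
    freqs = np.fft.rfftfreq(n, d=dt)
    df = 1.0 / (n * dt)
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=freqs.size)
    amps = np.zeros(freqs.size)
    pos = freqs > 0
    amps[pos] = np.sqrt(2.0 * np.asarray(input_psd(model, freqs[pos])) * df)
    coeff = 0.5 * n * amps * np.exp(1j * phases)
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = 0.0  # drop the Nyquist bin
    samples = np.fft.irfft(coeff, n=n)
    return NoiseSeries(
        dt=dt, duration=n * dt, samples=samples, seed=seed, frequencies=freqs
    )


# --------------------------------------------------------------------------
# mixed-noise scenario

#: High-conductance membrane: default R_m reduced tenfold to 0.3 Ohm m^2 to
#: mimic an in-vivo-like state.
HIGH_CONDUCTANCE_PARAMS = DEFAULT_PARAMS.with_(membrane_resistance=0.3)


@dataclass
class MixedNoiseResult:
    """Composite soma-potential PSD for pink + synaptic input noise."""

    f: np.ndarray
    psd_pink: np.ndarray  # V^2/Hz
    psd_synaptic: np.ndarray  # V^2/Hz
    psd_total: np.ndarray  # V^2/Hz
    slope: SlopeCurve  # local slope of the total PSD
    crossover_hz: Optional[float]
    sigma_pink: float  # achieved band std (V)
    sigma_total: float
    band: Tuple[float, float]
    scale_pink: float = field(repr=False, default=1.0)
    scale_synaptic: float = field(repr=False, default=1.0)


def _band_variance(f: np.ndarray, psd: np.ndarray, band: Tuple[float, float]) -> float:
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    return float(np.trapezoid(psd[mask], f[mask]))


def mixed_noise_scenario(
    params: PhysicalParams = HIGH_CONDUCTANCE_PARAMS,
    synapse_model: Optional[InputPSDModel] = None,
    pink_model: Optional[InputPSDModel] = None,
    sigma_pink: float = 0.6e-3,
    sigma_total: float = 2.5e-3,
    f_band: Tuple[float, float] = (0.2, 100.0),
    f_grid: Optional[np.ndarray] = None,
    ensemble: Optional[InputEnsembleSpec] = None,
) -> MixedNoiseResult:
    """Soma-potential PSD from combined pink and synaptic current noise.

    Both noise populations are uncorrelated and homogeneous (default density
    2 um^-2 on soma and stick).  The pink component is rescaled so its
    band-integrated soma-potential standard deviation equals ``sigma_pink``
    (default 0.6 mV over 0.2-100 Hz) and the synaptic component so that the
    total reaches ``sigma_total`` (default 2.5 mV).  Variance targeting uses
    the analytic soma-potential PSD integral over the band, not time-domain
    simulation.
    """
    if sigma_pink <= 0 or sigma_total <= sigma_pink:
        raise ValueError("require 0 < sigma_pink < sigma_total")
    synapse_model = synapse_model or InputPSDModel(kind="exp_synapse", tau_s=1e-3)
    pink_model = pink_model or InputPSDModel(kind="pink")
    ensemble = ensemble or InputEnsembleSpec(n_d=2e12, n_s=2e12, coherence=0.0)
    if f_grid is None:
        f_grid = np.logspace(-1, 6, 60 * 7 + 1)
    f = np.asarray(f_grid, dtype=float)
    tr = psd_transfer(params, f, "soma_potential", ensemble)
    T = tr.T_unc_soma + tr.T_unc_dend  # uncorrelated all-input transfer
    raw_pink = np.asarray(input_psd(pink_model, f)) * T
    raw_syn = np.asarray(input_psd(synapse_model, f)) * T
    var_pink = _band_variance(f, raw_pink, f_band)
    scale_pink = sigma_pink**2 / var_pink
    psd_pink = scale_pink * raw_pink
    var_syn_target = sigma_total**2 - sigma_pink**2
    scale_syn = var_syn_target / _band_variance(f, raw_syn, f_band)
    psd_syn = scale_syn * raw_syn
    total = psd_pink + psd_syn
    slope = local_slope(f, total, modality="soma_potential", input_class="mixed")
    # crossover: lowest f > 1 Hz where the two components are equal
    crossover = None
    diff = np.log(psd_syn) - np.log(psd_pink)
    for i in range(len(f) - 1):
        if f[i] < 1.0:
            continue
        if diff[i] == 0.0:
            crossover = float(f[i])
            break
        if diff[i] * diff[i + 1] < 0:
            t = diff[i] / (diff[i] - diff[i + 1])
            crossover = float(
                np.exp(np.log(f[i]) + t * (np.log(f[i + 1]) - np.log(f[i])))
            )
            break
    return MixedNoiseResult(
        f=f,
        psd_pink=psd_pink,
        psd_synaptic=psd_syn,
        psd_total=total,
        slope=slope,
        crossover_hz=crossover,
        sigma_pink=math.sqrt(_band_variance(f, psd_pink, f_band)),
        sigma_total=math.sqrt(_band_variance(f, total, f_band)),
        band=f_band,
        scale_pink=scale_pink,
        scale_synaptic=scale_syn,
    )
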