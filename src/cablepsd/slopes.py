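"""Local power-law slopes, frequency-regime segmentation and slope maps.

The local slope of a PSD is its negative log-log derivative,
``mu(f) = -d log S / d log f``; for a pure power law ``S ~ f**-alpha`` the
slope is ``alpha`` everywhere.  Because the neuron is linear, composing a
transfer function with an input PSD adds slopes pointwise, and rescaling a
PSD leaves the slope unchanged.

Low/intermediate/high-frequency regimes are defined relative to the
asymptotic exponent ``alpha_inf``: the *lf*->*if* boundary is the lowest
frequency where ``mu`` crosses a low threshold fraction of ``alpha_inf``
(default 0.10) and the *if*->*hf* boundary the lowest crossing of a high
fraction (default 0.90).  Slope curves need not be monotone (the
soma-potential/soma-input case has a concave double-hump), so all crossings
are reported alongside the first ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distributed import InputEnsembleSpec, psd_transfer
from .params import PhysicalParams, params_from_dimensionless

__all__ = [
    "SlopeCurve",
    "RegimeBoundaries",
    "local_slope",
    "slope_of_transfer",
    "regime_boundaries",
    "slope_map",
    "transfer_curve",
]

_CLASS_DENSITIES = {
    # input_class -> (n_d, n_s) used for shape evaluation; slopes are
    # invariant under overall density scaling.
    "unc_dend": (1.0, 0.0),
    "unc_soma": (0.0, 1.0),
    "corr_dend": (1.0, 0.0),
}


@dataclass
class SlopeCurve:
    """Local slope ``mu`` on a frequency (or ``W``) grid."""

    f: np.ndarray
    mu: np.ndarray
    modality: Optional[str] = None
    input_class: Optional[str] = None


def local_slope(f, S, modality=None, input_class=None) -> SlopeCurve:
    """Negative log-log derivative of a tabulated PSD.

    Central finite differences on (log f, log S); one-sided at the ends.
    Rejects non-positive PSD values (the logarithm is undefined there).
    """
    f = np.asarray(f, dtype=float)
    S = np.asarray(S, dtype=float)
    if f.size < 3:
        raise ValueError("need at least 3 grid points for a slope estimate")
    if np.any(S <= 0):
        raise ValueError("PSD must be strictly positive for log-log slopes")
    mu = -np.gradient(np.log(S), np.log(f))
    return SlopeCurve(f=f, mu=mu, modality=modality, input_class=input_class)


def transfer_curve(
    W,
    modality: str,
    input_class: str,
    L: float = 1.0,
    b: float = 0.2,
    rho: float = 0.5,
    base: Optional[PhysicalParams] = None,
):
    """Exact PSD transfer shape over a ``W`` grid for one input class.

    Evaluated from the closed forms via a physical parameter set realizing
    ``(b, L)``; the amplitude normalization is arbitrary (slopes do not
    depend on it).  ``rho`` sets the soma/dendrite density split where it
    matters (correlated input, ``all``).
    """
    from .params import DEFAULT_PARAMS

    base = base or DEFAULT_PARAMS
    params = params_from_dimensionless(b, L, base)
    tau = params.membrane_resistance * params.membrane_capacitance
    W = np.asarray(W, dtype=float)
    f = W / (2.0 * math.pi * tau)
    if input_class in _CLASS_DENSITIES:
        n_d, n_s = _CLASS_DENSITIES[input_class]
    elif input_class == "corr":
        if modality in ("soma_current", "dipole"):
            # shape independent of the densities; avoid the equal-density zero
            n_d, n_s = 1.0, 0.0
        else:
            n_d, n_s = 1.0 - rho, rho
    elif input_class == "all":
        n_d, n_s = 1.0 - rho, rho
    else:
        raise ValueError(f"unknown input class {input_class!r}")
    ens = InputEnsembleSpec(n_d=n_d, n_s=n_s, coherence=0.0, input_psd=1.0)
    tr = psd_transfer(params, f, modality, ens)
    if input_class == "unc_dend":
        return tr.T_unc_dend
    if input_class == "unc_soma":
        return tr.T_unc_soma
    if input_class in ("corr", "corr_dend"):
        return tr.T_corr
    # 'all': uncorrelated everywhere plus an (equal-weight) correlated term
    return 0.5 * (tr.T_unc_soma + tr.T_unc_dend) + 0.5 * tr.T_corr


def slope_of_transfer(
    W,
    modality: str,
    input_class: str,
    L: float = 1.0,
    b: float = 0.2,
    rho: float = 0.5,
    rel_step: float = 10 ** (1.0 / 120.0),
) -> SlopeCurve:
    """Local slope of the exact PSD transfer at the requested ``W`` values.

    Uses a symmetric finite-difference stencil of half-width 1/120 decade on
    the analytic transfer (accurate to ~1e-6 in the slope for these smooth
    curves).
    """
    W = np.atleast_1d(np.asarray(W, dtype=float))
    up = transfer_curve(W * rel_step, modality, input_class, L=L, b=b, rho=rho)
    lo = transfer_curve(W / rel_step, modality, input_class, L=L, b=b, rho=rho)
    mu = -(np.log(up) - np.log(lo)) / (2.0 * math.log(rel_step))
    return SlopeCurve(f=W, mu=mu, modality=modality, input_class=input_class)


@dataclass
class RegimeBoundaries:
    """Regime transition frequencies for one slope curve."""

    f_lf_if: Optional[float]
    f_if_hf: Optional[float]
    thresholds: tuple = (0.1, 0.9)
    crossings_low: list = field(default_factory=list)
    crossings_high: list = field(default_factory=list)


def _crossings(f: np.ndarray, mu: np.ndarray, level: float) -> list:
    out = []
    sign = mu - level
    for i in range(len(f) - 1):
        if sign[i] == 0.0:
            out.append(float(f[i]))
        elif sign[i] * sign[i + 1] < 0:
            # log-linear interpolation
            t = sign[i] / (sign[i] - sign[i + 1])
            out.append(float(np.exp(np.log(f[i]) + t * (np.log(f[i + 1]) - np.log(f[i])))))
    return out


def regime_boundaries(
    slope: SlopeCurve, alpha_inf: float, thresholds=(0.1, 0.9)
) -> RegimeBoundaries:
    """Locate the lf->if and if->hf transition frequencies.

    Boundaries are the lowest frequencies where ``mu`` crosses
    ``thresholds * alpha_inf``; a threshold that is never crossed yields
    ``None``.  All crossings are also reported for non-monotone curves.
    """
    if alpha_inf <= 0:
        raise ValueError("alpha_inf must be positive")
    lo, hi = thresholds
    cl = _crossings(slope.f, slope.mu, lo * alpha_inf)
    ch = _crossings(slope.f, slope.mu, hi * alpha_inf)
    return RegimeBoundaries(
        f_lf_if=cl[0] if cl else None,
        f_if_hf=ch[0] if ch else None,
        thresholds=(lo, hi),
        crossings_low=cl,
        crossings_high=ch,
    )


def slope_map(
    L: float,
    b_grid: Sequence[float],
    W_grid: Sequence[float],
    modality: str,
    input_class: str,
    rho: float = 0.5,
) -> np.ndarray:
    """Matrix of local slopes ``mu[b, W]`` for fixed electrotonic length.

    Evaluated from the exact closed forms; suitable for heat-map export.
    """
    b_grid = np.asarray(b_grid, dtype=float)
    W_grid = np.asarray(W_grid, dtype=float)
    out = np.empty((b_grid.size, W_grid.size))
    for i, b in enumerate(b_grid):
        out[i] = slope_of_transfer(
            W_grid, modality, input_class, L=L, b=float(b), rho=rho
        ).mu
    return out
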