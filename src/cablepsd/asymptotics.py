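"""High-frequency power-law asymptotics of the PSD transfer functions.

For ``W >> 1`` every PSD transfer component approaches
``T ~ A * W**(-alpha_inf)`` with a half-integer exponent.  The exponents are
analytical results and are stored as exact rationals; the leading amplitudes
``A`` are hard-coded in terms of the biophysical parameters and validated
numerically against the exact closed forms (they are obtained by dropping
exponentially decaying terms and keeping the leading reciprocal power).

Exponent table (modality x input class):

===============  =====  ==========  ========  ========
modality         corr   corr(rho=0) unc_soma  unc_dend
===============  =====  ==========  ========  ========
soma_current     1      1           1         1/2
dipole           2      2           2         3/2
soma_potential   2      3           2         5/2
===============  =====  ==========  ========  ========

For homogeneous correlated input with equal densities the soma-current and
dipole amplitudes vanish identically (iso-potential neuron) and the exponent
is undefined.  With "all" types of input present the smallest exponent of
the contributing classes wins: 1/2 for the soma current, 3/2 for the dipole
and 2 for the soma potential (the uncorrelated somatic term dominates the
dendritic ``W**-5/2`` term).

Composing the transfer with an input-current PSD that is itself a power law
simply adds exponents: e.g. uncorrelated dendritic input with a pink (1/f)
spectrum gives a soma-current PSD falling as ``f**-1.5``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np

from .params import PhysicalParams, derive_constants

__all__ = [
    "AsymptoticLaw",
    "asymptotic_exponent",
    "amplitude",
    "hf_transfer",
    "EXPONENTS",
]

_MODALITIES = ("dipole", "soma_current", "soma_potential")

#: (modality, input_class) -> exact asymptotic exponent.  ``corr`` assumes a
#: non-degenerate density combination; ``corr_dend`` is dendrite-only
#: correlated input (rho = 0).
EXPONENTS = {
    ("soma_current", "corr"): Fraction(1),
    ("soma_current", "corr_dend"): Fraction(1),
    ("soma_current", "unc_soma"): Fraction(1),
    ("soma_current", "unc_dend"): Fraction(1, 2),
    ("dipole", "corr"): Fraction(2),
    ("dipole", "corr_dend"): Fraction(2),
    ("dipole", "unc_soma"): Fraction(2),
    ("dipole", "unc_dend"): Fraction(3, 2),
    ("soma_potential", "corr"): Fraction(2),
    ("soma_potential", "corr_dend"): Fraction(3),
    ("soma_potential", "unc_soma"): Fraction(2),
    ("soma_potential", "unc_dend"): Fraction(5, 2),
}


@dataclass(frozen=True)
class AsymptoticLaw:
    """Asymptotic law ``T ~ amplitude * W**(-exponent)`` for one case."""

    modality: str
    input_class: str
    exponent: Fraction
    amplitude: float


class DegenerateCombination(ValueError):
    """Raised for combinations whose asymptotic amplitude vanishes."""


def asymptotic_exponent(
    modality: str,
    input_class: str,
    rho: Optional[float] = 0.5,
    coherence: float = 0.5,
) -> Fraction:
    """Exact asymptotic exponent ``alpha_inf`` for one combination.

    ``input_class`` is one of ``corr``, ``corr_dend``, ``unc_soma``,
    ``unc_dend`` or ``all``.  ``rho = n_s/(n_s + n_d)`` selects the
    correlated sub-case (``rho = 0``: dendrite-only) and, for ``all``,
    which source locations are present; ``coherence`` decides whether the
    correlated class contributes to ``all``.
    """
    if modality not in _MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if input_class == "all":
        classes = []
        if rho is None:
            rho = 0.5
        if rho > 0 and coherence < 1:
            classes.append("unc_soma")
        if rho < 1 and coherence < 1:
            classes.append("unc_dend")
        if coherence > 0:
            # equal densities kill the correlated I and p terms
            degenerate = (
                modality in ("soma_current", "dipole") and rho == 0.5
            )
            if not degenerate:
                classes.append("corr_dend" if rho == 0 else "corr")
        if not classes:
            raise DegenerateCombination(
                "no contributing input class for this density/coherence mix"
            )
        return min(EXPONENTS[(modality, cls)] for cls in classes)
    if input_class == "corr" and rho == 0:
        input_class = "corr_dend"
    key = (modality, input_class)
    if key not in EXPONENTS:
        raise ValueError(f"unknown input class {input_class!r}")
    if (
        input_class == "corr"
        and rho == 0.5
        and modality in ("soma_current", "dipole")
    ):
        raise DegenerateCombination(
            f"correlated {modality} with equal densities has zero amplitude; "
            "the asymptotic exponent is undefined"
        )
    return EXPONENTS[key]


def amplitude(
    params: PhysicalParams,
    modality: str,
    input_class: str,
    n_d: float = 1.0,
    n_s: float = 1.0,
) -> float:
    """Dimensional asymptotic amplitude ``A`` with ``T ~ A * W**-alpha_inf``.

    Uncorrelated amplitudes are linear in the matching density, correlated
    ones quadratic in the density difference (soma current, dipole) or in
    the individual densities (soma potential).
    """
    if modality not in _MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    c = derive_constants(params)
    lam = c.length_constant
    g_inf = c.infinite_stick_conductance
    b = params.soma_area * params.membrane_conductance / g_inf
    a_d = n_d * math.pi * params.stick_diameter * lam
    a_s = n_s * params.soma_area
    sqrt2 = math.sqrt(2.0)
    if input_class == "unc_dend":
        return {
            "soma_current": a_d / sqrt2,
            "dipole": a_d * lam**2 / sqrt2,
            "soma_potential": a_d / (sqrt2 * g_inf**2 * b**2),
        }[modality]
    if input_class == "unc_soma":
        return {
            "soma_current": a_s / b**2,
            "dipole": a_s * lam**2 / b**2,
            "soma_potential": a_s / (g_inf**2 * b**2),
        }[modality]
    if input_class in ("corr", "corr_dend"):
        if input_class == "corr_dend":
            n_s, a_s = 0.0, 0.0
        if modality == "soma_current":
            amp = (a_d * b - a_s) ** 2 / b**2
        elif modality == "dipole":
            amp = lam**2 * (a_s - a_d * b) ** 2 / b**2
        else:  # soma potential
            if n_s > 0:
                amp = a_s**2 / (g_inf**2 * b**2)
            else:
                amp = a_d**2 / (g_inf**2 * b**2)  # carries W**-3
        if amp == 0.0:
            raise DegenerateCombination(
                f"correlated {modality} amplitude vanishes for these densities"
            )
        return amp
    raise ValueError(f"unknown input class {input_class!r}")


def hf_transfer(
    params: PhysicalParams,
    W,
    modality: str,
    input_class: str,
    n_d: float = 1.0,
    n_s: float = 1.0,
):
    """Leading-order high-frequency PSD transfer ``A * W**-alpha_inf``.

    The ratio of the exact transfer to this value tends to 1 as
    ``W -> infinity``; a warning is emitted if evaluated below ``W = 10``
    where the expansion is meaningless.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 10.0):
        warnings.warn(
            "high-frequency expansion evaluated at W < 10; result unreliable",
            stacklevel=2,
        )
    rho = n_s / (n_s + n_d) if (n_s + n_d) > 0 else 0.5
    alpha = asymptotic_exponent(modality, input_class, rho=rho)
    amp = amplitude(params, modality, input_class, n_d=n_d, n_s=n_s)
    out = amp * W ** (-float(alpha))
    return out if out.ndim else float(out)
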