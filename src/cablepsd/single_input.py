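"""Transfer functions for a single current input on the ball-and-stick neuron.

A current ``I_0`` injected at dimensionless position ``X'`` (soma at ``X = 0``,
sealed end at ``X = L``) drives return currents through the membrane.  In the
frequency domain the membrane potential obeys ``V'' = q**2 V`` with
``q = sqrt(1 + i W)``, which yields closed forms for every measurement
modality once the two boundary admittances are attached:

* distal stick (sealed end): ``Y_d = Y_inf * tanh(q*(L - X'))``
* proximal stick + lumped soma: ``Y_p = Y_inf * (sinh(q X') + B cosh(q X'))
  / (cosh(q X') + B sinh(q X'))``

All transfer functions share the denominator ``Dq = sinh(qL) + B*cosh(qL)``:

* soma potential:  ``H_V = cosh(q*(L - X')) / (Y_inf * Dq)``      (Ohm)
* soma current:    ``H_I = B * cosh(q*(L - X')) / Dq``            (1)
* dipole moment:   ``H_p = (lambda/q) * (cosh(q*(L - X'))
  - cosh(q X') - B*sinh(q X')) / Dq``                             (m)

Sign conventions: outward membrane current is positive, the z-axis points
from the soma toward the distal end, and the current-dipole moment is the sum
of (signed) transmembrane currents times their z-position, the injected
current counting as an inward transmembrane current at its injection site.
With these conventions a somatic input creates a positive (distally pointing)
dipole and the injected current is part of the measured net soma current when
and only when it is delivered to the soma.

Evaluation uses exponentially scaled forms (all exponents have non-positive
real part), so the expressions stay finite for arbitrarily large ``W``
(``|q|L`` far beyond the ~700 overflow limit of cosh/sinh in double
precision).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .params import DimensionlessPoint

__all__ = [
    "Modality",
    "TransferValue",
    "input_admittance",
    "transfer_single",
    "membrane_current_density",
    "membrane_current_profile",
    "dipole_from_profile",
]

Modality = Literal["dipole", "soma_current", "soma_potential"]
_MODALITIES = ("dipole", "soma_current", "soma_potential")


@dataclass(frozen=True)
class TransferValue:
    """A complex single-input transfer value for one modality.

    Units: m (dipole per unit current), dimensionless (soma current ratio) or
    Ohm (soma potential per unit current).
    """

    modality: str
    value: complex


def _check_position(point: DimensionlessPoint, x_prime: float) -> None:
    if not (0.0 <= x_prime <= point.L):
        raise ValueError(
            f"input position X'={x_prime!r} outside the stick [0, {point.L!r}]"
        )


def _denominator(point: DimensionlessPoint):
    """``2*exp(-qL) * (sinh(qL) + B*cosh(qL))`` — overflow-safe."""
    q, L, B = point.q, point.L, point.B
    return (1.0 + B) - (1.0 - B) * np.exp(-2.0 * q * L)


def input_admittance(point: DimensionlessPoint, x_prime: float) -> complex:
    """Total input admittance (S) seen by a current input at ``X'``.

    Sum of the distal sealed-end finite-stick admittance and the proximal
    stick-plus-lumped-soma admittance.  Continuous in the limits ``X' -> L``
    and ``b -> 0``.
    """
    _check_position(point, x_prime)
    q, L, B = point.q, point.L, point.B
    y_inf = point.infinite_stick_conductance * q
    e_p = np.exp(-2.0 * q * x_prime)
    e_d = np.exp(-2.0 * q * (L - x_prime))
    y_prox = y_inf * ((1.0 + B) - (1.0 - B) * e_p) / ((1.0 + B) + (1.0 - B) * e_p)
    y_dist = y_inf * (1.0 - e_d) / (1.0 + e_d)
    return complex(y_prox + y_dist)


def transfer_single(
    point: DimensionlessPoint,
    x_prime: float,
    modality: Modality,
    is_somatic: bool = False,
) -> TransferValue:
    """Complex transfer from a unit current input at ``X'`` to one modality.

    ``is_somatic`` distinguishes injection into the soma compartment from
    injection at the proximal stick end ``X' = 0``: the soma potential and the
    dipole moment coincide for the two cases (the soma-to-stick coupling
    resistance is zero), but the net soma membrane current does not, because a
    somatic injection is itself part of the measured soma current.
    """
    if modality not in _MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    _check_position(point, x_prime)
    if is_somatic and x_prime != 0.0:
        raise ValueError("somatic input requires X' = 0")
    if is_somatic and modality == "soma_potential" and point.b == 0.0:
        raise ValueError(
            "degenerate: b = 0 leaves no soma membrane for a somatic input"
        )
    q, L, B = point.q, point.L, point.B
    lam = point.length_constant
    den = _denominator(point)
    # 2*exp(-qL)*cosh(q*(L - X'))
    cosh_dist = np.exp(-q * x_prime) + np.exp(-q * (2.0 * L - x_prime))
    if modality == "soma_potential":
        y_inf = point.infinite_stick_conductance * q
        value = cosh_dist / (y_inf * den)
    elif modality == "soma_current":
        if is_somatic:
            # net soma membrane current = soma return - injected = -axial
            # current entering the stick
            value = -(1.0 - np.exp(-2.0 * q * L)) / den
        else:
            value = B * cosh_dist / den
    else:  # dipole
        value = (
            (lam / q)
            * (
                cosh_dist
                - (1.0 + B) * np.exp(-q * (L - x_prime))
                - (1.0 - B) * np.exp(-q * (L + x_prime))
            )
            / den
        )
    return TransferValue(modality=modality, value=complex(value))


def _potential_along(point: DimensionlessPoint, x_prime: float, X):
    """Membrane potential per unit input current, V(X)/I_0 (Ohm), vectorized.

    Reciprocal in ``X`` and ``X'`` (the same four-exponential kernel applies
    on both sides of the injection point).
    """
    q, L, B = point.q, point.L, point.B
    y_inf = point.infinite_stick_conductance * q
    den = _denominator(point)
    X = np.asarray(X, dtype=float)
    lo = np.minimum(X, x_prime)
    hi = np.maximum(X, x_prime)
    num = 0.5 * (
        (1.0 + B) * np.exp(-q * (hi - lo))
        + (1.0 - B) * np.exp(-q * (hi + lo))
        + (1.0 + B) * np.exp(-q * (2.0 * L - hi - lo))
        + (1.0 - B) * np.exp(-q * (2.0 * L - hi + lo))
    )
    return num / (y_inf * den)


def membrane_current_density(point: DimensionlessPoint, x_prime: float, X):
    """Return-current density per unit injected current, d(I/I_0)/dX.

    Outward membrane current (leak + capacitive) per unit dimensionless
    length at stick position ``X``; equals ``q**2 * G_inf * V(X)/I_0``.
    """
    _check_position(point, x_prime)
    q = point.q
    return q * q * point.infinite_stick_conductance * _potential_along(
        point, x_prime, X
    )


@dataclass(frozen=True)
class CurrentProfile:
    """Membrane return-current profile for a single input."""

    X: np.ndarray
    stick_density: np.ndarray  # complex, per unit dimensionless length, / I_0
    soma_return: complex  # outward soma membrane current / I_0
    x_prime: float


def membrane_current_profile(
    point: DimensionlessPoint, x_prime: float, X_grid
) -> CurrentProfile:
    """Return-current profile over ``X_grid`` plus the somatic return current.

    Kirchhoff holds per frequency: the stick density integrated over
    ``[0, L]`` plus the somatic return equals the injected current.
    """
    _check_position(point, x_prime)
    X_grid = np.asarray(X_grid, dtype=float)
    if X_grid.size and (X_grid.min() < 0 or X_grid.max() > point.L):
        raise ValueError("X_grid must lie within [0, L]")
    density = membrane_current_density(point, x_prime, X_grid)
    y_soma = point.B * point.infinite_stick_conductance * point.q
    soma_return = complex(y_soma * _potential_along(point, x_prime, 0.0))
    return CurrentProfile(
        X=X_grid, stick_density=density, soma_return=soma_return, x_prime=x_prime
    )


def dipole_from_profile(
    point: DimensionlessPoint, x_prime: float, n_quad: int = 2000
) -> complex:
    """Dipole moment (m per unit current) by quadrature of the return profile.

    Integrates the z-weighted membrane return-current density over the stick
    (splitting at the injection point, where the density has a kink), adds the
    somatic return at ``z = 0`` and subtracts the injected current at
    ``z = lambda*X'``.  Deliberately takes the integration route rather than
    the closed form, so it can serve as an internal cross-check of
    :func:`transfer_single` with ``modality="dipole"``.
    """
    _check_position(point, x_prime)
    lam = point.length_constant
    total = 0.0 + 0.0j
    for a, b_ in ((0.0, x_prime), (x_prime, point.L)):
        if b_ - a <= 0:
            continue
        # Gauss-Legendre on each smooth piece
        nodes, weights = np.polynomial.legendre.leggauss(min(n_quad, 400))
        X = 0.5 * (b_ - a) * nodes + 0.5 * (b_ + a)
        w = 0.5 * (b_ - a) * weights
        total += np.sum(w * X * membrane_current_density(point, x_prime, X))
    return complex(lam * (total - x_prime))
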