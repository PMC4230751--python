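"""Physical and dimensionless description of the ball-and-stick neuron.

The model is a lumped iso-potential soma ("ball") attached at ``z = 0`` to a
uniform cylindrical dendrite ("stick") of diameter ``d`` and length ``l`` with
a sealed distal end.  Soma and stick share the specific membrane resistance
``R_m`` (Ohm m^2), specific capacitance ``C_m`` (F/m^2) and axial resistivity
``R_i`` (Ohm m).  The soma membrane area follows the sphere-surface convention
``pi * D**2`` for a soma of diameter ``D``.

Everything downstream is controlled by a handful of dimensionless numbers:

``W``
    dimensionless angular frequency, ``2*pi*f*tau`` with ``tau = R_m*C_m``.
``L``
    electrotonic stick length ``l/lambda`` with
    ``lambda = sqrt(d*R_m/(4*R_i))``.
``b``
    DC ratio of soma conductance to the infinite-stick conductance
    ``G_inf``; equals ``D**2/(d*lambda)``.
``q``
    principal square root of ``1 + i*W``; the frequency dependence of the
    infinite-stick admittance ``Y_inf = G_inf*q``.
``B``
    soma-to-infinite-stick admittance ratio.  With identical specific
    membrane properties in soma and stick, ``B = b*q``.

Internally everything is SI.  :func:`load_params` accepts the customary
neuroscience units (um, ms, Ohm cm^2, uF/cm^2, Ohm cm) via unit-suffixed
strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import yaml

__all__ = [
    "PhysicalParams",
    "DerivedConstants",
    "DimensionlessPoint",
    "DEFAULT_PARAMS",
    "derive_constants",
    "dimensionless_map",
    "q_factor",
    "admittance_set",
    "params_from_dimensionless",
    "load_params",
    "parse_quantity",
]


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional neuron description (SI units).

    Attributes
    ----------
    stick_diameter : float
        Dendritic stick diameter ``d`` (m).
    soma_diameter : float
        Soma diameter ``D`` (m); soma membrane area is ``pi*D**2``.
    stick_length : float
        Stick length ``l`` (m).
    membrane_resistance : float
        Specific membrane resistance ``R_m`` (Ohm m^2).
    membrane_capacitance : float
        Specific membrane capacitance ``C_m`` (F/m^2).
    axial_resistivity : float
        Inner (axial) resistivity ``R_i`` (Ohm m).
    """

    stick_diameter: float
    soma_diameter: float
    stick_length: float
    membrane_resistance: float
    membrane_capacitance: float
    axial_resistivity: float

    def __post_init__(self) -> None:
        for name in (
            "stick_diameter",
            "soma_diameter",
            "stick_length",
            "membrane_resistance",
            "membrane_capacitance",
            "axial_resistivity",
        ):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(
                    f"parameter {name!r} must be strictly positive, got {value!r}"
                )

    @property
    def membrane_conductance(self) -> float:
        """Specific membrane conductance ``G_m = 1/R_m`` (S/m^2)."""
        return 1.0 / self.membrane_resistance

    @property
    def soma_area(self) -> float:
        """Soma membrane area ``pi*D**2`` (m^2)."""
        return math.pi * self.soma_diameter**2

    @property
    def stick_area(self) -> float:
        """Stick membrane area ``pi*d*l`` (m^2)."""
        return math.pi * self.stick_diameter * self.stick_length

    def with_(self, **kwargs) -> "PhysicalParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


#: Default parameter set: d = 2 um, D = 20 um, l = 1 mm, R_m = 3 Ohm m^2,
#: C_m = 0.01 F/m^2, R_i = 1.5 Ohm m.  Gives tau = 30 ms, lambda = 1 mm,
#: L = 1 and b = 0.2.
DEFAULT_PARAMS = PhysicalParams(
    stick_diameter=2e-6,
    soma_diameter=20e-6,
    stick_length=1e-3,
    membrane_resistance=3.0,
    membrane_capacitance=0.01,
    axial_resistivity=1.5,
)


@dataclass(frozen=True)
class DerivedConstants:
    """Cable constants derived from :class:`PhysicalParams` (SI units)."""

    length_constant: float  # lambda (m)
    time_constant: float  # tau (s)
    infinite_stick_conductance: float  # G_inf (S)
    axial_resistance_per_length: float  # r_i (Ohm/m)
    membrane_conductance_per_length: float  # g_m * pi * d (S/m)
    membrane_capacitance_per_length: float  # c_m * pi * d (F/m)


@dataclass(frozen=True)
class DimensionlessPoint:
    """Reduced coordinates that fully determine all transfer functions.

    ``length_constant`` and ``infinite_stick_conductance`` are carried along
    so that dimensional transfer values (Ohm for potentials, m for dipole
    moments) can be reconstructed without re-deriving them.
    """

    W: float
    L: float
    X: float
    b: float
    q: complex
    B: complex
    length_constant: float
    infinite_stick_conductance: float


def derive_constants(params: PhysicalParams) -> DerivedConstants:
    """Compute lambda, tau, G_inf and the per-length cable quantities.

    ``lambda = sqrt(d*R_m/(4*R_i))``, ``tau = R_m*C_m`` and the
    infinite-stick (semi-infinite cable) DC conductance
    ``G_inf = 1/(r_i*lambda) = pi*d**(3/2)/(2*sqrt(R_m*R_i))``.
    """
    d = params.stick_diameter
    lam = math.sqrt(d * params.membrane_resistance / (4.0 * params.axial_resistivity))
    tau = params.membrane_resistance * params.membrane_capacitance
    r_i = 4.0 * params.axial_resistivity / (math.pi * d**2)
    g_per_len = math.pi * d * params.membrane_conductance
    c_per_len = math.pi * d * params.membrane_capacitance
    g_inf = 1.0 / (r_i * lam)
    return DerivedConstants(
        length_constant=lam,
        time_constant=tau,
        infinite_stick_conductance=g_inf,
        axial_resistance_per_length=r_i,
        membrane_conductance_per_length=g_per_len,
        membrane_capacitance_per_length=c_per_len,
    )


def q_factor(W):
    """Principal square root of ``1 + i*W`` (``Re q >= 1`` for ``W >= 0``).

    Every hyperbolic identity used by the transfer functions assumes this
    branch; the principal branch of the complex square root guarantees it for
    arguments with positive real part.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("dimensionless frequency W must be non-negative")
    out = np.sqrt(1.0 + 1j * W)
    return out if out.ndim else complex(out)


def dimensionless_map(
    params: PhysicalParams, f: float, x: float = 0.0
) -> DimensionlessPoint:
    """Map (frequency in Hz, position in m) to the dimensionless coordinates."""
    if f < 0:
        raise ValueError("frequency f must be non-negative")
    if not (0.0 <= x <= params.stick_length):
        raise ValueError(
            f"position x={x!r} lies outside the stick [0, {params.stick_length!r}]"
        )
    c = derive_constants(params)
    W = 2.0 * math.pi * f * c.time_constant
    b = (
        params.soma_area
        * params.membrane_conductance
        / c.infinite_stick_conductance
    )
    q = q_factor(W)
    return DimensionlessPoint(
        W=W,
        L=params.stick_length / c.length_constant,
        X=x / c.length_constant,
        b=b,
        q=q,
        B=b * q,
        length_constant=c.length_constant,
        infinite_stick_conductance=c.infinite_stick_conductance,
    )


def admittance_set(params: PhysicalParams, W: float):
    """Return ``(Y_inf, Y_soma, B)`` at dimensionless frequency ``W``.

    ``Y_soma = pi*D**2*G_m*(1 + i*W)`` (lumped RC membrane),
    ``Y_inf = G_inf*q`` and ``B = Y_soma/Y_inf = b*q``.
    """
    c = derive_constants(params)
    q = q_factor(W)
    y_soma = params.soma_area * params.membrane_conductance * (1.0 + 1j * np.asarray(W))
    y_inf = c.infinite_stick_conductance * q
    b = params.soma_area * params.membrane_conductance / c.infinite_stick_conductance
    return y_inf, y_soma, b * q


def params_from_dimensionless(
    b: float,
    L: float,
    base: PhysicalParams = DEFAULT_PARAMS,
) -> PhysicalParams:
    """Construct a physical parameter set realizing given ``(b, L)``.

    Keeps ``d``, ``R_m``, ``C_m`` and ``R_i`` from ``base`` and solves for the
    soma diameter (``D = sqrt(b*d*lambda)``) and stick length (``l =
    L*lambda``).  Used by the slope-map machinery, where only the
    dimensionless coordinates matter.
    """
    if b < 0 or L <= 0:
        raise ValueError("require b >= 0 and L > 0")
    lam = derive_constants(base).length_constant
    soma_d = math.sqrt(max(b, 1e-300) * base.stick_diameter * lam)
    return base.with_(soma_diameter=soma_d, stick_length=L * lam)


# --------------------------------------------------------------------------
# config / unit handling

_UNIT_FACTORS = {
    # length
    "m": 1.0,
    "cm": 1e-2,
    "mm": 1e-3,
    "um": 1e-6,
    # time
    "s": 1.0,
    "ms": 1e-3,
    # specific membrane resistance
    "ohm.m2": 1.0,
    "ohm.cm2": 1e-4,
    "kohm.cm2": 1e-1,
    # axial resistivity
    "ohm.m": 1.0,
    "ohm.cm": 1e-2,
    # specific capacitance
    "f/m2": 1.0,
    "uf/cm2": 1e-2,
}

_FIELD_ALIASES = {
    "d": "stick_diameter",
    "stick_diameter": "stick_diameter",
    "D": "soma_diameter",
    "soma_diameter": "soma_diameter",
    "l": "stick_length",
    "stick_length": "stick_length",
    "r_m": "membrane_resistance",
    "rm": "membrane_resistance",
    "membrane_resistance": "membrane_resistance",
    "specific_membrane_resistance": "membrane_resistance",
    "c_m": "membrane_capacitance",
    "cm_spec": "membrane_capacitance",
    "membrane_capacitance": "membrane_capacitance",
    "specific_capacitance": "membrane_capacitance",
    "r_i": "axial_resistivity",
    "ri": "axial_resistivity",
    "axial_resistivity": "axial_resistivity",
    "inner_resistivity": "axial_resistivity",
}


def _normalize_unit(unit: str) -> str:
    u = unit.strip()
    u = u.replace("µ", "u").replace("μ", "u")  # micro signs
    u = u.replace("Ω", "ohm").replace("Ω", "ohm")
    u = u.replace("·", ".").replace("*", ".").replace(" ", ".")
    u = u.replace("^", "").replace("²", "2")
    u = u.lower()
    while ".." in u:
        u = u.replace("..", ".")
    return u.strip(".")


def parse_quantity(value: Union[str, float, int]) -> float:
    """Parse ``"2 um"``-style unit-suffixed quantities to SI floats.

    Bare numbers are taken to be SI already.
    """
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    parts = text.split(None, 1)
    if len(parts) == 1:
        return float(parts[0])
    number, unit = parts
    key = _normalize_unit(unit)
    if key not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {unit!r} in quantity {value!r}")
    return float(number) * _UNIT_FACTORS[key]


def load_params(source: Union[str, Path, Mapping, None] = "default") -> PhysicalParams:
    """Load physical parameters from a mapping, a YAML file or the fixture.

    ``"default"`` (or ``None``) returns :data:`DEFAULT_PARAMS`.  Mapping keys
    may use either the long field names or the short symbols ``d``, ``D``,
    ``l``, ``R_m``, ``C_m``, ``R_i``; values may be unit-suffixed strings.
    """
    if source is None or (isinstance(source, str) and source == "default"):
        return DEFAULT_PARAMS
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, Mapping):
            raise ValueError(f"config file {source!s} did not contain a mapping")
        return load_params(mapping)
    fields = dict(DEFAULT_PARAMS.__dict__)
    for key, raw in source.items():
        canon = _FIELD_ALIASES.get(key if key == "D" else str(key).lower())
        if canon is None:
            raise ValueError(f"unknown parameter key {key!r}")
        fields[canon] = parse_quantity(raw)
    return PhysicalParams(**fields)
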