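"""Independent numerical validator: frequency-domain compartmental solver.

The ball-and-stick neuron is discretized into a chain of iso-potential
segments (a lumped soma at ``z = 0`` plus uniform dendritic segments with
potentials at segment centers and axial resistances between centers; the
soma-to-stick coupling resistance is zero).  At each frequency the complex
node potentials solve the tridiagonal admittance system

``(diag(Y_mem) + G_axial) V = I_inj``

which is handled by a banded LU solve.  This path shares no code with the
analytic closed forms (no hyperbolic functions), making it a genuinely
independent oracle; it converges to the analytic solution with second-order
accuracy in the segment length.

A Crank-Nicolson time-domain mode is included for protocol-level
reproduction (noise injected as a sum of sinusoids, fixed time step,
transient discarded); the frequency-domain solve is the canonical oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded, solveh_banded

from .distributed import InputEnsembleSpec
from .params import PhysicalParams

__all__ = [
    "CompartmentChain",
    "FrequencyResponse",
    "build_ball_stick_chain",
    "solve_frequency_response",
    "extract_modalities",
    "ensemble_psd",
    "chain_to_table",
    "chain_from_table",
    "simulate_time_domain",
]


@dataclass
class CompartmentChain:
    """Discretized chain: soma is segment 0, distal tip the last segment.

    ``axial_resistance[k]`` (Ohm) couples segment ``k`` to segment ``k-1``
    (``axial_resistance[0]`` is unused).  Membrane properties are stored per
    segment so imported custom chains remain self-contained.
    """

    z: np.ndarray  # m, along the stick axis, soma at 0
    length: np.ndarray  # m
    diameter: np.ndarray  # m
    area: np.ndarray  # m^2 membrane area
    axial_resistance: np.ndarray  # Ohm
    is_soma: np.ndarray  # bool
    g_m: np.ndarray  # S/m^2
    c_m: np.ndarray  # F/m^2

    @property
    def n(self) -> int:
        return self.z.size

    def membrane_admittance(self, f: float) -> np.ndarray:
        return self.area * (self.g_m + 2j * math.pi * f * self.c_m)


def build_ball_stick_chain(
    params: PhysicalParams, n_segments: int = 200
) -> CompartmentChain:
    """Uniform discretization: one lumped soma + ``n_segments`` stick segments.

    The soma (area ``pi*D**2``) sits at ``z = 0``; dendritic segment centers
    at ``z = (k - 1/2) * l/n``.  Axial resistance soma->first center is half
    a segment (the soma couples to the stick's proximal end with zero
    resistance).
    """
    if n_segments < 1:
        raise ValueError("need at least one dendritic segment")
    d, l = params.stick_diameter, params.stick_length
    seg = l / n_segments
    r_per_len = 4.0 * params.axial_resistivity / (math.pi * d**2)
    n = n_segments + 1
    z = np.concatenate(([0.0], (np.arange(n_segments) + 0.5) * seg))
    length = np.concatenate(([params.soma_diameter], np.full(n_segments, seg)))
    diameter = np.concatenate(
        ([params.soma_diameter], np.full(n_segments, d))
    )
    area = np.concatenate(
        ([params.soma_area], np.full(n_segments, math.pi * d * seg))
    )
    axial = np.concatenate(
        ([np.inf, r_per_len * seg / 2.0], np.full(n_segments - 1, r_per_len * seg))
    )
    is_soma = np.zeros(n, dtype=bool)
    is_soma[0] = True
    g_m = np.full(n, params.membrane_conductance)
    c_m = np.full(n, params.membrane_capacitance)
    return CompartmentChain(
        z=z,
        length=length,
        diameter=diameter,
        area=area,
        axial_resistance=axial,
        is_soma=is_soma,
        g_m=g_m,
        c_m=c_m,
    )


@dataclass
class FrequencyResponse:
    """Complex potentials and transmembrane currents for one input."""

    f: float
    input_segment: int
    injected_current: complex
    potential: np.ndarray  # V, complex
    membrane_current: np.ndarray  # A, outward leak+capacitive, complex


def _banded_system(chain: CompartmentChain, f: float) -> np.ndarray:
    """Assemble the (1,1)-banded complex admittance matrix."""
    n = chain.n
    g_ax = np.zeros(n)
    g_ax[1:] = 1.0 / chain.axial_resistance[1:]
    diag = chain.membrane_admittance(f).astype(complex)
    diag[:-1] += g_ax[1:]
    diag[1:] += g_ax[1:]
    ab = np.zeros((3, n), dtype=complex)
    ab[0, 1:] = -g_ax[1:]
    ab[1] = diag
    ab[2, :-1] = -g_ax[1:]
    return ab


def solve_frequency_response(
    chain: CompartmentChain,
    input_segment: int,
    f: float,
    injected_current: complex = 1.0,
) -> FrequencyResponse:
    """Solve the compartmental system for a unit current input at one segment.

    Kirchhoff holds to machine precision: the outward membrane currents sum
    to the injected current at every frequency.
    """
    if not 0 <= input_segment < chain.n:
        raise ValueError(f"input segment {input_segment} out of range")
    if f < 0:
        raise ValueError("frequency must be non-negative")
    y_mem = chain.membrane_admittance(f)
    if np.all(y_mem == 0):
        raise ValueError("singular system: all membrane admittances vanish")
    ab = _banded_system(chain, f)
    rhs = np.zeros(chain.n, dtype=complex)
    rhs[input_segment] = injected_current
    v = solve_banded((1, 1), ab, rhs)
    return FrequencyResponse(
        f=f,
        input_segment=input_segment,
        injected_current=injected_current,
        potential=v,
        membrane_current=y_mem * v,
    )


def extract_modalities(
    response: FrequencyResponse, chain: CompartmentChain
) -> Dict[str, complex]:
    """Soma potential (V), net soma membrane current (A) and dipole ``p_z``.

    The injected current counts as an inward transmembrane current at its
    segment, so the signed currents sum to zero, the dipole moment is
    translation invariant, and a somatic injection is part of the measured
    net soma current.
    """
    inj = np.zeros(chain.n, dtype=complex)
    inj[response.input_segment] = response.injected_current
    net = response.membrane_current - inj
    return {
        "soma_potential": complex(response.potential[0]),
        "soma_current": complex(net[0]),
        "dipole": complex(np.sum(net * chain.z)),
    }


def _green_rows(chain: CompartmentChain, f: float):
    """Transfer rows F_m[j] (modality value per unit input at segment j)."""
    ab = _banded_system(chain, f)
    eye = np.eye(chain.n, dtype=complex)
    G = solve_banded((1, 1), ab, eye)  # G[k, j]: potential at k per input at j
    y_mem = chain.membrane_admittance(f)
    y_s = y_mem[0]
    e0 = np.zeros(chain.n)
    e0[0] = 1.0
    rows = {
        "soma_potential": G[0],
        "soma_current": y_s * G[0] - e0,
        "dipole": (y_mem * chain.z) @ G - chain.z,
    }
    return rows


def ensemble_psd(
    chain: CompartmentChain,
    ensemble: InputEnsembleSpec,
    modality: str,
    f_grid: Sequence[float],
    mode: str = "uncorrelated",
) -> np.ndarray:
    """PSD of one modality for distributed input over the whole chain.

    Per-segment source counts are ``density * area``; uncorrelated inputs sum
    as ``sum_j n_j A_j |F_j|^2 s(f)`` and correlated inputs as
    ``|sum_j n_j A_j F_j|^2 s(f)``.
    """
    if mode not in ("uncorrelated", "correlated"):
        raise ValueError(f"unknown mode {mode!r}")
    density = np.where(chain.is_soma, ensemble.n_s, ensemble.n_d)
    weights = density * chain.area
    f_grid = np.asarray(f_grid, dtype=float)
    s = np.asarray(ensemble.input_psd_at(f_grid), dtype=float)
    out = np.empty(f_grid.size)
    for i, f in enumerate(f_grid):
        F = _green_rows(chain, float(f))[modality]
        if mode == "uncorrelated":
            out[i] = float(np.sum(weights * np.abs(F) ** 2))
        else:
            out[i] = float(np.abs(np.sum(weights * F)) ** 2)
    return out * s


# --------------------------------------------------------------------------
# plain-text chain import/export

_TABLE_COLUMNS = ["index", "z", "length", "diameter", "is_soma"]


def chain_to_table(chain: CompartmentChain, path: Union[str, Path]) -> None:
    """Write the chain geometry as a TSV segment table."""
    df = pd.DataFrame(
        {
            "index": np.arange(chain.n),
            "z": chain.z,
            "length": chain.length,
            "diameter": chain.diameter,
            "is_soma": chain.is_soma.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def chain_from_table(
    path: Union[str, Path], params: PhysicalParams
) -> CompartmentChain:
    """Read a TSV segment table; membrane/axial properties come from params.

    Soma segments get sphere-surface areas (``pi * diameter**2``), stick
    segments cylinder side areas; axial resistances follow the
    center-to-center convention with zero soma coupling resistance.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment table {path!s} lacks columns {missing}")
    df = df.sort_values("index").reset_index(drop=True)
    z = df["z"].to_numpy(dtype=float)
    length = df["length"].to_numpy(dtype=float)
    diameter = df["diameter"].to_numpy(dtype=float)
    is_soma = df["is_soma"].to_numpy().astype(bool)
    if not is_soma[0] or is_soma.sum() != 1:
        raise ValueError("segment table must have exactly one soma at index 0")
    area = np.where(
        is_soma, math.pi * diameter**2, math.pi * diameter * length
    )
    n = z.size
    axial = np.full(n, np.inf)
    for k in range(1, n):
        r_here = 4.0 * params.axial_resistivity / (math.pi * diameter[k] ** 2)
        if is_soma[k - 1]:
            axial[k] = r_here * length[k] / 2.0
        else:
            r_prev = 4.0 * params.axial_resistivity / (math.pi * diameter[k - 1] ** 2)
            axial[k] = r_here * length[k] / 2.0 + r_prev * length[k - 1] / 2.0
    return CompartmentChain(
        z=z,
        length=length,
        diameter=diameter,
        area=area,
        axial_resistance=axial,
        is_soma=is_soma,
        g_m=np.full(n, params.membrane_conductance),
        c_m=np.full(n, params.membrane_capacitance),
    )


# --------------------------------------------------------------------------
# time-domain mode (protocol-level reproduction)

def simulate_time_domain(
    chain: CompartmentChain,
    input_currents: Dict[int, np.ndarray],
    dt: float = 0.0625e-3,
    discard: float = 0.2,
) -> Dict[str, np.ndarray]:
    """Crank-Nicolson time stepping of the passive compartment chain.

    ``input_currents`` maps segment index to an injected current trace (A);
    all traces must share ``dt`` and length.  The first ``discard`` seconds
    are removed from the returned soma-potential, net-soma-current and
    dipole traces.  Provided for protocol-level reproduction (sum-of-
    sinusoids input, fixed time step, transient removal); the
    frequency-domain solve is the canonical oracle.
    """
    if not input_currents:
        raise ValueError("need at least one input trace")
    lengths = {len(tr) for tr in input_currents.values()}
    if len(lengths) != 1:
        raise ValueError("all input traces must have the same length")
    n_steps = lengths.pop()
    n = chain.n
    g_ax = np.zeros(n)
    g_ax[1:] = 1.0 / chain.axial_resistance[1:]
    cap = chain.area * chain.c_m
    # conductance matrix A (leak + axial), banded symmetric
    diag = chain.area * chain.g_m
    diag = diag.astype(float)
    diag[:-1] += g_ax[1:]
    diag[1:] += g_ax[1:]
    off = -g_ax[1:]
    # (C/dt + A/2) V_{n+1} = (C/dt - A/2) V_n + I_{n+1/2}
    lhs = np.zeros((2, n))
    lhs[0, 1:] = off / 2.0
    lhs[1] = cap / dt + diag / 2.0
    rhs_diag = cap / dt - diag / 2.0
    v = np.zeros(n)
    inj = np.zeros((n_steps, n))
    for seg, trace in input_currents.items():
        inj[:, seg] = trace
    v_soma = np.empty(n_steps)
    i_soma = np.empty(n_steps)
    dipole = np.empty(n_steps)
    y_leak = chain.area * chain.g_m
    for step in range(n_steps):
        rhs = rhs_diag * v
        rhs[:-1] -= off / 2.0 * v[1:]
        rhs[1:] -= off / 2.0 * v[:-1]
        rhs += inj[step]
        v_new = solveh_banded(lhs, rhs)
        dv = (v_new - v) / dt
        v = v_new
        mem = y_leak * v + cap * dv - inj[step]
        v_soma[step] = v[0]
        i_soma[step] = mem[0]
        dipole[step] = float(np.sum(mem * chain.z))
    start = int(round(discard / dt))
    return {
        "t": (np.arange(n_steps) + 1) * dt,
        "soma_potential": v_soma[start:],
        "soma_current": i_soma[start:],
        "dipole": dipole[start:],
    }
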