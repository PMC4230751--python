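"""Named scenario runners emitting CSV tables plus a reproducibility manifest.

Each scenario resolves the default fixture (optionally overridden), runs the
closed-form machinery and writes plain-text tables.  Tables are the
contract; rendering them is left to the user.  A ``manifest.json`` with the
resolved parameters, package version and seed accompanies every run, and a
rerun from the same manifest produces byte-identical CSVs.

Scenarios
---------
``psd_overview``
    PSDs of all three modalities for white/pink/brown uncorrelated input and
    correlated white input, plus slope estimates at 1 kHz.
``return_current_profiles``
    Membrane return-current envelopes for a single distal input at
    1/10/100/1000 Hz and the soma-current attenuation ratios.
``slope_maps``
    Local-slope maps mu(b, W) at electrotonic lengths 0.25, 1, 4 in long
    CSV format.
``parameter_sweeps``
    PSDs while varying stick length, membrane resistance, stick diameter
    and soma diameter around the defaults (uncorrelated and correlated).
``mixed_noise``
    The pink + synaptic soma-potential composition with variance targeting,
    crossover frequency and slope curve.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .distributed import (
    InputEnsembleSpec,
    compose_total_psd,
    default_frequency_grid,
    psd_transfer,
)
from .noise import InputPSDModel, mixed_noise_scenario
from .params import DEFAULT_PARAMS, PhysicalParams, derive_constants, dimensionless_map, load_params
from .single_input import membrane_current_profile, transfer_single
from .slopes import local_slope, slope_map

logger = logging.getLogger("cablepsd")

__all__ = ["ScenarioConfig", "default_fixture", "run_scenario", "SCENARIOS"]

_MODALITIES = ("soma_current", "dipole", "soma_potential")


def default_fixture():
    """The default parameter set and input ensemble.

    Ball-and-stick neuron with b = 0.2, L = 1, tau = 30 ms, lambda = 1 mm;
    white-noise current sources of PSD 1 fA^2/Hz at density 2 um^-2 on both
    soma and stick, uncorrelated.
    """
    ensemble = InputEnsembleSpec(
        n_d=2e12, n_s=2e12, coherence=0.0, input_psd=1e-30
    )
    return DEFAULT_PARAMS, ensemble


@dataclass
class ScenarioConfig:
    """A named scenario with overrides, output directory and seed."""

    name: str
    overrides: Dict = dataclass_field(default_factory=dict)
    outdir: Path = Path("scenario-out")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.name!r}; known: {sorted(SCENARIOS)}"
            )
        unknown = set(self.overrides) - {
            "params",
            "n_d",
            "n_s",
            "coherence",
            "input_psd",
            "f_min",
            "f_max",
            "per_decade",
        }
        if unknown:
            raise ValueError(f"unknown override keys {sorted(unknown)}")


def _resolve(config: ScenarioConfig):
    params, ensemble = default_fixture()
    ov = config.overrides
    if "params" in ov:
        params = ov["params"] if isinstance(ov["params"], PhysicalParams) else load_params(ov["params"])
    kwargs = {}
    for key in ("n_d", "n_s", "coherence", "input_psd"):
        if key in ov:
            kwargs[key] = ov[key]
    if kwargs:
        ensemble = InputEnsembleSpec(
            n_d=kwargs.get("n_d", ensemble.n_d),
            n_s=kwargs.get("n_s", ensemble.n_s),
            coherence=kwargs.get("coherence", ensemble.coherence),
            input_psd=kwargs.get("input_psd", ensemble.input_psd),
        )
    f = default_frequency_grid(
        ov.get("f_min", 0.1), ov.get("f_max", 1e4), ov.get("per_decade", 60)
    )
    return params, ensemble, f


def _manifest(config: ScenarioConfig, params: PhysicalParams, extra: Dict) -> Dict:
    c = derive_constants(params)
    point = dimensionless_map(params, 0.0)
    return {
        "scenario": config.name,
        "seed": config.seed,
        "version": __version__,
        "params": {
            "stick_diameter_m": params.stick_diameter,
            "soma_diameter_m": params.soma_diameter,
            "stick_length_m": params.stick_length,
            "membrane_resistance_ohm_m2": params.membrane_resistance,
            "membrane_capacitance_F_m2": params.membrane_capacitance,
            "axial_resistivity_ohm_m": params.axial_resistivity,
        },
        "dimensionless": {
            "b": point.b,
            "L": point.L,
            "tau_s": c.time_constant,
            "lambda_m": c.length_constant,
        },
        **extra,
    }


def _slope_at(f: np.ndarray, S: np.ndarray, f0: float) -> float:
    mu = local_slope(f, S).mu
    return float(np.interp(math.log(f0), np.log(f), mu))


def _scenario_psd_overview(config, outdir):
    params, ensemble, f = _resolve(config)
    rows = []
    slope_rows = []
    noise_kinds = ("white", "pink", "brown")
    for modality in _MODALITIES:
        tr = psd_transfer(params, f, modality, ensemble)
        for kind in noise_kinds:
            model = InputPSDModel(kind=kind, s0=1e-30, f_cut=min(f) / 2)
            ens = InputEnsembleSpec(
                n_d=ensemble.n_d, n_s=ensemble.n_s, coherence=0.0, input_psd=model
            )
            S = compose_total_psd(tr, ens)
            rows.append(
                pd.DataFrame(
                    {
                        "modality": modality,
                        "input_noise": kind,
                        "correlation": "uncorrelated",
                        "f_hz": f,
                        "psd": S,
                    }
                )
            )
            slope_rows.append(
                {
                    "modality": modality,
                    "input_noise": kind,
                    "correlation": "uncorrelated",
                    "mu_at_1khz": _slope_at(f, S, 1e3),
                }
            )
        # correlated white input drives only the soma potential for equal
        # densities (no net soma current / dipole moment)
        if modality == "soma_potential":
            ens = InputEnsembleSpec(
                n_d=ensemble.n_d, n_s=ensemble.n_s, coherence=1.0, input_psd=1e-30
            )
            S = compose_total_psd(tr, ens)
            rows.append(
                pd.DataFrame(
                    {
                        "modality": modality,
                        "input_noise": "white",
                        "correlation": "correlated",
                        "f_hz": f,
                        "psd": S,
                    }
                )
            )
            slope_rows.append(
                {
                    "modality": modality,
                    "input_noise": "white",
                    "correlation": "correlated",
                    "mu_at_1khz": _slope_at(f, S, 1e3),
                }
            )
    pd.concat(rows, ignore_index=True).to_csv(outdir / "psd.csv", index=False)
    pd.DataFrame(slope_rows).to_csv(outdir / "slopes_1khz.csv", index=False)
    return {"tables": ["psd.csv", "slopes_1khz.csv"]}


def _scenario_return_current_profiles(config, outdir):
    # single input at X' = 0.8 L: reproduces the soma-current attenuation
    # ratios ~1/7.3, 1/7.5, 1/22, 1/3100 at 1/10/100/1000 Hz
    params, _, _ = _resolve(config)
    freqs = (1.0, 10.0, 100.0, 1000.0)
    x_rel = 0.8
    X = np.linspace(0.0, 1.0, 201)
    rows = []
    ratios = []
    for f0 in freqs:
        point = dimensionless_map(params, f0)
        grid = X * point.L
        prof = membrane_current_profile(point, x_rel * point.L, grid)
        rows.append(
            pd.DataFrame(
                {
                    "f_hz": f0,
                    "X": grid,
                    "density_abs": np.abs(prof.stick_density),
                    "density_re": prof.stick_density.real,
                    "density_im": prof.stick_density.imag,
                }
            )
        )
        h = transfer_single(point, x_rel * point.L, "soma_current").value
        ratios.append(
            {
                "f_hz": f0,
                "soma_over_input": abs(h),
                "one_over_ratio": 1.0 / abs(h),
            }
        )
    pd.concat(rows, ignore_index=True).to_csv(outdir / "profiles.csv", index=False)
    pd.DataFrame(ratios).to_csv(outdir / "soma_ratios.csv", index=False)
    return {"tables": ["profiles.csv", "soma_ratios.csv"]}


_MAP_CASES = {
    "soma_current": ("corr", "unc_dend", "all"),
    "dipole": ("corr", "unc_dend", "all"),
    "soma_potential": ("corr_dend", "unc_soma", "unc_dend", "all", "corr"),
}


def _scenario_slope_maps(config, outdir):
    b_grid = np.logspace(-2, 1, 16)
    W_grid = np.logspace(-2, 8, 51)
    rows = []
    for L in (0.25, 1.0, 4.0):
        for modality, classes in _MAP_CASES.items():
            for cls in classes:
                mu = slope_map(L, b_grid, W_grid, modality, cls)
                bb, ww = np.meshgrid(b_grid, W_grid, indexing="ij")
                rows.append(
                    pd.DataFrame(
                        {
                            "L": L,
                            "modality": modality,
                            "input_class": cls,
                            "b": bb.ravel(),
                            "W": ww.ravel(),
                            "mu": mu.ravel(),
                        }
                    )
                )
        logger.info("slope maps done for L=%s", L)
    pd.concat(rows, ignore_index=True).to_csv(outdir / "slope_maps.csv", index=False)
    return {"tables": ["slope_maps.csv"]}


def _scenario_parameter_sweeps(config, outdir):
    params, ensemble, f = _resolve(config)
    sweeps = {
        "stick_length": ("stick_length", (0.25e-3, 1e-3, 4e-3)),
        "membrane_resistance": ("membrane_resistance", (0.75, 3.0, 12.0)),
        "stick_diameter": ("stick_diameter", (0.5e-6, 2e-6, 8e-6)),
        "soma_diameter": ("soma_diameter", (5e-6, 20e-6, 80e-6)),
    }
    rows = []
    slope_rows = []
    for corr_label, coherence in (("uncorrelated", 0.0), ("correlated", 1.0)):
        for sweep_name, (field_name, values) in sweeps.items():
            for value in values:
                p = params.with_(**{field_name: value})
                for modality in _MODALITIES:
                    ens = InputEnsembleSpec(
                        n_d=ensemble.n_d,
                        n_s=0.0 if coherence == 1.0 else ensemble.n_s,
                        coherence=coherence,
                        input_psd=1e-30,
                    )
                    tr = psd_transfer(p, f, modality, ens)
                    S = compose_total_psd(tr, ens)
                    rows.append(
                        pd.DataFrame(
                            {
                                "correlation": corr_label,
                                "sweep": sweep_name,
                                "value_si": value,
                                "modality": modality,
                                "f_hz": f,
                                "psd": S,
                            }
                        )
                    )
                    if np.all(S > 0):
                        slope_rows.append(
                            {
                                "correlation": corr_label,
                                "sweep": sweep_name,
                                "value_si": value,
                                "modality": modality,
                                "mu_at_1khz": _slope_at(f, S, 1e3),
                            }
                        )
    pd.concat(rows, ignore_index=True).to_csv(outdir / "sweeps.csv", index=False)
    pd.DataFrame(slope_rows).to_csv(outdir / "sweep_slopes_1khz.csv", index=False)
    return {"tables": ["sweeps.csv", "sweep_slopes_1khz.csv"]}


def _scenario_mixed_noise(config, outdir):
    result = mixed_noise_scenario()
    pd.DataFrame(
        {
            "f_hz": result.f,
            "psd_pink_V2_per_hz": result.psd_pink,
            "psd_synaptic_V2_per_hz": result.psd_synaptic,
            "psd_total_V2_per_hz": result.psd_total,
            "mu_total": result.slope.mu,
        }
    ).to_csv(outdir / "mixed_noise.csv", index=False)
    return {
        "tables": ["mixed_noise.csv"],
        "crossover_hz": result.crossover_hz,
        "sigma_pink_mV": result.sigma_pink * 1e3,
        "sigma_total_mV": result.sigma_total * 1e3,
    }


SCENARIOS = {
    "psd_overview": _scenario_psd_overview,
    "return_current_profiles": _scenario_return_current_profiles,
    "slope_maps": _scenario_slope_maps,
    "parameter_sweeps": _scenario_parameter_sweeps,
    "mixed_noise": _scenario_mixed_noise,
}


def run_scenario(config: ScenarioConfig) -> Dict:
    """Run one scenario; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir!s}: {exc}") from exc
    params, _, _ = _resolve(config)
    logger.info(
        "scenario %s -> %s (b=%.3g, L=%.3g)",
        config.name,
        outdir,
        dimensionless_map(params, 0.0).b,
        dimensionless_map(params, 0.0).L,
    )
    extra = SCENARIOS[config.name](config, outdir)
    manifest = _manifest(config, params, extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
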