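"""Seeded synthetic datasets for every assay layout the package analyzes.

Each generator draws from the forward model the corresponding analysis
assumes, with additive Gaussian noise on the instrument observable
(anisotropy, luminescence, fluorescence, peak-area ratio) — noise arises
at the detector, not on derived quantities. Output is a long-format CSV
(the consuming module's dialect) plus a truth record containing every
ground-truth parameter, so estimator recovery can be scored without any
external data. The same spec and seed produce byte-identical output.

Default designs mirror the published assay conditions: 10 nM probe with a
3-fold protein dilution series from 50 uM (saturation FP); 2-fold
inhibitor dilutions against 50 nM protein (covalent FP; the printed
300 uM protein / 100 mM inhibitor figures are internally inconsistent
unit typos, so consistent nanomolar/micromolar conditions are used and
recorded); a 16-point 40-72 degC CETSA grid; a 1 degC 25-95 degC DSF
ramp; GSH sampling over 2 h at 37 degC.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .binding import AnisotropyCalibration, anisotropy_from_fraction
from .equilibria import bound_probe_quadratic, competitive_equilibrium
from .fixtures import HEADLINE, published_values  # noqa: F401  (re-exported)

__all__ = ["GeneratorSpec", "default_spec", "generate", "published_values"]

AssayType = Literal["saturation_fp", "covalent_fp", "cetsa", "dsf",
                    "gsh_decay", "modification_ms"]

#: Demo-only default seed; every API call takes an explicit seed.
DEMO_SEED = 20231010


class GeneratorSpec(BaseModel):
    """Specification of one synthetic dataset.

    truth holds the mechanism/curve parameters of the forward model;
    design the concentration/time/temperature grids and replicate count;
    noise the additive Gaussian SD in observable units (an optional
    proportional term adds noise_proportional * |signal|).
    """

    assay_type: AssayType
    truth: dict
    design: dict
    noise: float = Field(ge=0.0)
    noise_proportional: float = Field(default=0.0, ge=0.0)
    seed: int

    @field_validator("design")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("design must not be empty")
        return v


_DEFAULTS = {
    "saturation_fp": dict(
        truth={"K_L": HEADLINE["probe_K_L"], "A_f": 20.0, "A_b": 120.0},
        design={"protein_top": 50e-6, "dilution": 3.0, "n_conc": 12,
                "probe": 10e-9, "replicates": 3},
        noise=0.5,
    ),
    "covalent_fp": dict(
        truth={"k_inact": HEADLINE["k_inact"], "K_I": HEADLINE["K_I"],
               "K_i": HEADLINE["Ki_t0"], "K_L": HEADLINE["probe_K_L"],
               "A_f": 20.0, "A_b": 120.0},
        design={"inhibitor_top": 50e-6, "dilution": 2.0, "n_conc": 10,
                "include_zero": True, "probe": 10e-9, "protein": 50e-9,
                "t_end": 3600.0, "n_times": 31, "replicates": 3},
        noise=0.3,
    ),
    "cetsa": dict(
        truth={"T_agg0": 50.0, "max_shift": 5.0, "EC50": HEADLINE["cetsa_ec50_8h"],
               "slope_factor": -1.6, "bottom_fraction": 0.08, "top_signal": 1e5},
        design={"T_min": 40.0, "T_max": 72.0, "n_temps": 16,
                "conc_top": 50e-6, "dilution": 3.0, "n_conc": 8,
                "include_zero": True, "replicates": 3},
        noise=1500.0,
    ),
    "dsf": dict(
        truth={"T_m_apo": 55.0, "shift": HEADLINE["dsf_shift_C"],
               "slope_factor": 1.2, "baseline": 200.0, "amplitude": 1000.0},
        design={"T_min": 25.0, "T_max": 95.0, "step": 1.0, "replicates": 2},
        noise=5.0,
    ),
    "gsh_decay": dict(
        truth={"C0": 1.0, "k_e": np.log(2.0) / 70.0},  # T_half 70 min
        design={"t_end_min": 120.0, "n_times": 13},
        noise=0.01,
    ),
    "modification_ms": dict(
        truth={"k": np.log(20.0) / 7200.0},  # 95% occupancy at 2 h
        design={"t_end": 7200.0, "n_times": 13},
        noise=0.02,
    ),
}


def default_spec(assay_type: AssayType, seed: int, noise: float | None = None,
                 **overrides) -> GeneratorSpec:
    """Build a GeneratorSpec with the study-condition defaults.

    ``overrides`` update truth/design keys (pass nested dicts ``truth=`` /
    ``design=`` to replace individual entries).
    """
    base = _DEFAULTS[assay_type]
    truth = {**base["truth"], **overrides.pop("truth", {})}
    design = {**base["design"], **overrides.pop("design", {})}
    if overrides:
        raise TypeError(f"unknown overrides: {sorted(overrides)}")
    return GeneratorSpec(
        assay_type=assay_type, truth=truth, design=design,
        noise=base["noise"] if noise is None else noise, seed=seed,
    )


def _dilution_series(top: float, factor: float, n: int) -> np.ndarray:
    return top / factor ** np.arange(n)


def generate(spec: GeneratorSpec):
    """Generate one dataset.

    Returns
    -------
    (df, truth) : pandas.DataFrame in the consuming module's CSV dialect,
    and a truth dict echoing the spec plus derived ground-truth values.
    Deterministic: same spec + seed gives identical output.
    """
    rng = np.random.default_rng(spec.seed)
    fn = {
        "saturation_fp": _gen_saturation_fp,
        "covalent_fp": _gen_covalent_fp,
        "cetsa": _gen_cetsa,
        "dsf": _gen_dsf,
        "gsh_decay": _gen_gsh_decay,
        "modification_ms": _gen_modification_ms,
    }[spec.assay_type]
    df, truth = fn(spec, rng)
    truth = {**truth, "assay_type": spec.assay_type, "seed": spec.seed,
             "noise": spec.noise, "noise_proportional": spec.noise_proportional}
    return df, truth


def _noisy(rng, spec, signal):
    sd = spec.noise + spec.noise_proportional * np.abs(signal)
    if spec.noise == 0 and spec.noise_proportional == 0:
        return np.asarray(signal, dtype=float)
    return signal + rng.normal(0.0, sd, size=np.shape(signal))


def _gen_saturation_fp(spec, rng):
    t, d = spec.truth, spec.design
    n = int(d["n_conc"])
    if n < 6:
        raise ValueError("saturation_fp needs >= 6 concentrations (fit precondition)")
    P = _dilution_series(d["protein_top"], d["dilution"], n)
    calib = AnisotropyCalibration(t["A_f"], t["A_b"])
    rows = []
    for rep in range(1, int(d["replicates"]) + 1):
        x = bound_probe_quadratic(P, d["probe"], t["K_L"])
        A = _noisy(rng, spec, anisotropy_from_fraction(x, calib))
        for c, a in zip(P, A):
            rows.append(("probe_titration", c * 1e9, "nM", a, "anisotropy", rep))
    df = pd.DataFrame(rows, columns=["series_id", "concentration",
                                     "concentration_unit", "response",
                                     "response_type", "replicate"])
    return df, {**t, "probe": d["probe"]}


def _gen_covalent_fp(spec, rng):
    t, d = spec.truth, spec.design
    n = int(d["n_conc"])
    if n < 5:
        raise ValueError("covalent_fp needs >= 5 inhibitor concentrations")
    conc = list(_dilution_series(d["inhibitor_top"], d["dilution"], n))
    if d.get("include_zero", True):
        conc.append(0.0)
    times = np.linspace(0.0, d["t_end"], int(d["n_times"]))
    if times.size < 4:
        raise ValueError("covalent_fp needs >= 4 time points")
    calib = AnisotropyCalibration(t["A_f"], t["A_b"])
    E, L = d["protein"], d["probe"]
    rows = []
    for I in conc:
        eq = competitive_equilibrium(E, L, I, t["K_L"], t["K_i"])
        F_b0 = eq["EL"] / L
        k_obs = t["k_inact"] * I / (t["K_I"] + I)
        F_b = F_b0 * np.exp(-k_obs * times)
        for rep in range(1, int(d["replicates"]) + 1):
            A = _noisy(rng, spec, anisotropy_from_fraction(F_b, calib))
            for tt, a in zip(times, A):
                rows.append(("covalent_fp", I * 1e6, "uM", tt, a, rep))
    df = pd.DataFrame(rows, columns=["series_id", "inhibitor_conc", "conc_unit",
                                     "time_s", "response", "replicate"])
    truth = {**t, "efficiency": t["k_inact"] / t["K_I"],
             "probe": L, "protein": E}
    return df, truth


def _boltz(T, top, bottom, T_mid, s):
    return bottom + (top - bottom) / (1.0 + np.exp((T_mid - T) / s))


def _gen_cetsa(spec, rng):
    t, d = spec.truth, spec.design
    temps = np.linspace(d["T_min"], d["T_max"], int(d["n_temps"]))
    if temps.size < 8:
        raise ValueError("cetsa needs >= 8 temperature points")
    conc = list(_dilution_series(d["conc_top"], d["dilution"], int(d["n_conc"])))
    if d.get("include_zero", True):
        conc.append(0.0)
    if len([c for c in conc if c > 0]) < 5:
        raise ValueError("cetsa dose-response needs >= 5 concentrations")
    top, bot = t["top_signal"], t["top_signal"] * t["bottom_fraction"]
    rows = []
    tagg_by_conc = {}
    for c in sorted(conc):
        T_agg = t["T_agg0"] + t["max_shift"] * c / (c + t["EC50"]) if c > 0 else t["T_agg0"]
        tagg_by_conc[c] = T_agg
        for rep in range(1, int(d["replicates"]) + 1):
            S = _noisy(rng, spec, _boltz(temps, top, bot, T_agg, t["slope_factor"]))
            for T, s_ in zip(temps, np.maximum(S, 0.0)):
                rows.append(("cetsa", "MN551" if c > 0 else "DMSO",
                             c * 1e6, "uM", T, s_, rep))
    df = pd.DataFrame(rows, columns=["series_id", "compound", "conc",
                                     "conc_unit", "temperature_C", "signal",
                                     "replicate"])
    return df, {**t, "T_agg_by_conc": {f"{c:.6g}": v for c, v in tagg_by_conc.items()}}


def _gen_dsf(spec, rng):
    t, d = spec.truth, spec.design
    temps = np.arange(d["T_min"], d["T_max"] + d["step"] / 2, d["step"])
    if temps.size < 8:
        raise ValueError("dsf needs >= 8 temperature points")
    rows = []
    for label, T_m in (("apo", t["T_m_apo"]),
                       ("holo", t["T_m_apo"] + t["shift"])):
        for rep in range(1, int(d["replicates"]) + 1):
            S = _noisy(rng, spec, _boltz(temps, t["baseline"] + t["amplitude"],
                                         t["baseline"], T_m, t["slope_factor"]))
            for T, s_ in zip(temps, S):
                rows.append(("dsf", label, 0.0 if label == "apo" else 50.0,
                             "uM", T, s_, rep))
    df = pd.DataFrame(rows, columns=["series_id", "compound", "conc",
                                     "conc_unit", "temperature_C", "signal",
                                     "replicate"])
    return df, {**t, "T_m_holo": t["T_m_apo"] + t["shift"]}


def _gen_gsh_decay(spec, rng):
    t, d = spec.truth, spec.design
    times = np.linspace(0.0, d["t_end_min"], int(d["n_times"]))
    if times.size < 4:
        raise ValueError("gsh_decay needs >= 4 time points")
    y = _noisy(rng, spec, t["C0"] * np.exp(-t["k_e"] * times))
    df = pd.DataFrame({"time_min": times, "response": y})
    return df, {**t, "T_half_min": float(np.log(2.0) / t["k_e"])}


def _gen_modification_ms(spec, rng):
    t, d = spec.truth, spec.design
    times = np.linspace(0.0, d["t_end"], int(d["n_times"]))
    if times.size < 4:
        raise ValueError("modification_ms needs >= 4 time points")
    f = np.clip(_noisy(rng, spec, 1.0 - np.exp(-t["k"] * times)), 0.0, 1.0)
    df = pd.DataFrame({"series_id": "modification", "inhibitor_conc": 40.0,
                       "conc_unit": "uM", "time_s": times, "response": f,
                       "replicate": 1})
    return df, {**t, "t95": float(np.log(20.0) / t["k"])}
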