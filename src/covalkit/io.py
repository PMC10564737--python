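"""CSV dialects for plate-reader-style tabular inputs.

Long-format CSVs with explicit unit columns; concentrations are converted
to molar on read. Dialects:

* dose series:   ``series_id, concentration, concentration_unit, response,
  response_type, replicate``
* time courses:  ``series_id, inhibitor_conc, conc_unit, time_s, response,
  replicate``
* melt curves:   ``series_id, compound, conc, conc_unit, temperature_C,
  signal, replicate``
* decay series:  ``time_min, response``
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import DoseSeries
from .covalent import TimeSeries
from .thermal import MeltCurve
from .units import to_molar

DOSE_COLUMNS = ["series_id", "concentration", "concentration_unit",
                "response", "response_type", "replicate"]
TIMECOURSE_COLUMNS = ["series_id", "inhibitor_conc", "conc_unit",
                      "time_s", "response", "replicate"]
MELT_COLUMNS = ["series_id", "compound", "conc", "conc_unit",
                "temperature_C", "signal", "replicate"]
DECAY_COLUMNS = ["time_min", "response"]


def _require(df: pd.DataFrame, columns, path):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_dose_csv(path, fixed_components=None) -> list[DoseSeries]:
    """Read a dose-series CSV into one DoseSeries per (series_id, replicate).

    Duplicate concentrations within a replicate are averaged before
    construction (tie handling for technical repeats reported long-form).
    """
    df = pd.read_csv(path)
    _require(df, DOSE_COLUMNS, path)
    out = []
    for (sid, rep), grp in df.groupby(["series_id", "replicate"], sort=True):
        conc = np.array([to_molar(v, u) for v, u in
                         zip(grp["concentration"], grp["concentration_unit"])])
        # round to 9 significant digits so unit round-trips (1000 nM vs
        # 1 uM) land on the same tie before averaging
        conc = np.array([float(f"{c:.9e}") for c in conc])
        resp = grp["response"].to_numpy(dtype=float)
        agg = pd.DataFrame({"c": conc, "y": resp}).groupby("c", sort=True).mean()
        out.append(DoseSeries(
            concentrations=agg.index.to_numpy(),
            responses=agg["y"].to_numpy(),
            fixed_components=dict(fixed_components or {}),
            replicate_id=str(rep),
            response_type=str(grp["response_type"].iloc[0]),
        ))
    return out


def read_timecourse_csv(path) -> list[TimeSeries]:
    """Read time courses into one TimeSeries per (inhibitor conc, replicate)."""
    df = pd.read_csv(path)
    _require(df, TIMECOURSE_COLUMNS, path)
    out = []
    keys = ["series_id", "inhibitor_conc", "conc_unit", "replicate"]
    for (sid, conc, unit, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_s")
        out.append(TimeSeries(
            times=grp["time_s"].to_numpy(dtype=float),
            values=grp["response"].to_numpy(dtype=float),
            inhibitor_concentration=to_molar(float(conc), unit),
            replicate_id=str(rep),
        ))
    return out


def average_replicates(series: list[TimeSeries]) -> list[TimeSeries]:
    """Average technical replicates per time point within each condition."""
    byconc: dict = {}
    for ts in series:
        byconc.setdefault(ts.inhibitor_concentration, []).append(ts)
    out = []
    for conc in sorted(byconc):
        group = byconc[conc]
        t0 = group[0].times
        for ts in group[1:]:
            if not np.allclose(ts.times, t0):
                raise ValueError("replicates must share a common time grid")
        mean = np.mean([ts.values for ts in group], axis=0)
        out.append(TimeSeries(times=t0, values=mean,
                              inhibitor_concentration=conc, replicate_id="mean"))
    return out


def read_melt_csv(path) -> list[MeltCurve]:
    """Read melt curves into one MeltCurve per (series, compound, conc, rep)."""
    df = pd.read_csv(path)
    _require(df, MELT_COLUMNS, path)
    out = []
    keys = ["series_id", "compound", "conc", "conc_unit", "replicate"]
    for (sid, cmpd, conc, unit, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("temperature_C")
        conc_molar = to_molar(float(conc), unit) if float(conc) > 0 else 0.0
        out.append(MeltCurve(
            temperatures=grp["temperature_C"].to_numpy(dtype=float),
            signals=grp["signal"].to_numpy(dtype=float),
            condition={"compound": str(cmpd), "concentration": conc_molar},
            replicate_id=str(rep),
        ))
    return out


def read_decay_csv(path):
    """Read a GSH-decay CSV; returns (times_min, responses) arrays."""
    df = pd.read_csv(path)
    _require(df, DECAY_COLUMNS, path)
    df = df.sort_values("time_min")
    return df["time_min"].to_numpy(dtype=float), df["response"].to_numpy(dtype=float)
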