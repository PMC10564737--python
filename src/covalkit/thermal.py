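"""Thermal-shift analysis: DSF melting temperatures and CETSA aggregation.

Differential scanning fluorimetry (DSF) reports protein unfolding as a
rise in dye fluorescence on a 1 degC temperature ramp; the melting
temperature T_m is taken at the steepest rise, i.e. the extremum of the
first derivative after mild smoothing.

The cellular thermal shift assay (CETSA, split-NanoLuc readout) reports
the soluble reporter-tagged protein as luminescence after heating; signals
are normalized to the lowest temperature (percent stabilized) and fitted
with a Boltzmann sigmoid to obtain the aggregation temperature T_agg.
Ligand-induced stabilization shows as a positive shift dT_agg, and the
shift versus compound concentration yields a cellular EC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .binding import FitError

__all__ = [
    "MeltCurve",
    "TaggResult",
    "percent_stabilized",
    "fit_tagg_boltzmann",
    "dsf_tm",
    "fit_tagg_shift_ec50",
]


@dataclass
class MeltCurve:
    """Signal versus temperature for one well/condition."""

    temperatures: np.ndarray  # degC, strictly increasing
    signals: np.ndarray       # fluorescence or luminescence, >= 0
    condition: dict = field(default_factory=dict)
    replicate_id: str = "1"

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.temperatures.size < 8:
            raise ValueError("a melt curve needs at least 8 temperature points")
        if self.temperatures.shape != self.signals.shape:
            raise ValueError("temperatures and signals must have equal length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(~np.isfinite(self.signals)):
            raise ValueError("signals contain missing values")


@dataclass
class TaggResult:
    """Midpoint-temperature result (Boltzmann T_agg or derivative T_m)."""

    T: float  # degC
    method: str  # "boltzmann" | "derivative"
    top: float | None = None
    bottom: float | None = None
    slope_factor: float | None = None
    standard_errors: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


def percent_stabilized(curve: MeltCurve, reference_T: float | None = None) -> MeltCurve:
    """Normalize a CETSA curve to percent of the reference-temperature signal.

    The reference defaults to the lowest measured temperature (with a
    warning if that is not the nominal 40 degC start of the assay grid).
    Idempotent and invariant to uniform scaling of the raw signals.
    """
    T, S = curve.temperatures, curve.signals
    if reference_T is None:
        reference_T = float(T[0])
        if abs(reference_T - 40.0) > 1e-9:
            warnings.warn(
                f"normalizing to lowest measured temperature {reference_T} degC "
                "(not 40 degC)", stacklevel=2,
            )
    idx = np.nonzero(np.isclose(T, reference_T))[0]
    if idx.size == 0:
        raise ValueError(f"reference temperature {reference_T} not on the grid")
    ref = S[idx[0]]
    if ref == 0:
        raise ValueError("zero signal at the reference temperature")
    return MeltCurve(
        temperatures=T.copy(), signals=100.0 * S / ref,
        condition=dict(curve.condition), replicate_id=curve.replicate_id,
    )


def _boltzmann(T, top, bottom, T_mid, s):
    return bottom + (top - bottom) / (1.0 + np.exp((T_mid - T) / s))


def fit_tagg_boltzmann(curve: MeltCurve) -> TaggResult:
    """Boltzmann sigmoid fit of a (normalized) melt curve.

    f(T) = bottom + (top - bottom)/(1 + exp((T_agg - T)/s)); the sign of
    the slope factor s is auto-detected from the curve direction (CETSA
    luminescence decays with temperature, s < 0; a rising curve gets
    s > 0) and recorded in the result.
    """
    T, S = curve.temperatures, curve.signals
    if np.ptp(S) == 0:
        raise FitError("no transition: constant signal")
    decreasing = S[-1] < S[0]
    # initialize T_mid from the half-maximum crossing
    half = (S.max() + S.min()) / 2.0
    cross = np.nonzero(np.diff(np.sign(S - half)))[0]
    T_mid0 = float(T[cross[0]]) if cross.size else float(np.median(T))
    span = float(T[-1] - T[0])
    s0 = -span / 10 if decreasing else span / 10
    p0 = [S[0], S[-1], T_mid0, s0]
    try:
        popt, pcov = curve_fit(_boltzmann, T, S, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    top, bottom, T_mid, s = popt
    resid = S - _boltzmann(T, *popt)
    if np.sqrt(np.mean(resid**2)) > 0.3 * np.ptp(S):
        raise FitError("no clear sigmoid transition",
                       residuals=resid)
    se = np.sqrt(np.diag(pcov))
    flags = {"direction": "decreasing" if decreasing else "increasing"}
    if not (T[0] <= T_mid <= T[-1]):
        flags["extrapolated"] = True
    return TaggResult(
        T=float(T_mid), method="boltzmann", top=float(top), bottom=float(bottom),
        slope_factor=float(s),
        standard_errors=dict(zip(["top", "bottom", "T", "slope_factor"], se)),
        flags=flags,
    )


def dsf_tm(curve: MeltCurve, window: int = 5, polyorder: int = 2) -> TaggResult:
    """DSF melting temperature from the first-derivative extremum.

    The raw fluorescence is smoothed with a Savitzky-Golay filter
    (default 5-point window, order 2), differentiated on the grid, and
    T_m is located at the steepest rise (the minimum of d(-F)/dT) with
    quadratic interpolation around the grid extremum. A transition at the
    grid boundary is flagged unreliable.
    """
    T, S = curve.temperatures, curve.signals
    if window >= T.size:
        raise ValueError("smoothing window must be shorter than the curve")
    smooth = savgol_filter(S, window_length=window, polyorder=polyorder)
    dS = np.gradient(smooth, T)
    i = int(np.argmax(dS))  # steepest increase == minimum of d(-F)/dT
    flags = {}
    # a meaningful melt needs a derivative peak standing out from the
    # baseline slope; a monotone-linear signal has none
    typical = np.ptp(smooth) / np.ptp(T)
    if i == 0 or i == T.size - 1 or \
            dS[i] - np.median(dS) < 0.05 * typical:
        flags["boundary"] = True
        return TaggResult(T=float(T[i]), method="derivative", flags=flags)
    # quadratic interpolation through the three points around the extremum
    y0, y1, y2 = dS[i - 1], dS[i], dS[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        T_m = float(T[i])
    else:
        # offset in grid units for a locally uniform grid
        delta = 0.5 * (y0 - y2) / denom
        step = (T[i + 1] - T[i - 1]) / 2.0
        T_m = float(T[i] + np.clip(delta, -1, 1) * step)
    return TaggResult(T=T_m, method="derivative", flags=flags)


def fit_tagg_shift_ec50(shifts, hill_free: bool = False):
    """EC50 of the aggregation-temperature shift dose-response.

    Parameters
    ----------
    shifts : sequence of (concentration_molar, dTagg_degC) pairs
    hill_free : fit the Hill slope instead of fixing it at 1

    Model: dT(c) = dT_max * c^h / (c^h + EC50^h) (log-logistic through
    zero shift at c = 0; h = 1 by default).

    Returns
    -------
    dict with EC50 (molar), max_shift (degC), hill, standard_errors
    """
    pairs = np.asarray(list(shifts), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 5:
        raise FitError("need at least 5 (concentration, shift) pairs")
    c, dT = pairs[:, 0], pairs[:, 1]
    if np.ptp(dT) == 0:
        raise FitError("no shift signal: constant dT_agg")
    pos = c[c > 0]
    s_c = float(np.exp(np.mean(np.log(pos))))  # rescale molar concs to O(1)
    cn = c / s_c

    if hill_free:
        def model(c, dTmax, ec50, h):
            return dTmax * np.power(c, h) / (np.power(c, h) + ec50**h)
        p0 = [dT.max(), float(np.median(pos)) / s_c, 1.0]
        bounds = ([0, pos.min() / s_c / 1e4, 0.1],
                  [np.inf, pos.max() / s_c * 1e4, 10])
        names = ["max_shift", "EC50", "hill"]
    else:
        def model(c, dTmax, ec50):
            return dTmax * c / (c + ec50)
        p0 = [dT.max(), float(np.median(pos)) / s_c]
        bounds = ([0, pos.min() / s_c / 1e4], [np.inf, pos.max() / s_c * 1e4])
        names = ["max_shift", "EC50"]
    try:
        popt, pcov = curve_fit(model, cn, dT, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"EC50 fit did not converge: {exc}") from exc
    popt[1] *= s_c
    pcov[1, :] *= s_c
    pcov[:, 1] *= s_c
    se = np.sqrt(np.diag(pcov))
    out = dict(zip(names, map(float, popt)))
    out.setdefault("hill", 1.0)
    out["standard_errors"] = dict(zip(names, map(float, se)))
    if c.max() < 2 * out["EC50"]:
        warnings.warn("dose range does not saturate the shift: EC50 poorly "
                      "constrained", stacklevel=2)
    return out
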