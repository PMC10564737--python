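"""Covalent inhibition kinetics from FP probe-displacement time courses.

A covalent inhibitor first binds reversibly (E + I <-> EI, dissociation
constant K_i) and then reacts irreversibly (EI -> E-I at rate k_inact). In
a competition FP assay the protein-bound probe fraction F_b decays over
time as protein is irreversibly consumed; the apparent first-order rate

    k_obs = k_inact * [I] / (K_I + [I])

saturates at k_inact, with K_I the inhibitor concentration giving
half-maximal k_obs. The overall potency metric is the covalent efficiency
k_inact/K_I (M^-1 s^-1), which at [I] << K_I is simply the slope of k_obs
versus [I].

The module provides:

* a mass-action ODE realization of the full mechanism (probe + inhibitor
  competing for protein, covalent sink) for simulation and oracle checks;
* the published analysis chain: early-window linearization of F_b(t) to
  (F_b0, k_obs), the saturation fit for (k_inact, K_I), the low-
  concentration linear fit for k_inact/K_I, and K_i at t = 0 from the
  F_b0 dose-response;
* a pseudo-first-order fit for time-dependent covalent modification
  measured by intact MS (fraction modified -> rate and time to 95%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, curve_fit

from .binding import (
    AnisotropyCalibration,
    CompetitionFit,
    DoseSeries,
    FitError,
    bound_fraction,
    fit_ic50,
    ic50_to_Ki,
)
from .equilibria import competitive_equilibrium

__all__ = [
    "MechanismParams",
    "TimeSeries",
    "LinearizationResult",
    "CovalentFitResult",
    "simulate_mechanism",
    "linearize_timecourse",
    "fit_kinact_KI",
    "fit_efficiency_linear",
    "ki_at_t0",
    "fit_modification_timecourse",
]

#: Linearization keeps points that have decayed by at most this fraction
#: of the initial bound fraction (<= 30% decay). The raw -slope/intercept
#: estimate of a first-order rate is biased low by roughly half the
#: fractional decay spanned; the default curvature correction removes
#: that bias exactly for first-order decay, so the deeper window can be
#: used for its better noise averaging.
LINEAR_WINDOW_FRACTION = 0.7


@dataclass(frozen=True)
class MechanismParams:
    """Mass-action rate constants and totals for the competition mechanism.

    Probe: E + P <-> EP with kon_P (M^-1 s^-1) / koff_P (s^-1),
    K_L = koff_P/kon_P. Inhibitor: E + I <-> EI with kon_I/koff_I,
    K_i = koff_I/kon_I, followed by EI -> E-I at k_inact (s^-1).
    E_total, P_total, I_total are molar totals.
    """

    kon_P: float
    koff_P: float
    kon_I: float
    koff_I: float
    k_inact: float
    E_total: float
    P_total: float
    I_total: float

    def __post_init__(self):
        for name in ("kon_P", "koff_P", "kon_I", "koff_I", "k_inact",
                     "E_total", "P_total", "I_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def K_L(self) -> float:
        return self.koff_P / self.kon_P

    @property
    def K_i(self) -> float:
        return self.koff_I / self.kon_I

    @property
    def K_I_intrinsic(self) -> float:
        """(koff_I + k_inact)/kon_I: the kinetic half-saturation constant."""
        return (self.koff_I + self.k_inact) / self.kon_I


@dataclass
class TimeSeries:
    """Response versus time at fixed composition (one inhibitor conc)."""

    times: np.ndarray
    values: np.ndarray
    inhibitor_concentration: float = 0.0
    replicate_id: str = "1"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size < 4:
            raise ValueError("a time course needs at least 4 points")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class LinearizationResult:
    """Early-window linear fit of a bound-fraction time course.

    k_obs = -slope/F_b0 (>= 0 for probe displacement); window gives the
    indices of the points used.
    """

    F_b0: float
    slope: float
    k_obs: float
    window: tuple
    standard_errors: dict
    flags: dict = field(default_factory=dict)


@dataclass
class CovalentFitResult:
    """Full covalent-inference output."""

    k_inact: float | None
    K_I: float | None
    efficiency: float
    Ki_t0: float | None
    per_concentration: list
    regime: str  # "saturation" | "linear"
    standard_errors: dict
    metadata: dict = field(default_factory=dict)


def simulate_mechanism(params: MechanismParams, times, rtol: float = 1e-8,
                       pre_equilibrate: bool = False):
    """Integrate the mass-action competition mechanism.

    State variables are [EP], [EI] and the covalent adduct [E-I]; free
    species follow from conservation. Returns a dict of trajectories
    (``E, P, EP, I, EI, EIx`` molar) plus the observable bound probe
    fraction ``F_b = EP/P_total``.

    With ``pre_equilibrate`` the integration starts from the reversible
    (k_inact = 0) equilibrium instead of all-free species, emulating a
    time course whose t = 0 follows fast mixing and equilibration.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    p = params
    if p.P_total <= 0:
        raise ValueError("P_total must be > 0 for an observable bound fraction")

    def rhs(_, y):
        EP, EI, C = y
        E = p.E_total - EP - EI - C
        P = p.P_total - EP
        I = p.I_total - EI - C
        return [
            p.kon_P * E * P - p.koff_P * EP,
            p.kon_I * E * I - (p.koff_I + p.k_inact) * EI,
            p.k_inact * EI,
        ]

    y0 = [0.0, 0.0, 0.0]
    if pre_equilibrate and p.kon_P > 0 and p.koff_P > 0:
        if p.kon_I > 0 and p.koff_I > 0 and p.I_total > 0:
            eq = competitive_equilibrium(p.E_total, p.P_total, p.I_total,
                                         p.K_L, p.K_i)
        else:
            eq = competitive_equilibrium(p.E_total, p.P_total, 0.0, p.K_L, 1.0)
        y0 = [eq["EL"], eq["EI"], 0.0]

    t_span = (min(0.0, t[0]), t[-1])
    sol = solve_ivp(rhs, t_span, y0, t_eval=t, method="LSODA",
                    rtol=rtol, atol=rtol * max(p.E_total, p.P_total, 1e-12))
    if not sol.success:
        raise RuntimeError(f"mechanism integration failed: {sol.message}")
    EP, EI, C = sol.y
    out = {
        "t": t,
        "EP": EP,
        "EI": EI,
        "EIx": C,  # covalent adduct E-I
        "E": p.E_total - EP - EI - C,
        "P": p.P_total - EP,
        "I": p.I_total - EI - C,
    }
    out["F_b"] = EP / p.P_total
    return out


def _ols_line(tw, yw):
    X = np.column_stack([np.ones_like(tw), tw])
    coef, rss, *_ = np.linalg.lstsq(X, yw, rcond=None)
    return X, float(coef[0]), float(coef[1]), rss


def linearize_timecourse(ts: TimeSeries, calib: AnisotropyCalibration | None = None,
                         window_fraction: float = LINEAR_WINDOW_FRACTION,
                         method: str = "linear",
                         curvature_correction: bool = True):
    """Extract (F_b0, k_obs) from an early, approximately linear window.

    If a calibration is given the values are anisotropies and are first
    converted to bound fraction; otherwise they are taken as F_b already.
    The window keeps points with F_b >= window_fraction * F_b0 (initial
    estimate = first point), at least 4 points. Ordinary least squares
    gives intercept F_b0 and slope; k_obs = -slope/F_b0. A positive slope
    beyond noise maps to k_obs = 0 with a flag.

    The raw initial-rate ratio underestimates a first-order rate by about
    half the fractional decay the window spans. With
    ``curvature_correction`` (default) the rate k is taken as the root of
    ``-slope/intercept of an OLS line through exp(-k t) on the same grid
    == measured ratio``, which is exact for first-order decay; the raw
    ratio is kept in ``flags['k_obs_raw']``.

    ``method="log"`` fits the same window on ln(F_b) instead (also exact
    for exponential decay but undefined once noise drives F_b <= 0).
    """
    t = ts.times
    if calib is not None:
        y, _, _ = bound_fraction(ts.values, calib)
    else:
        y = np.asarray(ts.values, dtype=float)
    if method not in ("linear", "log"):
        raise ValueError("method must be 'linear' or 'log'")

    f0_est = y[0]
    keep = y >= window_fraction * f0_est
    # window must be contiguous from the start and contain >= 4 points
    n_keep = int(np.argmin(keep)) if not keep.all() else y.size
    n_keep = max(n_keep, 4)
    if n_keep > y.size:
        raise FitError("fewer than 4 usable points in the linear window")
    tw, yw = t[:n_keep], y[:n_keep]

    if method == "log":
        if np.any(yw <= 0):
            raise FitError("log-linearization needs strictly positive F_b")
        X = np.column_stack([np.ones_like(tw), tw])
        coef, rss, *_ = np.linalg.lstsq(X, np.log(yw), rcond=None)
        lnF0, negk = float(coef[0]), float(coef[1])
        F_b0 = float(np.exp(lnF0))
        k_obs = max(-negk, 0.0)
        dof = max(n_keep - 2, 1)
        s2 = float(rss[0]) / dof if rss.size else 0.0
        cov = s2 * np.linalg.inv(X.T @ X)
        se_int, se_slope = np.sqrt(np.diag(cov))
        flags = {"window_fraction": window_fraction, "method": "log"}
        if negk > 0:
            flags["wrong_sign_slope"] = True
        return LinearizationResult(
            F_b0=F_b0, slope=negk * F_b0, k_obs=k_obs, window=(0, n_keep),
            standard_errors={"F_b0": float(F_b0 * se_int),
                             "slope": float(se_slope * F_b0),
                             "k_obs": float(se_slope)},
            flags=flags,
        )

    X, F_b0, slope, rss = _ols_line(tw, yw)
    dof = max(n_keep - 2, 1)
    s2 = float(rss[0]) / dof if rss.size else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    se_int, se_slope = np.sqrt(np.diag(cov))

    flags = {"window_fraction": window_fraction,
             "residual_sd": float(np.sqrt(s2))}
    if F_b0 <= 0 or F_b0 > 1:
        F_b0 = float(np.clip(F_b0, 1e-12, 1.0))
        flags["intercept_clamped"] = True
    if slope > 0:
        if se_slope > 0 and slope > 2 * se_slope:
            warnings.warn("positive slope beyond noise: no displacement; k_obs = 0",
                          stacklevel=2)
        k_obs = 0.0
        flags["wrong_sign_slope"] = True
    else:
        k_obs = -slope / F_b0
        if k_obs < 1e-15:  # numerical zero from a flat series
            k_obs = 0.0
        flags["k_obs_raw"] = float(k_obs)
        if curvature_correction and k_obs > 0:
            ratio = k_obs

            def mismatch(k):
                _, a1, b1, _ = _ols_line(tw, np.exp(-k * tw))
                return -b1 / a1 - ratio

            try:
                k_obs = brentq(mismatch, ratio * 0.2, ratio * 5.0)
            except ValueError:
                flags["curvature_correction_failed"] = True
            else:
                _, a1, _, _ = _ols_line(tw, np.exp(-k_obs * tw))
                F_b0 = float(np.clip(F_b0 / a1, 1e-12, 1.0))
                flags["curvature_corrected"] = True
    # slope noise dominates; intercept noise enters in proportion to k_obs
    se_k = np.hypot(se_slope / F_b0, k_obs * se_int / F_b0)
    return LinearizationResult(
        F_b0=F_b0, slope=slope, k_obs=float(k_obs), window=(0, n_keep),
        standard_errors={"F_b0": float(se_int), "slope": float(se_slope),
                         "k_obs": float(se_k)},
        flags=flags,
    )


def _kobs_model(I, k_inact, K_I):
    return k_inact * I / (K_I + I)


def fit_kinact_KI(kobs_by_conc, sigma=None) -> CovalentFitResult:
    """Fit k_obs([I]) saturation to obtain k_inact, K_I and k_inact/K_I.

    Parameters
    ----------
    kobs_by_conc : sequence of (I_molar, k_obs_per_s) pairs
    sigma : optional per-point k_obs standard errors for a weighted fit

    The efficiency standard error is propagated from the (k_inact, K_I)
    covariance by the delta method.
    """
    pairs = np.asarray(list(kobs_by_conc), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 5:
        raise FitError("need at least 5 (concentration, k_obs) pairs")
    I, k = pairs[:, 0], pairs[:, 1]
    if np.any(I < 0) or np.any(k < 0):
        raise ValueError("concentrations and rates must be >= 0")
    # nondimensionalize: molar concentrations (~1e-6) and rates (~1e-4)
    # are far from unit scale, which stalls trust-region steps
    s_I = float(np.median(I[I > 0]))
    s_k = float(k.max()) if k.max() > 0 else 1e-4
    if sigma is not None:
        sigma = np.maximum(np.asarray(sigma, dtype=float), 1e-12 * s_k) / s_k
    p0 = [1.2, 1.0]
    try:
        popt, pcov = curve_fit(_kobs_model, I / s_I, k / s_k, p0=p0,
                               sigma=sigma, absolute_sigma=sigma is not None,
                               bounds=([0, 0], [np.inf, np.inf]), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"k_inact/K_I fit did not converge: {exc}") from exc
    scale = np.array([s_k, s_I])
    popt = popt * scale
    pcov = pcov * np.outer(scale, scale)
    k_inact, K_I = popt
    if I.max() < K_I:
        warnings.warn(
            "all concentrations below fitted K_I: saturation ill-conditioned; "
            "consider the linear-regime efficiency fit", stacklevel=2,
        )
    eff = k_inact / K_I
    # delta method: var(eff) = J @ cov @ J.T with J = [1/K_I, -k_inact/K_I^2]
    J = np.array([1.0 / K_I, -k_inact / K_I**2])
    var_eff = float(J @ pcov @ J)
    se = np.sqrt(np.diag(pcov))
    return CovalentFitResult(
        k_inact=float(k_inact), K_I=float(K_I), efficiency=float(eff),
        Ki_t0=None, per_concentration=[], regime="saturation",
        standard_errors={"k_inact": float(se[0]), "K_I": float(se[1]),
                         "efficiency": float(np.sqrt(max(var_eff, 0.0)))},
    )


def fit_efficiency_linear(kobs_by_conc, K_I: float | None = None,
                          max_conc_fraction_of_KI: float = 0.2):
    """Covalent efficiency k_inact/K_I from the low-concentration regime.

    At [I] << K_I, k_obs = (k_inact/K_I)*[I]; the efficiency is the
    zero-intercept least-squares slope. If K_I is supplied, concentrations
    above ``max_conc_fraction_of_KI * K_I`` trigger a regime warning. A
    free-intercept diagnostic refit is reported in the result metadata but
    does not alter the headline slope.

    Returns a :class:`CovalentFitResult` with regime="linear".
    """
    pairs = np.asarray(list(kobs_by_conc), dtype=float)
    if pairs.size == 0:
        raise FitError("no (concentration, k_obs) pairs supplied")
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise FitError("need at least 2 pairs for a slope")
    I, k = pairs[:, 0], pairs[:, 1]
    if K_I is not None and np.any(I > max_conc_fraction_of_KI * K_I):
        warnings.warn(
            f"concentrations exceed {max_conc_fraction_of_KI:.0%} of K_I: "
            "linear-regime assumption violated", stacklevel=2,
        )
    slope = float(I @ k / (I @ I))
    resid = k - slope * I
    dof = max(I.size - 1, 1)
    se_slope = float(np.sqrt((resid @ resid) / dof / (I @ I)))
    # diagnostic free-intercept refit
    X = np.column_stack([np.ones_like(I), I])
    coef, *_ = np.linalg.lstsq(X, k, rcond=None)
    return CovalentFitResult(
        k_inact=None, K_I=None, efficiency=slope, Ki_t0=None,
        per_concentration=[], regime="linear",
        standard_errors={"efficiency": se_slope},
        metadata={"diagnostic_intercept": float(coef[0]),
                  "diagnostic_slope": float(coef[1])},
    )


def ki_at_t0(fb0_by_conc, L_total, K_L, P_total):
    """Reversible K_i at time zero from the F_b0 dose-response.

    Fits the 4PL IC50 of initial bound fraction versus inhibitor
    concentration, then converts with the competitive-equilibrium
    (Nikolovska-Coleska) accounting.

    Returns
    -------
    (K_i, CompetitionFit)
    """
    pairs = np.asarray(list(fb0_by_conc), dtype=float)
    series = DoseSeries(
        concentrations=pairs[:, 0], responses=pairs[:, 1],
        fixed_components={"probe": L_total, "protein": P_total},
        response_type="bound_fraction",
    )
    fit = fit_ic50(series)
    K_i = ic50_to_Ki(fit.IC50, L_total, K_L, P_total)
    result = CompetitionFit(
        IC50=fit.IC50, hill=fit.hill, top=fit.top, bottom=fit.bottom,
        K_i=K_i, standard_errors=fit.standard_errors,
        metadata={**fit.metadata, "conversion": "nikolovska-coleska"},
    )
    return K_i, result


def analyze_covalent_fp(series, calib: AnisotropyCalibration | None,
                        L_total: float, K_L: float, E_total: float,
                        method: str = "linear",
                        window_fraction: float = LINEAR_WINDOW_FRACTION,
                        min_snr: float = 5.0) -> CovalentFitResult:
    """Full covalent FP analysis chain over a set of time courses.

    Each TimeSeries (one inhibitor concentration; technical replicates
    already averaged) is linearized to (F_b0, k_obs); the k_obs values are
    fitted to the saturation model for (k_inact, K_I); the F_b0 values to
    the 4PL for IC50 and converted to the reversible K_i at t = 0.

    A pseudo-first-order validity warning fires when any inhibitor total
    is below 10x the protein total. Concentrations whose initial bound
    fraction falls below ``min_snr`` times the linear-fit residual noise
    carry no quantifiable displacement signal (the probe is already fully
    displaced at t = 0); their k_obs is excluded from the saturation fit,
    though their F_b0 still informs the IC50. The saturation fit is
    weighted by the per-concentration k_obs standard errors.
    """
    if not series:
        raise FitError("no time courses supplied")
    if any(0 < ts.inhibitor_concentration < 10 * E_total for ts in series):
        warnings.warn("inhibitor below 10x protein total: pseudo-first-order "
                      "assumption weak", stacklevel=2)
    lins = []
    for ts in sorted(series, key=lambda s: s.inhibitor_concentration):
        lin = linearize_timecourse(ts, calib, window_fraction=window_fraction,
                                   method=method)
        lins.append((ts.inhibitor_concentration, lin))
    kobs_pairs, sigmas, excluded = [], [], []
    for c, lin in lins:
        if c <= 0:
            continue
        noise_sd = lin.flags.get("residual_sd", 0.0)
        if lin.F_b0 < min_snr * noise_sd:
            excluded.append(c)
            continue
        kobs_pairs.append((c, lin.k_obs))
        sigmas.append(lin.standard_errors.get("k_obs", 0.0))
    sat = fit_kinact_KI(kobs_pairs, sigma=sigmas)
    fb0_pairs = [(c, lin.F_b0) for c, lin in lins]
    Ki, comp = ki_at_t0(fb0_pairs, L_total, K_L, E_total)
    return CovalentFitResult(
        k_inact=sat.k_inact, K_I=sat.K_I, efficiency=sat.efficiency,
        Ki_t0=Ki, per_concentration=[lin for _, lin in lins],
        regime="saturation",
        standard_errors=sat.standard_errors,
        metadata={"IC50_t0": comp.IC50, "linearization": method,
                  "window_fraction": window_fraction,
                  "excluded_low_signal": excluded},
    )


def fit_modification_timecourse(ts: TimeSeries):
    """Pseudo-first-order fit of covalent modification (intact MS).

    Fraction modified follows f(t) = 1 - exp(-k*t); returns (k, t95) with
    t95 = ln(20)/k the time to 95% occupancy.
    """
    t, f = ts.times, np.asarray(ts.values, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions modified must lie in [0, 1]")
    diffs = np.diff(f)
    if np.any(diffs < -3 * max(np.std(diffs), 1e-12)):
        warnings.warn("non-monotone modification time course beyond noise",
                      stacklevel=2)

    def model(t, k):
        return 1.0 - np.exp(-k * t)

    t_pos = t[t > 0]
    k0 = 1.0 / np.median(t_pos) if t_pos.size else 1e-3
    popt, pcov = curve_fit(model, t, f, p0=[k0], bounds=(0, np.inf), maxfev=20000)
    k = float(popt[0])
    if k <= 0:
        raise FitError("no detectable modification rate")
    return {
        "k": k,
        "t95": float(np.log(20.0) / k),
        "standard_errors": {"k": float(np.sqrt(pcov[0, 0]))},
    }
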