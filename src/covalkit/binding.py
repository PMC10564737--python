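"""Equilibrium probe binding by fluorescence polarization (FP).

An SH2-domain protein is titrated into a fixed, low concentration of a
fluorescein-labelled phosphopeptide-mimetic probe; anisotropy A rises from
the free-probe value A_f to the bound value A_b. The bound fraction of the
probe is

    F_b = (A_f - A) / (A_f - A_b)

and the forward model for a saturation titration is the exact 1:1 binding
quadratic with ligand depletion (probe and K_L are within an order of
magnitude here, so the hyperbolic approximation is biased).

Competition experiments titrate an inhibitor against fixed probe and
protein; the IC50 of the bound-fraction dose-response is converted to the
inhibitor dissociation constant K_i with the exact competitive-equilibrium
accounting used for FP assays (Nikolovska-Coleska convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .equilibria import bound_probe_quadratic, competitive_equilibrium

__all__ = [
    "AnisotropyCalibration",
    "DoseSeries",
    "BindingFit",
    "CompetitionFit",
    "FitError",
    "bound_fraction",
    "anisotropy_from_fraction",
    "saturation_curve",
    "fit_probe_KL",
    "fit_ic50",
    "ic50_to_Ki",
]


class FitError(RuntimeError):
    """A least-squares fit failed or the data carry no signal.

    Carries the residuals (if any) on the ``residuals`` attribute.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class AnisotropyCalibration:
    """Anisotropy endpoints of the probe (milli-anisotropy units).

    A_f: free probe; A_b: fully bound probe. They must differ.
    """

    A_f: float
    A_b: float

    def __post_init__(self):
        if not (np.isfinite(self.A_f) and np.isfinite(self.A_b)):
            raise ValueError("calibration anisotropies must be finite")
        if self.A_f == self.A_b:
            raise ValueError("degenerate calibration: A_f == A_b")


@dataclass
class DoseSeries:
    """Response measured across a concentration series.

    concentrations are molar (a single zero point is allowed, e.g. a
    no-inhibitor control); fixed_components records the other species'
    total concentrations (e.g. ``{"probe": 1e-8, "protein": 5e-8}``).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    fixed_components: dict = field(default_factory=dict)
    replicate_id: str = "1"
    response_type: str = "anisotropy"

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if np.unique(self.concentrations).size != self.concentrations.size:
            raise ValueError("concentrations must be unique within a replicate")
        if any(v < 0 for v in self.fixed_components.values()):
            raise ValueError("fixed_components concentrations must be >= 0")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.responses = self.responses[order]


@dataclass
class BindingFit:
    """Result of a probe saturation fit: K_L plus anisotropy endpoints."""

    K_L: float
    A_f: float
    A_b: float
    standard_errors: dict
    goodness: dict

    def __post_init__(self):
        if self.K_L <= 0:
            raise ValueError("K_L must be > 0")


@dataclass
class CompetitionFit:
    """Result of a competition dose-response fit (4PL) plus K_i conversion."""

    IC50: float
    hill: float
    top: float
    bottom: float
    K_i: float | None
    standard_errors: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.IC50 <= 0:
            raise ValueError("IC50 must be > 0")
        if self.bottom > self.top:
            raise ValueError("bottom asymptote exceeds top")


def bound_fraction(A, calib: AnisotropyCalibration, clamp: bool = True):
    """Bound probe fraction from measured anisotropy.

    F_b = (A_f - A)/(A_f - A_b). Noise can push F_b outside [0, 1]; such
    values are clamped (with a warning) while the raw value is returned
    alongside.

    Returns
    -------
    (F_b, raw, clamped) : tuple of array/scalar, array/scalar, bool array
    """
    A = np.asarray(A, dtype=float)
    raw = (calib.A_f - A) / (calib.A_f - calib.A_b)
    clamped = (raw < 0) | (raw > 1)
    if clamp and np.any(clamped):
        warnings.warn(
            "bound fraction outside [0, 1]; clamped (raw values retained)",
            stacklevel=2,
        )
    out = np.clip(raw, 0.0, 1.0) if clamp else raw
    if out.ndim == 0:
        return float(out), float(raw), bool(clamped)
    return out, raw, clamped


def anisotropy_from_fraction(F_b, calib: AnisotropyCalibration):
    """Inverse of :func:`bound_fraction`: A = A_f + (A_b - A_f) * F_b."""
    F_b = np.asarray(F_b, dtype=float)
    out = calib.A_f + (calib.A_b - calib.A_f) * F_b
    return float(out) if out.ndim == 0 else out


def saturation_curve(P_total, L_total, K_L, calib: AnisotropyCalibration):
    """Predicted anisotropy for a protein titration at fixed probe.

    Uses the exact binding quadratic (ligand depletion); anisotropy is the
    linear mix of the calibration endpoints weighted by bound fraction.
    """
    x = bound_probe_quadratic(P_total, L_total, K_L)
    return anisotropy_from_fraction(x, calib)


def fit_probe_KL(data: DoseSeries, calib: AnisotropyCalibration | None = None) -> BindingFit:
    """Fit the probe dissociation constant K_L from a saturation titration.

    K_L, A_f and A_b are estimated jointly unless a calibration is
    supplied, in which case only K_L is free. Concentrations are protein
    totals; the probe total is read from ``fixed_components['probe']``.
    """
    P = data.concentrations
    A = data.responses
    if P.size < 6:
        raise FitError("need at least 6 concentration points to fit K_L")
    if np.ptp(A) == 0:
        raise FitError("no binding signal: all responses identical")
    try:
        L = data.fixed_components["probe"]
    except KeyError:
        raise ValueError("DoseSeries.fixed_components must declare 'probe'") from None

    span = np.ptp(A)
    s_c = float(np.exp(np.mean(np.log(P[P > 0]))))  # rescale K_L to O(1)
    if calib is None:
        def model(P, K_Ln, A_f, A_b):
            return saturation_curve(P, L, K_Ln * s_c, AnisotropyCalibration(A_f, A_b))

        p0 = [np.median(P[P > 0]) / s_c, A[0], A[-1]]
        names = ["K_L", "A_f", "A_b"]
        bounds = ([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
    else:
        def model(P, K_Ln):
            return saturation_curve(P, L, K_Ln * s_c, calib)

        p0 = [np.median(P[P > 0]) / s_c]
        names = ["K_L"]
        bounds = ([1e-12], [np.inf])

    try:
        popt, pcov = curve_fit(model, P, A, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"K_L fit did not converge: {exc}") from exc
    resid = A - model(P, *popt)
    popt[0] *= s_c
    pcov[0, :] *= s_c
    pcov[:, 0] *= s_c
    if span > 0 and np.sqrt(np.mean(resid**2)) > 0.5 * span:
        raise FitError("K_L fit failed: residuals comparable to signal", residuals=resid)
    se = np.sqrt(np.diag(pcov))
    params = dict(zip(names, popt))
    errors = dict(zip(names, se))
    K_L = params["K_L"]
    tested = P[P > 0]
    if K_L < tested.min() or K_L > tested.max():
        warnings.warn(
            f"fitted K_L = {K_L:.3g} M lies outside the tested range "
            f"[{tested.min():.3g}, {tested.max():.3g}] M",
            stacklevel=2,
        )
    return BindingFit(
        K_L=K_L,
        A_f=params.get("A_f", calib.A_f if calib else np.nan),
        A_b=params.get("A_b", calib.A_b if calib else np.nan),
        standard_errors=errors,
        goodness={"rss": float(resid @ resid), "n": int(P.size),
                  "rmse": float(np.sqrt(np.mean(resid**2)))},
    )


def _logistic4(c, top, bottom, ic50, hill):
    # decreasing 4PL in linear concentration; c = 0 maps to `top` exactly
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_ic50(data: DoseSeries) -> CompetitionFit:
    """Fit a 4-parameter logistic dose-response for the competition IC50.

    The response (bound fraction at time zero, F_b0) falls from ``top`` to
    ``bottom`` as inhibitor concentration rises; IC50 is the concentration
    at the half-way point between the asymptotes. Hill slope is free and
    the fit is initialized from data quartiles.
    """
    c = data.concentrations
    y = data.responses
    if c.size < 6:
        raise FitError("need at least 6 inhibitor concentrations")
    if np.ptp(y) == 0:
        raise FitError("no inhibitor effect: constant response")
    pos = c[c > 0]
    # quartile-based initialization; concentrations rescaled to unit order
    # (molar values ~1e-6 stall trust-region steps)
    s_c = float(np.exp(np.mean(np.log(pos))))
    top0, bot0 = float(np.max(y)), float(np.min(y))
    half = (top0 + bot0) / 2.0
    below = pos[y[c > 0] <= half]
    ic0 = float(below.min()) if below.size else float(np.median(pos))
    p0 = [top0, bot0, ic0 / s_c, 1.0]
    bounds = ([-np.inf, -np.inf, pos.min() / s_c / 1e4, 0.1],
              [np.inf, np.inf, pos.max() / s_c * 1e4, 10.0])
    try:
        popt, pcov = curve_fit(_logistic4, c / s_c, y, p0=p0, bounds=bounds,
                               maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"IC50 fit did not converge: {exc}") from exc
    popt[2] *= s_c
    pcov[2, :] *= s_c
    pcov[:, 2] *= s_c
    top, bottom, ic50, hill = popt
    if bottom > top:  # direction degenerate under noise
        top, bottom = bottom, top
    resid = y - _logistic4(c, *popt)
    if np.sqrt(np.mean(resid**2)) > 0.5 * np.ptp(y):
        raise FitError("IC50 fit failed: residuals comparable to signal",
                       residuals=resid)
    meta = {}
    if not (pos.min() <= ic50 <= pos.max()):
        warnings.warn("IC50 outside tested concentration range (extrapolated)",
                      stacklevel=2)
        meta["extrapolated"] = True
    se = np.sqrt(np.diag(pcov))
    return CompetitionFit(
        IC50=float(ic50), hill=float(hill), top=float(top), bottom=float(bottom),
        K_i=None,
        standard_errors=dict(zip(["top", "bottom", "IC50", "hill"], se)),
        metadata=meta,
    )


def ic50_to_Ki(IC50, L_total, K_L, P_total):
    """Convert a competition-FP IC50 to the inhibitor K_i.

    Exact competitive-equilibrium accounting (the Nikolovska-Coleska
    convention for FP assays): at 50% inhibition the bound probe is half of
    its no-inhibitor value; free probe, free protein and bound inhibitor
    follow from the equilibrium relations, and

        K_i = [P]_free50 * [I]_free50 / [PI]_50,  [I]_free50 = IC50 - [PI]_50.

    K_i <= IC50 always, with equality in the zero-depletion limit
    (probe and protein both far below K_L).
    """
    if min(IC50, L_total, K_L, P_total) <= 0:
        raise ValueError("all inputs must be > 0")
    # bound probe with no inhibitor, exact quadratic
    PL0 = bound_probe_quadratic(P_total, L_total, K_L) * L_total
    PL50 = PL0 / 2.0
    L_free50 = L_total - PL50
    P_free50 = K_L * PL50 / L_free50
    PI50 = P_total - P_free50 - PL50
    if PI50 <= 0:
        # negligible inhibitor depletion: denominator-form limit
        return IC50 / (L_free50 / K_L + P_free50 / K_L + 1.0)
    I_free50 = IC50 - PI50
    if I_free50 <= 0:
        raise ValueError(
            "IC50 below the stoichiometrically bound inhibitor: "
            "tight-binding regime, conversion invalid"
        )
    return float(P_free50 * I_free50 / PI50)
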