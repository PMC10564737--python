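"""Closed-form and numerical binding equilibria.

Two systems appear throughout the package:

* protein P + fluorescent probe L -- the 1:1 equilibrium with ligand
  depletion, solved exactly by the binding quadratic;
* protein + probe + competing inhibitor I -- the three-species competitive
  equilibrium, solved numerically for free protein (a single monotone
  scalar equation, bracketed and solved with Brent's method).

The competitive solver is the independent oracle for the IC50->K_i
conversion and for the k_inact = 0 limit of the covalent mechanism.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = ["bound_probe_quadratic", "competitive_equilibrium"]


def bound_probe_quadratic(P_total, L_total, K_d):
    """Fraction of probe bound for 1:1 binding with depletion.

    Solves [PL] from the exact quadratic
    ``[PL]^2 - (P+L+Kd)[PL] + P*L = 0`` (stable root) and returns
    ``x = [PL]/L_total``. Inputs may be scalars or arrays (broadcast).

    Raises
    ------
    ValueError
        If ``L_total == 0`` (the probe fraction is undefined).
    """
    P = np.asarray(P_total, dtype=float)
    L = float(L_total)
    if L <= 0:
        raise ValueError("L_total must be > 0: probe bound fraction undefined")
    if K_d <= 0:
        raise ValueError("K_d must be > 0")
    if np.any(P < 0):
        raise ValueError("protein concentrations must be >= 0")
    s = P + L + K_d
    disc = s * s - 4.0 * P * L
    PL = (s - np.sqrt(np.maximum(disc, 0.0))) / 2.0
    return PL / L


def competitive_equilibrium(E_total, L_total, I_total, K_L, K_i):
    """Solve the three-species competitive equilibrium.

    Protein E binds probe L (dissociation constant ``K_L``) and inhibitor I
    (``K_i``) mutually exclusively. Free protein E satisfies

        E_total = E * (1 + L_free/K_L + I_free/K_i)

    with ``L_free = L_total / (1 + E/K_L)`` and
    ``I_free = I_total / (1 + E/K_i)``; the right-hand side is strictly
    increasing in E so the root is unique on ``(0, E_total]``.

    Returns
    -------
    dict
        Free and bound species concentrations (molar):
        ``E, L, I, EL, EI`` with ``EL + E + EI == E_total`` etc.
    """
    E_T, L_T, I_T = float(E_total), float(L_total), float(I_total)
    for name, v in (("E_total", E_T), ("L_total", L_T), ("I_total", I_T)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if K_L <= 0 or K_i <= 0:
        raise ValueError("dissociation constants must be > 0")
    if E_T == 0:
        return {"E": 0.0, "L": L_T, "I": I_T, "EL": 0.0, "EI": 0.0}

    def residual(E):
        L_free = L_T / (1.0 + E / K_L)
        I_free = I_T / (1.0 + E / K_i)
        return E * (1.0 + L_free / K_L + I_free / K_i) - E_T

    lo = E_T * 1e-15
    if residual(lo) > 0:  # essentially no binding
        E = E_T
    else:
        E = brentq(residual, lo, E_T, xtol=1e-30, rtol=1e-14)
    L_free = L_T / (1.0 + E / K_L)
    I_free = I_T / (1.0 + E / K_i)
    return {
        "E": E,
        "L": L_free,
        "I": I_free,
        "EL": E * L_free / K_L,
        "EI": E * I_free / K_i,
    }
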