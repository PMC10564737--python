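"""Published reference values for the SOCS2/SBC2 ligand series.

Immutable records of the printed characterization numbers (dissociation
constants, calorimetric thermodynamics, ligand efficiencies, covalent
kinetic parameters) used by the internal-consistency test suite and as
sensible defaults for the synthetic-data generator. All concentrations
are molar, energies kcal/mol, rates s^-1.
"""

from __future__ import annotations

from types import MappingProxyType

__all__ = ["HEADLINE", "TABLE1", "TABLE2", "published_values"]

#: Headline parameters of the covalent ligand (MN551) and the FP probe.
HEADLINE = MappingProxyType({
    "probe_K_L": 77.56e-9,          # FP probe dissociation constant, M
    "k_inact": 2.1e-4,              # maximal inactivation rate, s^-1
    "K_I": 3.6e-6,                  # half-maximal k_obs concentration, M
    "efficiency": 58.0,             # k_inact/K_I, M^-1 s^-1 (printed)
    "Ki_t0": 1.1e-6,                # reversible K_i at t = 0 (FP), M
    "Ki_itc": 2.2e-6,               # reversible affinity by ITC, M
    "gsh_T_half_min": 70.0,         # GSH reactivity half-life lower bound, min
    "dsf_shift_C": 6.0,             # DSF melting-temperature shift, degC
    "cetsa_ec50_8h": 2.5e-6,        # cellular EC50 after 8 h, M
    "cetsa_ec50_2h": 3.8e-6,        # cellular EC50 after 2 h, M
    "adduct_mass_Da": 542.0,        # covalent adduct mass on Cys111, Da
    "adduct_composition": "C(26)H(25)N(3)O(7)FP",
    "maxquant_modification": "C(26)H(25)N(3)O(7)FPSe(-1)S",
    "ligand_composition": "C(26)H(26)ClFN(3)O(7)P",
    "pY_K_D": 190e-6,               # free phosphotyrosine K_D (ITC), M
    "pY_NHA": 17,                   # heavy atoms of phosphotyrosine C9H12NO6P
    "pY_LE": 0.29,                  # printed LE, kcal/mol/NHA
})

#: First-round series: (compound, NMR K_D [M], NMR LE, SPR K_D [M], SPR LE).
TABLE1 = (
    {"compound": "1", "KD_nmr": 186e-6, "LE_nmr": 0.24, "KD_spr": 269e-6,
     "LE_spr": 0.23, "NHA": 21},
    {"compound": "2", "KD_nmr": 106e-6, "LE_nmr": 0.22, "KD_spr": 126e-6,
     "LE_spr": 0.22},
    {"compound": "3", "KD_nmr": 352e-6, "LE_nmr": 0.17, "KD_spr": 205e-6,
     "LE_spr": 0.18},
    {"compound": "4", "KD_nmr": 62e-6, "LE_nmr": 0.21, "KD_spr": 114e-6,
     "LE_spr": 0.20},
    {"compound": "5", "KD_nmr": 32e-6, "LE_nmr": 0.215, "KD_spr": 49e-6,
     "LE_spr": 0.21},
    {"compound": "6", "KD_nmr": 50e-6, "LE_nmr": 0.20, "KD_spr": 58e-6,
     "LE_spr": 0.20},
    {"compound": "7", "KD_nmr": 34e-6, "LE_nmr": 0.19, "KD_spr": 44e-6,
     "LE_spr": 0.19},
    {"compound": "8", "KD_nmr": 85e-6, "LE_nmr": 0.20, "KD_spr": 75e-6,
     "LE_spr": 0.20},
)

#: Second-round series: SPR/ITC K_D [M], calorimetric split [kcal/mol], LE.
TABLE2 = (
    {"compound": "9", "KD_spr": 4.2e-6, "KD_itc": 2.6e-6, "dG": -7.65,
     "dH": -4.1, "minusTdS": -3.55, "LE": 0.21},
    {"compound": "10", "KD_spr": 3.7e-6, "KD_itc": 1.1e-6, "dG": -8.12,
     "dH": -5.81, "minusTdS": -2.31, "LE": 0.23},
    {"compound": "11", "KD_spr": 2.7e-6, "KD_itc": 1.0e-6, "dG": -8.23,
     "dH": -5.25, "minusTdS": -2.98, "LE": 0.22},
    {"compound": "12", "KD_spr": 2.2e-6, "KD_itc": 0.51e-6, "dG": -8.59,
     "dH": -8.16, "minusTdS": -0.43, "LE": 0.23},
    {"compound": "13", "KD_spr": 2.4e-6, "KD_itc": 0.38e-6, "dG": -8.75,
     "dH": -7.13, "minusTdS": -1.62, "LE": 0.23},
    {"compound": "14", "KD_spr": 2.4e-6, "KD_itc": 0.48e-6, "dG": -8.61,
     "dH": -6.31, "minusTdS": -2.26, "LE": 0.23},
)


def published_values():
    """Return the full published-value fixture set.

    Returns
    -------
    dict with keys ``headline`` (mapping), ``table1`` and ``table2``
    (tuples of per-compound records). Immutable; the count of records is
    stable across calls.
    """
    return {"headline": HEADLINE, "table1": TABLE1, "table2": TABLE2}
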