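"""Headspace-equilibration chemistry: from a syringe gas sample to the
dissolved CH4 concentration of the lake water.

The field method equilibrates ~400 mL of lake water with ~100 mL of pure N2
in a syringe.  Afterwards the headspace CH4 mixing ratio is measured by gas
chromatography.  Three steps recover the in-situ dissolved concentration:

1. ideal gas law: moles of CH4 in the headspace, ``n = P_m V_h / (R T_air)``;
2. headspace concentration ``C_h = n / V_h``;
3. mass balance over the syringe, ``C_w = (C_h V_h + S V_w) / V_w``,
   where ``S`` is the CH4 solubility (the dissolved concentration in
   equilibrium with the headspace partial pressure at the equilibration
   temperature).

Solubility uses the Wiesenburg & Guinasso (1979) Bunsen-coefficient fit for
methane at salinity 0, the standard freshwater parameterization.  The same
function yields the air-equilibrium concentration ``C_eq`` that enters the
diffusive-flux gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GasConstants",
    "DissolvedConcentration",
    "bunsen_solubility",
    "methane_solubility",
    "headspace_moles",
    "headspace_concentration",
    "dissolved_concentration",
    "equilibrium_concentration",
]


@dataclass(frozen=True)
class GasConstants:
    """Physical constants of the concentration pipeline.

    ``atm_ch4_ppm`` is the atmospheric CH4 dry mixing ratio used for the
    air-equilibrium concentration; the default 1.9 ppm corresponds to the
    Waliguan baseline record of the early 2020s and is configurable.
    """

    R: float = 0.082057  # L atm / (K mol)
    molar_mass_ch4: float = 16.04  # g/mol
    molar_mass_c: float = 12.0  # g/mol
    atm_ch4_ppm: float = 1.9

    def __post_init__(self) -> None:
        for name in ("R", "molar_mass_ch4", "molar_mass_c", "atm_ch4_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class DissolvedConcentration:
    """Per-point result: dissolved, air-equilibrium and solubility terms."""

    c_w: float  # umol/L dissolved in lake water
    c_eq: float  # umol/L at equilibrium with the atmosphere
    s: float  # umol/L solubility at the headspace partial pressure


#: Molar volume of an ideal gas at STP (L/mol); converts a Bunsen
#: coefficient (volume of gas per volume of water) to molar units.
MOLAR_VOLUME_STP = 22.414

# Wiesenburg & Guinasso (1979) coefficients for ln(Bunsen) of CH4.
_WG_A = (-68.8862, 101.4956, 28.7314)
_WG_B = (-0.076146, 0.043970, -0.0068672)

_T_VALID = (-1.0, 40.0)  # deg C validity window enforced on inputs


def bunsen_solubility(t_water_c, salinity: float = 0.0):
    """Bunsen solubility coefficient of CH4 in water.

    Volume of CH4 at STP absorbed per volume of water when the partial
    pressure of CH4 is 1 atm.  ``t_water_c`` in deg C (scalar or array),
    salinity in permil (0 for the freshwater lakes modelled here).
    """
    t = np.asarray(t_water_c, dtype=float)
    if np.any(t < _T_VALID[0]) or np.any(t > _T_VALID[1]):
        raise ValueError(f"water temperature outside {_T_VALID} deg C")
    tk = t + 273.15
    a1, a2, a3 = _WG_A
    b1, b2, b3 = _WG_B
    ln_beta = (
        a1
        + a2 * (100.0 / tk)
        + a3 * np.log(tk / 100.0)
        + salinity * (b1 + b2 * (tk / 100.0) + b3 * (tk / 100.0) ** 2)
    )
    out = np.exp(ln_beta)
    return out.item() if np.isscalar(t_water_c) else out


def methane_solubility(p_ch4_atm, t_water_c):
    """Dissolved CH4 concentration (umol/L) in equilibrium with a CH4
    partial pressure ``p_ch4_atm`` (atm) at ``t_water_c`` (deg C)."""
    p = np.asarray(p_ch4_atm, dtype=float)
    if np.any(p < 0):
        raise ValueError("partial pressure must be >= 0")
    beta = bunsen_solubility(t_water_c)
    out = np.asarray(beta) * p / MOLAR_VOLUME_STP * 1.0e6
    return float(out) if out.ndim == 0 else out


def headspace_moles(p_m_atm, v_h_l, t_air_k, constants: GasConstants = GasConstants()):
    """Moles of CH4 in the syringe headspace, ``n = P_m V_h / (R T_air)``."""
    p = np.asarray(p_m_atm, dtype=float)
    vh = np.asarray(v_h_l, dtype=float)
    t = np.asarray(t_air_k, dtype=float)
    if np.any(p < 0):
        raise ValueError("headspace partial pressure must be >= 0")
    if np.any(vh <= 0):
        raise ValueError("headspace volume must be > 0")
    if np.any(t <= 0):
        raise ValueError("air temperature must be > 0 K")
    out = p * vh / (constants.R * t)
    return float(out) if out.ndim == 0 else out


def headspace_concentration(p_m_atm, t_air_k, constants: GasConstants = GasConstants()):
    """Headspace CH4 concentration C_h = n/V_h in umol/L.

    V_h cancels: C_h depends only on the partial pressure and temperature.
    """
    vh = 1.0
    n = headspace_moles(p_m_atm, vh, t_air_k, constants)
    out = np.asarray(n) / vh * 1.0e6
    return float(out) if out.ndim == 0 else out


def dissolved_concentration(c_h, v_h_l, v_w_l, s):
    """Syringe mass balance: dissolved CH4 in the sampled water (umol/L).

    ``C_w = (C_h V_h + S V_w) / V_w``: the CH4 driven into the headspace
    plus what stays dissolved at equilibrium, per litre of sampled water.
    """
    ch = np.asarray(c_h, dtype=float)
    vh = np.asarray(v_h_l, dtype=float)
    vw = np.asarray(v_w_l, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    if np.any(vw <= 0):
        raise ValueError("water volume must be > 0")
    if np.any(vh < 0):
        raise ValueError("headspace volume must be >= 0")
    if np.any(ch < 0) or np.any(s_arr < 0):
        raise ValueError("concentrations must be >= 0")
    out = (ch * vh + s_arr * vw) / vw
    return float(out) if out.ndim == 0 else out


def equilibrium_concentration(
    t_water_c,
    p_atm,
    mixing_ratio_ppm: float | None = None,
    constants: GasConstants = GasConstants(),
):
    """Dissolved CH4 concentration (umol/L) at equilibrium with the
    atmosphere: Bunsen solubility scaled by the atmospheric CH4 partial
    pressure ``mixing_ratio * P_atm``."""
    if mixing_ratio_ppm is None:
        mixing_ratio_ppm = constants.atm_ch4_ppm
    if mixing_ratio_ppm < 0:
        raise ValueError("mixing ratio must be >= 0")
    p = np.asarray(p_atm, dtype=float)
    if np.any(p <= 0):
        raise ValueError("atmospheric pressure must be > 0")
    return methane_solubility(mixing_ratio_ppm * 1.0e-6 * p, t_water_c)
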