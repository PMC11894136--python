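"""Gas transfer velocity of CH4 across the air-water interface.

Thin-boundary-layer gas exchange: the transfer velocity normalized to a
Schmidt number of 600 (k600) is parameterized from the 10-m wind speed as
the mean of three published wind relations, then rescaled to the CH4
Schmidt number at the observed water temperature,

    K = (Sc/600)^(-x) * k600,

with the exponent x = 0.66 for low winds (U10 <= 3 m/s, smooth surface) and
x = 0.5 above (wavy surface).  Wind measured at height Z is brought to 10 m
with a neutral logarithmic profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GasTransferParams",
    "TransferVelocity",
    "schmidt_number",
    "wind_at_10m",
    "k600",
    "transfer_velocity",
    "transfer_velocity_from_met",
]


@dataclass(frozen=True)
class GasTransferParams:
    """Constants of the wind/transfer-velocity parameterization.

    ``c_d10`` (10-m drag coefficient) and ``kappa`` (von Karman constant)
    take the standard neutral-atmosphere values; the Schmidt-number exponent
    switches from ``x_low`` to ``x_high`` above ``wind_threshold`` (the
    threshold itself uses ``x_low``).
    """

    c_d10: float = 0.0013
    kappa: float = 0.41
    wind_threshold: float = 3.0  # m/s
    x_low: float = 0.66
    x_high: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.c_d10 < 0.01:
            raise ValueError("c_d10 out of range (0, 0.01)")
        if not 0.3 < self.kappa < 0.5:
            raise ValueError("kappa out of range (0.3, 0.5)")


@dataclass(frozen=True)
class TransferVelocity:
    sc: float  # CH4 Schmidt number, dimensionless
    k600: float  # cm/h
    k: float  # cm/h, rescaled to the CH4 Schmidt number
    u10: float  # m/s


# Schmidt-number polynomial coefficients for CH4 in fresh water
# (constant, T, T^2, T^3), T in deg C.
_SC_COEFFS = (1897.8, -114.28, 3.2902, -0.039061)

_SC_RANGE = (0.0, 30.0)  # calibration range of the polynomial, deg C


def schmidt_number(t_water_c, *, clamp: bool = True):
    """CH4 Schmidt number from water temperature (deg C).

    The cubic fit is only physical on [0, 30] degC; inputs outside are
    clamped to that range (a warning is emitted) rather than extrapolated.
    """
    t = np.asarray(t_water_c, dtype=float)
    lo, hi = _SC_RANGE
    if clamp and (np.any(t < lo) or np.any(t > hi)):
        warnings.warn(
            f"water temperature clamped to Schmidt-number range {_SC_RANGE} degC",
            stacklevel=2,
        )
        t = np.clip(t, lo, hi)
    c0, c1, c2, c3 = _SC_COEFFS
    out = c0 + c1 * t + c2 * t**2 + c3 * t**3
    return float(out) if out.ndim == 0 else out


def wind_at_10m(u_z, z_m, params: GasTransferParams = GasTransferParams()):
    """Neutral log-profile correction of wind speed from height Z to 10 m:
    ``U10 = U_z * (1 + sqrt(C_d10)/kappa * ln(10/Z))``."""
    u = np.asarray(u_z, dtype=float)
    z = np.asarray(z_m, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    if np.any(z <= 0):
        raise ValueError("measurement height must be > 0")
    out = u * (1.0 + np.sqrt(params.c_d10) / params.kappa * np.log(10.0 / z))
    return float(out) if out.ndim == 0 else out


def k600(u10):
    """k600 (cm/h) from 10-m wind: mean of three wind parameterizations.

    Averaging the three published relations reduces the structural spread
    between single parameterizations.
    """
    u = np.asarray(u10, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    k1 = 2.07 + 0.215 * u**1.7
    k2 = 0.45 * u**1.64
    k3 = 1.68 + 0.228 * u**2.2
    out = (k1 + k2 + k3) / 3.0
    return float(out) if out.ndim == 0 else out


def transfer_velocity(sc, k_600, u10, params: GasTransferParams = GasTransferParams()):
    """Rescale k600 to the CH4 Schmidt number: ``K = (Sc/600)^(-x) k600``.

    The exponent is ``x_low`` for ``u10 <= wind_threshold`` (inclusive) and
    ``x_high`` above.
    """
    sc_arr = np.asarray(sc, dtype=float)
    k_arr = np.asarray(k_600, dtype=float)
    u = np.asarray(u10, dtype=float)
    if np.any(sc_arr <= 0) or np.any(k_arr <= 0):
        raise ValueError("Schmidt number and k600 must be > 0")
    x = np.where(u <= params.wind_threshold, params.x_low, params.x_high)
    out = (sc_arr / 600.0) ** (-x) * k_arr
    return float(out) if out.ndim == 0 else out


def transfer_velocity_from_met(
    t_water_c, u_z, z_m, params: GasTransferParams = GasTransferParams()
) -> TransferVelocity | np.ndarray:
    """Convenience composition: met inputs -> CH4 transfer velocity.

    Scalar inputs return a :class:`TransferVelocity`; array inputs return
    the array of K values (cm/h).
    """
    u10 = wind_at_10m(u_z, z_m, params)
    sc = schmidt_number(t_water_c)
    k6 = k600(u10)
    k = transfer_velocity(sc, k6, u10, params)
    if np.isscalar(t_water_c) and np.isscalar(u_z):
        return TransferVelocity(sc=sc, k600=k6, k=k, u10=u10)
    return k
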