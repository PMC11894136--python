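"""Methanogenic-pathway diagnosis from stable carbon isotopes.

Hydrogenotrophic methanogenesis (CO2 reduction) discriminates more strongly
against 13C than acetoclastic methanogenesis, and methane oxidation
enriches the residual CH4 in 13C.  The apparent fractionation factor

    alpha_C = (d13C-CO2 + 1000) / (d13C-CH4 + 1000)

therefore separates the pathways: alpha_C > 1.055 indicates CO2 reduction,
1.040-1.055 acetate fermentation, and < 1.040 oxidation-dominated signals.
Both threshold values are assigned to the acetate-fermentation class (the
band is read as closed).
"""

from __future__ import annotations

from enum import Enum

import numpy as np

__all__ = ["Pathway", "alpha_c", "classify_pathway", "ALPHA_ACETATE_LOW", "ALPHA_ACETATE_HIGH"]

ALPHA_ACETATE_LOW = 1.040
ALPHA_ACETATE_HIGH = 1.055


class Pathway(str, Enum):
    CO2_REDUCTION = "CO2_reduction"
    ACETATE_FERMENTATION = "acetate_fermentation"
    OXIDATION_DOMINATED = "oxidation_dominated"


def alpha_c(d13c_co2, d13c_ch4):
    """Apparent carbon fractionation factor between dissolved CO2 and CH4.

    Delta values in permil on the VPDB scale; both must exceed -1000 (the
    physical floor of the delta notation).
    """
    co2 = np.asarray(d13c_co2, dtype=float)
    ch4 = np.asarray(d13c_ch4, dtype=float)
    if np.any(co2 <= -1000.0) or np.any(ch4 <= -1000.0):
        raise ValueError("delta values must exceed -1000 permil")
    out = (co2 + 1000.0) / (ch4 + 1000.0)
    return float(out) if out.ndim == 0 else out


def classify_pathway(alpha):
    """Three-way pathway classification of alpha_C values.

    Scalar input returns a :class:`Pathway`; array input returns an object
    array of Pathway members.  Every finite positive alpha maps to exactly
    one class.
    """
    arr = np.asarray(alpha, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("alpha_C must be finite and > 0")
    flat = np.empty(arr.size, dtype=object)
    for i, a in enumerate(arr.ravel()):
        if a < ALPHA_ACETATE_LOW:
            flat[i] = Pathway.OXIDATION_DOMINATED
        elif a <= ALPHA_ACETATE_HIGH:
            flat[i] = Pathway.ACETATE_FERMENTATION
        else:
            flat[i] = Pathway.CO2_REDUCTION
    if arr.ndim == 0:
        return flat[0]
    return flat.reshape(arr.shape)
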