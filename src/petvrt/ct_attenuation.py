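"""CT Hounsfield units to 511 keV linear attenuation coefficients.

Bilinear CT-based attenuation conversion (Burger-style): below a soft
tissue/bone breakpoint the attenuation scales with the water-like slope,
above it with a shallower bone slope, continuous at the breakpoint.
Used to characterize printed phantom materials whose density differs
from water.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hu_to_mu511", "BREAKPOINT_HU", "SLOPE_BELOW", "SLOPE_ABOVE", "INTERCEPT_ABOVE"]

#: Slope below the breakpoint, cm^-1 per HU (zero attenuation at air, -1000 HU).
SLOPE_BELOW = 9.6e-5
#: Slope above the breakpoint, cm^-1 per HU.
SLOPE_ABOVE = 5.1e-5
#: Intercept of the upper branch, cm^-1.
INTERCEPT_ABOVE = 4.71e-2
#: Breakpoint between the water-like and bone-like branches, HU.  Derived
#: from the slopes and intercept so the two branches meet exactly; with
#: the published rounded constants this lands at ~46.7 HU (commonly
#: quoted as 47 HU).
BREAKPOINT_HU = INTERCEPT_ABOVE / (SLOPE_BELOW - SLOPE_ABOVE) - 1000.0


def hu_to_mu511(
    hu,
    breakpoint_hu: float = BREAKPOINT_HU,
    slope_below: float = SLOPE_BELOW,
    slope_above: float = SLOPE_ABOVE,
    intercept_above: float = INTERCEPT_ABOVE,
):
    """Linear attenuation coefficient at 511 keV (cm^-1) for CT values (HU).

    mu = slope_below * (HU + 1000)                     for HU <= breakpoint
    mu = slope_above * (HU + 1000) + intercept_above   for HU >  breakpoint

    Accepts scalars or arrays; HU below -1000 (denser than vacuum on the
    CT scale) is rejected.  With the default constants, air (-1000 HU)
    maps to 0 and water (0 HU) to 0.096 cm^-1.
    """
    hu_arr = np.asarray(hu, dtype=float)
    if np.any(hu_arr < -1000):
        raise ValueError("HU values below -1000 are outside the CT scale")
    mu = np.where(
        hu_arr <= breakpoint_hu,
        slope_below * (hu_arr + 1000.0),
        slope_above * (hu_arr + 1000.0) + intercept_above,
    )
    if np.isscalar(hu) or hu_arr.ndim == 0:
        return float(mu)
    return mu
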