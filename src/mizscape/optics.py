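"""Euphotic-depth optics: depth of the 1% downwelling light level.

Irradiance attenuates as dE/dz = -(K_w + k_chl * chl(z)) * E, a two-component
diffuse attenuation with a clear-water term K_w (m**-1) and a
chlorophyll-specific term k_chl (m**2 per mg Chl-a).  The 1% depth is where
the optical depth integral reaches ln(100); light here is relative to the
just-below-surface value, so surface transmittance (open water vs
snow-covered ice) scales absolute light but not this depth.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = ["LightDepth", "depth_1pct_light", "K_W_DEFAULT", "K_CHL_DEFAULT"]

K_W_DEFAULT = 0.046     # clear-seawater diffuse attenuation, m^-1
K_CHL_DEFAULT = 0.016   # chlorophyll-specific attenuation, m^2 (mg Chl-a)^-1


class LightDepth(NamedTuple):
    depth_m: float
    reached: bool  # False when 1% is not attained within the profile


def depth_1pct_light(
    depths,
    chl,
    k_w: float = K_W_DEFAULT,
    k_chl: float = K_CHL_DEFAULT,
    fraction: float = 0.01,
) -> LightDepth:
    """Depth (m) at which relative irradiance E(z)/E(0-) falls to ``fraction``.

    The optical depth tau(z) = integral of K_w + k_chl*chl is accumulated by
    the trapezoid rule on the profile grid and inverted linearly between grid
    points.  If the profile ends before tau reaches -ln(fraction), the bottom
    depth is returned with ``reached=False``.
    """
    depths = np.asarray(depths, dtype=float)
    chl = np.asarray(chl, dtype=float)
    if depths.size == 0:
        raise ValueError("empty chlorophyll profile")
    if depths.shape != chl.shape:
        raise ValueError("depths and chl must have the same shape")
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly increasing")
    if np.any(chl < 0):
        raise ValueError("chlorophyll must be nonnegative")
    if k_w <= 0 or k_chl < 0:
        raise ValueError("k_w must be positive and k_chl nonnegative")

    if depths[0] > 0:  # extend to the surface assuming surface-value chl
        depths = np.concatenate([[0.0], depths])
        chl = np.concatenate([[chl[0]], chl])

    target = -np.log(fraction)
    k = k_w + k_chl * chl
    tau = cumulative_trapezoid(k, depths, initial=0.0)
    if tau[-1] < target:
        return LightDepth(float(depths[-1]), False)
    i = int(np.searchsorted(tau, target))
    # linear inversion within [i-1, i]
    z = depths[i - 1] + (target - tau[i - 1]) / (tau[i] - tau[i - 1]) * (depths[i] - depths[i - 1])
    return LightDepth(float(z), True)
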