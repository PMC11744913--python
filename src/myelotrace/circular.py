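"""Circular helpers for axial orientation data.

Orientations of fibres are axial: an angle is defined modulo 180 deg
(a fibre has no head or tail).  All circular statistics therefore double
the angles onto the full circle, operate there, and halve back.
"""

from __future__ import annotations

import numpy as np


def wrap_axial(theta_deg):
    """Wrap angles into the axial range [0, 180)."""
    return np.mod(theta_deg, 180.0)


def circ_mean_deg(angles_deg, axial: bool = True) -> float:
    """Circular mean direction in degrees.

    With ``axial=True`` the input is interpreted modulo 180 deg, doubled to
    the full circle for averaging, and the mean halved back to [0, 180).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle array")
    fac = 2.0 if axial else 1.0
    rad = np.deg2rad(a * fac)
    mean = np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())
    out = np.rad2deg(mean) / fac
    return float(np.mod(out, 180.0 if axial else 360.0))


def circ_sd_deg(angles_deg, axial: bool = True) -> float:
    """Circular standard deviation (Mardia), on the axial scale if requested."""
    a = np.asarray(angles_deg, dtype=float)
    fac = 2.0 if axial else 1.0
    rad = np.deg2rad(a * fac)
    R = np.hypot(np.sin(rad).mean(), np.cos(rad).mean())
    R = min(max(R, 1e-300), 1.0)
    sd = np.sqrt(-2.0 * np.log(R))
    return float(np.rad2deg(sd) / fac)


def axial_diff_deg(a_deg: float, b_deg: float) -> float:
    """Signed shortest axial difference ``a - b`` in (-90, 90]."""
    d = (float(a_deg) - float(b_deg)) % 180.0
    if d > 90.0:
        d -= 180.0
    return d
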