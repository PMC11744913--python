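"""Cell-centre annotation with a 3D Gabor spherical-shell kernel.

The kernel is a radially offset Gaussian envelope modulated by a radial
plane wave,

    K(x, y, z) = 1/(2 pi sigma r0) * exp(-pi ((r' - r0)/sigma)^2)
                 * exp(i (2 pi f0 (r' - r0) + phi)),

where ``r'`` is the Euclidean distance from the kernel origin with the z
coordinate stretched by a compression factor to account for the coarser z
sampling of light-sheet data.  Convolving its real part with a somata
channel produces strong local maxima at the centres of hollow, shell-like
cell bodies; maxima above a relative threshold are marked as cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max

from .volume import VolumeStack


@dataclass
class ShellKernel:
    real_part: np.ndarray
    imag_part: np.ndarray
    r0: float
    sigma: float
    f0: float
    phase: float
    z_compression: float


def _radial_profile(r, r0, sigma, f0, phase):
    amp = 1.0 / (2.0 * np.pi * sigma * r0)
    env = np.exp(-np.pi * ((r - r0) / sigma) ** 2)
    return amp * env, 2.0 * np.pi * f0 * (r - r0) + phase


def build_shell_kernel(r0=22.0, sigma=12.0, f0=0.1, phase=3.7,
                       z_compression=2.0, support_sigmas=3.0) -> ShellKernel:
    """Evaluate the complex spherical-shell kernel on an odd 3D grid.

    The grid is cubic in XY with half-width ``r0 + support_sigmas * sigma``
    (the envelope is below 1e-12 there) and its Z extent divided by
    ``z_compression``.
    """
    if r0 <= 0 or sigma <= 0:
        raise ValueError("r0 and sigma must be strictly positive")
    if z_compression < 1:
        raise ValueError("z_compression must be >= 1")
    hw = int(np.ceil(r0 + support_sigmas * sigma))
    hwz = max(1, int(round(hw / z_compression)))
    z, y, x = np.meshgrid(np.arange(-hwz, hwz + 1),
                          np.arange(-hw, hw + 1),
                          np.arange(-hw, hw + 1), indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2 + (z * z_compression) ** 2)
    mag, arg = _radial_profile(r, r0, sigma, f0, phase)
    return ShellKernel(real_part=mag * np.cos(arg), imag_part=mag * np.sin(arg),
                       r0=r0, sigma=sigma, f0=f0, phase=phase,
                       z_compression=z_compression)


def shell_match_radius_px(r0=22.0, sigma=12.0, f0=0.1, phase=3.7):
    """Radius (px) at which the real kernel profile is maximal.

    A bright soma rim at this radius produces a positive, centred response
    under convolution with the real part; useful for building well-posed
    synthetic shells matched to a given kernel.
    """
    rs = np.linspace(max(r0 - 4 * sigma, 0.0), r0 + 4 * sigma, 4001)
    mag, arg = _radial_profile(rs, r0, sigma, f0, phase)
    coarse = rs[np.argmax(mag * np.cos(arg))]
    res = minimize_scalar(
        lambda r: -(lambda m, a: m * np.cos(a))(*_radial_profile(r, r0, sigma, f0, phase)),
        bracket=None, bounds=(max(coarse - 2, 0.01), coarse + 2), method="bounded")
    return float(res.x)


@dataclass
class CellCentres:
    """Annotated 3D cell centres in both physical and voxel coordinates."""

    points_um: np.ndarray                        # (n, 3) as (x, y, z) um
    points_px: np.ndarray                        # (n, 3) as (z, y, x) voxels
    scores: np.ndarray | None = None
    sample_id: str | None = None
    side: str | None = None
    near_border: np.ndarray | None = None

    def __len__(self):
        return len(self.points_um)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points_um, columns=["x_um", "y_um", "z_um"])
        if self.scores is not None:
            df["score"] = self.scores
        if self.near_border is not None:
            df["near_border"] = self.near_border
        return df

    @classmethod
    def from_um(cls, points_um, voxel_size_um, **kw) -> "CellCentres":
        pts = np.atleast_2d(np.asarray(points_um, float))
        vx, vy, vz = voxel_size_um
        px = np.column_stack([pts[:, 2] / vz, pts[:, 1] / vy, pts[:, 0] / vx])
        return cls(points_um=pts, points_px=px, **kw)


def detect_cells(stack: VolumeStack, kernel: ShellKernel,
                 min_distance_um=None, rel_threshold=0.3,
                 channel=0) -> CellCentres:
    """FFT-convolve the real kernel and mark supra-threshold local maxima.

    ``min_distance_um`` is the minimum separation between detections
    (default: the kernel radius in XY, converted to um); it is applied as
    an anisotropic voxel footprint.  Maxima below ``rel_threshold`` times
    the global response maximum are discarded.  Detections closer than the
    kernel half-width to a volume border are flagged ``near_border``.
    """
    vol = stack.channel(channel).astype(float)
    if any(k > s for k, s in zip(kernel.real_part.shape, vol.shape)):
        raise ValueError("kernel larger than the volume")
    vx, vy, vz = stack.voxel_size_um
    if min_distance_um is None:
        min_distance_um = kernel.r0 * vx

    response = fftconvolve(vol, kernel.real_part, mode="same")

    md_px = np.maximum([int(round(min_distance_um / v)) for v in (vz, vy, vx)], 1)
    footprint = np.ones(2 * md_px + 1, dtype=bool)
    peaks = peak_local_max(response, footprint=footprint,
                           threshold_rel=rel_threshold, exclude_border=False)
    scores = response[tuple(peaks.T)] if len(peaks) else np.empty(0)

    hw = np.array([s // 2 for s in kernel.real_part.shape])
    if len(peaks):
        near = np.any((peaks < hw) | (peaks >= np.array(vol.shape) - hw), axis=1)
        um = np.column_stack([peaks[:, 2] * vx, peaks[:, 1] * vy, peaks[:, 0] * vz])
    else:
        near = np.zeros(0, dtype=bool)
        um = np.empty((0, 3))
    return CellCentres(points_um=um, points_px=np.asarray(peaks, float),
                       scores=np.asarray(scores), near_border=near)


def score_detection(detected: CellCentres, truth: CellCentres,
                    match_radius_um=5.0) -> dict:
    """Greedy one-to-one nearest matching of detections to ground truth.

    Returns accuracy (matched / truth), false-positive (unmatched
    detections / detections) and false-negative (unmatched truth / truth)
    rates, in percent.
    """
    t = np.atleast_2d(truth.points_um)
    if t.size == 0:
        raise ValueError("empty ground truth: rates undefined")
    d = np.atleast_2d(detected.points_um)
    if d.size == 0:
        return {"accuracy_pct": 0.0, "false_positive_pct": 0.0,
                "false_negative_pct": 100.0, "n_matched": 0}

    dist = np.linalg.norm(d[:, None, :] - t[None, :, :], axis=2)
    pairs = np.argwhere(dist <= match_radius_um)
    order = np.argsort(dist[tuple(pairs.T)]) if len(pairs) else []
    used_d, used_t = set(), set()
    matched = 0
    for k in order:
        i, j = pairs[k]
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matched += 1
    return {
        "accuracy_pct": 100.0 * matched / len(t),
        "false_positive_pct": 100.0 * (len(d) - matched) / len(d),
        "false_negative_pct": 100.0 * (len(t) - matched) / len(t),
        "n_matched": matched,
    }
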