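"""Structure-tensor orientation analysis of myelin planes.

Local dominant orientations are estimated per 2D plane: the myelin channel
is median- and ridge-filtered and normalised, then the structure tensor
(the window-averaged covariance of image gradients) is evaluated in
non-overlapping 24 x 24 px windows.  Each window yields an orientation

    phi = 1/2 atan2(2 J12, J22 - J11)    (axial, degrees in [0, 180)),

an energy ``E = trace(J)`` (near 0 for homogeneous windows) and a
coherence ``C = (lmax - lmin)/(lmax + lmin)`` in [0, 1] (1 for a single
dominant direction, 0 for isotropic structure).  Windows with ``E * C``
below a gate threshold are rejected.  Orientations are then corrected for
cortical curvature using a quadratic surface fitted to the
autofluorescence channel — the gradient of a distance transform of the
fitted surface gives the local tangent — and assigned to cortical layers
by depth below the surface.  Layer 6 is excluded from analysis (poor
staining contrast at depth).  The analysis is strictly in-plane: the z
sampling is too coarse for 3D tensors.

Angle convention: counter-clockwise from +x with the pia up, so fibres
running along the depth axis (radial) read 90 deg and fibres parallel to
a flat surface read 0 deg.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import median, sato, threshold_otsu

from .volume import VolumeStack

logger = logging.getLogger(__name__)

LAYER_NAMES = ["L1", "L2/3", "L4", "L5", "L6"]
ANALYSED_LAYERS = ["L1", "L2/3", "L4", "L5"]


def preprocess_myelin(plane, median_size=3, sato_sigmas=(1, 2)):
    """Median filter, Sato tubeness (bright ridges), min-max normalise.

    A constant plane has no structure to normalise; it maps to all zeros
    with a warning.
    """
    plane = np.asarray(plane, float)
    if plane.size == 0:
        raise ValueError("empty plane")
    filt = median(plane, footprint=np.ones((median_size, median_size)))
    ridged = sato(filt, sigmas=sato_sigmas, black_ridges=False)
    lo, hi = ridged.min(), ridged.max()
    if hi - lo <= 0:
        warnings.warn("constant plane after filtering; returning zeros")
        return np.zeros_like(ridged)
    return (ridged - lo) / (hi - lo)


def structure_tensor_window(window):
    """Dominant orientation, energy and coherence of one 2D patch.

    Gradients are central differences; J is the plain (unweighted) window
    mean of the gradient products.  Returns ``(phi_deg, E, C)`` with
    ``C = 0`` by convention when ``E = 0``.
    """
    w = np.asarray(window, float)
    if w.shape[0] < 3 or w.shape[1] < 3:
        raise ValueError("window must be at least 3x3")
    gy, gx = np.gradient(w)
    j11 = np.mean(gx * gx)
    j12 = np.mean(gx * gy)
    j22 = np.mean(gy * gy)
    energy = j11 + j22
    phi = 0.5 * np.rad2deg(np.arctan2(2.0 * j12, j22 - j11))
    phi = float(np.mod(phi, 180.0))
    if energy <= 0:
        return phi, 0.0, 0.0
    # (lmax - lmin) = sqrt((J11 - J22)^2 + 4 J12^2); (lmax + lmin) = E
    coherence = float(np.sqrt((j11 - j22) ** 2 + 4.0 * j12 ** 2) / energy)
    return phi, float(energy), min(coherence, 1.0)


def orientation_field(plane, window=24, gate_threshold=None,
                      gate_quantile=0.6, plane_index=0,
                      preprocess=True) -> pd.DataFrame:
    """Orientation records for all non-overlapping windows of one plane.

    The gate is ``E * C >= threshold``; if no absolute ``gate_threshold``
    is given it is set to the ``gate_quantile`` quantile of ``E * C``
    within the plane.  Rejected windows are kept in the table with
    ``retained=False``.
    """
    plane = np.asarray(plane, float)
    ny, nx = plane.shape
    if window > ny or window > nx:
        raise ValueError("window larger than the plane")
    img = preprocess_myelin(plane) if preprocess else plane

    recs = []
    for r0 in range(0, ny - window + 1, window):
        for c0 in range(0, nx - window + 1, window):
            phi, e, c = structure_tensor_window(img[r0:r0 + window,
                                                    c0:c0 + window])
            recs.append((plane_index, r0 + window / 2.0, c0 + window / 2.0,
                         phi, e, c))
    df = pd.DataFrame(recs, columns=["plane", "row", "col", "phi_raw",
                                     "energy", "coherence"])
    gate = df["energy"] * df["coherence"]
    if gate_threshold is None:
        gate_threshold = float(gate.quantile(gate_quantile)) if len(df) else 0.0
    df["retained"] = gate >= gate_threshold
    return df


def fit_cortical_surface(af_plane, blur_px=2.0):
    """Quadratic cortical-surface fit with distance and tangent maps.

    The autofluorescence plane is Otsu-thresholded; the top tissue
    boundary per column is least-squares fitted with
    ``row = a x^2 + b x + c``.  The signed distance (px, positive below
    the surface) to the fitted curve is computed by distance transform,
    and its smoothed gradient yields the local surface-normal direction;
    the tangent is the normal rotated by 90 deg.
    """
    plane = np.asarray(af_plane, float)
    thr = threshold_otsu(plane)
    mask = plane > thr
    if mask.all() or not mask.any():
        raise ValueError("plane is all tissue or all background")
    ny, nx = plane.shape
    cols, rows = [], []
    for x in range(nx):
        hit = np.flatnonzero(mask[:, x])
        if len(hit) and hit[0] > 0:
            i = hit[0]
            v0, v1 = plane[i - 1, x], plane[i, x]
            # sub-pixel crossing of the threshold level
            frac = (thr - v0) / (v1 - v0) if v1 > v0 else 0.5
            cols.append(x)
            rows.append(i - 1 + frac)
        elif len(hit):
            cols.append(x)
            rows.append(0.0)
    if len(cols) < 3:
        raise ValueError("too few boundary points for a quadratic fit")
    coeffs = np.polyfit(cols, rows, 2)          # highest power first
    a, b, c = coeffs

    srow = a * np.arange(nx) ** 2 + b * np.arange(nx) + c
    below = np.arange(ny)[:, None] > srow[None, :]
    dist = (ndimage.distance_transform_edt(below)
            - ndimage.distance_transform_edt(~below))
    smooth = ndimage.gaussian_filter(dist.astype(float), blur_px)
    gy, gx = np.gradient(smooth)
    # visual angle of the inward normal; tangent is normal + 90 deg
    normal_deg = np.mod(np.rad2deg(np.arctan2(-gy, gx)), 180.0)
    tangent_deg = np.mod(normal_deg + 90.0, 180.0)
    return {"coeffs": (float(a), float(b), float(c)),
            "distance_map": dist.astype(float),
            "normal_angle_map": normal_deg,
            "tangent_angle_map": tangent_deg}


def correct_and_layer(field: pd.DataFrame, surface: dict,
                      layer_boundaries_um, pixel_size_um=0.54,
                      drop_l6=True) -> pd.DataFrame:
    """Surface-correct orientations and assign cortical layers.

    ``phi_corrected = (phi_raw - local tangent) mod 180``.  The layer is
    taken from the window centre's depth below the fitted surface against
    ``layer_boundaries_um`` (depths of the L1 top and the bottoms of L1,
    L2/3, L4, L5, L6); a window exactly on a boundary goes to the deeper
    layer.  Windows above the surface or below the deepest boundary are
    dropped, as is L6.
    """
    bounds = np.asarray(layer_boundaries_um, float)
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("layer boundaries must be strictly increasing")
    out = field.copy()
    rr = out["row"].to_numpy().round().astype(int).clip(0, surface["distance_map"].shape[0] - 1)
    cc = out["col"].to_numpy().round().astype(int).clip(0, surface["distance_map"].shape[1] - 1)
    tangent = surface["tangent_angle_map"][rr, cc]
    depth_um = surface["distance_map"][rr, cc] * pixel_size_um
    out["phi_corrected"] = np.mod(out["phi_raw"].to_numpy() - tangent, 180.0)
    out["depth_um"] = depth_um

    inner = bounds[1:-1]
    idx = np.searchsorted(inner, depth_um, side="right")
    labels = np.array(LAYER_NAMES[:len(bounds) - 1], dtype=object)
    out["layer"] = labels[idx]
    keep = (depth_um >= bounds[0]) & (depth_um < bounds[-1])
    n_deep = int((~keep).sum())
    if n_deep:
        logger.info("dropped %d windows outside the layered depth range", n_deep)
    out = out[keep]
    if drop_l6:
        out = out[out["layer"] != "L6"]
    return out.reset_index(drop=True)


def analyse_stack(myelin: VolumeStack, af: VolumeStack, layer_boundaries_um,
                  window=24, gate_threshold=None, gate_quantile=0.6,
                  side=None, sex=None, sample_id=None) -> pd.DataFrame:
    """Full per-plane orientation analysis of a myelin/autofluorescence pair.

    Returns the tidy retained-window table feeding the circular regression:
    one record per retained window with corrected angle, layer and labels.
    """
    vol = myelin.channel(0)
    af_vol = af.channel(0)
    frames = []
    for iz in range(vol.shape[0]):
        field = orientation_field(vol[iz], window=window,
                                  gate_threshold=gate_threshold,
                                  gate_quantile=gate_quantile, plane_index=iz)
        surface = fit_cortical_surface(af_vol[iz])
        frames.append(correct_and_layer(field, surface, layer_boundaries_um,
                                        pixel_size_um=myelin.voxel_size_um[1]))
    df = pd.concat(frames, ignore_index=True)
    df = df[df["retained"]].reset_index(drop=True)
    df["theta_deg"] = df["phi_corrected"]
    df["side"] = side if side is not None else ""
    df["sex"] = sex if sex is not None else ""
    df["sample_id"] = sample_id if sample_id is not None else ""
    return df


def orientation_qc_image(field: pd.DataFrame, plane_shape, window=24):
    """Orientation-coloured RGB QC image (hue = angle, masked where rejected)."""
    from matplotlib import cm
    ny, nx = plane_shape
    img = np.zeros((ny // window, nx // window, 3))
    sub = field[field["plane"] == field["plane"].iloc[0]] if len(field) else field
    for _, rec in sub.iterrows():
        r = int(rec["row"] // window)
        c = int(rec["col"] // window)
        if rec["retained"]:
            img[r, c] = cm.hsv(rec["phi_raw"] / 180.0)[:3]
    return img
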