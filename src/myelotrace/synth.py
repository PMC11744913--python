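"""Synthetic cleared-tissue volumes and circular datasets with ground truth.

The generators emulate the statistical structure the downstream analysis
assumes — microcolumnar somata, predominantly radial myelinated fibres with
per-layer angular offsets, a quadratically curved cortical surface, and
anisotropic light-sheet voxels — and export the exact ground truth used to
render, so every measurement stage can be validated without microscopy data.

Geometry conventions
--------------------
Arrays are ``(z, y, x)``; the cortical surface runs near the top of each
plane (low ``y``/row index) and depth increases with the row index.
Orientations are *axial* angles in degrees on [0, 180), measured
counter-clockwise from the +x axis with the pia "up": a fibre running along
the depth axis (radial) reads 90 deg, a fibre parallel to a flat surface
reads 0 deg.  Truth angles are stored relative to the local surface
tangent, which is the convention the orientation analysis reports in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line_aa

from .volume import DEFAULT_VOXEL_SIZE_UM, VolumeStack

#: Default layer boundaries as fractions of total cortical depth
#: (pia to white matter).  Mouse-cortex-plausible; expert annotation of a
#: given dataset should override these.
DEFAULT_LAYER_FRACTIONS = {
    "L1": (0.0, 0.10),
    "L2/3": (0.10, 0.35),
    "L4": (0.35, 0.50),
    "L5": (0.50, 0.75),
    "L6": (0.75, 1.0),
}


@dataclass
class TissueTruth:
    """Ground truth exported by the volume generators."""

    cell_centres_um: np.ndarray | None = None   # (n, 3) as (x, y, z) um
    column_ids: np.ndarray | None = None
    fibre_segments: list | None = None          # (start_um, end_um, layer)
    fibre_angles_deg: np.ndarray | None = None  # tangent-relative, axial
    fibre_layers: list | None = None
    layer_boundaries_um: list | None = None     # depths of layer boundaries
    surface_coeffs: tuple | None = None         # (a, b, c), row = a x^2+b x+c (px)
    side: str | None = None
    sex: str | None = None
    sample_id: str | None = None

    def save_points_csv(self, path) -> None:
        if self.cell_centres_um is None:
            raise ValueError("no cell centres in truth")
        df = pd.DataFrame(self.cell_centres_um, columns=["x_um", "y_um", "z_um"])
        df["column_id"] = self.column_ids
        df.to_csv(path, index=False)


@dataclass
class Stratum:
    """One design cell of a circular-orientation sampling design."""

    side: str
    mu_deg: float           # axial circular mean, [0, 180)
    kappa: float            # latent mean-vector length (concentration)
    n: int
    layer: str | None = None
    sex: str | None = None
    sample_id: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.mu_deg < 180.0):
            raise ValueError("stratum means must lie in [0, 180)")
        if self.kappa <= 0:
            raise ValueError("spread parameter must be strictly positive")
        if self.n < 1:
            raise ValueError("n per stratum must be >= 1")


@dataclass
class PNGroupDesign:
    """Stratified projected-normal sampling design for orientation data."""

    strata: list
    seed: int = 0


def surface_row(coeffs, x):
    """Surface row (depth in px) at lateral position ``x``: a x^2 + b x + c."""
    a, b, c = coeffs
    return a * np.asarray(x, float) ** 2 + b * np.asarray(x, float) + c


def surface_tangent_deg(coeffs, x):
    """Local surface tangent as an axial visual angle in [0, 180)."""
    a, b, _ = coeffs
    slope = 2.0 * a * np.asarray(x, float) + b
    return np.mod(np.rad2deg(np.arctan2(-slope, 1.0)), 180.0)


def _check_surface_in_frame(coeffs, shape_zyx):
    ny, nx = shape_zyx[-2], shape_zyx[-1]
    rows = surface_row(coeffs, np.arange(nx))
    if rows.min() < 0 or rows.max() >= ny:
        raise ValueError("quadratic surface leaves the frame for the used x-range")


def layer_boundaries_from_fractions(total_depth_um, fractions=None):
    """Boundary depths (um below surface) of L1|L2/3|L4|L5|L6 from fractions."""
    fractions = fractions or DEFAULT_LAYER_FRACTIONS
    edges = sorted({f for lo_hi in fractions.values() for f in lo_hi})
    return [f * total_depth_um for f in edges]


# ---------------------------------------------------------------------------
# somata / microcolumns
# ---------------------------------------------------------------------------

def _render_shells(shape_zyx, centres_px, rim_radius_px, rim_width_px,
                   z_factor, core_amp=0.3):
    """Additively stamp hollow-shell somata (bright rim, dimmer core).

    ``centres_px`` is (n, 3) in (z, y, x) voxel coordinates (floats allowed).
    The shell is isotropic in physical space; its z extent is compressed by
    ``z_factor`` because z voxels are coarser.
    """
    vol = np.zeros(shape_zyx, dtype=float)
    hw_xy = int(np.ceil(rim_radius_px + 3 * rim_width_px))
    hw_z = max(1, int(np.ceil(hw_xy / z_factor)))
    nz, ny, nx = shape_zyx
    for cz, cy, cx in centres_px:
        z0, z1 = int(np.floor(cz)) - hw_z, int(np.floor(cz)) + hw_z + 1
        y0, y1 = int(np.floor(cy)) - hw_xy, int(np.floor(cy)) + hw_xy + 1
        x0, x1 = int(np.floor(cx)) - hw_xy, int(np.floor(cx)) + hw_xy + 1
        zs = np.arange(max(z0, 0), min(z1, nz))
        ys = np.arange(max(y0, 0), min(y1, ny))
        xs = np.arange(max(x0, 0), min(x1, nx))
        if len(zs) == 0 or len(ys) == 0 or len(xs) == 0:
            continue
        dz = (zs - cz)[:, None, None] * z_factor
        dy = (ys - cy)[None, :, None]
        dx = (xs - cx)[None, None, :]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        rim = np.exp(-0.5 * ((r - rim_radius_px) / rim_width_px) ** 2)
        core = core_amp * np.exp(-0.5 * (r / (0.5 * rim_radius_px)) ** 2)
        vol[np.ix_(zs, ys, xs)] += rim + core
    return vol


def gen_cell_volume(shape=(24, 256, 256), spacing_um=6.0, pitch_um=20.0,
                    jitter_um=0.5, cell_radius_um=5.0, snr=10.0,
                    voxel_size_um=DEFAULT_VOXEL_SIZE_UM, z_compression=None,
                    rim_width_um=1.0, background=10.0, read_noise_sd=1.0,
                    margin_um=None, apply_noise=True, seed=0):
    """Render microcolumns of hollow-shell somata with Poisson background.

    Cells are stacked along the depth (y) axis with ``spacing_um``
    intra-column spacing, columns laid out on an (x, z) grid with
    ``pitch_um``, and isotropic Gaussian positional jitter.  ``snr`` scales
    the rim peak relative to the background shot-noise standard deviation;
    ``snr=0`` renders pure background (truth unchanged).

    Returns ``(VolumeStack, TissueTruth)`` with every centre in um.
    """
    if spacing_um <= 0:
        raise ValueError("intra-column spacing must be positive")
    if jitter_um > 0 and spacing_um <= 2.0 * jitter_um:
        raise ValueError("spacing must exceed twice the jitter sd")
    vx, vy, vz = voxel_size_um
    nz, ny, nx = shape
    zf = z_compression if z_compression is not None else vz / vx
    rng = np.random.default_rng(seed)

    if margin_um is None:
        margin_um = cell_radius_um + 3 * rim_width_um
    x_extent, y_extent, z_extent = nx * vx, ny * vy, nz * vz
    xs = np.arange(margin_um, x_extent - margin_um, pitch_um)
    zs = np.arange(margin_um, z_extent - margin_um, pitch_um)
    n_per_col = int((y_extent - 2 * margin_um) // spacing_um) + 1
    if len(xs) == 0 or len(zs) == 0 or n_per_col < 1:
        raise ValueError("shape too small to hold a single microcolumn")

    centres, col_ids = [], []
    cid = 0
    for x0 in xs:
        for z0 in zs:
            ys_um = margin_um + spacing_um * np.arange(n_per_col)
            pts = np.column_stack([
                np.full(n_per_col, x0), ys_um, np.full(n_per_col, z0)])
            if jitter_um > 0:
                pts = pts + rng.normal(0.0, jitter_um, pts.shape)
            centres.append(pts)
            col_ids.append(np.full(n_per_col, cid))
            cid += 1
    centres_um = np.concatenate(centres)
    col_ids = np.concatenate(col_ids)

    centres_px = np.column_stack([
        centres_um[:, 2] / vz, centres_um[:, 1] / vy, centres_um[:, 0] / vx])
    amplitude = snr * np.sqrt(background) if background > 0 else snr
    if amplitude != 0:
        signal = _render_shells(shape, centres_px, cell_radius_um / vx,
                                rim_width_um / vx, zf)
        lam = background + amplitude * signal
    else:
        lam = np.full(shape, float(background))
    if apply_noise:
        data = rng.poisson(lam).astype(float)
        if read_noise_sd > 0:
            data = np.clip(data + rng.normal(0, read_noise_sd, data.shape),
                           0, None)
    else:
        data = lam.astype(float)

    stack = VolumeStack(data=data, voxel_size_um=voxel_size_um,
                        channel_names=["somata"])
    truth = TissueTruth(cell_centres_um=centres_um, column_ids=col_ids)
    return stack, truth


# ---------------------------------------------------------------------------
# myelinated fibres
# ---------------------------------------------------------------------------

@dataclass
class LayerDesign:
    """Per-layer fibre design: tangent-relative angular statistics."""

    name: str
    mean_deg: float          # tangent-relative axial mean, [0, 180)
    sd_deg: float            # angular sd (wrapped normal)
    n_per_plane: int = 60
    width_px: float = 1.0
    length_px: float = 30.0

    def __post_init__(self):
        if not (0.0 <= self.mean_deg < 180.0):
            raise ValueError("layer mean angle must lie in [0, 180)")


def default_fibre_layers(delta_deg=0.0):
    """Radial fibre design: L1 parallel to the surface, L2/3-L5 radial+delta."""
    return [
        LayerDesign("L1", 0.0, 4.0),
        LayerDesign("L2/3", (90.0 + delta_deg) % 180.0, 4.0),
        LayerDesign("L4", (90.0 + delta_deg) % 180.0, 4.0),
        LayerDesign("L5", (90.0 + delta_deg) % 180.0, 4.0),
    ]


def gen_fibre_volume(layers, surface_coeffs=(0.0, 0.0, 10.0),
                     shape=(4, 512, 512), layer_boundaries_um=None,
                     voxel_size_um=DEFAULT_VOXEL_SIZE_UM, snr=20.0,
                     background=5.0, smooth_px=0.7, seed=0,
                     side=None, sex=None, sample_id=None):
    """Render per-layer fibre segments beneath a quadratic cortical surface.

    Each fibre's angle *relative to the local surface tangent* is drawn from
    a wrapped normal with the layer's mean and sd, so the tangent-relative
    truth is invariant to surface curvature by construction.  Segments are
    drawn anti-aliased, in-plane (one plane per fibre), and kept fully
    inside the frame.

    ``layer_boundaries_um`` must have ``len(layers) + 1`` increasing depths
    starting at 0; by default the layer fractions are applied to the depth
    remaining below the surface vertex.
    """
    if not layers:
        raise ValueError("empty layer list")
    _check_surface_in_frame(surface_coeffs, shape)
    vx, vy, _ = voxel_size_um
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)

    if layer_boundaries_um is None:
        depth_um = (ny - 1 - surface_row(surface_coeffs, nx / 2)) * vy
        fr = [DEFAULT_LAYER_FRACTIONS[l.name] for l in layers]
        layer_boundaries_um = [fr[0][0] * depth_um] + [hi * depth_um for _, hi in fr]
    bounds = np.asarray(layer_boundaries_um, float)
    if len(bounds) != len(layers) + 1 or np.any(np.diff(bounds) <= 0):
        raise ValueError("layer boundaries must be increasing, one per layer edge")

    data = np.zeros(shape, dtype=float)
    segments, angles, layer_labels = [], [], []
    for iz in range(nz):
        plane = np.zeros((ny, nx), dtype=float)
        for li, layer in enumerate(layers):
            lo, hi = bounds[li], bounds[li + 1]
            for _ in range(layer.n_per_plane):
                for _attempt in range(50):
                    x0 = rng.uniform(0, nx - 1)
                    depth = rng.uniform(lo, hi)
                    row0 = surface_row(surface_coeffs, x0) + depth / vy
                    psi = rng.normal(layer.mean_deg, layer.sd_deg) % 180.0
                    theta = (surface_tangent_deg(surface_coeffs, x0) + psi) % 180.0
                    t = np.deg2rad(theta)
                    h = layer.length_px / 2.0
                    # visual angle: +x right, y up => row decreases with sin
                    xa, ya = x0 - h * np.cos(t), row0 + h * np.sin(t)
                    xb, yb = x0 + h * np.cos(t), row0 - h * np.sin(t)
                    if (0 <= xa < nx and 0 <= xb < nx
                            and 0 <= ya < ny and 0 <= yb < ny):
                        break
                else:
                    continue
                rr, cc, val = line_aa(int(round(ya)), int(round(xa)),
                                      int(round(yb)), int(round(xb)))
                keep = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
                plane[rr[keep], cc[keep]] += val[keep]
                segments.append(((xa * vx, ya * vy, iz * voxel_size_um[2]),
                                 (xb * vx, yb * vy, iz * voxel_size_um[2]),
                                 layer.name))
                angles.append(psi)
                layer_labels.append(layer.name)
        if smooth_px > 0:
            plane = ndimage.gaussian_filter(plane, smooth_px)
        data[iz] = plane

    amplitude = snr * np.sqrt(background)
    lam = background + amplitude * data
    noisy = rng.poisson(np.clip(lam, 0, None)).astype(float)
    stack = VolumeStack(data=noisy, voxel_size_um=voxel_size_um,
                        channel_names=["myelin"])
    truth = TissueTruth(fibre_segments=segments,
                        fibre_angles_deg=np.asarray(angles),
                        fibre_layers=layer_labels,
                        layer_boundaries_um=list(bounds),
                        surface_coeffs=tuple(surface_coeffs),
                        side=side, sex=sex, sample_id=sample_id)
    return stack, truth


def gen_af_surface(surface_coeffs, shape=(4, 512, 512), blur=2.0,
                   voxel_size_um=DEFAULT_VOXEL_SIZE_UM):
    """Autofluorescence-like channel: bright tissue below a quadratic surface.

    Every plane carries a smooth intensity step across the curve
    ``row = a x^2 + b x + c`` (tissue bright, background dark).
    """
    _check_surface_in_frame(surface_coeffs, shape)
    nz, ny, nx = shape
    rows = np.arange(ny)[:, None]
    srow = surface_row(surface_coeffs, np.arange(nx))[None, :]
    # anti-aliased step: pixel intensity = fraction of the pixel below the
    # curve, so the 50% level crosses exactly at the surface
    plane = np.clip(rows + 0.5 - srow, 0.0, 1.0)
    if blur > 0:
        plane = ndimage.gaussian_filter(plane, blur)
    data = np.repeat(plane[None, :, :], nz, axis=0)
    return VolumeStack(data=data, voxel_size_um=voxel_size_um,
                       channel_names=["autofluorescence"])


# ---------------------------------------------------------------------------
# direct circular sampling (projected-normal group designs)
# ---------------------------------------------------------------------------

#: Reported pooled per-side mean orientations (degrees), side-only model.
MODEL1_SIDE_MEANS = {"L": 90.9, "R": 90.2}

#: Reported per-(side, layer) mean orientations, side+layer model.
MODEL2_CELL_MEANS = {("L", "L2/3"): 90.1, ("R", "L2/3"): 89.0,
                     ("L", "L4"): 90.9, ("R", "L4"): 90.2,
                     ("L", "L5"): 91.4, ("R", "L5"): 90.8}

#: Reported 95% HPD widths per cell (degrees): the dominant-direction
#: dispersion is wider in L2/3 than in L4/L5.  Stratum concentrations are
#: taken inversely proportional to these widths.
MODEL2_HPD_WIDTHS = {("L", "L2/3"): 1.3, ("R", "L2/3"): 1.2,
                     ("L", "L4"): 0.7, ("R", "L4"): 0.7,
                     ("L", "L5"): 0.7, ("R", "L5"): 0.6}

#: Reported per-side means split by sex (side-only model per sex group).
SEX_SIDE_MEANS = {"M": {"L": 90.5, "R": 87.8},
                  "F": {"L": 91.2, "R": 92.0}}


def side_only_design(n_per_side=10000, kappa=10.0, seed=0,
                     means=None) -> PNGroupDesign:
    """Two-stratum L/R design at the pooled study means (overridable)."""
    means = means or MODEL1_SIDE_MEANS
    strata = [Stratum(side, mu, kappa, n_per_side)
              for side, mu in means.items()]
    return PNGroupDesign(strata, seed)


def _additive_cell_concentrations(means, anchor_widths, scale=7.0):
    """Latent mean-vector lengths of the exact additive parameterisation.

    The side+layer regression is additive in the latent bivariate space.
    Its 8 free parameters can represent the six per-cell mean directions
    exactly, with a two-parameter family of solutions; anchoring the two
    L2/3 lengths at ``scale / width`` (widths from the reported L2/3 HPD
    intervals, the most dispersed stratum) picks one member.  Simulating
    with these cell concentrations makes the generating process a member
    of the fitted model family, so the fit recovers the injected
    per-layer differences without representation bias.
    """
    def unit(a):
        return np.array([np.cos(np.deg2rad(2 * a)), np.sin(np.deg2rad(2 * a))])

    def cross(a, b):
        return a[0] * b[1] - a[1] * b[0]

    base = [k for k in means if k[1] == "L2/3"]
    (l_key,) = [k for k in base if k[0] == "L"]
    (r_key,) = [k for k in base if k[0] == "R"]
    t_l = scale / anchor_widths[l_key]
    t_r = scale / anchor_widths[r_key]
    intercept = t_l * unit(means[l_key])
    side_vec = t_r * unit(means[r_key]) - intercept

    lengths = {l_key: t_l, r_key: t_r}
    for lay in sorted({k[1] for k in means} - {"L2/3"}):
        a_l, a_r = means[("L", lay)], means[("R", lay)]
        # t * u(a_l) + side_vec must point along u(a_r)
        t = -cross(side_vec, unit(a_r)) / cross(unit(a_l), unit(a_r))
        vec = t * unit(a_l) + side_vec
        if t <= 0 or vec @ unit(a_r) <= 0:
            raise ValueError(f"no valid additive solution for layer {lay}")
        lengths[("L", lay)] = t
        lengths[("R", lay)] = float(np.linalg.norm(vec))
    return lengths


def side_layer_design(n_per_cell=10000, concentration_scale=7.0,
                      seed=0) -> PNGroupDesign:
    """Six-cell (side x layer) design at the per-layer study means.

    Cell concentrations come from the exact additive latent
    parameterisation anchored at the reported L2/3 HPD widths (see
    :func:`_additive_cell_concentrations`); L2/3 remains the most
    dispersed stratum, as reported.
    """
    lengths = _additive_cell_concentrations(MODEL2_CELL_MEANS,
                                            MODEL2_HPD_WIDTHS,
                                            concentration_scale)
    strata = [Stratum(key[0], mu, lengths[key], n_per_cell, layer=key[1])
              for key, mu in MODEL2_CELL_MEANS.items()]
    return PNGroupDesign(strata, seed)


def sex_split_design(sex, n_per_side=10000, kappa=10.0,
                     seed=0) -> PNGroupDesign:
    """L/R design at the per-sex study means (``sex`` in {'M', 'F'})."""
    strata = [Stratum(side, mu, kappa, n_per_side, sex=sex)
              for side, mu in SEX_SIDE_MEANS[sex].items()]
    return PNGroupDesign(strata, seed)

def gen_orientation_samples(design: PNGroupDesign) -> pd.DataFrame:
    """Draw axial angles per stratum from projected-normal group models.

    Axial angles are mapped to the full circle by doubling: the latent
    bivariate normal has mean ``kappa * (cos 2mu, sin 2mu)`` and identity
    covariance; the observed angle is the latent vector's direction halved
    back to [0, 180).  Large ``kappa`` concentrates the draws (angular sd
    about ``1/(2 kappa)`` radians on the axial scale).

    Returns a tidy frame with columns ``theta_deg, side, layer, sex,
    sample_id``.
    """
    rng = np.random.default_rng(design.seed)
    frames = []
    for s in design.strata:
        if not isinstance(s, Stratum):
            s = Stratum(**s)
        mu2 = np.deg2rad(2.0 * s.mu_deg)
        mean_vec = s.kappa * np.array([np.cos(mu2), np.sin(mu2)])
        y = rng.normal(size=(s.n, 2)) + mean_vec
        theta2 = np.mod(np.arctan2(y[:, 1], y[:, 0]), 2 * np.pi)
        theta = np.rad2deg(theta2) / 2.0
        frames.append(pd.DataFrame({
            "theta_deg": theta,
            "side": s.side,
            "layer": s.layer if s.layer is not None else "",
            "sex": s.sex if s.sex is not None else "",
            "sample_id": s.sample_id if s.sample_id is not None else "",
        }))
    return pd.concat(frames, ignore_index=True)
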