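"""Analytic deforming-LV phantom.

The phantom is a cylindrical annulus (one geometry per short-axis slice)
whose midwall circumference shortens with a prescribed per-sector peak
amplitude and timing delay.  Motion is purely radial:

* the local shortening fraction ``s(theta, t)`` is a smoothed piecewise-
  constant sector profile times a raised-cosine activation pulse peaking
  at the aortic-valve-closure time plus the sector delay;
* the midwall radius maps as ``R_m = r_m (1 - s)`` and every other radius
  follows the area-preserving rule ``R² = r² - r_m² + R_m²``, so the wall
  thickens as the cavity shrinks and annulus area is conserved per ray.

Because the map is radial with a closed-form inverse, tagged images can be
rendered exactly by pulling each deformed pixel back to its reference
position, and ground-truth circumferential shortening (csh) is available
by numeric arc-length integration of the deformed midwall contour.

Intensities: inside the deformed myocardium a 1-1 SPAMM pattern
``baseline (1 + cos(2π e·X / tag_spacing)) / 2`` evaluated at the
reference position X; background is zero; Gaussian noise is added per
frame.  Tissue maps (T2w, LGE) use crisp angular arcs at end-diastole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    N_SECTORS,
    SECTOR_WIDTH_DEG,
    PhantomConfig,
    arc_contains,
    arc_width,
    wrap_angle_deg,
)
from .errors import ValidationError

_BLEND_HALF_WIDTH_DEG = 4.0  # smoothstep half-width at sector boundaries
_MAX_SHORTENING = 0.95


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def unit_vector(theta_deg):
    """(row, col) unit vector for angle(s) in degrees (0° = up, clockwise)."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    return np.stack([-np.cos(th), np.sin(th)], axis=-1)


def position_angle(drow, dcol):
    """Angle in [0, 360) of an offset from the LV center, (row, col) mm."""
    return wrap_angle_deg(np.rad2deg(np.arctan2(dcol, -np.asarray(drow, dtype=float))))


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def sector_profile(theta_deg, values, half_width: float = _BLEND_HALF_WIDTH_DEG):
    """Piecewise-constant per-sector values, smoothstep-blended at boundaries.

    Continuity in angle (periodic) is required by the motion model; the
    blend zone is narrow (±4°) so sector-mean values stay close to the
    configured per-sector values.
    """
    theta = wrap_angle_deg(theta_deg)
    values = np.asarray(values, dtype=float)
    idx = np.floor(theta / SECTOR_WIDTH_DEG).astype(int) % N_SECTORS
    local = theta - idx * SECTOR_WIDTH_DEG
    out = values[idx]
    # blend with previous sector near the lower boundary
    lo = local < half_width
    u = (local + half_width) / (2.0 * half_width)
    prev = values[(idx - 1) % N_SECTORS]
    out = np.where(lo, prev + _smoothstep(u) * (values[idx] - prev), out)
    # blend with next sector near the upper boundary
    hi = local > SECTOR_WIDTH_DEG - half_width
    u = (local - (SECTOR_WIDTH_DEG - half_width)) / (2.0 * half_width)
    nxt = values[(idx + 1) % N_SECTORS]
    out = np.where(hi, values[idx] + _smoothstep(u) * (nxt - values[idx]), out)
    return out


def smooth_arc_indicator(theta_deg, arc, half_width: float = _BLEND_HALF_WIDTH_DEG):
    """Indicator of an angular arc with smoothstep edges (for motion only).

    Edges are blended over ±``half_width`` of signed angular distance from
    each boundary; suitable for arc widths between ~2*half_width and
    ~360-2*half_width.
    """
    w = arc_width(arc)
    if w <= 0.0:
        return np.zeros(np.shape(theta_deg))
    if w >= 360.0:
        return np.ones(np.shape(theta_deg))
    theta = np.asarray(theta_deg, dtype=float)
    d_start = np.mod(theta - arc[0] + 180.0, 360.0) - 180.0   # signed distance past start
    d_end = np.mod(theta - (arc[0] + w) + 180.0, 360.0) - 180.0  # signed distance past end
    rise = _smoothstep((d_start + half_width) / (2.0 * half_width))
    fall = 1.0 - _smoothstep((d_end + half_width) / (2.0 * half_width))
    return np.clip(rise * fall, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Motion model
# ---------------------------------------------------------------------------

def activation_pulse(tau_ms, peak_ms):
    """Raised-cosine pulse: 0 at tau<=0, 1 at tau=peak, 0 at tau>=2*peak."""
    tau = np.asarray(tau_ms, dtype=float)
    if peak_ms <= 0.0:
        return np.zeros_like(tau)
    inside = (tau > 0.0) & (tau < 2.0 * peak_ms)
    return np.where(inside, 0.5 * (1.0 - np.cos(np.pi * tau / peak_ms)), 0.0)


def shortening_fraction(config: PhantomConfig, theta_deg, t_ms):
    """Local midwall shortening fraction s(theta, t) in [0, 0.95].

    The pulse for a sector with delay d is the zero-delay pulse shifted by
    d ms, so delayed sectors trace the same csh curve shifted in time.
    """
    amp = sector_profile(theta_deg, np.asarray(config.sector_amplitudes) / 100.0)
    delay = sector_profile(theta_deg, config.sector_delays)
    s = amp * activation_pulse(np.asarray(t_ms, dtype=float) - delay, config.avc_time)
    if config.post_systolic_fraction > 0.0 and arc_width(config.necrosis_arc) > 0.0:
        ps = (config.post_systolic_fraction * amp
              * smooth_arc_indicator(theta_deg, config.necrosis_arc)
              * activation_pulse(np.asarray(t_ms, dtype=float) - delay - config.post_systolic_lag,
                                 config.avc_time))
        s = s + ps
    return np.clip(s, 0.0, _MAX_SHORTENING)


_ANGLE_GRID_N = 1440  # quadrature/interpolation resolution for the angle remap


def mean_shortening(config: PhantomConfig, t_ms) -> float:
    """Circumference-averaged shortening fraction at time t."""
    theta = np.arange(_ANGLE_GRID_N) * (360.0 / _ANGLE_GRID_N)
    return float(shortening_fraction(config, theta, t_ms).mean())


def _angle_map_table(config: PhantomConfig, t_ms):
    """Tabulated deformed angle phi(theta) and the mean shortening.

    The midwall deforms as a circle of radius ``r_m (1 - s̄(t))`` with a
    tangential angle remap ``dphi/dtheta = (1 - s(theta,t)) / (1 - s̄(t))``
    so that the *local* material arc element shortens exactly by
    ``s(theta, t)``.  The remap is offset so the mean of phi - theta is
    zero (no net rotation).
    """
    n = _ANGLE_GRID_N
    theta = np.arange(n + 1) * (360.0 / n)
    s = shortening_fraction(config, theta, t_ms)
    sbar = float(np.mean(s[:-1]))
    dphi = (1.0 - s) / (1.0 - sbar)
    # trapezoidal cumulative integral of dphi over theta
    step = 360.0 / n
    phi = np.concatenate([[0.0], np.cumsum(0.5 * (dphi[1:] + dphi[:-1]) * step)])
    phi = phi * (360.0 / phi[-1])          # exact periodic closure
    phi = phi + (theta.mean() - phi.mean())  # zero-mean tangential offset
    return theta, phi, sbar


def deformed_angle(config: PhantomConfig, theta_deg, t_ms):
    """Deformed angle phi of the material ray at reference angle theta."""
    theta_g, phi_g, _ = _angle_map_table(config, t_ms)
    th = wrap_angle_deg(theta_deg)
    return wrap_angle_deg(np.interp(th, theta_g, phi_g))


def reference_angle(config: PhantomConfig, phi_deg, t_ms):
    """Inverse of :func:`deformed_angle` (phi is strictly increasing in theta)."""
    theta_g, phi_g, _ = _angle_map_table(config, t_ms)
    q = phi_g[0] + np.mod(np.asarray(phi_deg, dtype=float) - phi_g[0], 360.0)
    return wrap_angle_deg(np.interp(q, phi_g, theta_g))


def deformed_radius(config: PhantomConfig, radius_mm, t_ms):
    """Radius at time t of the material circle at reference radius r.

    Radial motion is uniform in angle and conserves annulus area exactly:
    ``R² = r² - r_m² + R_m²`` with ``R_m = r_m (1 - s̄(t))``.
    """
    r = np.asarray(radius_mm, dtype=float)
    rm = config.midwall_radius
    Rm = rm * (1.0 - mean_shortening(config, t_ms))
    return np.sqrt(np.clip(r * r - rm * rm + Rm * Rm, 0.0, None))


def reference_radius(config: PhantomConfig, radius_mm, t_ms):
    """Inverse of :func:`deformed_radius` (closed form)."""
    R = np.asarray(radius_mm, dtype=float)
    rm = config.midwall_radius
    Rm = rm * (1.0 - mean_shortening(config, t_ms))
    return np.sqrt(np.clip(R * R + rm * rm - Rm * Rm, 0.0, None))


def motion_displacement(config: PhantomConfig, angle_deg, radius_mm, frame: int):
    """Displacement (row, col) mm of the reference point (angle, radius) at a frame.

    Angles outside [0, 360) are wrapped.  Frame 0 returns zero displacement
    identically (end-diastole is the reference).
    """
    if not 0 <= frame < config.n_frames:
        raise ValidationError("frame out of range")
    t = frame * config.frame_interval
    theta = wrap_angle_deg(angle_deg)
    r = np.asarray(radius_mm, dtype=float)
    R = deformed_radius(config, r, t)
    phi = deformed_angle(config, theta, t)
    new = np.asarray(R)[..., None] * unit_vector(phi)
    old = r[..., None] * unit_vector(theta)
    return new - old


# ---------------------------------------------------------------------------
# Ground-truth circumferential shortening
# ---------------------------------------------------------------------------

def ground_truth_csh(config: PhantomConfig, n_theta: int = 3600) -> np.ndarray:
    """Per-sector csh (%) of the analytic midwall contour, shape (6, n_frames).

    Computed by dense polyline integration of the deformed midwall arc
    length; segments are assigned to the sector containing their angular
    midpoint, so sector arcs tile the circumference.  Identical for every
    slice (the phantom has no through-plane variation).
    """
    theta = (np.arange(n_theta) + 0.5) * (360.0 / n_theta)
    rm = config.midwall_radius
    seg_sector = (np.floor(wrap_angle_deg(theta + 180.0 / n_theta) / SECTOR_WIDTH_DEG)
                  .astype(int) % N_SECTORS)
    csh = np.zeros((N_SECTORS, config.n_frames))
    L0 = None
    for f in range(config.n_frames):
        t = f * config.frame_interval
        Rm = rm * (1.0 - mean_shortening(config, t))
        pts = Rm * unit_vector(deformed_angle(config, theta, t))
        seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        L = np.bincount(seg_sector, weights=seg, minlength=N_SECTORS)
        if f == 0:
            L0 = L
        csh[:, f] = 100.0 * (L0 - L) / L0
    return csh


# ---------------------------------------------------------------------------
# Tagged-image rendering
# ---------------------------------------------------------------------------

@dataclass
class TaggedSeries:
    """One slice's cine stack for one tag direction."""

    images: np.ndarray            # (n_frames, rows, cols)
    pixel_spacing: float          # mm
    frame_times: np.ndarray       # ms, strictly increasing
    tag_direction: tuple          # unit 2-vector, (row, col)
    tag_spacing: float            # mm
    slice_index: int = 0

    def __post_init__(self):
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")


def _grid_mm(config: PhantomConfig, center_offset_mm=(0.0, 0.0)):
    """Row/col offsets (mm) of every pixel center from the LV center."""
    coords = np.arange(config.grid_size) * config.pixel_spacing
    cr, cc = config.center_mm
    drow = coords[:, None] - (cr + center_offset_mm[0])
    dcol = coords[None, :] - (cc + center_offset_mm[1])
    return np.broadcast_arrays(drow, dcol)


def render_tagged_frame(config: PhantomConfig, frame: int, tag_direction,
                        center_offset_mm=(0.0, 0.0)) -> np.ndarray:
    """Noise-free tagged image of one frame (any slice; slices are identical).

    ``center_offset_mm`` rigidly translates the whole phantom — tag pattern
    and myocardium together — which is useful for known-shift validation.
    """
    if config.tag_spacing <= 2.0 * config.pixel_spacing:
        raise ValidationError("tags unresolvable: tag_spacing must exceed 2 x pixel_spacing")
    e = np.asarray(tag_direction, dtype=float)
    t = frame * config.frame_interval
    drow, dcol = _grid_mm(config, center_offset_mm)
    R = np.hypot(drow, dcol)
    phi = position_angle(drow, dcol)
    refR = reference_radius(config, R, t)
    inside = (refR >= config.endo_radius) & (refR <= config.epi_radius)
    # reference position of the material point now at this pixel
    theta_ref = reference_angle(config, phi, t)
    u = unit_vector(theta_ref)
    phase = 2.0 * np.pi * (refR * (u @ e)) / config.tag_spacing
    baseline = config.signal_levels.remote_mean
    if config.tag_fading > 0.0:
        cycle = config.n_frames * config.frame_interval
        baseline = baseline * max(0.0, 1.0 - config.tag_fading * t / cycle)
    img = np.where(inside, baseline * 0.5 * (1.0 + np.cos(phase)), 0.0)
    return img


def render_tagged_series(config: PhantomConfig, slice_index: int,
                         tag_direction) -> TaggedSeries:
    """Render the full cine for one slice and one configured tag direction."""
    config.validate()
    dirs = [tuple(d) for d in config.tag_directions]
    e = tuple(float(x) for x in tag_direction)
    if e not in dirs:
        raise ValidationError("tag_direction is not one of config.tag_directions")
    if not 0 <= slice_index < config.n_slices:
        raise ValidationError("slice_index out of range")
    frames = np.stack([render_tagged_frame(config, f, e) for f in range(config.n_frames)])
    if config.noise_sd > 0.0:
        rng = np.random.default_rng([config.seed, 101, slice_index, dirs.index(e)])
        frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
    return TaggedSeries(images=frames, pixel_spacing=config.pixel_spacing,
                        frame_times=config.frame_times, tag_direction=e,
                        tag_spacing=config.tag_spacing, slice_index=slice_index)


# ---------------------------------------------------------------------------
# Cine masks (stand-in for manually delineated endo/epi borders)
# ---------------------------------------------------------------------------

@dataclass
class CineMasks:
    """Binary masks of the deforming annulus, (n_slices, n_frames, rows, cols)."""

    endo: np.ndarray   # cavity discs
    epi: np.ndarray    # full epicardial discs
    pixel_spacing: float
    frame_times: np.ndarray

    @property
    def myocardium(self) -> np.ndarray:
        return self.epi & ~self.endo


def render_cine_masks(config: PhantomConfig) -> CineMasks:
    config.validate()
    drow, dcol = _grid_mm(config)
    R = np.hypot(drow, dcol)
    endo = np.empty((config.n_frames,) + R.shape, dtype=bool)
    epi = np.empty_like(endo)
    for f in range(config.n_frames):
        t = f * config.frame_interval
        endo[f] = R < deformed_radius(config, config.endo_radius, t)
        epi[f] = R <= deformed_radius(config, config.epi_radius, t)
    endo = np.broadcast_to(endo, (config.n_slices,) + endo.shape).copy()
    epi = np.broadcast_to(epi, (config.n_slices,) + epi.shape).copy()
    return CineMasks(endo=endo, epi=epi, pixel_spacing=config.pixel_spacing,
                     frame_times=config.frame_times)


# ---------------------------------------------------------------------------
# Tissue maps (T2w edema, LGE necrosis)
# ---------------------------------------------------------------------------

@dataclass
class TissueStudy:
    """Static tissue-contrast study rendered at end-diastole."""

    t2w_slices: np.ndarray        # (3, rows, cols)
    t2w_slice_indices: tuple
    lge_slices: np.ndarray        # (n_slices, rows, cols)
    myocardial_mask: np.ndarray   # (rows, cols), annular, shared by all slices
    remote_roi: np.ndarray        # (rows, cols), within remote myocardium
    pixel_spacing: float
    slice_thickness: float
    slice_positions: np.ndarray   # mm
    edema_arc: tuple = (0.0, 0.0)
    necrosis_arc: tuple = (0.0, 0.0)


def render_tissue_maps(config: PhantomConfig) -> TissueStudy:
    """Render T2w (3 slices) and LGE (full stack) with crisp tissue arcs.

    Pixels are classified by the angle of their center; edema on T2w and
    necrosis on LGE are transmural.  The remote ROI is a 60°-wide annular
    arc diametrically opposite the edema center (shrunk if the edema arc
    leaves less room), guaranteed disjoint from both lesion arcs.
    """
    config.validate()
    drow, dcol = _grid_mm(config)
    R = np.hypot(drow, dcol)
    theta = position_angle(drow, dcol)
    myo = (R >= config.endo_radius) & (R <= config.epi_radius)
    sl = config.signal_levels
    rng = np.random.default_rng([config.seed, 202])

    def _render(arc, lesion_mean, n_images, stream):
        in_arc = arc_contains(theta, arc) & myo if arc_width(arc) > 0 else np.zeros_like(myo)
        base = np.where(in_arc, lesion_mean, sl.remote_mean)
        out = np.zeros((n_images,) + myo.shape)
        for i in range(n_images):
            img = np.where(myo, base, 0.0)
            if sl.remote_sd > 0:
                img = img + np.where(myo, rng.normal(0.0, sl.remote_sd, size=myo.shape), 0.0)
            if config.noise_sd > 0:
                img = img + rng.normal(0.0, config.noise_sd, size=myo.shape)
            out[i] = img
        return out

    t2w_idx = (1, config.n_slices // 2, config.n_slices - 2)
    t2w = _render(config.edema_arc, sl.edema_mean, 3, 0)
    lge = _render(config.necrosis_arc, sl.necrosis_mean, config.n_slices, 1)

    ew = arc_width(config.edema_arc)
    gap = 360.0 - ew
    roi_width = min(60.0, max(gap - 10.0, 0.0))
    center = wrap_angle_deg(config.edema_arc[0] + ew / 2.0 + 180.0)
    roi_arc = (wrap_angle_deg(center - roi_width / 2.0), wrap_angle_deg(center + roi_width / 2.0))
    remote_roi = myo & arc_contains(theta, roi_arc) & ~arc_contains(theta, config.edema_arc)
    if remote_roi.sum() < 20:
        raise ValidationError("remote ROI too small: edema arc leaves no remote tissue")

    positions = np.arange(config.n_slices) * (config.slice_thickness + config.slice_gap)
    return TissueStudy(t2w_slices=t2w, t2w_slice_indices=t2w_idx, lge_slices=lge,
                       myocardial_mask=myo, remote_roi=remote_roi,
                       pixel_spacing=config.pixel_spacing,
                       slice_thickness=config.slice_thickness,
                       slice_positions=positions,
                       edema_arc=tuple(config.edema_arc),
                       necrosis_arc=tuple(config.necrosis_arc))
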