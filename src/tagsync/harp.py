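"""Harmonic-phase (HARP) analysis of tagged images.

A SPAMM tag pattern modulates tissue magnetization sinusoidally, so its
Fourier spectrum carries harmonic peaks at ±1/tag_spacing along the tag
direction.  Isolating the +1 harmonic with a band-pass filter and inverse
transforming yields a complex image whose phase is a material property of
the underlying tissue: a point keeps its harmonic phase as it moves.  With
two tag directions the pair of phases is (locally) a coordinate system, so
a landmark can be tracked frame-to-frame by solving the two wrapped
phase-matching equations with Newton iteration.

All phase arithmetic is routed through :func:`wrap_phase`, which maps into
(-pi, pi]; complex harmonic images are interpolated bilinearly (real and
imaginary parts), never their wrapped phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrackingError, ValidationError
from .phantom import TaggedSeries

DEFAULT_FILTER_FRACTION = 0.4   # band-pass radius as a fraction of 1/tag_spacing
DEFAULT_MAGNITUDE_FLOOR = 0.05  # of the slice maximum harmonic magnitude
NEWTON_TOL_PX = 0.01
NEWTON_MAX_ITER = 20


def wrap_phase(phi):
    """Wrap phase(s) into (-pi, pi]."""
    w = np.mod(np.asarray(phi, dtype=float), 2.0 * np.pi)
    return np.where(w > np.pi, w - 2.0 * np.pi, w)


@dataclass
class HarmonicImage:
    """Complex first-harmonic image of one tagged frame."""

    data: np.ndarray              # complex, (rows, cols)
    tag_direction: tuple          # unit 2-vector (row, col)
    tag_frequency: float          # cycles/mm
    filter_center: tuple          # cycles/mm, (row, col)
    filter_radius: float          # cycles/mm
    pixel_spacing: float          # mm

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase in (-pi, pi]."""
        return wrap_phase(np.angle(self.data))


def isolate_harmonic(frame: np.ndarray, tag_direction, tag_spacing: float,
                     pixel_spacing: float,
                     filter_radius: float | None = None) -> HarmonicImage:
    """Band-pass the +1 tag harmonic and return the complex harmonic image.

    The filter is a circularly symmetric raised-cosine window of radius
    ``filter_radius`` (default 0.4/tag_spacing) centered on the harmonic
    peak at ``tag_direction/tag_spacing`` cycles/mm; it must not reach DC.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValidationError("isolate_harmonic expects a 2D image")
    e = np.asarray(tag_direction, dtype=float)
    f0 = 1.0 / tag_spacing
    if filter_radius is None:
        filter_radius = DEFAULT_FILTER_FRACTION * f0
    if filter_radius >= f0:
        raise ValidationError("filter overlaps DC")
    krow = np.fft.fftfreq(frame.shape[0], d=pixel_spacing)
    kcol = np.fft.fftfreq(frame.shape[1], d=pixel_spacing)
    kr, kc = np.meshgrid(krow, kcol, indexing="ij")
    center = e * f0
    dist = np.hypot(kr - center[0], kc - center[1])
    window = np.where(dist < filter_radius,
                      0.5 * (1.0 + np.cos(np.pi * dist / filter_radius)), 0.0)
    harmonic = np.fft.ifft2(np.fft.fft2(frame) * window)
    return HarmonicImage(data=harmonic, tag_direction=tuple(e),
                         tag_frequency=f0, filter_center=tuple(center),
                         filter_radius=filter_radius, pixel_spacing=pixel_spacing)


# ---------------------------------------------------------------------------
# Interpolation and Newton phase tracking
# ---------------------------------------------------------------------------

def _bilinear(im: np.ndarray, pts_px: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a (possibly complex) image at (N, 2) pixel coords."""
    h, w = im.shape
    r = np.clip(pts_px[:, 0], 0.0, h - 1.0)
    c = np.clip(pts_px[:, 1], 0.0, w - 1.0)
    r0 = np.clip(np.floor(r).astype(int), 0, h - 2)
    c0 = np.clip(np.floor(c).astype(int), 0, w - 2)
    fr = r - r0
    fc = c - c0
    return ((1 - fr) * (1 - fc) * im[r0, c0] + (1 - fr) * fc * im[r0, c0 + 1]
            + fr * (1 - fc) * im[r0 + 1, c0] + fr * fc * im[r0 + 1, c0 + 1])


def _phase_at(h: HarmonicImage, pts_px: np.ndarray) -> np.ndarray:
    return np.angle(_bilinear(h.data, pts_px))


def track_points(pair_f, pair_g, points_mm: np.ndarray,
                 magnitude_floor: float = DEFAULT_MAGNITUDE_FLOOR):
    """Track several landmarks from frame f to frame g=f+1 simultaneously.

    Parameters
    ----------
    pair_f, pair_g : (HarmonicImage, HarmonicImage)
        The two tag-direction harmonics at the source and target frames.
    points_mm : (N, 2) array
        Landmark positions (row, col) in mm at frame f.
    magnitude_floor : float
        Minimum harmonic magnitude at the source point, as a fraction of
        the slice maximum; below it a point is a signal void.

    Returns
    -------
    new_points_mm : (N, 2) array (NaN where tracking failed)
    status : (N,) array of strings, "ok", "signal void" or "tracking diverged"
    """
    h1f, h2f = pair_f
    h1g, h2g = pair_g
    sp = h1f.pixel_spacing
    tag_spacing_px = 1.0 / (h1f.tag_frequency * sp)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) / sp
    n = pts.shape[0]
    status = np.array(["ok"] * n, dtype=object)

    floor1 = magnitude_floor * np.abs(h1f.data).max()
    floor2 = magnitude_floor * np.abs(h2f.data).max()
    void = (np.abs(_bilinear(h1f.data, pts)) < floor1) | (np.abs(_bilinear(h2f.data, pts)) < floor2)
    status[void] = "signal void"

    target1 = _phase_at(h1f, pts)
    target2 = _phase_at(h2f, pts)
    cur = pts.copy()
    active = ~void
    delta = 0.5  # px, finite-difference step for the wrapped-phase gradient
    for _ in range(NEWTON_MAX_ITER):
        if not active.any():
            break
        idx = np.where(active)[0]
        p = cur[idx]
        f1 = wrap_phase(_phase_at(h1g, p) - target1[idx])
        f2 = wrap_phase(_phase_at(h2g, p) - target2[idx])
        # wrapped central differences of the target-frame phases
        dr = np.array([[delta, 0.0]])
        dc = np.array([[0.0, delta]])
        j11 = wrap_phase(_phase_at(h1g, p + dr) - _phase_at(h1g, p - dr)) / (2 * delta)
        j12 = wrap_phase(_phase_at(h1g, p + dc) - _phase_at(h1g, p - dc)) / (2 * delta)
        j21 = wrap_phase(_phase_at(h2g, p + dr) - _phase_at(h2g, p - dr)) / (2 * delta)
        j22 = wrap_phase(_phase_at(h2g, p + dc) - _phase_at(h2g, p - dc)) / (2 * delta)
        det = j11 * j22 - j12 * j21
        bad = np.abs(det) < 1e-12
        det = np.where(bad, 1.0, det)
        step_r = -(j22 * f1 - j12 * f2) / det
        step_c = -(-j21 * f1 + j11 * f2) / det
        step_r = np.where(bad, 0.0, step_r)
        step_c = np.where(bad, 0.0, step_c)
        cur[idx, 0] += step_r
        cur[idx, 1] += step_c
        diverged = np.hypot(cur[idx, 0] - pts[idx, 0], cur[idx, 1] - pts[idx, 1]) > tag_spacing_px
        status[idx[diverged | bad]] = "tracking diverged"
        converged = np.hypot(step_r, step_c) < NEWTON_TOL_PX
        still = np.zeros_like(active)
        still[idx] = ~(converged | diverged | bad)
        active = still
    out = cur * sp
    failed = status != "ok"
    out[failed] = np.nan
    return out, status


def track_point(pair_f, pair_g, point_mm,
                magnitude_floor: float = DEFAULT_MAGNITUDE_FLOOR):
    """Track a single landmark; raises on failure.

    Raises :class:`TrackingError` with message "signal void" when the
    harmonic magnitude at the source point is below the floor, or
    "tracking diverged" when the Newton step jumps by more than a tag
    period (phase jumping).
    """
    new, status = track_points(pair_f, pair_g, np.asarray(point_mm, dtype=float)[None, :],
                               magnitude_floor)
    if status[0] != "ok":
        raise TrackingError(status[0])
    return new[0]


# ---------------------------------------------------------------------------
# Midwall contours
# ---------------------------------------------------------------------------

@dataclass
class ContourTrack:
    """Ordered midwall landmarks through the cardiac cycle.

    ``positions`` holds (row, col) mm coordinates, origin at pixel (0, 0);
    landmarks are ordered clockwise from 0° at the configured angular
    step, and the contour is closed (last landmark connects to first).
    """

    slice_index: int
    positions: np.ndarray     # (n_frames, n_points, 2) mm
    angles_deg: np.ndarray    # (n_points,), reference-frame landmark angles
    angular_step: float
    reference_frame: int = 0
    frame_times: np.ndarray = field(default_factory=lambda: np.zeros(1))
    flags: np.ndarray = field(default=None)   # (n_frames, n_points) bool

    def __post_init__(self):
        if self.flags is None:
            self.flags = np.zeros(self.positions.shape[:2], dtype=bool)

    @property
    def n_points(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def _ray_crossings(mask: np.ndarray, center_px, theta_deg, step_px: float = 0.25):
    """First (endo) and last (epi) myocardial radii (px) along one ray."""
    h, w = mask.shape
    u = np.array([-np.cos(np.deg2rad(theta_deg)), np.sin(np.deg2rad(theta_deg))])
    rmax = float(np.hypot(h, w))
    radii = np.arange(0.0, rmax, step_px)
    rr = np.round(center_px[0] + radii * u[0]).astype(int)
    cc = np.round(center_px[1] + radii * u[1]).astype(int)
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    inside = np.zeros_like(radii, dtype=bool)
    inside[ok] = mask[rr[ok], cc[ok]]
    hits = np.where(inside)[0]
    if hits.size == 0:
        return None
    return radii[hits[0]], radii[hits[-1]]


def annulus_center(mask: np.ndarray):
    """Cavity centroid of an annular mask.

    Falls back to the mask centroid for a ring that is not closed (no
    enclosed cavity); a solid mask without any cavity is rejected.
    """
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValidationError("mask is not annular: empty mask")
    cavity = ndimage.binary_fill_holes(mask) & ~mask
    if cavity.sum() > 0:
        return ndimage.center_of_mass(cavity)
    center = ndimage.center_of_mass(mask)
    if mask[int(round(center[0])), int(round(center[1]))]:
        raise ValidationError("mask is not annular: no cavity found")
    return center


def init_midwall_contour(mask: np.ndarray, pixel_spacing: float,
                         angular_step: float = 5.0,
                         slice_index: int = 0,
                         frame_times=None) -> ContourTrack:
    """Place midwall landmarks on an annular mask at frame 0.

    The landmark at each angle is the midpoint between the endocardial and
    epicardial boundary crossings of the ray from the cavity centroid
    (72 points at the default 5° step).
    """
    mask = np.asarray(mask, dtype=bool)
    center = annulus_center(mask)
    n = int(round(360.0 / angular_step))
    angles = np.arange(n) * angular_step
    pts = np.empty((n, 2))
    for i, th in enumerate(angles):
        crossing = _ray_crossings(mask, center, th)
        if crossing is None:
            raise ValidationError("open myocardium: ray without myocardial crossing")
        r_mid = 0.5 * (crossing[0] + crossing[1])
        u = np.array([-np.cos(np.deg2rad(th)), np.sin(np.deg2rad(th))])
        pts[i] = (np.asarray(center) + r_mid * u) * pixel_spacing
    if frame_times is None:
        frame_times = np.zeros(1)
    return ContourTrack(slice_index=slice_index, positions=pts[None, :, :],
                        angles_deg=angles, angular_step=angular_step,
                        reference_frame=0, frame_times=np.asarray(frame_times, dtype=float))


def _interpolate_failed(points: np.ndarray, failed: np.ndarray) -> np.ndarray:
    """Replace failed landmarks by circular linear interpolation of neighbours."""
    n = points.shape[0]
    out = points.copy()
    valid = np.where(~failed)[0]
    for i in np.where(failed)[0]:
        # nearest valid neighbour on each side (circular)
        dist_fwd = (valid - i) % n
        dist_bwd = (i - valid) % n
        nxt = valid[np.argmin(dist_fwd)]
        prv = valid[np.argmin(dist_bwd)]
        df = (nxt - i) % n
        db = (i - prv) % n
        w = df + db
        out[i] = (points[prv] * df + points[nxt] * db) / w
    return out


def track_contour(series_pair, contour: ContourTrack,
                  magnitude_floor: float = DEFAULT_MAGNITUDE_FLOOR,
                  filter_radius: float | None = None,
                  max_fail_fraction: float = 0.25) -> ContourTrack:
    """Track all landmarks of a midwall contour through the cine.

    Tracking is sequential (frame-to-frame): inter-frame motion stays well
    below half a tag period, which avoids phase jumping.  Landmarks that
    fail in a frame are interpolated from their angular neighbours and
    flagged; if more than ``max_fail_fraction`` of landmarks fail in any
    frame the whole track is rejected.
    """
    s1, s2 = series_pair
    if s1.images.shape != s2.images.shape or not np.allclose(s1.frame_times, s2.frame_times):
        raise ValidationError("both tag-direction series must cover identical frames")
    n_frames = s1.images.shape[0]
    n_pts = contour.n_points
    harmonics = []
    for s in (s1, s2):
        harmonics.append([isolate_harmonic(s.images[f], s.tag_direction, s.tag_spacing,
                                           s.pixel_spacing, filter_radius)
                          for f in range(n_frames)])
    positions = np.empty((n_frames, n_pts, 2))
    flags = np.zeros((n_frames, n_pts), dtype=bool)
    positions[0] = contour.positions[0]
    for f in range(n_frames - 1):
        pair_f = (harmonics[0][f], harmonics[1][f])
        pair_g = (harmonics[0][f + 1], harmonics[1][f + 1])
        new, status = track_points(pair_f, pair_g, positions[f], magnitude_floor)
        failed = status != "ok"
        if failed.mean() > max_fail_fraction:
            raise TrackingError(f"track quality: {int(failed.sum())}/{n_pts} landmarks "
                                f"failed at frame {f + 1}")
        if failed.all():
            raise TrackingError("track quality: all landmarks failed")
        if failed.any():
            new = _interpolate_failed(np.where(failed[:, None], positions[f], new), failed)
        positions[f + 1] = new
        flags[f + 1] = failed
    return ContourTrack(slice_index=contour.slice_index, positions=positions,
                        angles_deg=contour.angles_deg, angular_step=contour.angular_step,
                        reference_frame=0, frame_times=s1.frame_times, flags=flags)
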