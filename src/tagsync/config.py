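"""Phantom and cohort configuration objects.

Conventions used throughout the package
---------------------------------------
* Images are ``(row, col)`` arrays, 0-based; physical positions are in mm.
* Angles are in degrees, measured clockwise as viewed from the apex, with
  0° at the anterior junction of the right and left ventricle.  In image
  coordinates the unit vector of angle ``theta`` is
  ``(-cos(theta), sin(theta))`` in ``(row, col)`` order, i.e. 0° points
  "up" in the displayed image and 90° points right.
* The circumference is divided into six 60° sectors S1..S6 starting at 0°,
  numbered clockwise.
* Frame 0 is end-diastole, the undeformed reference; end-systole is the
  frame of aortic-valve closure (``avc_frame``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ValidationError

SECTOR_LABELS = ("S1", "S2", "S3", "S4", "S5", "S6")
N_SECTORS = 6
SECTOR_WIDTH_DEG = 360.0 / N_SECTORS
MYOCARDIUM_DENSITY_G_PER_ML = 1.05  # standard CMR convention


@dataclass
class SignalLevels:
    """Mean tissue intensities (arbitrary units) for the phantom renderer.

    ``remote_sd`` is intra-tissue texture of remote myocardium, distinct
    from the acquisition noise ``PhantomConfig.noise_sd``.
    """

    remote_mean: float = 100.0
    remote_sd: float = 5.0
    edema_mean: float = 200.0
    necrosis_mean: float = 300.0


@dataclass
class PhantomConfig:
    """Full generative description of one synthetic subject.

    Geometry defaults approximate the study conditions: 9 short-axis
    slices of 8 mm, a 20/30 mm endo/epi annulus (cylindrical LV), 45 ms
    temporal resolution with aortic-valve closure at frame 8 (360 ms),
    7 mm tag spacing, and an anterior edema arc of 207° (57.5 %circ)
    enclosing a transmural 108° necrosis arc (30 %circ and %LV mass).
    """

    grid_size: int = 108
    pixel_spacing: float = 1.0          # mm / pixel
    n_slices: int = 9
    slice_thickness: float = 8.0        # mm
    slice_gap: float = 0.0              # mm
    endo_radius: float = 20.0           # mm at end-diastole
    epi_radius: float = 30.0            # mm at end-diastole
    n_frames: int = 20
    frame_interval: float = 45.0        # ms
    avc_frame: int = 8
    tag_spacing: float = 7.0            # mm
    tag_directions: tuple = ((1.0, 0.0), (0.0, 1.0))
    sector_amplitudes: tuple = (15.0,) * 6   # peak csh per sector, %
    sector_delays: tuple = (0.0,) * 6        # ms
    post_systolic_fraction: float = 0.0      # extra shortening after AVC in infarct sectors
    post_systolic_lag: float = 90.0          # ms after the sector's own peak
    edema_arc: tuple = (0.0, 207.0)          # degrees (start, end), clockwise
    necrosis_arc: tuple = (49.5, 157.5)      # degrees, nested in edema_arc
    signal_levels: SignalLevels = field(default_factory=SignalLevels)
    noise_sd: float = 5.0                # acquisition noise, intensity units
    tag_fading: float = 0.0              # linear tag-contrast loss per cardiac cycle (0 = CSPAMM-like)
    seed: int = 0

    # -- derived helpers -------------------------------------------------
    @property
    def midwall_radius(self) -> float:
        return 0.5 * (self.endo_radius + self.epi_radius)

    @property
    def frame_times(self) -> np.ndarray:
        """Frame times in ms; frame 0 is end-diastole at t = 0."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval

    @property
    def avc_time(self) -> float:
        return self.avc_frame * self.frame_interval

    @property
    def center_mm(self) -> tuple:
        c = (self.grid_size - 1) / 2.0 * self.pixel_spacing
        return (c, c)

    # -- validation ------------------------------------------------------
    def validate(self) -> "PhantomConfig":
        if self.endo_radius >= self.epi_radius:
            raise ValidationError("endo_radius must be < epi_radius")
        if not (0 <= self.avc_frame < self.n_frames):
            raise ValidationError("avc_frame must lie in [0, n_frames)")
        if self.n_frames < 2:
            raise ValidationError("need at least 2 frames")
        if min(self.sector_amplitudes) < 0:
            raise ValidationError("sector_amplitudes must be >= 0")
        if len(self.sector_amplitudes) != N_SECTORS or len(self.sector_delays) != N_SECTORS:
            raise ValidationError("sector_amplitudes and sector_delays need 6 entries")
        if self.tag_spacing <= 2.0 * self.pixel_spacing:
            raise ValidationError("tags unresolvable: tag_spacing must exceed 2 x pixel_spacing")
        d = np.asarray(self.tag_directions, dtype=float)
        if d.shape != (2, 2):
            raise ValidationError("tag_directions must be two 2-vectors")
        if not np.allclose(d @ d.T, np.eye(2), atol=1e-6):
            raise ValidationError("tag_directions must be orthonormal")
        for name, arc in (("edema_arc", self.edema_arc), ("necrosis_arc", self.necrosis_arc)):
            if arc_width(arc) > 360.0:
                raise ValidationError(f"{name} wider than 360 degrees")
        if not arc_contains_arc(self.edema_arc, self.necrosis_arc):
            raise ValidationError("necrosis_arc must be nested within edema_arc")
        sl = self.signal_levels
        if sl.edema_mean <= sl.remote_mean + 2.0 * sl.remote_sd:
            raise ValidationError("edema_mean must exceed remote mean + 2 SD")
        if sl.necrosis_mean <= sl.remote_mean + 2.0 * sl.remote_sd:
            raise ValidationError("necrosis_mean must exceed remote mean + 2 SD")
        if not (2 * self.epi_radius < self.grid_size * self.pixel_spacing):
            raise ValidationError("epicardium does not fit in the field of view")
        if not 0.0 <= self.post_systolic_fraction <= 1.0:
            raise ValidationError("post_systolic_fraction must lie in [0, 1]")
        return self

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signal_levels"] = dataclasses.asdict(self.signal_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "signal_levels" in d and isinstance(d["signal_levels"], dict):
            d["signal_levels"] = SignalLevels(**d["signal_levels"])
        for key in ("tag_directions", "sector_amplitudes", "sector_delays",
                    "edema_arc", "necrosis_arc"):
            if key in d and d[key] is not None:
                val = d[key]
                if key == "tag_directions":
                    d[key] = tuple(tuple(float(x) for x in v) for v in val)
                else:
                    d[key] = tuple(float(x) for x in val)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "PhantomConfig":
        """Load from YAML or JSON (YAML is a JSON superset)."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        blob = json.dumps(_jsonable(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Arc helpers (angles in degrees; arcs are (start, end) traversed clockwise,
# i.e. in the direction of increasing angle, possibly wrapping through 360).
# ---------------------------------------------------------------------------

def wrap_angle_deg(theta):
    """Wrap angle(s) into [0, 360)."""
    return np.mod(theta, 360.0)


def arc_width(arc) -> float:
    start, end = arc
    if end == start:
        return 0.0
    w = (end - start) % 360.0
    return 360.0 if w == 0.0 else w


def arc_contains(theta, arc):
    """Boolean mask: is ``theta`` inside the (half-open) arc?"""
    w = arc_width(arc)
    offs = np.mod(np.asarray(theta, dtype=float) - arc[0], 360.0)
    return offs < w


def arc_contains_arc(outer, inner) -> bool:
    if arc_width(inner) == 0.0:
        return True
    if arc_width(outer) >= 360.0:
        return True
    start_off = (inner[0] - outer[0]) % 360.0
    return start_off + arc_width(inner) <= arc_width(outer) + 1e-9


def acute_mi_config(**overrides) -> PhantomConfig:
    """Preset phantom emulating an acute anterior infarct.

    Sectors under the necrosis arc (anteroseptal S2/S3) are hypokinetic
    and delayed with a post-systolic component; the edema arc extends into
    the neighbouring sectors.  Yields a dyssynchronous ventricle with
    CURE below the synchronous default.
    """
    base = dict(
        sector_amplitudes=(12.0, 5.0, 5.0, 13.0, 15.0, 14.0),
        sector_delays=(30.0, 90.0, 90.0, 0.0, 0.0, 0.0),
        post_systolic_fraction=0.3,
    )
    base.update(overrides)
    return PhantomConfig(**base).validate()


@dataclass
class CohortParams:
    """Distributional settings for the measure-level cohort generator.

    Defaults are calibrated to the studied acute anterior-infarct cohort:
    edema 57.5 ± 14.0 %circ, necrosis 30.6 ± 12.6 %circ, necrosis mass
    30 ± 10 %LV, CURE 0.91 ± 0.05 acute and 0.94 ± 0.03 at follow-up, with
    an edema→CURE linear link whose explained variance is ≈0.63 and a
    necrosis-dependent recovery term for the follow-up CURE.
    """

    edema_mean: float = 57.5
    edema_sd: float = 14.0
    necrosis_frac_mean: float = 0.532    # necrosis extent as fraction of edema extent
    necrosis_frac_sd: float = 0.17
    mass_slope: float = 0.6              # necrosis mass vs necrosis extent
    mass_intercept: float = 29.6 - 0.6 * 30.6
    mass_noise_sd: float = 6.0
    cure_link_slope: float = -0.002835   # CURE_acute per %circ edema (negative direction)
    cure_link_intercept: float = 0.91 + 0.002835 * 57.5
    cure_link_noise_sd: float = 0.0304   # tuned so r² ≈ 0.63 with edema_sd = 14
    followup_carry: float = 0.35         # shrinkage of acute CURE deviation at follow-up
    followup_necrosis_slope: float = 0.0008  # ΔCURE per %circ necrosis (regression with larger scar)
    followup_mean: float = 0.94
    followup_noise_sd: float = 0.02
    lvedv_mean: float = 156.8
    lvedv_sd: float = 50.5
    ef_mean: float = 40.5
    ef_sd: float = 8.2
    lv_mass_mean: float = 133.0
    lv_mass_sd: float = 36.0

    def validate(self) -> "CohortParams":
        positive = ("edema_sd", "necrosis_frac_sd", "lvedv_sd", "ef_sd", "lv_mass_sd")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        nonneg = ("mass_noise_sd", "cure_link_noise_sd", "followup_noise_sd")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        return self

    @property
    def configured_r2(self) -> float:
        """Explained variance of the edema→CURE_acute link implied by settings."""
        explained = (self.cure_link_slope * self.edema_sd) ** 2
        total = explained + self.cure_link_noise_sd ** 2
        return explained / total if total > 0 else float("nan")
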