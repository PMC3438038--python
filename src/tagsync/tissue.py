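"""Edema/necrosis extents, necrosis mass, salvage and LV volumes.

Edema on T2-weighted images is tissue brighter than remote myocardium by
more than k·SD (k = 2), measured along the LV mid-myocardial centreline
(which avoids the subendocardial region where stagnant blood confounds
the signal) and expressed as % of circumference over three short-axis
slices.  Necrosis on LGE images is quantified the same way (automated
default k = 5, typical for bright infarct cores) and, over the full
stack, as % of LV mass by pixel counting.  Salvaged myocardium is the
area-at-risk minus necrosis, in % of circumference.  LV volumes use
short-axis disc summation; mass assumes 1.05 g/ml myocardium.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .config import MYOCARDIUM_DENSITY_G_PER_ML
from .errors import QuantError, ValidationError
from .harp import _bilinear, _ray_crossings

MIN_REMOTE_ROI_PIXELS = 20
DEFAULT_K_EDEMA = 2.0
DEFAULT_K_LGE = 5.0


@dataclass
class CircumferentialProfile:
    """Intensities sampled along the mid-myocardial centreline of one slice."""

    intensities: np.ndarray   # (n_samples,), periodic
    angles_deg: np.ndarray    # sample-center angles
    slice_index: int
    angular_step: float

    @property
    def n_samples(self) -> int:
        return self.intensities.size


@dataclass
class TissueExtents:
    """Circumferential/mass extents of edema and necrosis plus salvage."""

    edema_extent: float          # %circ
    necrosis_extent: float       # %circ
    necrosis_mass: float         # %LV mass
    salvage: float               # %circ
    remote_mean: float
    remote_sd: float
    remote_mean_lge: float = float("nan")
    remote_sd_lge: float = float("nan")
    salvage_clipped: bool = False

    def to_json(self, path=None) -> str:
        d = {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in asdict(self).items()}
        blob = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob


def remote_stats(image: np.ndarray, remote_roi: np.ndarray):
    """Sample mean and SD of intensities within the remote-tissue ROI."""
    roi = np.asarray(remote_roi, dtype=bool)
    if roi.sum() < MIN_REMOTE_ROI_PIXELS:
        raise ValidationError(f"remote ROI too small: needs >= {MIN_REMOTE_ROI_PIXELS} pixels")
    vals = np.asarray(image, dtype=float)[roi]
    return float(vals.mean()), float(vals.std(ddof=1))


def midline_profile(image: np.ndarray, mask: np.ndarray, pixel_spacing: float = 1.0,
                    step: float = 1.0, slice_index: int = 0) -> CircumferentialProfile:
    """Sample the image along the mid-myocardial centreline.

    One sample per ``step`` degrees (360 samples by default), placed at the
    midpoint of the endo/epi ray crossings from the cavity centroid and
    interpolated bilinearly.  Samples sit at angular bin centers
    (step/2, 3·step/2, ...).
    """
    from .harp import annulus_center

    mask = np.asarray(mask, dtype=bool)
    center = annulus_center(mask)
    n = int(round(360.0 / step))
    angles = (np.arange(n) + 0.5) * step
    pts = np.empty((n, 2))
    for i, th in enumerate(angles):
        crossing = _ray_crossings(mask, center, th)
        if crossing is None:
            raise ValidationError("open myocardium: ray without myocardial crossing")
        r_mid = 0.5 * (crossing[0] + crossing[1])
        u = np.array([-np.cos(np.deg2rad(th)), np.sin(np.deg2rad(th))])
        pts[i] = np.asarray(center) + r_mid * u
    vals = _bilinear(np.asarray(image, dtype=float), pts).real
    return CircumferentialProfile(intensities=vals, angles_deg=angles,
                                  slice_index=slice_index, angular_step=step)


def extent_above_threshold(profiles, remote_mean: float, remote_sd: float,
                           k: float = DEFAULT_K_EDEMA, pooled: bool = False) -> float:
    """%circumference of samples brighter than remote mean + k·SD.

    ``profiles`` is one profile or a list (typically the 3 T2w/LGE
    slices); the slice extents are averaged (``pooled=True`` pools all
    samples instead — the two coincide when slices have equal sample
    counts of hyperintense tissue variance, and differ only in weighting).
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if isinstance(profiles, CircumferentialProfile):
        profiles = [profiles]
    profiles = list(profiles)
    if not profiles or any(p.n_samples == 0 for p in profiles):
        raise ValidationError("empty profile")
    thr = remote_mean + k * remote_sd
    if pooled:
        allv = np.concatenate([p.intensities for p in profiles])
        return float(100.0 * np.mean(allv > thr))
    return float(np.mean([100.0 * np.mean(p.intensities > thr) for p in profiles]))


def necrosis_mass_fraction(lge_stack: np.ndarray, masks: np.ndarray,
                           remote_mean: float, remote_sd: float,
                           k: float = DEFAULT_K_LGE) -> float:
    """Hyperenhanced fraction of total myocardial pixels over all slices (%).

    With uniform pixel volume and tissue density the pixel ratio equals
    the mass ratio.
    """
    lge = np.asarray(lge_stack, dtype=float)
    masks = np.asarray(masks, dtype=bool)
    if lge.ndim == 2:
        lge = lge[None]
    if masks.ndim == 2:
        masks = np.broadcast_to(masks, lge.shape)
    if lge.shape != masks.shape:
        raise ValidationError("LGE stack and masks must be congruent")
    total = masks.sum()
    if total == 0:
        raise ValidationError("empty myocardium")
    thr = remote_mean + k * remote_sd
    hyper = ((lge > thr) & masks).sum()
    return float(100.0 * hyper / total)


def salvage_extent(edema_pct: float, necrosis_pct: float):
    """Salvaged myocardium = area-at-risk − necrosis (%circumference).

    Negative results (measurement noise inverting the nesting) are clipped
    to 0 with a warning; returns ``(salvage, clipped)``.
    """
    for v in (edema_pct, necrosis_pct):
        if not 0.0 <= v <= 100.0:
            raise ValidationError("extents must lie in [0, 100]")
    salvage = edema_pct - necrosis_pct
    if salvage < 0.0:
        warnings.warn("salvage negative (necrosis extent exceeds edema extent); clipped to 0",
                      stacklevel=2)
        return 0.0, True
    return float(salvage), False


def quantify_tissue(study, k_edema: float = DEFAULT_K_EDEMA,
                    k_lge: float = DEFAULT_K_LGE) -> TissueExtents:
    """Full tissue quantification of a :class:`~tagsync.phantom.TissueStudy`."""
    t2_mean, t2_sd = remote_stats(study.t2w_slices[0], study.remote_roi)
    t2_profiles = [midline_profile(img, study.myocardial_mask, study.pixel_spacing,
                                   slice_index=i)
                   for i, img in enumerate(study.t2w_slices)]
    edema = extent_above_threshold(t2_profiles, t2_mean, t2_sd, k_edema)

    lge_mean, lge_sd = remote_stats(study.lge_slices[0], study.remote_roi)
    lge_idx = study.t2w_slice_indices
    lge_profiles = [midline_profile(study.lge_slices[i], study.myocardial_mask,
                                    study.pixel_spacing, slice_index=i)
                    for i in lge_idx]
    necrosis = extent_above_threshold(lge_profiles, lge_mean, lge_sd, k_lge)
    mass = necrosis_mass_fraction(study.lge_slices, study.myocardial_mask,
                                  lge_mean, lge_sd, k_lge)
    salvage, clipped = salvage_extent(edema, necrosis)
    return TissueExtents(edema_extent=edema, necrosis_extent=necrosis,
                         necrosis_mass=mass, salvage=salvage,
                         remote_mean=t2_mean, remote_sd=t2_sd,
                         remote_mean_lge=lge_mean, remote_sd_lge=lge_sd,
                         salvage_clipped=clipped)


# ---------------------------------------------------------------------------
# LV volumes / EF / mass by disc summation
# ---------------------------------------------------------------------------

@dataclass
class LVVolumes:
    lvedv_ml: float
    lvesv_ml: float
    ef_pct: float
    lv_mass_g: float
    ef_negative: bool = False

    def to_json(self, path=None) -> str:
        blob = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob


def lv_volumes(endo_ed: np.ndarray, epi_ed: np.ndarray,
               endo_es: np.ndarray, epi_es: np.ndarray,
               pixel_spacing: float, slice_thickness: float,
               gap: float = 0.0) -> LVVolumes:
    """Disc-summation LV volumes, ejection fraction and mass.

    Masks are (n_slices, rows, cols) binaries of the cavity (endo) and the
    full epicardial disc at end-diastole and end-systole.  Each slice
    contributes area × (thickness + gap); mass is end-diastolic
    myocardial volume × 1.05 g/ml.  ESV > EDV is permitted but flagged.
    """
    if slice_thickness <= 0:
        raise ValidationError("slice_thickness must be positive")
    stacks = [np.asarray(m, dtype=bool) for m in (endo_ed, epi_ed, endo_es, epi_es)]
    if len({s.shape for s in stacks}) != 1:
        raise ValidationError("mask stacks must be congruent")
    px_area = pixel_spacing ** 2                       # mm²
    disc = slice_thickness + gap                       # mm
    vol = [s.sum() * px_area * disc / 1000.0 for s in stacks]   # ml
    edv, epiv_ed, esv, _ = vol
    myo_ml = epiv_ed - edv
    mass = myo_ml * MYOCARDIUM_DENSITY_G_PER_ML
    ef = 100.0 * (edv - esv) / edv if edv > 0 else float("nan")
    negative = ef < 0
    if negative:
        warnings.warn("ESV exceeds EDV: negative ejection fraction", stacklevel=2)
    return LVVolumes(lvedv_ml=float(edv), lvesv_ml=float(esv), ef_pct=float(ef),
                     lv_mass_g=float(mass), ef_negative=bool(negative))
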