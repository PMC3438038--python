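"""Measure-level and image-level synthetic cohorts.

The measure-level generator draws per-subject tissue and dyssynchrony
measures directly from the distributional structure the study reports:
edema extent and the necrotic fraction of the edema territory are
Gaussian, acute CURE follows a linear link on edema extent (negative
slope, explained variance ≈ 0.63 by default), and follow-up CURE adds a
necrosis-dependent recovery term — ventricles with larger necrosis show
more regression of dyssynchrony.  Salvage is definitionally
edema − necrosis.  All extents are clipped to valid ranges.

The image-level fidelity maps each drawn subject to a
:class:`~tagsync.config.PhantomConfig` (arcs sized from the drawn extents,
hypokinesia and delay in infarct sectors) so the full imaging pipeline can
be run per subject.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import CohortParams, PhantomConfig, arc_width, wrap_angle_deg
from .errors import ValidationError

COHORT_COLUMNS = ("subject", "edema_extent", "necrosis_extent", "necrosis_mass",
                  "salvage", "CURE_acute", "CURE_followup",
                  "LVEDV", "LVESV", "LV_mass", "EF")


def generate_cohort_measures(n: int, params: CohortParams | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Draw a measure-level synthetic cohort of ``n`` subjects.

    Reproducible given ``seed``; the salvage column equals
    ``edema_extent - necrosis_extent`` exactly (clipped at 0).
    """
    if n < 2:
        raise ValidationError("cohort size must be >= 2")
    params = (params or CohortParams()).validate()
    rng = np.random.default_rng([seed, 303])

    edema = np.clip(rng.normal(params.edema_mean, params.edema_sd, n), 0.0, 100.0)
    frac = np.clip(rng.normal(params.necrosis_frac_mean, params.necrosis_frac_sd, n), 0.0, 1.0)
    necrosis = np.clip(edema * frac, 0.0, 100.0)
    mass = np.clip(params.mass_intercept + params.mass_slope * necrosis
                   + rng.normal(0.0, params.mass_noise_sd, n) * (params.mass_noise_sd > 0),
                   0.0, 100.0)
    cure_acute = np.clip(params.cure_link_intercept + params.cure_link_slope * edema
                         + rng.normal(0.0, params.cure_link_noise_sd, n)
                         * (params.cure_link_noise_sd > 0), 0.0, 1.0)
    cure_fu = np.clip(params.followup_mean
                      + params.followup_carry * (cure_acute - 0.91)
                      + params.followup_necrosis_slope * (necrosis - 30.6)
                      + rng.normal(0.0, params.followup_noise_sd, n)
                      * (params.followup_noise_sd > 0), 0.0, 1.0)
    lvedv = np.clip(rng.normal(params.lvedv_mean, params.lvedv_sd, n), 40.0, None)
    ef = np.clip(rng.normal(params.ef_mean, params.ef_sd, n), 5.0, 80.0)
    lvesv = lvedv * (1.0 - ef / 100.0)
    lv_mass = np.clip(rng.normal(params.lv_mass_mean, params.lv_mass_sd, n), 30.0, None)
    salvage = np.clip(edema - necrosis, 0.0, None)

    return pd.DataFrame({
        "subject": np.arange(n),
        "edema_extent": edema,
        "necrosis_extent": necrosis,
        "necrosis_mass": mass,
        "salvage": salvage,
        "CURE_acute": cure_acute,
        "CURE_followup": cure_fu,
        "LVEDV": lvedv,
        "LVESV": lvesv,
        "LV_mass": lv_mass,
        "EF": ef,
    })


def subject_config_from_measures(row, base: PhantomConfig | None = None,
                                 seed: int | None = None) -> PhantomConfig:
    """Image-level fidelity: phantom config for one cohort-table row.

    The edema and necrosis arcs are sized from the drawn circumferential
    extents (centered on the anterior wall); sectors overlapped by the
    necrosis arc become hypokinetic and delayed in proportion to their
    overlap, which injects the dyssynchrony the drawn CURE reflects.
    """
    base = base or PhantomConfig()
    edema_w = float(row["edema_extent"]) * 3.6
    necrosis_w = float(row["necrosis_extent"]) * 3.6
    center = wrap_angle_deg(base.edema_arc[0] + arc_width(base.edema_arc) / 2.0)
    edema_arc = (wrap_angle_deg(center - edema_w / 2.0), wrap_angle_deg(center + edema_w / 2.0))
    necrosis_arc = (wrap_angle_deg(center - necrosis_w / 2.0),
                    wrap_angle_deg(center + necrosis_w / 2.0))
    amplitudes = []
    delays = []
    for s in range(6):
        lo, hi = 60.0 * s, 60.0 * (s + 1)
        overlap = _arc_overlap_deg(necrosis_arc, (lo, hi)) / 60.0
        amplitudes.append(base.sector_amplitudes[s] * (1.0 - 0.6 * overlap))
        delays.append(base.sector_delays[s] + 40.0 * overlap)
    cfg = dataclasses.replace(
        base, edema_arc=edema_arc, necrosis_arc=necrosis_arc,
        sector_amplitudes=tuple(amplitudes), sector_delays=tuple(delays),
        post_systolic_fraction=max(base.post_systolic_fraction, 0.2),
        seed=int(seed if seed is not None else base.seed + int(row["subject"])))
    return cfg.validate()


def _arc_overlap_deg(arc_a, arc_b) -> float:
    """Angular overlap (degrees) of two arcs, handling wrap-around."""
    wa = arc_width(arc_a)
    if wa == 0.0 or arc_width(arc_b) == 0.0:
        return 0.0
    # sample-free computation on the unwrapped interval of arc_b
    b0 = arc_b[0] % 360.0
    wb = arc_width(arc_b)
    a0 = (arc_a[0] - b0) % 360.0
    lo = a0
    hi = a0 + wa
    overlap = max(0.0, min(hi, wb) - lo) + max(0.0, min(hi - 360.0, wb))
    return min(overlap, wb)
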