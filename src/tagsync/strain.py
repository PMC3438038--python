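"""Segmental circumferential shortening and dyssynchrony indices.

Circumferential shortening (csh, %) of a 60° sector is the relative arc-
length change of the midwall contour landmarks in that sector versus
end-diastole (frame 0), shortening positive.  From the slice × sector ×
frame csh field three dyssynchrony measures are derived:

* ``T_max`` — time to the maximum csh of each segment (earliest frame on
  ties); segments peaking in the first three or the last frame are flagged;
* ``CV_csh`` — coefficient of variation of segmental csh at end-systole
  (aortic-valve closure);
* ``CURE`` — circumferential uniformity ratio estimate.  For each slice
  and frame the six sector csh values are Fourier-transformed around the
  circumference; with ``A0 = |c_0|²`` (uniform power) and ``A1 = |c_1|²``
  (first-harmonic power), ``CURE = sqrt(Σ A0 / Σ (A0 + A1))`` summed over
  slices and systolic frames.  CURE is 1 for a spatially uniform field
  (complete synchrony) and 0 for a zero-mean pure first harmonic (pure
  dyssynchrony).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import N_SECTORS, SECTOR_LABELS, SECTOR_WIDTH_DEG
from .errors import QuantError, ValidationError
from .harp import ContourTrack
from .phantom import position_angle

CV_MEAN_FLOOR = 0.5          # %, below which CV_csh is degenerate
TMAX_EARLY_FRAMES = (0, 1, 2)


@dataclass
class StrainField:
    """csh (%) indexed by slice × sector × frame; the central exchange object."""

    csh: np.ndarray           # (n_slices, n_sectors, n_frames)
    frame_times: np.ndarray   # ms
    avc_frame: int
    sector_labels: tuple = SECTOR_LABELS

    def __post_init__(self):
        self.csh = np.asarray(self.csh, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.csh.ndim != 3:
            raise ValidationError("csh must be (n_slices, n_sectors, n_frames)")
        if self.csh.shape[2] != self.frame_times.size:
            raise ValidationError("frame_times length must match csh frames")
        if not 0 <= self.avc_frame < self.csh.shape[2]:
            raise ValidationError("avc_frame out of range")
        if np.max(np.abs(self.csh[:, :, 0])) > 1e-9:
            raise ValidationError("csh at frame 0 must be zero (end-diastolic reference)")

    @property
    def n_slices(self) -> int:
        return self.csh.shape[0]

    @property
    def n_sectors(self) -> int:
        return self.csh.shape[1]

    @property
    def n_frames(self) -> int:
        return self.csh.shape[2]

    @property
    def n_segments(self) -> int:
        return self.n_slices * self.n_sectors

    def at_avc(self) -> np.ndarray:
        """Segmental csh at end-systole, shape (n_slices, n_sectors)."""
        return self.csh[:, :, self.avc_frame]

    @classmethod
    def stack(cls, fields) -> "StrainField":
        """Combine per-slice fields into one multi-slice field."""
        fields = list(fields)
        base = fields[0]
        for f in fields[1:]:
            if f.n_frames != base.n_frames or f.avc_frame != base.avc_frame:
                raise ValidationError("cannot stack fields with differing timing")
        return cls(csh=np.concatenate([f.csh for f in fields], axis=0),
                   frame_times=base.frame_times, avc_frame=base.avc_frame)

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sl in range(self.n_slices):
            for sec in range(self.n_sectors):
                for f in range(self.n_frames):
                    rows.append((sl, sec, f, self.frame_times[f], self.csh[sl, sec, f]))
        return pd.DataFrame(rows, columns=["slice", "sector", "frame", "time_ms", "csh_pct"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, avc_frame: int) -> "StrainField":
        df = pd.read_csv(path)
        n_sl = int(df["slice"].max()) + 1
        n_sec = int(df["sector"].max()) + 1
        n_fr = int(df["frame"].max()) + 1
        csh = np.zeros((n_sl, n_sec, n_fr))
        csh[df["slice"], df["sector"], df["frame"]] = df["csh_pct"]
        times = np.zeros(n_fr)
        times[df["frame"]] = df["time_ms"]
        return cls(csh=csh, frame_times=times, avc_frame=avc_frame)


def sector_csh(track: ContourTrack, avc_frame: int,
               center_mm=None) -> StrainField:
    """Segmental csh of one slice from a tracked midwall contour.

    Landmarks are binned into 60° sectors by their reference-frame angle;
    each sector's arc length is the polyline through its landmarks plus
    the closing segment to the first landmark of the next sector, so the
    six arcs tile the circumference.  csh = 100 (L(0) - L(f)) / L(0).
    """
    pos = track.positions
    n_frames, n_pts = pos.shape[0], pos.shape[1]
    if center_mm is None:
        center_mm = pos[0].mean(axis=0)
    angles = (track.angles_deg if track.angles_deg is not None else
              position_angle(pos[0, :, 0] - center_mm[0], pos[0, :, 1] - center_mm[1]))
    sector_of = (np.floor(np.mod(angles, 360.0) / SECTOR_WIDTH_DEG).astype(int) % N_SECTORS)
    counts = np.bincount(sector_of, minlength=N_SECTORS)
    if counts.min() < 3:
        raise QuantError("sector under-sampled: fewer than 3 landmarks in a sector")
    # each segment (i -> i+1, circular) belongs to the sector of its start landmark
    order = np.argsort(np.mod(angles, 360.0), kind="stable")
    seg_sector = sector_of[order]
    csh = np.zeros((1, N_SECTORS, n_frames))
    L0 = None
    for f in range(n_frames):
        p = pos[f][order]
        seg_len = np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)
        L = np.bincount(seg_sector, weights=seg_len, minlength=N_SECTORS)
        if f == 0:
            L0 = L
        csh[0, :, f] = 100.0 * (L0 - L) / L0
    return StrainField(csh=csh, frame_times=track.frame_times, avc_frame=avc_frame)


# ---------------------------------------------------------------------------
# Dyssynchrony indices
# ---------------------------------------------------------------------------

@dataclass
class TmaxResult:
    t_max_ms: np.ndarray      # (n_slices, n_sectors), NaN where undefined
    flagged: np.ndarray       # bool, same shape
    reasons: list             # list of (slice, sector, reason)


def time_to_peak(field: StrainField) -> TmaxResult:
    """Time to maximum csh per segment, with automatic flagging.

    Ties resolve to the earliest frame.  Segments whose peak falls in the
    first three or the last acquired frame are flagged (the automated
    stand-in for observer inspection); an all-zero curve is flagged
    "no peak" with undefined T_max.
    """
    if field.n_frames < 5:
        raise ValidationError("time_to_peak requires at least 5 frames")
    csh = field.csh
    argmax = np.argmax(csh, axis=2)   # earliest frame on ties
    t_max = field.frame_times[argmax].astype(float)
    no_peak = np.all(csh == 0.0, axis=2)
    edge = np.isin(argmax, TMAX_EARLY_FRAMES) | (argmax == field.n_frames - 1)
    t_max[no_peak] = np.nan
    flagged = edge | no_peak
    reasons = []
    for sl, sec in zip(*np.nonzero(flagged)):
        reason = "no peak" if no_peak[sl, sec] else "peak in first three or last frame"
        reasons.append((int(sl), int(sec), reason))
    return TmaxResult(t_max_ms=t_max, flagged=flagged, reasons=reasons)


def cv_csh(field_or_values, avc_frame: int | None = None,
           mean_floor: float = CV_MEAN_FLOOR) -> float:
    """Coefficient of variation (%) of segmental csh at end-systole.

    100 × sample SD / |mean| over all segments.  Accepts a
    :class:`StrainField` or a flat array of end-systolic csh values.
    """
    if isinstance(field_or_values, StrainField):
        values = field_or_values.at_avc().ravel()
    else:
        values = np.asarray(field_or_values, dtype=float).ravel()
    if values.size < 2:
        raise ValidationError("cv_csh requires at least 2 segments")
    mean = values.mean()
    if abs(mean) < mean_floor:
        raise QuantError("degenerate mean shortening")
    return float(100.0 * values.std(ddof=1) / abs(mean))


def cure_index(field: StrainField, frame_range=None,
               harmonic_convention: str = "one_sided") -> float:
    """Circumferential uniformity ratio estimate, in [0, 1].

    Spatial Fourier power around the circumference, summed over slices and
    the systolic frames (default frames 1..avc_frame):
    ``CURE = sqrt(Σ A0 / Σ (A0 + A1))`` with ``A0 = |c_0|²`` and
    ``A1 = |c_1|²`` (plus ``|c_{-1}|²`` under the two-sided convention;
    the 0/1 extremes and all invariances hold under either).
    """
    if field.n_sectors < 3:
        raise ValidationError("cure_index requires at least 3 sectors per slice")
    if harmonic_convention not in ("one_sided", "two_sided"):
        raise ValidationError("harmonic_convention must be 'one_sided' or 'two_sided'")
    if frame_range is None:
        frame_range = range(1, field.avc_frame + 1)
    frames = np.asarray(list(frame_range), dtype=int)
    if frames.size == 0:
        raise ValidationError("empty frame range")
    x = field.csh[:, :, frames]                      # (slices, sectors, frames)
    c = np.fft.fft(x, axis=1) / field.n_sectors
    a0 = np.abs(c[:, 0, :]) ** 2
    a1 = np.abs(c[:, 1, :]) ** 2
    if harmonic_convention == "two_sided":
        a1 = a1 + np.abs(c[:, -1, :]) ** 2
    sum0 = a0.sum()
    sum01 = (a0 + a1).sum()
    if sum01 == 0.0:
        raise QuantError("degenerate strain field: no spatial Fourier power")
    return float(np.sqrt(sum0 / sum01))


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclass
class DyssynchronyReport:
    """Slice-aggregated dyssynchrony summary of one study."""

    cure: float
    cv_csh_pct: float
    t_max_mean_ms: float
    t_max_sd_ms: float
    mean_csh_avc_pct: float
    n_segments: int
    n_flagged: int
    flagged_segments: list      # (slice, sector, reason)
    t_max_ms: list              # per-segment, row-major (slice, sector), NaN -> None

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        for key in ("t_max_mean_ms", "t_max_sd_ms"):
            if d[key] is not None and np.isnan(d[key]):
                d[key] = None
        blob = json.dumps(d, indent=2, allow_nan=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob

    @classmethod
    def from_json(cls, source) -> "DyssynchronyReport":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            d = json.loads(source)
        d["flagged_segments"] = [tuple(x) for x in d["flagged_segments"]]
        return cls(**d)


def dyssynchrony_report(field: StrainField, frame_range=None,
                        harmonic_convention: str = "one_sided") -> DyssynchronyReport:
    """Compute CURE, CV_csh and T_max statistics for a strain field.

    T_max mean/SD are taken over unflagged segments only (the automated
    counterpart of observer-corrected peaks); CURE and CV use all
    segments.
    """
    tmax = time_to_peak(field)
    good = ~tmax.flagged
    if good.any():
        t_mean = float(tmax.t_max_ms[good].mean())
        t_sd = float(tmax.t_max_ms[good].std(ddof=1)) if good.sum() > 1 else 0.0
    else:
        t_mean = float("nan")
        t_sd = float("nan")
    t_list = [None if np.isnan(v) else float(v) for v in tmax.t_max_ms.ravel()]
    return DyssynchronyReport(
        cure=cure_index(field, frame_range, harmonic_convention),
        cv_csh_pct=cv_csh(field),
        t_max_mean_ms=t_mean,
        t_max_sd_ms=t_sd,
        mean_csh_avc_pct=float(field.at_avc().mean()),
        n_segments=field.n_segments,
        n_flagged=int(tmax.flagged.sum()),
        flagged_segments=[(sl, sec, reason) for sl, sec, reason in tmax.reasons],
        t_max_ms=t_list,
    )
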