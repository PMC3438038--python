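"""End-to-end orchestration: simulate → track → metrics → tissue.

``run_pipeline`` executes every stage on a phantom subject and writes a
manifest recording the config hash, seed, per-stage parameters, output
paths and content hashes.  All randomness flows from the single config
seed; deterministic stages therefore produce identical content hashes on
re-runs with the same config.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .config import PhantomConfig
from .errors import TagsyncError
from .harp import init_midwall_contour, track_contour
from .phantom import (ground_truth_csh, render_cine_masks, render_tagged_series,
                      render_tissue_maps)
from .strain import StrainField, dyssynchrony_report, sector_csh
from .tissue import lv_volumes, quantify_tissue

log = logging.getLogger("tagsync")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_params: dict
    outputs: dict = field(default_factory=dict)     # name -> path
    output_hashes: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def add(self, name: str, path: Path) -> None:
        self.outputs[name] = str(path)
        self.output_hashes[name] = tio.file_digest(path)
        self.timestamps[name] = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def simulate_subject(config: PhantomConfig, out_dir) -> dict:
    """Render and write one subject's phantom study; returns output paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate()
    paths = {}
    config.to_yaml(out / "config.yaml")
    paths["config"] = out / "config.yaml"

    for k, e in enumerate(config.tag_directions):
        stack = np.stack([render_tagged_series(config, s, e).images
                          for s in range(config.n_slices)])        # (slice, frame, r, c)
        tio.write_image_stack(out / f"tagged_dir{k}.nii.gz",
                              stack.transpose(0, 2, 3, 1), config.pixel_spacing,
                              config.slice_thickness, config.frame_interval)
        paths[f"tagged_dir{k}"] = out / f"tagged_dir{k}.nii.gz"

    masks = render_cine_masks(config)
    for name, arr in (("masks_endo", masks.endo), ("masks_epi", masks.epi)):
        tio.write_image_stack(out / f"{name}.nii.gz",
                              arr.transpose(0, 2, 3, 1).astype(np.float64),
                              config.pixel_spacing, config.slice_thickness,
                              config.frame_interval)
        paths[name] = out / f"{name}.nii.gz"

    study = render_tissue_maps(config)
    tio.write_image_stack(out / "t2w.nii.gz", study.t2w_slices,
                          config.pixel_spacing, config.slice_thickness)
    tio.write_image_stack(out / "lge.nii.gz", study.lge_slices,
                          config.pixel_spacing, config.slice_thickness)
    tio.write_image_stack(out / "myo_mask.nii.gz",
                          np.broadcast_to(study.myocardial_mask,
                                          study.lge_slices.shape).astype(np.float64),
                          config.pixel_spacing, config.slice_thickness)
    tio.write_image_stack(out / "remote_roi.nii.gz",
                          study.remote_roi[None].astype(np.float64),
                          config.pixel_spacing, config.slice_thickness)
    for name in ("t2w", "lge", "myo_mask", "remote_roi"):
        paths[name] = out / f"{name}.nii.gz"

    meta = {"tag_directions": [list(d) for d in config.tag_directions],
            "tag_spacing": config.tag_spacing,
            "pixel_spacing": config.pixel_spacing,
            "frame_times_ms": config.frame_times.tolist(),
            "avc_frame": config.avc_frame,
            "t2w_slice_indices": list(study.t2w_slice_indices)}
    tio.write_json(out / "meta.json", meta)
    paths["meta"] = out / "meta.json"
    return paths


def track_subject(config: PhantomConfig, out_dir=None) -> list:
    """HARP-track midwall contours on every slice of a phantom subject."""
    masks = render_cine_masks(config)
    tracks = []
    for s in range(config.n_slices):
        myo0 = masks.myocardium[s, 0]
        contour = init_midwall_contour(myo0, config.pixel_spacing, slice_index=s,
                                       frame_times=config.frame_times)
        pair = tuple(render_tagged_series(config, s, e) for e in config.tag_directions)
        tracks.append(track_contour(pair, contour))
    if out_dir is not None:
        write_tracks_csv(Path(out_dir) / "tracks.csv", tracks)
    return tracks


def write_tracks_csv(path, tracks) -> None:
    import pandas as pd

    rows = []
    for tr in tracks:
        for f in range(tr.n_frames):
            for i in range(tr.n_points):
                rows.append((tr.slice_index, f, tr.frame_times[f], tr.angles_deg[i],
                             tr.positions[f, i, 1], tr.positions[f, i, 0],
                             int(tr.flags[f, i])))
    pd.DataFrame(rows, columns=["slice", "frame", "time_ms", "angle_deg",
                                "x_mm", "y_mm", "flag"]).to_csv(path, index=False)


def read_tracks_csv(path) -> list:
    import pandas as pd

    from .harp import ContourTrack

    df = pd.read_csv(path)
    tracks = []
    for sl, grp in df.groupby("slice"):
        frames = np.sort(grp["frame"].unique())
        angles = np.sort(grp[grp["frame"] == frames[0]]["angle_deg"].to_numpy())
        n_f, n_p = frames.size, angles.size
        pos = np.empty((n_f, n_p, 2))
        flags = np.zeros((n_f, n_p), dtype=bool)
        times = np.empty(n_f)
        grp = grp.sort_values(["frame", "angle_deg"])
        pos[:, :, 0] = grp["y_mm"].to_numpy().reshape(n_f, n_p)
        pos[:, :, 1] = grp["x_mm"].to_numpy().reshape(n_f, n_p)
        flags[:, :] = grp["flag"].to_numpy().reshape(n_f, n_p).astype(bool)
        times = grp.groupby("frame")["time_ms"].first().to_numpy()
        step = 360.0 / n_p
        tracks.append(ContourTrack(slice_index=int(sl), positions=pos, angles_deg=angles,
                                   angular_step=step, frame_times=times, flags=flags))
    return tracks


def run_pipeline(config: PhantomConfig | str, out_dir, seed: int | None = None) -> RunManifest:
    """Execute simulate → track → metrics → tissue on one subject.

    Raises with the failing stage named; on success every manifest entry
    exists on disk.
    """
    if not isinstance(config, PhantomConfig):
        config = PhantomConfig.from_file(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()   # fail fast before any computation
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.content_hash(), seed=config.seed,
                           stage_params={"n_slices": config.n_slices,
                                         "n_frames": config.n_frames,
                                         "avc_frame": config.avc_frame,
                                         "tag_spacing": config.tag_spacing})
    stage = "simulate"
    try:
        paths = simulate_subject(config, out)
        for name, p in paths.items():
            manifest.add(name, p)

        stage = "track"
        log.info(json.dumps({"stage": "track", "n_slices": config.n_slices}))
        tracks = track_subject(config)
        write_tracks_csv(out / "tracks.csv", tracks)
        manifest.add("tracks", out / "tracks.csv")

        stage = "metrics"
        fields = [sector_csh(tr, config.avc_frame) for tr in tracks]
        strain = StrainField.stack(fields)
        strain.to_csv(out / "strain.csv")
        manifest.add("strain", out / "strain.csv")
        report = dyssynchrony_report(strain)
        report.to_json(out / "report.json")
        manifest.add("report", out / "report.json")

        stage = "tissue"
        study = render_tissue_maps(config)
        extents = quantify_tissue(study)
        extents.to_json(out / "extents.json")
        manifest.add("extents", out / "extents.json")

        masks = render_cine_masks(config)
        vols = lv_volumes(masks.endo[:, 0], masks.epi[:, 0],
                          masks.endo[:, config.avc_frame], masks.epi[:, config.avc_frame],
                          config.pixel_spacing, config.slice_thickness, config.slice_gap)
        vols.to_json(out / "volumes.json")
        manifest.add("volumes", out / "volumes.json")
    except TagsyncError as err:
        log.error(json.dumps({"stage": stage, "error": str(err)}))
        raise type(err)(f"stage '{stage}' failed: {err}") from err

    manifest.write(out / "manifest.json")
    return manifest


def ground_truth_strain(config: PhantomConfig) -> StrainField:
    """Analytic per-sector csh of the phantom as a StrainField (all slices)."""
    gt = ground_truth_csh(config)
    csh = np.broadcast_to(gt, (config.n_slices,) + gt.shape).copy()
    return StrainField(csh=csh, frame_times=config.frame_times, avc_frame=config.avc_frame)
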