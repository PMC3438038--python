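"""NIfTI and tabular readers/writers.

Axis conventions: in-memory stacks are ``(slice, row, col)`` or
``(slice, row, col, frame)``; on disk NIfTI stores ``(row, col, slice
[, frame])`` with pixel spacing and slice thickness in the header zooms.
Hashing of ``.nii.gz`` files is done on the decompressed stream so
manifests are stable across gzip metadata differences.
"""

from __future__ import annotations

import gzip
import hashlib
import json

import nibabel as nib
import numpy as np

from .errors import ValidationError


def write_image_stack(path, stack: np.ndarray, pixel_spacing: float,
                      slice_thickness: float, frame_interval: float | None = None) -> None:
    """Write a (slice, row, col[, frame]) stack as NIfTI."""
    stack = np.asarray(stack)
    if stack.ndim == 3:
        data = stack.transpose(1, 2, 0)
        zooms = (pixel_spacing, pixel_spacing, slice_thickness)
    elif stack.ndim == 4:
        data = stack.transpose(1, 2, 0, 3)
        zooms = (pixel_spacing, pixel_spacing, slice_thickness,
                 frame_interval if frame_interval else 1.0)
    else:
        raise ValidationError("stack requires 3 or 4 dims")
    affine = np.diag([pixel_spacing, pixel_spacing, slice_thickness, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(data.astype(np.float64)), affine)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_image_stack(path):
    """Read a NIfTI stack; returns (array, spacing dict).

    The array comes back as (slice, row, col[, frame]); spacing holds
    ``pixel_spacing`` (mm), ``slice_thickness`` (mm) and, for 4D input,
    ``frame_interval``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim < 3:
        raise ValidationError("stack requires >=3 dims")
    zooms = img.header.get_zooms()
    if len(zooms) < 3 or zooms[0] <= 0 or zooms[2] <= 0:
        raise ValidationError("missing spacing fields: pixel spacing / slice thickness "
                              "not present in header zooms")
    spacing = {"pixel_spacing": float(zooms[0]),
               "pixel_spacing_col": float(zooms[1]),
               "slice_thickness": float(zooms[2])}
    if data.ndim == 3:
        out = data.transpose(2, 0, 1)
    elif data.ndim == 4:
        out = data.transpose(2, 0, 1, 3)
        spacing["frame_interval"] = float(zooms[3]) if len(zooms) > 3 else None
    else:
        raise ValidationError("stacks with more than 4 dims are not supported")
    return out, spacing


def file_digest(path) -> str:
    """SHA-256 of a file; gzip members are hashed decompressed."""
    h = hashlib.sha256()
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
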