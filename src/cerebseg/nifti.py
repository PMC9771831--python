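"""NIfTI I/O with canonical R-A-S reorientation.

Volumes are reoriented to the closest canonical (RAS) axis order at load so
that the anatomical planes used by the multi-view machinery are well
defined; label maps written back carry the same affine, so results line up
with the input in any NIfTI viewer.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import LabelMap, Volume


def load_volume(path) -> Volume:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, np.asarray(img.affine))


def load_labels(path) -> LabelMap:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-3):
            raise ValueError(f"{path} does not look like an integer label map")
        data = rounded
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(data.astype(np.int32), spacing, np.asarray(img.affine))


def save_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def save_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int16), labels.affine)
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))


def save_sidecar(info: dict, path) -> None:
    Path(path).write_text(json.dumps(info, indent=1, default=str))
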