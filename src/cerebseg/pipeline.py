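"""End-to-end inference: native T1-style volume in, native-space labels and
a tabulated volume report out.

The path is: robust intensity normalization -> cerebellum localization ->
fixed cubic crop -> three per-view predictions -> sagittal lateral
expansion -> probability-space view aggregation -> argmax -> embed into the
native grid -> per-structure volume report.  No bias-field correction and
no atlas registration appear anywhere in the path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import LabelMap, Volume, robust_normalize
from .localization import cerebellum_mask, crop, embed, fit_bounding_box
from .model import ReferenceNet
from .multiview import (
    expand_sagittal,
    extract_stack_array,
    predict_view,
    probabilities_to_labels,
    view_aggregate,
    DEFAULT_VIEW_WEIGHTS,
)
from .protocol import REGION_NAMES, LabelProtocol, aggregate_regions

SPACING_TOLERANCE = (0.5, 1.5)  # accepted voxel size range, mm
ANISOTROPY_TOLERANCE = 1.15  # max/min spacing ratio


def check_spacing(volume: Volume) -> None:
    lo, hi = SPACING_TOLERANCE
    s = volume.spacing
    if min(s) < lo or max(s) > hi:
        raise ValueError(
            f"voxel spacing {s} outside the supported ~1 mm range [{lo}, {hi}]"
        )
    if max(s) / min(s) > ANISOTROPY_TOLERANCE:
        raise ValueError(f"anisotropic spacing beyond tolerance: {s}")


def segment(
    t1: Volume,
    models: dict[str, ReferenceNet],
    protocol: LabelProtocol,
    localization_labels: LabelMap,
    cerebellar_ids=None,
    weights: tuple[float, float, float] = DEFAULT_VIEW_WEIGHTS,
) -> tuple[LabelMap, pd.DataFrame]:
    """Segment a native-space volume with the three per-view models.

    ``localization_labels`` is any label volume on the native grid carrying
    cerebellar labels (ground truth at phantom scale, a coarse whole-brain
    segmentation in production); ``cerebellar_ids`` defaults to the full
    protocol id set.
    """
    for view in ("axial", "coronal", "sagittal"):
        if view not in models:
            raise ValueError(f"missing checkpoint for the {view} view")
    hashes = {m.config.protocol_hash for m in models.values()}
    if len(hashes) > 1:
        raise ValueError("refusing to aggregate checkpoints trained under different protocols")
    if hashes != {""} and hashes != {protocol.hash()}:
        raise ValueError("checkpoints were trained under a different label protocol")
    check_spacing(t1)

    norm = robust_normalize(t1)
    ids = cerebellar_ids if cerebellar_ids is not None else protocol.ids()
    mask = cerebellum_mask(localization_labels, ids)
    side = models["axial"].config.crop_side
    box = fit_bounding_box(mask, side=side)
    cropped = crop(norm, box)

    p_ax = predict_view(models["axial"], extract_stack_array(cropped, "axial"), "axial")
    p_co = predict_view(models["coronal"], extract_stack_array(cropped, "coronal"), "coronal")
    p_sa_m = predict_view(
        models["sagittal"], extract_stack_array(cropped, "sagittal"), "sagittal"
    )
    p_sa = expand_sagittal(p_sa_m, protocol)
    agg = view_aggregate(p_ax, p_co, p_sa, weights)
    crop_labels = probabilities_to_labels(agg, t1.spacing)
    native = embed(crop_labels, box, t1.shape)
    native = LabelMap(native.data, t1.spacing, t1.affine)
    report = volumes_from_labels(native, protocol)
    return native, report


def volumes_from_labels(labels: LabelMap, protocol: LabelProtocol) -> pd.DataFrame:
    """Exact voxel-count volumes per structure, plus merged-region rows."""
    vox = labels.voxel_volume_mm3
    counts = np.bincount(labels.data.ravel(), minlength=max(protocol.ids()) + 1)
    rows = [
        {
            "structure_id": s.label_id,
            "name": s.name,
            "volume_mm3": float(counts[s.label_id]) * vox,
        }
        for s in protocol.structures
    ]
    merged = aggregate_regions(labels, protocol)
    mcounts = np.bincount(merged.data.ravel(), minlength=max(REGION_NAMES) + 1)
    for rid, rname in REGION_NAMES.items():
        rows.append(
            {
                "structure_id": 100 + rid,  # offset keeps merged ids distinct
                "name": rname,
                "volume_mm3": float(mcounts[rid]) * vox,
            }
        )
    return pd.DataFrame(rows)
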