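"""Cerebellum localization: fixed-size working crop and native-space embed.

Segmentation operates on a fixed cubic crop (128 voxels per axis at 1 mm by
default) placed symmetrically around the cerebellum, which both bounds the
memory footprint and frees the networks from modeling the rest of the head.
The box is centered on the midpoint of the cerebellar extent per axis
(floor-rounded), clamped into the grid, and the volume is zero-padded when
the grid itself is smaller than the box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

from .core import LabelMap, Volume


@dataclass(frozen=True)
class BoundingBox:
    """A cubic crop: ``start`` voxel indices (0-based) and side length.

    ``pad_before`` records zero-padding added on the low side of each axis
    when the native grid is smaller than the box, so crops can always be
    mapped back to the native grid.
    """

    start: tuple[int, int, int]
    side: int
    grid_shape: tuple[int, int, int]
    pad_before: tuple[int, int, int] = (0, 0, 0)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(
            slice(s, min(s + self.side - p, n))
            for s, p, n in zip(self.start, self.pad_before, self.grid_shape)
        )  # type: ignore[return-value]


def cerebellum_mask(source: LabelMap, cerebellar_ids: Iterable[int]) -> np.ndarray:
    """Binary union of the listed label ids.

    ``source`` may be ground-truth labels (at phantom scale) or any coarse
    whole-brain segmentation carrying cerebellar labels (in production).
    """
    ids = sorted(set(int(i) for i in cerebellar_ids))
    if not ids:
        raise ValueError("cerebellar id set is empty")
    mask = np.isin(source.data, ids)
    if not mask.any():
        raise ValueError("no cerebellum found: listed ids absent from the label map")
    return mask


def fit_bounding_box(mask: np.ndarray, side: int = 128) -> BoundingBox:
    """Fit a cubic box of fixed ``side`` symmetrically around a mask.

    Per axis the box is centered on the midpoint of the mask's extent
    (rounded down) and clamped into the grid.  If the grid is smaller than
    ``side`` on an axis, the box covers the whole axis and the crop is
    zero-padded; if the mask is wider than ``side``, a containment warning
    is emitted but the side stays fixed.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot fit a bounding box around an empty mask")
    start, pad = [], []
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        prof = mask.any(axis=other)
        lo = int(np.argmax(prof))
        hi = int(len(prof) - np.argmax(prof[::-1]))  # exclusive
        if hi - lo > side:
            warnings.warn(
                f"mask extent {hi - lo} exceeds box side {side} on axis {ax}; "
                "the crop will not contain the full cerebellum",
                stacklevel=2,
            )
        n = mask.shape[ax]
        s = (lo + hi) // 2 - side // 2  # midpoint centering, floor rounding
        if n < side:
            start.append(0)
            pad.append((side - n) // 2)
        else:
            start.append(int(np.clip(s, 0, n - side)))
            pad.append(0)
    return BoundingBox(tuple(start), int(side), mask.shape, tuple(pad))


GridLike = Union[Volume, LabelMap]


def crop(item: GridLike, box: BoundingBox) -> GridLike:
    """Extract the box from a volume or label map, zero-padding as recorded."""
    if item.shape != box.grid_shape:
        raise ValueError(f"grid {item.shape} does not match box grid {box.grid_shape}")
    out = np.zeros((box.side,) * 3, dtype=item.data.dtype)
    src = box.slices()
    dst = tuple(
        slice(p, p + (s.stop - s.start)) for p, s in zip(box.pad_before, src)
    )
    out[dst] = item.data[src]
    return item.with_data(out)


def embed(cropped: LabelMap, box: BoundingBox, native_shape: tuple[int, int, int]) -> LabelMap:
    """Place cropped labels back into the native grid (background outside)."""
    if cropped.shape != (box.side,) * 3:
        raise ValueError(f"cropped shape {cropped.shape} does not match box side {box.side}")
    if tuple(native_shape) != tuple(box.grid_shape):
        raise ValueError("native shape does not match the box's grid shape")
    out = np.zeros(native_shape, dtype=cropped.data.dtype)
    src = box.slices()
    dst = tuple(slice(p, p + (s.stop - s.start)) for p, s in zip(box.pad_before, src))
    out[src] = cropped.data[dst]
    return cropped.with_data(out)
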