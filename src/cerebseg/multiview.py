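"""2.5D multi-view machinery: slice stacking, per-view prediction, and
probability-space view aggregation.

Each anatomical plane (axial, coronal, sagittal) is segmented by its own 2D
network.  Spatial information aggregation (SPI) hands the network volumetric
context by stacking each slice with its three preceding and three succeeding
neighbors into a 7-channel input; at the volume border missing neighbors are
replaced by the nearest valid slice (edge replication).  The three per-view
class-probability fields are combined by a weighted arithmetic mean in
probability space before the final argmax.

Sagittal slices cannot distinguish the two hemispheres, so the sagittal
network predicts lateral-merged classes; :func:`expand_sagittal` copies each
merged probability to both lateral classes before aggregation, and the
sagittal view receives half weight by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PLANE_AXIS, LabelMap, Volume
from .protocol import LabelProtocol

SPI_NEIGHBORS = 3  # slices on each side -> 7 channels
DEFAULT_VIEW_WEIGHTS = (1.0, 1.0, 0.5)  # axial, coronal, sagittal


@dataclass(frozen=True)
class SliceStack:
    """One 7-channel network input: a slice with its +/-3 neighbors."""

    channels: np.ndarray  # (7, H, W)
    plane: str
    index: int

    def __post_init__(self) -> None:
        if self.channels.shape[0] != 2 * SPI_NEIGHBORS + 1:
            raise ValueError(f"expected {2 * SPI_NEIGHBORS + 1} channels")


@dataclass
class ViewProbabilities:
    """Per-voxel class probabilities on the crop grid, from one view."""

    probs: np.ndarray  # (C, nx, ny, nz)
    view: str

    def __post_init__(self) -> None:
        if self.probs.ndim != 4:
            raise ValueError("probability field must be (C, nx, ny, nz)")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]


def extract_stack_array(volume: np.ndarray | Volume, plane: str) -> np.ndarray:
    """All slice stacks of a volume: (n_slices, 7, H, W), edge-replicated."""
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if plane not in PLANE_AXIS:
        raise ValueError(f"unknown plane {plane!r}")
    axis = PLANE_AXIS[plane]
    moved = np.moveaxis(data, axis, 0)
    n = moved.shape[0]
    if n < 1:
        raise ValueError("volume has no slices along the requested plane")
    offsets = np.arange(-SPI_NEIGHBORS, SPI_NEIGHBORS + 1)
    idx = np.clip(np.arange(n)[:, None] + offsets[None, :], 0, n - 1)
    return moved[idx]  # (n, 7, H, W)


def extract_stacks(volume: np.ndarray | Volume, plane: str) -> list[SliceStack]:
    """Ordered :class:`SliceStack` objects, one per slice of the plane."""
    arr = extract_stack_array(volume, plane)
    return [SliceStack(arr[i], plane, i) for i in range(arr.shape[0])]


def slice_positions(n: int) -> np.ndarray:
    """Slice indices normalized to [-1, 1] (0 for a single slice)."""
    if n == 1:
        return np.zeros(1, dtype=np.float32)
    return (2.0 * np.arange(n) / (n - 1) - 1.0).astype(np.float32)


def labels_to_slices(labels: np.ndarray | LabelMap, plane: str) -> np.ndarray:
    data = labels.data if isinstance(labels, LabelMap) else np.asarray(labels)
    return np.moveaxis(data, PLANE_AXIS[plane], 0)


def predict_view(
    model, stacks: list[SliceStack] | np.ndarray, plane: str | None = None,
    chunk: int = 32,
) -> ViewProbabilities:
    """Run a per-view model over all stacks and reassemble the crop volume.

    ``model`` must expose ``predict_proba(batch, slice_pos)`` mapping a
    (B, 7, H, W) batch to (B, C, H, W) probabilities (softmax contract) and
    a ``config.view`` tag; the view must match the stacks' plane.
    """
    if isinstance(stacks, np.ndarray):
        arr = stacks
        if plane is None:
            raise ValueError("plane required when passing a raw stack array")
    else:
        if not stacks:
            raise ValueError("no stacks to predict")
        plane = stacks[0].plane
        arr = np.stack([s.channels for s in stacks])
    view = getattr(getattr(model, "config", None), "view", plane)
    if view != plane:
        raise ValueError(f"model view {view!r} does not match stacks' plane {plane!r}")
    n, c = arr.shape[:2]
    if c != 2 * SPI_NEIGHBORS + 1:
        raise ValueError(f"stacks must have {2 * SPI_NEIGHBORS + 1} channels, got {c}")
    pos = slice_positions(n)
    outs = []
    fast = getattr(model, "predict_proba_cl", None)
    for i in range(0, n, chunk):
        if fast is not None:
            outs.append(np.moveaxis(fast(arr[i : i + chunk], pos[i : i + chunk]), -1, 1))
        else:
            outs.append(model.predict_proba(arr[i : i + chunk], pos[i : i + chunk]))
    probs2d = np.concatenate(outs)  # (n, C, H, W)
    if not np.allclose(probs2d.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("model violated the softmax contract (per-pixel unit sum)")
    # reassemble: slice axis back to its anatomical position
    vol = np.moveaxis(probs2d, 0, 1 + PLANE_AXIS[plane])  # (C, nx, ny, nz)
    return ViewProbabilities(vol.astype(np.float32), plane)


# ---------------------------------------------------------------------------
# class sets


def sagittal_class_lut(protocol: LabelProtocol) -> np.ndarray:
    """Map full label ids to lateral-merged class indices.

    Merged classes: 0 background, 1-10 the ten lobule types (left and right
    collapse), 11-15 the vermis segments, 16 white matter.
    """
    lut = np.zeros(max(protocol.ids()) + 1, dtype=np.int32)
    lobules_left = protocol.ids_of("lobule", "left")
    for i, lid in enumerate(lobules_left):
        lut[lid] = 1 + i
        lut[protocol.lr_swap(lid)] = 1 + i
    for j, vid in enumerate(protocol.ids_of("vermis")):
        lut[vid] = 11 + j
    for wid in protocol.ids_of("white_matter"):
        lut[wid] = 16
    return lut


def n_classes_for_view(protocol: LabelProtocol, view: str) -> int:
    if view == "sagittal":
        return int(sagittal_class_lut(protocol).max()) + 1
    return max(protocol.ids()) + 1


def class_lut_for_view(protocol: LabelProtocol, view: str) -> np.ndarray:
    """LUT translating label ids to the view's training class indices."""
    if view == "sagittal":
        return sagittal_class_lut(protocol)
    return np.arange(max(protocol.ids()) + 1, dtype=np.int32)


def expand_sagittal(
    probs_merged: ViewProbabilities, protocol: LabelProtocol
) -> ViewProbabilities:
    """Lift merged-lateral sagittal probabilities to the full class set.

    Each merged class's probability is copied to both its left and right
    full-set classes; background and vermis pass through; the result is
    renormalized per voxel.
    """
    lut = sagittal_class_lut(protocol)
    n_merged = int(lut.max()) + 1
    if probs_merged.n_classes != n_merged:
        raise ValueError(
            f"expected {n_merged} merged classes, got {probs_merged.n_classes}"
        )
    n_full = max(protocol.ids()) + 1
    full = np.empty((n_full,) + probs_merged.probs.shape[1:], dtype=np.float32)
    full[0] = probs_merged.probs[0]
    for lab in protocol.ids():
        full[lab] = probs_merged.probs[lut[lab]]
    full /= full.sum(axis=0, keepdims=True)
    return ViewProbabilities(full, "sagittal")


def view_aggregate(
    p_axial: ViewProbabilities,
    p_coronal: ViewProbabilities,
    p_sagittal: ViewProbabilities,
    weights: tuple[float, float, float] = DEFAULT_VIEW_WEIGHTS,
) -> ViewProbabilities:
    """Weighted arithmetic mean of per-view probabilities, renormalized."""
    maps = (p_axial, p_coronal, p_sagittal)
    shape = maps[0].probs.shape
    for m in maps[1:]:
        if m.probs.shape != shape:
            raise ValueError("view probability grids/class sets do not match")
    if all(w == 0 for w in weights):
        raise ValueError("at least one view weight must be nonzero")
    acc = np.zeros(shape, dtype=np.float64)
    for w, m in zip(weights, maps):
        if w:
            acc += w * m.probs
    acc /= acc.sum(axis=0, keepdims=True)
    return ViewProbabilities(acc.astype(np.float32), "aggregate")


def probabilities_to_labels(
    p: ViewProbabilities,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelMap:
    """Per-voxel argmax; ties resolve toward the lowest class id."""
    return LabelMap(np.argmax(p.probs, axis=0).astype(np.int32), spacing)
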