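"""The 27-structure cerebellar label protocol.

The cerebellum is subdivided into 27 disjoint macroscopic structures: ten
hemispheric lobules per hemisphere (I-IV, V, VI, Crus I, Crus II, VIIb,
VIIIa, VIIIb, IX, X), five vermal sub-segments (VI..X) and one white-matter
label per hemisphere.  Integer ids are assigned in a fixed, documented order:

====  ==========================
1-10  left lobules, superior to inferior order
11-20 right lobules, same order
21-25 vermis VI, VII, VIII, IX, X
26    left cerebellar white matter
27    right cerebellar white matter
====  ==========================

Id 0 is reserved for background.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelMap

LOBULE_NAMES = ("I_IV", "V", "VI", "Crus_I", "Crus_II", "VIIb", "VIIIa", "VIIIb", "IX", "X")
VERMIS_NAMES = ("VI", "VII", "VIII", "IX", "X")

# ids of the merged evaluation regions produced by aggregate_regions
REGION_LEFT_CGM = 1
REGION_RIGHT_CGM = 2
REGION_VERMIS = 3
REGION_LEFT_CWM = 4
REGION_RIGHT_CWM = 5
REGION_NAMES = {
    REGION_LEFT_CGM: "Left_CGM",
    REGION_RIGHT_CGM: "Right_CGM",
    REGION_VERMIS: "Vermis",
    REGION_LEFT_CWM: "Left_CWM",
    REGION_RIGHT_CWM: "Right_CWM",
}


@dataclass(frozen=True)
class StructureDef:
    label_id: int
    name: str
    laterality: str  # left | right | midline
    tissue: str  # gray | white
    group: str  # lobule | vermis | white_matter

    def __post_init__(self) -> None:
        if self.label_id <= 0:
            raise ValueError("label_id must be a positive integer (0 is background)")
        if self.laterality not in ("left", "right", "midline"):
            raise ValueError(f"bad laterality {self.laterality!r}")
        if self.tissue not in ("gray", "white"):
            raise ValueError(f"bad tissue {self.tissue!r}")
        if self.group not in ("lobule", "vermis", "white_matter"):
            raise ValueError(f"bad group {self.group!r}")
        if self.group == "white_matter" and self.tissue != "white":
            raise ValueError("white_matter structures must have tissue='white'")
        if self.group == "vermis" and self.laterality != "midline":
            raise ValueError("vermis structures must have laterality='midline'")


@dataclass(frozen=True)
class LabelProtocol:
    structures: tuple[StructureDef, ...]
    background_id: int = 0

    def __post_init__(self) -> None:
        ids = [s.label_id for s in self.structures]
        names = [s.name for s in self.structures]
        if len(set(ids)) != len(ids) or len(set(names)) != len(names):
            raise ValueError("structure ids and names must be unique")

    # -- lookups -------------------------------------------------------
    def by_id(self, label_id: int) -> StructureDef:
        for s in self.structures:
            if s.label_id == label_id:
                return s
        raise KeyError(f"unknown label id {label_id}")

    def ids(self) -> tuple[int, ...]:
        return tuple(s.label_id for s in self.structures)

    def gray_ids(self) -> tuple[int, ...]:
        return tuple(s.label_id for s in self.structures if s.tissue == "gray")

    def ids_of(self, group: str, laterality: str | None = None) -> tuple[int, ...]:
        return tuple(
            s.label_id
            for s in self.structures
            if s.group == group and (laterality is None or s.laterality == laterality)
        )

    # -- L/R involution ------------------------------------------------
    def lr_swap(self, label_id: int) -> int:
        if label_id == self.background_id:
            return label_id
        s = self.by_id(label_id)
        if s.laterality == "midline":
            return label_id
        want_side = "right" if s.laterality == "left" else "left"
        for t in self.structures:
            if t.laterality == want_side and t.group == s.group and _base_name(t) == _base_name(s):
                return t.label_id
        raise KeyError(f"no lateral homolog for id {label_id}")

    def lr_swap_lut(self) -> np.ndarray:
        """Lookup table mapping every id (0..max) to its lateral homolog."""
        lut = np.arange(max(self.ids()) + 1, dtype=np.int32)
        for s in self.structures:
            lut[s.label_id] = self.lr_swap(s.label_id)
        return lut

    def hash(self) -> str:
        text = ";".join(
            f"{s.label_id},{s.name},{s.laterality},{s.tissue},{s.group}"
            for s in self.structures
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _base_name(s: StructureDef) -> str:
    return s.name.removeprefix("Left_").removeprefix("Right_")


def build_protocol() -> LabelProtocol:
    """Build the canonical 27-structure protocol table."""
    structures: list[StructureDef] = []
    for i, nm in enumerate(LOBULE_NAMES):
        structures.append(StructureDef(1 + i, f"Left_{nm}", "left", "gray", "lobule"))
    for i, nm in enumerate(LOBULE_NAMES):
        structures.append(StructureDef(11 + i, f"Right_{nm}", "right", "gray", "lobule"))
    for i, nm in enumerate(VERMIS_NAMES):
        structures.append(StructureDef(21 + i, f"Vermis_{nm}", "midline", "gray", "vermis"))
    structures.append(StructureDef(26, "Left_CWM", "left", "white", "white_matter"))
    structures.append(StructureDef(27, "Right_CWM", "right", "white", "white_matter"))
    return LabelProtocol(tuple(structures))


def _validate_ids(labels: LabelMap, protocol: LabelProtocol, what: str) -> None:
    present = set(labels.ids().tolist())
    unknown = sorted(present - set(protocol.ids()))
    if unknown:
        raise ValueError(f"{what} contains unknown label ids: {unknown}")


def swap_lateral_labels(labelmap: LabelMap, protocol: LabelProtocol) -> LabelMap:
    """Replace every voxel id by its lateral homolog; geometry is untouched.

    Midline (vermis) ids are fixed points.  Applying the swap twice restores
    the input.  Mirroring of voxel positions is a separate operation and
    lives in the augmentation module.
    """
    _validate_ids(labelmap, protocol, "labelmap")
    lut = protocol.lr_swap_lut()
    return labelmap.with_data(lut[labelmap.data])


def merge_cortex_and_wm(
    cortex: LabelMap,
    wm_mask: np.ndarray,
    protocol: LabelProtocol,
    gap_mask: np.ndarray | None = None,
    cortex_wins: bool = True,
) -> LabelMap:
    """Merge a gray-structure label map with a white-matter mask.

    The cortex map provides the gray structures; ``wm_mask`` voxels are
    assigned the left or right white-matter id depending on their side of
    the grid's mid-sagittal plane.  Gap voxels -- background voxels whose
    26-neighborhood touches both tissue classes, or an explicit
    ``gap_mask`` -- are assigned the gray id of their nearest gray voxel
    (Euclidean distance in mm; ties broken toward the lowest label id).

    ``cortex_wins`` controls precedence on voxels claimed by both sources
    (default: cortex labels win, white matter fills only background).
    """
    _validate_ids(cortex, protocol, "cortex map")
    gray = set(protocol.gray_ids())
    present = set(cortex.ids().tolist())
    if not present:
        raise ValueError("cortex map is empty")
    if present - gray:
        raise ValueError(f"cortex map contains non-gray ids: {sorted(present - gray)}")
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if wm_mask.shape != cortex.shape:
        raise ValueError(f"grid mismatch: cortex {cortex.shape} vs wm {wm_mask.shape}")

    left_wm = protocol.ids_of("white_matter", "left")[0]
    right_wm = protocol.ids_of("white_matter", "right")[0]
    out = cortex.data.copy()

    # side of the mid-sagittal plane along the L-R axis (axis 0)
    nx = cortex.shape[0]
    x_index = np.arange(nx).reshape(-1, 1, 1)
    is_left = np.broadcast_to(x_index < nx / 2.0, cortex.shape)

    wm_target = wm_mask & (out == 0) if cortex_wins else wm_mask
    out[wm_target & is_left] = left_wm
    out[wm_target & ~is_left] = right_wm

    if gap_mask is None:
        # background voxel whose 26-neighborhood touches both tissue classes
        struct = np.ones((3, 3, 3), bool)
        is_gray_vox = np.isin(out, list(gray))
        is_wm_vox = (out == left_wm) | (out == right_wm)
        near_gray = ndimage.binary_dilation(is_gray_vox, struct)
        near_wm = ndimage.binary_dilation(is_wm_vox, struct)
        gap = (out == 0) & near_gray & near_wm
    else:
        gap = np.asarray(gap_mask, dtype=bool)
        if gap.shape != cortex.shape:
            raise ValueError("gap mask grid mismatch")
        gap = gap & (out == 0)

    if gap.any():
        gray_map = cortex.with_data(np.where(np.isin(out, list(gray)), out, 0))
        out[gap] = nearest_gray_labels(gray_map, protocol, gap)
    return cortex.with_data(out)


def nearest_gray_labels(
    cortex: LabelMap, protocol: LabelProtocol, query: np.ndarray
) -> np.ndarray:
    """Id of the nearest (mm, Euclidean) gray voxel for each query voxel.

    Distance ties are resolved toward the lowest label id, so the result is
    deterministic.  Implemented as one distance transform per present gray
    id, which is exact and fast for the ~27-label protocol.
    """
    gray_ids = [i for i in sorted(cortex.ids().tolist()) if i in set(protocol.gray_ids())]
    if not gray_ids:
        raise ValueError("no gray voxels to map gaps onto")
    best_d = np.full(int(query.sum()), np.inf)
    best_id = np.zeros(int(query.sum()), dtype=np.int32)
    for lab in gray_ids:  # ascending: strict '<' keeps the lowest id on ties
        d = ndimage.distance_transform_edt(cortex.data != lab, sampling=cortex.spacing)
        dq = d[query]
        take = dq < best_d - 1e-9
        best_d[take] = dq[take]
        best_id[take] = lab
    return best_id


def aggregate_regions(labelmap: LabelMap, protocol: LabelProtocol) -> LabelMap:
    """Relabel into the merged evaluation regions.

    Left/right hemispheric lobules collapse to left/right cerebellar gray
    matter, the five vermal segments to a single vermis region, and the
    white-matter labels stay separated by side.
    """
    _validate_ids(labelmap, protocol, "labelmap")
    lut = np.zeros(max(protocol.ids()) + 1, dtype=np.int32)
    for s in protocol.structures:
        if s.group == "lobule":
            lut[s.label_id] = REGION_LEFT_CGM if s.laterality == "left" else REGION_RIGHT_CGM
        elif s.group == "vermis":
            lut[s.label_id] = REGION_VERMIS
        else:
            lut[s.label_id] = REGION_LEFT_CWM if s.laterality == "left" else REGION_RIGHT_CWM
    return labelmap.with_data(lut[labelmap.data])


# -- exports -----------------------------------------------------------


def export_lookup_table(protocol: LabelProtocol, path) -> None:
    """Write the protocol as a tab-separated lookup table."""
    with open(path, "w") as fh:
        fh.write("id\tname\tlaterality\ttissue\tgroup\n")
        for s in protocol.structures:
            fh.write(f"{s.label_id}\t{s.name}\t{s.laterality}\t{s.tissue}\t{s.group}\n")


def export_color_lut(protocol: LabelProtocol, path) -> None:
    """Write a FreeSurfer-style color lookup table for NIfTI viewers."""
    rng = np.random.default_rng(1071)  # fixed palette
    with open(path, "w") as fh:
        fh.write(f"0\tBackground\t0\t0\t0\t0\n")
        for s in protocol.structures:
            r, g, b = rng.integers(40, 255, 3)
            fh.write(f"{s.label_id}\t{s.name}\t{r}\t{g}\t{b}\t255\n")
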