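"""Training-time data augmentation.

Four augmentation families are implemented:

* in-slice affine transforms (translation, rotation, scaling) sampled
  uniformly from fixed ranges: translation within +/-12 mm per in-slice
  axis, scaling in [0.95, 1.2], rotation within +/-20 degrees;
* random left-right flipping, which mirrors image and labels across the
  mid-sagittal plane and swaps lateralized label ids so that left labels
  remain on the anatomical left;
* additive bias fields synthesized as random cubic trivariate polynomials
  with coefficients uniform in [-0.5, 0.5] on coordinates normalized to
  [-1, 1]^3, superimposed on [0, 1]-normalized intensities;
* non-linear deformation by smooth displacement fields, applied by
  backward warping (linear interpolation for images, nearest-neighbor for
  labels), used to build a static set of deformed training cases.

Identity parameters are bit-exact no-ops, and label resampling can never
invent ids absent from the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelMap, Volume, check_same_grid
from .phantom import DisplacementField
from .protocol import LabelProtocol, swap_lateral_labels

TRANSLATION_RANGE_MM = (-12.0, 12.0)
SCALE_RANGE = (0.95, 1.2)
ROTATION_RANGE_DEG = (-20.0, 20.0)
BIAS_COEFF_RANGE = (-0.5, 0.5)

#: exponents (a, b, c) of all trivariate monomials x^a y^b z^c with
#: a+b+c <= 3, in graded lexicographic order -- 20 basis functions
BIAS_EXPONENTS: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for deg in range(4)
    for a in range(deg, -1, -1)
    for b in range(deg - a, -1, -1)
    for c in (deg - a - b,)
)
assert len(BIAS_EXPONENTS) == 20


@dataclass(frozen=True)
class AffineParams:
    """An in-slice affine transform composed about the slice center."""

    translation_mm: tuple[float, float]
    scale: float
    rotation_deg: float

    def matrix(self, spacing: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
        """3x3 homogeneous matrix T.R.S in pixel coordinates."""
        th = np.deg2rad(self.rotation_deg)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0, 0, 1.0]]
        )
        sc = np.diag([self.scale, self.scale, 1.0])
        tr = np.eye(3)
        tr[0, 2] = self.translation_mm[0] / spacing[0]
        tr[1, 2] = self.translation_mm[1] / spacing[1]
        return tr @ rot @ sc


def sample_affine(
    rng: np.random.Generator,
    translation_range: tuple[float, float] = TRANSLATION_RANGE_MM,
    scale_range: tuple[float, float] = SCALE_RANGE,
    rotation_range: tuple[float, float] = ROTATION_RANGE_DEG,
) -> AffineParams:
    """Draw affine parameters uniformly from the configured ranges."""
    t = rng.uniform(*translation_range, size=2)
    s = rng.uniform(*scale_range)
    r = rng.uniform(*rotation_range)
    return AffineParams((float(t[0]), float(t[1])), float(s), float(r))


def apply_affine_inplane(
    image_slice: np.ndarray,
    label_slice: np.ndarray | None,
    params: AffineParams,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply an in-slice affine transform by backward warping.

    The transform is composed about the slice center.  Images are resampled
    with linear interpolation, labels with nearest-neighbor; pixels mapping
    outside the field of view become background (0).  ``image_slice`` may
    be a single slice (H, W) or a channel stack (C, H, W) transformed
    identically per channel.
    """
    if params == AffineParams((0.0, 0.0), 1.0, 0.0):
        return image_slice, label_slice
    mat = params.matrix(spacing)
    if abs(np.linalg.det(mat)) < 1e-12:
        raise ValueError("affine matrix is singular")
    shape = image_slice.shape[-2:]
    center = (np.asarray(shape) - 1) / 2.0
    inv = np.linalg.inv(mat)
    a, offset = inv[:2, :2], inv[:2, 2]
    # compose about the slice center: x_src = A (x_dst - c) + A t + c
    full_offset = center - a @ center + offset
    def warp(sl: np.ndarray, order: int) -> np.ndarray:
        return ndimage.affine_transform(
            sl, a, offset=full_offset, order=order, mode="constant", cval=0.0,
            output=sl.dtype if order == 0 else np.float32,
        )
    if image_slice.ndim == 3:
        # one call for the whole channel stack: identity on the channel axis
        a3 = np.zeros((3, 3), dtype=float)
        a3[0, 0] = 1.0
        a3[1:, 1:] = a
        img = ndimage.affine_transform(
            image_slice, a3, offset=np.r_[0.0, full_offset], order=1,
            mode="constant", cval=0.0, output=np.float32,
        )
    else:
        img = warp(image_slice, 1)
    lab = None
    if label_slice is not None:
        lab = warp(label_slice, 0)
    return img, lab


def random_lr_flip(
    volume: Volume,
    labels: LabelMap,
    protocol: LabelProtocol,
    rng: np.random.Generator,
    p: float = 0.5,
    lr_axis: int = 0,
) -> tuple[Volume, LabelMap]:
    """With probability ``p``, mirror across the mid-sagittal plane.

    Both grids are mirrored along the left-right axis and lateralized label
    ids are swapped, so left structures stay labeled as left structures.
    Applying a forced flip twice restores the input exactly.
    """
    check_same_grid(volume, labels)
    if lr_axis != 0:
        raise ValueError("volumes must be in canonical R-A-S order (L-R axis 0)")
    if rng.uniform() >= p:
        return volume, labels
    flipped_img = volume.with_data(np.flip(volume.data, axis=lr_axis).copy())
    flipped_lab = labels.with_data(np.flip(labels.data, axis=lr_axis).copy())
    return flipped_img, swap_lateral_labels(flipped_lab, protocol)


def sample_bias_coeffs(rng: np.random.Generator) -> np.ndarray:
    """20 polynomial coefficients, uniform in [-0.5, 0.5]."""
    lo, hi = BIAS_COEFF_RANGE
    return rng.uniform(lo, hi, size=len(BIAS_EXPONENTS))


def sample_bias_field(
    grid_shape: tuple[int, int, int],
    rng: np.random.Generator,
    coeffs: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate a random cubic polynomial field on [-1, 1]^3 coordinates."""
    if coeffs is None:
        coeffs = sample_bias_coeffs(rng)
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (len(BIAS_EXPONENTS),):
        raise ValueError(f"expected {len(BIAS_EXPONENTS)} coefficients")
    axes = [
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in grid_shape
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    field = np.zeros(grid_shape, dtype=np.float32)
    for c, (a, b, g) in zip(coeffs, BIAS_EXPONENTS):
        if c != 0.0:
            field += np.float32(c) * (x ** a * y ** b * z ** g).astype(np.float32)
    return field


def apply_bias(volume: Volume, field: np.ndarray) -> Volume:
    """Additively superimpose a bias field on a [0, 1]-normalized volume."""
    field = np.asarray(field, dtype=np.float32)
    if field.shape != volume.shape:
        raise ValueError("bias field grid mismatch")
    if not field.any():
        return volume
    return volume.with_data(volume.data + field)


def apply_displacement(
    volume: Volume | None, labels: LabelMap | None, field: DisplacementField
) -> tuple[Volume | None, LabelMap | None]:
    """Backward-warp a volume and labels through a displacement field.

    The field gives, for each output voxel, the displacement (mm) to the
    source location sampled in the input.  Images use linear interpolation,
    labels nearest-neighbor; samples outside the grid become background.
    A zero field is an exact no-op.
    """
    ref = volume if volume is not None else labels
    if ref is None:
        raise ValueError("need at least one of volume/labels")
    if field.grid_shape != ref.shape:
        raise ValueError(
            f"field grid {field.grid_shape} does not match volume grid {ref.shape}"
        )
    if field.max_disp_mm == 0 or not field.vectors.any():
        return volume, labels
    spacing = np.asarray(field.spacing_mm)
    idx = np.indices(ref.shape, dtype=np.float32)
    coords = idx + np.moveaxis(field.vectors, -1, 0) / spacing.reshape(3, 1, 1, 1)
    out_vol = out_lab = None
    if volume is not None:
        out_vol = volume.with_data(
            ndimage.map_coordinates(volume.data, coords, order=1, mode="constant", cval=0.0)
        )
    if labels is not None:
        out_lab = labels.with_data(
            ndimage.map_coordinates(labels.data, coords, order=0, mode="constant", cval=0)
        )
    return out_vol, out_lab


def build_static_deformed_set(
    cases: list[tuple[Volume, LabelMap]],
    fields: list[DisplacementField],
    pairing_rng: np.random.Generator,
) -> list[tuple[Volume, LabelMap, tuple[int, int]]]:
    """Pair every deformation field with a training case.

    Each field deforms exactly one case; every case is used at least once
    (round-robin over a random case permutation, then random assignment for
    the remaining fields).  Outputs carry ``(case_index, field_index)``
    provenance.
    """
    if not cases or not fields:
        raise ValueError("need at least one case and one field")
    n_cases, n_fields = len(cases), len(fields)
    order = pairing_rng.permutation(n_cases)
    assignment = [int(order[i % n_cases]) for i in range(min(n_cases, n_fields))]
    if n_fields > n_cases:
        assignment += [int(i) for i in pairing_rng.integers(0, n_cases, n_fields - n_cases)]
    out = []
    for field_idx, case_idx in enumerate(assignment):
        vol, lab = cases[case_idx]
        dvol, dlab = apply_displacement(vol, lab, fields[field_idx])
        out.append((dvol, dlab, (case_idx, field_idx)))
    return out
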