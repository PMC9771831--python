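"""Core in-memory containers for volumes and label maps.

Arrays are kept in a canonical R-A-S axis order: axis 0 runs left->right,
axis 1 posterior->anterior, axis 2 inferior->superior.  Anatomical planes are
therefore fixed array axes: sagittal slices index axis 0, coronal slices axis
1, axial slices axis 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: slicing axis per anatomical plane in R-A-S array order
PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """A 3D intensity grid with isotropic-ish voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data, dtype=np.float32))


@dataclass
class LabelMap:
    """An integer label grid aligned with a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label data must be integer, got {self.data.dtype}")
        self.data = self.data.astype(np.int32, copy=False)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "LabelMap":
        return replace(self, data=np.asarray(data).astype(np.int32, copy=False))

    def ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the map."""
        u = np.unique(self.data)
        return u[u != 0]


def check_same_grid(a, b, what: str = "inputs") -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what} have mismatched grids: {a.shape} vs {b.shape}")
    if tuple(a.spacing) != tuple(b.spacing):
        raise ValueError(
            f"{what} have mismatched spacing: {a.spacing} vs {b.spacing}"
        )


def robust_normalize(volume: Volume, p_lo: float = 0.1, p_hi: float = 99.9) -> Volume:
    """Rescale intensities to [0, 1] using robust percentiles.

    Only a linear rescaling is applied -- no bias-field correction or
    histogram matching -- so fine intensity detail is preserved.
    """
    lo, hi = np.percentile(volume.data, [p_lo, p_hi])
    if hi <= lo:
        return volume.with_data(np.zeros_like(volume.data))
    out = (volume.data - lo) / (hi - lo)
    return volume.with_data(np.clip(out, 0.0, 1.0))
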