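"""Procedural cerebellum phantoms with ground-truth labels.

The generator emulates the gross geometry relevant to lobular segmentation:
two ellipsoidal gray-matter hemispheres whose cortical shell is partitioned
into ten angular "lobule" wedges each, a midline vermis partitioned into
five wedges, and a white-matter core with branches reaching into the cortex
band.  Intensities follow the T1 contrast ordering WM > GM > background on
a [0, 1] scale, with additive Gaussian noise and an optional smooth
multiplicative intensity drift per acquisition.

Subjects drawn with different seeds vary in hemisphere size, position and
wedge orientation, emulating inter-subject anatomical variability.  Atrophy
retracts the outer cortical surface inward and erodes white-matter branches,
jointly reducing gray- and white-matter volume.

All randomness flows through keyed ``numpy`` generator streams
``(seed, subject, purpose)``, so adding new outputs never perturbs existing
draws and every product is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import LabelMap, Volume
from .protocol import LabelProtocol, build_protocol, merge_cortex_and_wm

# purpose codes for RNG stream keying
_ANATOMY, _NOISE, _DRIFT, _JITTER, _FIELD = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cerebellum.

    ``hemisphere_radii_mm``, ``cortical_thickness_mm`` and
    ``vermis_halfwidth_mm`` default to fractions of the grid extent so the
    anatomy scales with the grid (4 mm cortex on the default 96 mm grid).
    ``noise_sd`` is the additive noise standard deviation as a fraction of
    the mean gray-matter intensity; ``drift_amplitude`` the peak relative
    amplitude of the smooth multiplicative intensity drift.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    hemisphere_radii_mm: tuple[float, float, float] | None = None
    cortical_thickness_mm: float | None = None
    n_lobule_sectors: int = 10
    vermis_halfwidth_mm: float | None = None
    wm_branch_count: int = 6
    noise_sd: float = 0.05
    drift_amplitude: float = 0.10
    atrophy: float = 0.0
    seed: int = 0
    # inter-subject anatomical variability (uniform half-ranges)
    center_jitter_mm: float = 1.5
    radii_jitter: float = 0.04
    phase_jitter_deg: float = 5.0

    # intensity means on a [0, 1] scale, T1 ordering WM > GM > background
    background_mean: float = 0.1
    gm_mean: float = 0.5
    wm_mean: float = 0.8

    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)

    def radii(self) -> np.ndarray:
        if self.hemisphere_radii_mm is not None:
            return np.asarray(self.hemisphere_radii_mm, float)
        ext = self.extent_mm()
        return np.asarray([0.19 * ext[0], 0.23 * ext[1], 0.17 * ext[2]])

    def thickness(self) -> float:
        if self.cortical_thickness_mm is not None:
            return float(self.cortical_thickness_mm)
        return float(0.042 * self.extent_mm().mean())

    def vermis_halfwidth(self) -> float:
        if self.vermis_halfwidth_mm is not None:
            return float(self.vermis_halfwidth_mm)
        return float(0.045 * self.extent_mm().mean())

    def validate(self) -> None:
        if not (0.0 <= self.atrophy <= 1.0):
            raise ValueError(f"atrophy must lie in [0, 1], got {self.atrophy}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if min(self.grid_shape) < 16:
            raise ValueError("grid too small to contain a cerebellum phantom")
        thick_eff = self.thickness() * (1.0 - self.atrophy)
        if thick_eff < max(self.spacing_mm):
            raise ValueError(
                "residual cortical thickness "
                f"{thick_eff:.2f} mm is below one voxel at spacing {self.spacing_mm}"
            )
        r = self.radii()
        ext = self.extent_mm()
        if 1.8 * r[0] * 2 > ext[0] or 2 * r[1] > ext[1] or 2 * r[2] > ext[2]:
            raise ValueError("grid too small for the requested hemisphere radii")


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement in mm, vanishing on the boundary."""

    vectors: np.ndarray  # (nx, ny, nz, 3)
    spacing_mm: tuple[float, float, float]
    max_disp_mm: float
    smoothness_mm: float

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]


def _rng(spec_seed: int, subject: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng([int(spec_seed) & 0x7FFFFFFF, subject, purpose])


def _mm_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)  # type: ignore[return-value]


def _build_anatomy(spec: PhantomSpec, rng: np.random.Generator,
                   protocol: LabelProtocol) -> LabelMap:
    """Rasterize the 27-structure ground-truth label map."""
    x, y, z = _mm_grids(spec)
    center = spec.extent_mm() / 2.0 + rng.uniform(
        -spec.center_jitter_mm, spec.center_jitter_mm, 3
    )
    radii = spec.radii() * (1.0 + rng.uniform(-spec.radii_jitter, spec.radii_jitter, 3))
    phase = np.deg2rad(rng.uniform(-spec.phase_jitter_deg, spec.phase_jitter_deg))
    a = spec.atrophy

    tau = spec.thickness() / radii.mean()  # shell thickness as radius fraction
    rho_in = 1.0 - tau  # WM/GM interface
    rho_out = 1.0 - a * tau  # cortical surface retracts with atrophy

    labels = np.zeros(spec.grid_shape, dtype=np.int32)

    # ---- vermis: midline ellipsoid, 5 angular wedges -----------------
    v_scale = 1.0 - a * tau
    v_radii = np.array([
        spec.vermis_halfwidth(), 0.75 * radii[1], 0.72 * radii[2]
    ]) * v_scale
    rho_v = np.sqrt(
        ((x - center[0]) / v_radii[0]) ** 2
        + ((y - center[1]) / v_radii[1]) ** 2
        + ((z - center[2]) / v_radii[2]) ** 2
    )
    # angle in the sagittal plane; wedge boundaries are radial planes
    phi = np.broadcast_to(
        np.mod(np.arctan2(z - center[2], y - center[1]) + phase, 2 * np.pi),
        spec.grid_shape,
    )
    vermis_ids = protocol.ids_of("vermis")
    in_vermis = rho_v <= 1.0
    sector_v = np.clip(
        np.floor(phi / (2 * np.pi / len(vermis_ids))).astype(int),
        0, len(vermis_ids) - 1,
    )
    labels[in_vermis] = np.asarray(vermis_ids, np.int32)[sector_v[in_vermis]]

    wm_mask = np.zeros(spec.grid_shape, dtype=bool)
    branch_pts = np.zeros(spec.grid_shape, dtype=bool)

    for side, sign in (("left", -1.0), ("right", +1.0)):
        c = center + np.array([sign * 0.80 * radii[0], 0.0, 0.0])
        rho = np.sqrt(
            ((x - c[0]) / radii[0]) ** 2
            + ((y - c[1]) / radii[1]) ** 2
            + ((z - c[2]) / radii[2]) ** 2
        )
        # cortical shell partitioned into angular wedges
        shell = (rho > rho_in) & (rho <= rho_out) & (labels == 0)
        n_sec = spec.n_lobule_sectors
        sec = np.clip(np.floor(phi / (2 * np.pi / n_sec)).astype(int), 0, n_sec - 1)
        lob_ids = np.asarray(protocol.ids_of("lobule", side), np.int32)
        labels[shell] = lob_ids[sec[shell]]

        # white matter: solid core plus radial branches into the cortex band
        wm_mask |= (rho <= rho_in) & ~in_vermis
        for _ in range(spec.wm_branch_count):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            reach = rng.uniform(0.75, 0.95)
            t = np.linspace(0.2, reach, 40)
            pts = c[None, :] + t[:, None] * (d[None, :] * radii[None, :])
            idx = np.round(pts / np.asarray(spec.spacing_mm) - 0.5).astype(int)
            ok = np.all((idx >= 0) & (idx < np.asarray(spec.grid_shape)), axis=1)
            idx = idx[ok]
            branch_pts[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    # branch tubes displace cortical gray tissue but never grow outside the
    # anatomy or into the vermis
    branch_radius = 1.6 * (1.0 - a)
    if branch_pts.any() and branch_radius >= min(spec.spacing_mm) / 2:
        d_branch = ndimage.distance_transform_edt(~branch_pts, sampling=spec.spacing_mm)
        tube = d_branch <= branch_radius
        wm_mask |= tube & ((labels != 0) | wm_mask) & ~in_vermis

    cortex = LabelMap(np.where(wm_mask, 0, labels), spec.spacing_mm)
    merged = merge_cortex_and_wm(cortex, wm_mask, protocol, gap_mask=np.zeros_like(wm_mask))
    return merged


def _smooth_unit_field(shape, spacing, smoothness_mm, rng) -> np.ndarray:
    """Smoothed white noise, normalized to peak magnitude 1."""
    noise = rng.standard_normal(shape)
    sigma = [smoothness_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma)
    peak = np.abs(smooth).max()
    return smooth / peak if peak > 0 else smooth


def _render_intensity(spec: PhantomSpec, labels: LabelMap, protocol: LabelProtocol,
                      rng_noise: np.random.Generator,
                      rng_drift: np.random.Generator) -> Volume:
    gray = np.isin(labels.data, list(protocol.gray_ids()))
    white = np.isin(labels.data, list(protocol.ids_of("white_matter")))
    img = np.full(spec.grid_shape, spec.background_mean, dtype=np.float32)
    img[gray] = spec.gm_mean
    img[white] = spec.wm_mean
    if spec.drift_amplitude > 0:
        drift = _smooth_unit_field(spec.grid_shape, spec.spacing_mm,
                                   0.25 * float(spec.extent_mm().mean()), rng_drift)
        img = img * (1.0 + spec.drift_amplitude * drift.astype(np.float32))
    if spec.noise_sd > 0:
        img = img + rng_noise.normal(
            0.0, spec.noise_sd * spec.gm_mean, spec.grid_shape
        ).astype(np.float32)
    return Volume(img, spec.spacing_mm)


def generate_phantom(
    spec: PhantomSpec, protocol: LabelProtocol | None = None, subject: int = 0
) -> tuple[Volume, LabelMap]:
    """Generate one intensity volume and its ground-truth label map."""
    spec.validate()
    protocol = protocol or build_protocol()
    labels = _build_anatomy(spec, _rng(spec.seed, subject, _ANATOMY), protocol)
    vol = _render_intensity(
        spec, labels, protocol,
        _rng(spec.seed, subject, _NOISE), _rng(spec.seed, subject, _DRIFT),
    )
    return vol, labels


def generate_retest_pair(
    spec: PhantomSpec,
    protocol: LabelProtocol | None = None,
    subject: int = 0,
    rigid_jitter_mm: float = 0.0,
    rigid_jitter_deg: float = 0.0,
) -> tuple[Volume, Volume, LabelMap]:
    """Two scans of the same anatomy with independent noise and drift.

    With jitter enabled the second scan receives a small rigid transform
    (labels are returned in scan 1's frame); by default the pair differs
    only in acquisition noise and drift.
    """
    spec.validate()
    protocol = protocol or build_protocol()
    labels = _build_anatomy(spec, _rng(spec.seed, subject, _ANATOMY), protocol)
    vol1 = _render_intensity(
        spec, labels, protocol,
        _rng(spec.seed, subject, _NOISE), _rng(spec.seed, subject, _DRIFT),
    )
    rng2 = _rng(spec.seed, subject, _NOISE + 100)
    rngd2 = _rng(spec.seed, subject, _DRIFT + 100)
    vol2 = _render_intensity(spec, labels, protocol, rng2, rngd2)
    if rigid_jitter_mm > 0 or rigid_jitter_deg > 0:
        rngj = _rng(spec.seed, subject, _JITTER)
        shift_vox = rngj.uniform(-rigid_jitter_mm, rigid_jitter_mm, 3) / np.asarray(
            spec.spacing_mm
        )
        angle = rngj.uniform(-rigid_jitter_deg, rigid_jitter_deg)
        img2 = ndimage.shift(vol2.data, shift_vox, order=1, mode="nearest")
        img2 = ndimage.rotate(img2, angle, axes=(1, 2), reshape=False,
                              order=1, mode="nearest")
        vol2 = vol2.with_data(img2)
    return vol1, vol2, labels


def generate_cohort(
    n_per_group: int,
    atrophy_levels: list[float],
    base_spec: PhantomSpec,
    protocol: LabelProtocol | None = None,
) -> list[tuple[Volume, LabelMap, str]]:
    """Independent subjects at each atrophy level, tagged by group.

    Group tags are ``atrophy=<level>``; each subject uses an independent
    RNG stream keyed off the base seed, so cohorts are reproducible and
    extending one group does not perturb another.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not atrophy_levels:
        raise ValueError("atrophy_levels must be nonempty")
    protocol = protocol or build_protocol()
    out = []
    for gi, level in enumerate(atrophy_levels):
        spec = replace(base_spec, atrophy=float(level))
        for si in range(n_per_group):
            vol, labels = generate_phantom(spec, protocol, subject=1000 * gi + si)
            out.append((vol, labels, f"atrophy={level:g}"))
    return out


def generate_displacement_field(
    grid_shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    max_disp_mm: float,
    smoothness_mm: float,
    seed: int,
) -> DisplacementField:
    """Smooth random displacement field, tapered to zero at the boundary.

    A white-noise 3-vector field is Gaussian-smoothed at ``smoothness_mm``,
    multiplied by a boundary taper window and rescaled so its maximum
    vector magnitude equals ``max_disp_mm`` exactly.
    """
    if max_disp_mm < 0:
        raise ValueError("max_disp_mm must be nonnegative")
    if smoothness_mm <= 0:
        raise ValueError("smoothness_mm must be positive")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, _FIELD])
    if max_disp_mm == 0:
        vec = np.zeros(tuple(grid_shape) + (3,), dtype=np.float32)
        return DisplacementField(vec, tuple(spacing_mm), 0.0, smoothness_mm)
    comps = [
        _smooth_unit_field(tuple(grid_shape), spacing_mm, smoothness_mm, rng)
        for _ in range(3)
    ]
    vec = np.stack(comps, axis=-1)
    # taper: linear ramp from the boundary over ~2 smoothing lengths
    win = np.ones(tuple(grid_shape))
    for ax, (n, s) in enumerate(zip(grid_shape, spacing_mm)):
        ramp_len = max(2.0, 2.0 * smoothness_mm / s)
        i = np.arange(n)
        prof = np.minimum(i, n - 1 - i) / ramp_len
        prof = np.clip(prof, 0.0, 1.0)
        shape = [1, 1, 1]
        shape[ax] = n
        win *= prof.reshape(shape)
    vec *= win[..., None]
    mag = np.sqrt((vec ** 2).sum(axis=-1))
    peak = mag.max()
    if peak > 0:
        vec *= max_disp_mm / peak
    return DisplacementField(vec.astype(np.float32), tuple(spacing_mm),
                             float(max_disp_mm), float(smoothness_mm))
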