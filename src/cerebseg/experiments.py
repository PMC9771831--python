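"""Scaled-down, self-contained experiments on phantom data.

These runners reproduce the pipeline's study designs at desk scale: train
the three per-view networks on phantom cohorts, measure segmentation
accuracy, run the augmentation ablation, the test-retest reliability
analysis, and the atrophy-sensitivity cohort comparison.  Everything is
generated procedurally -- no downloads -- and every run is reproducible
from a single seed.

Problem sizes default to values that keep a full run within minutes on one
CPU; they are the package's chosen desk scale, and all are adjustable.

Training phantom pools span a range of atrophy severities (as the intended
use spans healthy through atrophic cerebella), so the models see the
anatomical spectrum they are later evaluated on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import LabelMap, Volume, robust_normalize
from .evaluation import icc_agreement, per_structure_report
from .localization import cerebellum_mask, crop, fit_bounding_box
from .model import ModelConfig, ReferenceNet, build_reference_model
from .multiview import (
    expand_sagittal,
    extract_stack_array,
    n_classes_for_view,
    predict_view,
    probabilities_to_labels,
    view_aggregate,
)
from .phantom import (
    PhantomSpec,
    generate_cohort,
    generate_displacement_field,
    generate_phantom,
    generate_retest_pair,
)
from .pipeline import segment
from .protocol import LabelProtocol, build_protocol
from .training import (
    AugmentOptions,
    TrainConfig,
    pretrain_then_finetune,
    train_view,
)

VIEWS = ("axial", "coronal", "sagittal")


@dataclass(frozen=True)
class ToyScale:
    """Problem sizes of the desk-scale end-to-end experiment.

    Phantoms live on a 64 mm grid and the working crop is 48 voxels --
    the same crop-to-volume proportion as the production 128-of-256
    geometry.  Batch size and learning rate are scaled down with the
    problem (the tiny networks need many more optimizer steps than the
    full-scale recipe's 128-slice batches would allow here).
    """

    grid: int = 64
    crop_side: int = 48
    n_train: int = 40
    n_val: int = 10
    n_test: int = 10
    epochs: int = 8
    batch_size: int = 16
    slices_per_epoch: int | None = 1024
    lr0: float = 5e-3
    levels: int = 2
    base_filters: int = 16
    competition: bool = False
    coord_features: bool = True
    atrophy_range: tuple[float, float] = (0.0, 0.4)


def phantom_pool(
    n: int,
    protocol: LabelProtocol,
    grid: int,
    seed: int,
    subject_offset: int = 0,
    atrophy_range: tuple[float, float] = (0.0, 0.4),
    crop_side: int | None = None,
    **spec_overrides,
) -> list[tuple[Volume, LabelMap]]:
    """Generate ``n`` phantoms, localize, crop and normalize them.

    Atrophy severities are spread evenly over ``atrophy_range`` across the
    pool, emulating a cohort covering the disease spectrum.
    """
    spec0 = PhantomSpec(grid_shape=(grid,) * 3, seed=seed, **spec_overrides)
    out = []
    lo, hi = atrophy_range
    for i in range(n):
        a = lo if n == 1 else lo + (hi - lo) * (i % 5) / 4.0
        spec = replace(spec0, atrophy=float(a))
        vol, lab = generate_phantom(spec, protocol, subject=subject_offset + i)
        vol = robust_normalize(vol)
        if crop_side is not None:
            box = fit_bounding_box(
                cerebellum_mask(lab, protocol.ids()), side=crop_side
            )
            vol, lab = crop(vol, box), crop(lab, box)
        out.append((vol, lab))
    return out


def make_view_config(
    protocol: LabelProtocol, view: str, scale: ToyScale
) -> ModelConfig:
    return ModelConfig(
        n_classes=n_classes_for_view(protocol, view),
        view=view,
        levels=scale.levels,
        base_filters=scale.base_filters,
        competition_enabled=scale.competition,
        coord_features=scale.coord_features,
        crop_side=scale.crop_side,
        protocol_hash=protocol.hash(),
    )


def train_toy_models(
    protocol: LabelProtocol,
    scale: ToyScale = ToyScale(),
    seed: int = 0,
    augment: AugmentOptions | None = None,
) -> tuple[dict[str, ReferenceNet], dict[str, object]]:
    """Train the three per-view networks on a phantom cohort."""
    train_set = phantom_pool(
        scale.n_train, protocol, scale.grid, seed, 0,
        scale.atrophy_range, scale.crop_side,
    )
    val_set = phantom_pool(
        scale.n_val, protocol, scale.grid, seed, 10_000,
        scale.atrophy_range, scale.crop_side,
    )
    if augment is None:
        # accuracy-focused default: random flipping only (the augmentation
        # ablation exercises the other families at its own scale)
        augment = AugmentOptions(flip=True, affine=False, bias=False)
    models, histories = {}, {}
    for vi, view in enumerate(VIEWS):
        cfg = make_view_config(protocol, view, scale)
        model = build_reference_model(
            cfg, np.random.default_rng([seed & 0x7FFFFFFF, 50 + vi])
        )
        tc = TrainConfig(
            epochs=scale.epochs,
            batch_size=scale.batch_size,
            micro_batch=scale.batch_size,
            slices_per_epoch=scale.slices_per_epoch,
            lr0=scale.lr0,
            seed=seed * 10 + vi,
            augment=augment,
        )
        model, hist = train_view(model, train_set, val_set, tc, protocol)
        models[view] = model
        histories[view] = hist
    return models, histories


def evaluate_views_and_aggregate(
    models: dict[str, ReferenceNet],
    test_set: list[tuple[Volume, LabelMap]],
    protocol: LabelProtocol,
) -> pd.DataFrame:
    """Macro Dice per single view and for the aggregated prediction.

    Returns one row per test case with per-view and aggregated macro Dice
    (mean over the 27 structures present in the ground truth).
    """
    rows = []
    for vol, lab in test_set:
        preds = {}
        p_ax = predict_view(models["axial"], extract_stack_array(vol, "axial"), "axial")
        p_co = predict_view(models["coronal"], extract_stack_array(vol, "coronal"), "coronal")
        p_sa_m = predict_view(
            models["sagittal"], extract_stack_array(vol, "sagittal"), "sagittal"
        )
        p_sa = expand_sagittal(p_sa_m, protocol)
        preds["axial"], preds["coronal"], preds["sagittal"] = p_ax, p_co, p_sa
        agg = view_aggregate(p_ax, p_co, p_sa)
        row = {}
        for name, p in {**preds, "aggregate": agg}.items():
            seg = probabilities_to_labels(p, lab.spacing)
            rep = per_structure_report(lab, seg, protocol)
            row[f"dice_{name}"] = float(rep[rep.name == "macro_mean"].dice.iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ablation


ABLATION_ARMS = ("baseline", "flip", "bias", "affine", "deformation", "full")


@dataclass(frozen=True)
class AblationScale:
    grid: int = 32
    crop_side: int = 24
    n_train: int = 4
    n_val: int = 2
    n_test: int = 8
    n_pretrain: int = 16
    epochs: int = 25
    pretrain_epochs: int = 10
    batch_size: int = 8
    lr0: float = 5e-3
    plateau_patience: int = 10
    plateau_factor: float = 0.1
    n_fields: int = 8
    view: str = "axial"
    levels: int = 2
    base_filters: int = 16
    atrophy_range: tuple[float, float] = (0.0, 0.2)


def _arm_augment(arm: str, scale: AblationScale) -> AugmentOptions:
    # augmentation magnitudes are matched to the phantom cohort's actual
    # variability (center jitter +/-1.5 mm, wedge phase +/-5 deg, radii +/-4%,
    # drift +/-10%); the printed full-scale ranges target real-MRI variation
    # and overwhelm the miniature anatomy
    # translation: localization centers the crop, so residual positional
    # variability is the box-rounding error (sub-voxel)
    kw = dict(
        translation_range_mm=(-0.5, 0.5),
        rotation_range_deg=(-5.0, 5.0),
        scale_range=(0.96, 1.04),
        bias_coeff_range=(-0.12, 0.12),
    )
    base = AugmentOptions.none()
    if arm == "flip":
        return replace(base, flip=True)
    if arm == "bias":
        return replace(base, bias=True, **kw)
    if arm == "affine":
        return replace(base, affine=True, **kw)
    if arm == "full":
        return AugmentOptions(**kw)
    return base  # baseline and deformation train without on-the-fly augmentation


def run_ablation(
    seed: int = 0,
    n_seeds: int = 3,
    scale: AblationScale = AblationScale(),
    protocol: LabelProtocol | None = None,
    arms: tuple[str, ...] = ABLATION_ARMS,
) -> pd.DataFrame:
    """Single-view ablation of the augmentation families and pre-training.

    Each arm trains the same network on the same small cohort, differing
    only in one augmentation family (the ``full`` arm combines all of them
    with pre-training on a larger low-noise pool).  Test macro Dice is
    averaged over an independent phantom test set; the whole design is
    repeated for ``n_seeds`` seeds.
    """
    protocol = protocol or build_protocol()
    # a deliberately data-starved regime: with very few training subjects the
    # network overfits their specific anatomies, which is exactly the failure
    # mode the augmentation families (and pre-training) are designed to fix
    tscale = ToyScale(
        grid=scale.grid, crop_side=scale.crop_side, levels=scale.levels,
        base_filters=scale.base_filters, competition=False,
    )
    rows = []
    for s in range(n_seeds):
        run_seed = seed * 100 + s
        train_set = phantom_pool(
            scale.n_train, protocol, scale.grid, run_seed, 0,
            scale.atrophy_range, scale.crop_side,
        )
        val_set = phantom_pool(
            scale.n_val, protocol, scale.grid, run_seed, 10_000,
            scale.atrophy_range, scale.crop_side,
        )
        test_set = phantom_pool(
            scale.n_test, protocol, scale.grid, run_seed, 20_000,
            scale.atrophy_range, scale.crop_side,
        )
        view = scale.view
        cfg = make_view_config(protocol, view, tscale)
        for arm in arms:
            rng_init = np.random.default_rng([run_seed & 0x7FFFFFFF, 77])
            # every arm trains the same number of epochs over its own dataset
            # (static deformation and pre-training enlarge the data a model
            # sees, exactly as they would at full scale)
            tc = TrainConfig(
                epochs=scale.epochs, batch_size=scale.batch_size,
                micro_batch=scale.batch_size, lr0=scale.lr0, seed=run_seed,
                plateau_patience=scale.plateau_patience,
                plateau_factor=scale.plateau_factor,
                augment=_arm_augment(arm, scale),
            )
            arm_train = list(train_set)
            if arm in ("deformation", "full"):
                fields = [
                    generate_displacement_field(
                        (scale.crop_side,) * 3, (1.0, 1.0, 1.0),
                        max_disp_mm=3.0, smoothness_mm=6.0,
                        seed=run_seed * 1000 + k,
                    )
                    for k in range(scale.n_fields)
                ]
                from .augmentation import build_static_deformed_set

                deformed = build_static_deformed_set(
                    train_set, fields,
                    np.random.default_rng([run_seed & 0x7FFFFFFF, 88]),
                )
                arm_train = arm_train + [(v, l) for v, l, _ in deformed]
            if arm == "full":
                pre_train = phantom_pool(
                    scale.n_pretrain, protocol, scale.grid, run_seed, 30_000,
                    scale.atrophy_range, scale.crop_side, noise_sd=0.02,
                )
                pre_val = val_set
                pre_tc = TrainConfig(
                    epochs=scale.pretrain_epochs, batch_size=scale.batch_size,
                    micro_batch=scale.batch_size, lr0=scale.lr0, seed=run_seed,
                    plateau_patience=scale.plateau_patience,
                    plateau_factor=scale.plateau_factor,
                    augment=_arm_augment("full", scale),
                )
                model, _prov = pretrain_then_finetune(
                    cfg, (pre_train, pre_val), (arm_train, val_set),
                    pre_tc, tc, protocol,
                )
            else:
                model = build_reference_model(cfg, rng_init)
                model, _ = train_view(model, arm_train, val_set, tc, protocol)
            from .training import validation_macro_dice
            from .multiview import class_lut_for_view

            lut = class_lut_for_view(protocol, view)
            d = validation_macro_dice(model, test_set, view, lut)
            rows.append({"arm": arm, "seed": s, "test_macro_dice": d})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# test-retest and atrophy cohort


def run_retest(
    models: dict[str, ReferenceNet],
    protocol: LabelProtocol,
    n_pairs: int = 20,
    grid: int = 64,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment test-retest phantom pairs and assess per-structure volume ICC.

    Each pair shares one anatomy with independent noise and intensity
    drift.  Returns one row per structure with the test-retest volume ICC,
    its confidence interval, and the mean Dice against ground truth.
    """
    spec = PhantomSpec(grid_shape=(grid,) * 3, seed=seed)
    vols1, vols2, dices = [], [], []
    for i in range(n_pairs):
        s1, s2, lab = generate_retest_pair(spec, protocol, subject=40_000 + i)
        seg1, rep1 = segment(s1, models, protocol, lab)
        seg2, rep2 = segment(s2, models, protocol, lab)
        vols1.append(rep1.set_index("structure_id").volume_mm3)
        vols2.append(rep2.set_index("structure_id").volume_mm3)
        rep = per_structure_report(lab, seg1, protocol)
        dices.append(rep.set_index("structure_id").dice)
    v1 = pd.DataFrame(vols1)
    v2 = pd.DataFrame(vols2)
    dd = pd.DataFrame(dices)
    rows = []
    for s in protocol.structures:
        icc = icc_agreement(v1[s.label_id].values, v2[s.label_id].values)
        rows.append(
            {
                "structure_id": s.label_id,
                "name": s.name,
                "icc": icc.icc,
                "ci95_low": icc.ci95_low,
                "ci95_high": icc.ci95_high,
                "mean_dice": float(dd[s.label_id].mean()),
            }
        )
    return pd.DataFrame(rows)


def run_atrophy_cohort(
    models: dict[str, ReferenceNet],
    protocol: LabelProtocol,
    levels: tuple[float, ...] = (0.0, 0.2, 0.4),
    n_per_group: int = 10,
    grid: int = 64,
    seed: int = 0,
) -> pd.DataFrame:
    """Segmentation-derived mean gray-matter volume per atrophy level."""
    base = PhantomSpec(grid_shape=(grid,) * 3, seed=seed)
    cohort = generate_cohort(n_per_group, list(levels), base, protocol)
    gray_names = {s.name for s in protocol.structures if s.tissue == "gray"}
    rows = []
    for vol, lab, tag in cohort:
        _, rep = segment(vol, models, protocol, lab)
        gm = float(rep[rep.name.isin(gray_names)].volume_mm3.sum())
        true_gm = float(
            np.isin(lab.data, list(protocol.gray_ids())).sum() * lab.voxel_volume_mm3
        )
        rows.append({"group": tag, "gm_volume_mm3": gm, "true_gm_volume_mm3": true_gm})
    return pd.DataFrame(rows)
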