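import numpy as np
import pytest

from cerebseg.evaluation import (
    boundary_voxels,
    dice,
    hausdorff,
    icc_agreement,
    outlier_scan,
    paired_wilcoxon,
    per_structure_report,
    volume_similarity,
)

from oracles import (
    brute_boundary,
    brute_dice,
    brute_hausdorff,
    brute_volsim,
    exact_wilcoxon_p,
)


class TestDice:
    def test_identical_nonempty_masks_score_one(self, rng):
        m = rng.random((8, 8, 8)) > 0.6
        m[0, 0, 0] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[0, 0, 0] = True
        b[5, 5, 5] = True
        assert dice(a, b) == 0.0

    def test_shifted_cube_overlap(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[1:3, 1:3, 1:3] = True
        b[2:4, 1:3, 1:3] = True  # overlap 4 of 8+8
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        e = np.zeros((4, 4, 4), bool)
        assert dice(e, e) == 1.0

    def test_symmetry_and_grid_mismatch(self, rng):
        a = rng.random((5, 5, 5)) > 0.5
        b = rng.random((5, 5, 5)) > 0.5
        assert dice(a, b) == dice(b, a)
        with pytest.raises(ValueError):
            dice(a, np.zeros((4, 4, 4), bool))


class TestVolumeSimilarity:
    def test_equal_volumes_disjoint_masks_score_one(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[:2, :2, :2] = True
        b[5:7, 5:7, 5:7] = True
        assert volume_similarity(a, b) == 1.0

    def test_empty_prediction_scores_zero(self):
        a = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        assert volume_similarity(a, np.zeros((4, 4, 4), bool)) == 0.0

    def test_worked_example(self):
        # 60 vs 40 mm^3 -> 1 - 20/100 = 0.8
        a = np.zeros((5, 5, 5), bool).ravel()
        a[:60] = True
        b = np.zeros((5, 5, 5), bool).ravel()
        b[:40] = True
        assert volume_similarity(a.reshape(5, 5, 5), b.reshape(5, 5, 5)) == pytest.approx(0.8)

    def test_grid_free_across_different_grids(self, rng):
        a = rng.random((6, 6, 6)) > 0.5
        b_small = rng.random((4, 4, 4)) > 0.5
        b_embedded = np.zeros((6, 6, 6), bool)
        b_embedded[:4, :4, :4] = b_small
        assert volume_similarity(a, b_small) == volume_similarity(a, b_embedded)

    def test_both_empty_rejected(self):
        e = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError, match="undefined"):
            volume_similarity(e, e)


class TestBoundary:
    def test_single_voxel_is_its_own_boundary(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert boundary_voxels(m).shape == (1, 3)

    def test_solid_cube_surface(self):
        m = np.zeros((7, 7, 7), bool)
        m[2:5, 2:5, 2:5] = True
        assert boundary_voxels(m).shape[0] == 26  # all but the center voxel

    def test_full_grid_keeps_face_voxels(self):
        m = np.ones((4, 4, 4), bool)
        b = boundary_voxels(m)
        assert b.shape[0] == 4 ** 3 - 2 ** 3  # interior 2^3 removed


class TestHausdorff:
    def test_identical_masks_distance_zero(self, rng):
        m = rng.random((8, 8, 8)) > 0.6
        m[4, 4, 4] = True
        assert hausdorff(m, m, percentile=100) == 0.0
        assert hausdorff(m, m, percentile=95) == 0.0

    def test_parallel_planes_three_mm_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2] = True
        b[5] = True
        assert hausdorff(a, b, percentile=100) == pytest.approx(3.0)
        assert hausdorff(a, b, percentile=95) == pytest.approx(3.0)

    def test_outlier_inflates_hd_but_not_hd95(self):
        a = np.zeros((30, 4, 4), bool)
        b = np.zeros((30, 4, 4), bool)
        a[0, :, :] = True
        b[1, :, :] = True  # 16+16 boundary pairs at 1 mm
        b[11, 0, 0] = True  # one outlier 11 mm from a
        hd = hausdorff(a, b, percentile=100)
        hd95 = hausdorff(a, b, percentile=95)
        assert hd == pytest.approx(11.0)
        assert hd95 < hd

    def test_empty_mask_rejected(self):
        m = np.zeros((4, 4, 4), bool)
        n = m.copy()
        n[0, 0, 0] = True
        with pytest.raises(ValueError):
            hausdorff(m, n)


class TestAgainstBruteForceOracles:
    def test_random_masks_match_oracles(self, rng):
        spacing = (1.0, 1.3, 0.8)
        for _ in range(30):
            shape = tuple(rng.integers(3, 9, 3))
            a = rng.random(shape) > 0.6
            b = rng.random(shape) > 0.6
            if not a.any() or not b.any():
                continue
            assert dice(a, b) == pytest.approx(brute_dice(a, b), abs=1e-12)
            assert volume_similarity(a, b, spacing) == pytest.approx(
                brute_volsim(a, b, spacing), abs=1e-12
            )
            got = np.sort(boundary_voxels(a, spacing), axis=0)
            want = np.sort(brute_boundary(a, spacing), axis=0)
            assert np.allclose(got, want)
            for pct in (100.0, 95.0):
                assert hausdorff(a, b, spacing, pct) == pytest.approx(
                    brute_hausdorff(a, b, spacing, pct), abs=1e-9
                )


class TestPerStructureReport:
    def test_perfect_prediction(self, protocol, small_phantom):
        _, labels = small_phantom
        rep = per_structure_report(labels, labels, protocol)
        core = rep[rep.structure_id.between(1, 27)]
        assert (core.dice == 1.0).all()
        assert (core.hd_mm == 0.0).all()
        macro = rep[rep.name == "macro_mean"].iloc[0]
        assert macro.dice == 1.0

    def test_absent_structure_excluded_from_macro(self, protocol, small_phantom):
        _, labels = small_phantom
        dropped = labels.with_data(np.where(labels.data == 27, 0, labels.data))
        rep = per_structure_report(dropped, dropped, protocol)
        row = rep[rep.structure_id == 27].iloc[0]
        assert not row.present_gt and not row.present_pred
        assert np.isnan(row.hd_mm)
        present_rows = rep[rep.structure_id.between(1, 26)]
        macro = rep[rep.name == "macro_mean"].iloc[0]
        assert macro.dice == pytest.approx(present_rows.dice.mean())

    def test_macro_mean_recomputed_from_rows(self, protocol, small_phantom, rng):
        _, labels = small_phantom
        noisy = labels.data.copy()
        flip = rng.random(noisy.shape) < 0.05
        noisy[flip] = 0
        rep = per_structure_report(labels, labels.with_data(noisy), protocol)
        core = rep[rep.structure_id.between(1, 27)]
        ok = core[core.present_gt & core.present_pred]
        macro = rep[rep.name == "macro_mean"].iloc[0]
        assert macro.dice == pytest.approx(ok.dice.mean())


class TestICC:
    def test_identical_scans_give_exactly_one(self, rng):
        v = rng.random(12) * 100
        res = icc_agreement(v, v)
        assert res.icc == 1.0

    def test_constant_offset_keeps_consistency_icc_at_one(self, rng):
        v = rng.random(15) * 100
        res = icc_agreement(v, v + 7.5)
        assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(99)
        vals = [icc_agreement(rng.random(50), rng.random(50)).icc for _ in range(5)]
        assert abs(np.mean(vals)) < 0.3

    def test_matches_reference_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.random(20) * 10
        y = x + rng.normal(0, 0.8, 20)
        ours = icc_agreement(x, y)
        df = pd.DataFrame(
            {
                "subject": np.r_[np.arange(20), np.arange(20)],
                "rater": ["a"] * 20 + ["b"] * 20,
                "score": np.r_[x, y],
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        row = ref[ref.Type.str.contains(r"C,1|ICC3")].iloc[0]
        assert ours.icc == pytest.approx(row.ICC, abs=1e-9)
        lo, hi = row[ref.columns[ref.columns.str.startswith("CI95")][0]]
        assert ours.ci95_low == pytest.approx(lo, abs=0.02)
        assert ours.ci95_high == pytest.approx(hi, abs=0.02)
        assert ours.ci95_low <= ours.icc <= ours.ci95_high

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            icc_agreement([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            icc_agreement(np.ones(5), np.ones(5))


class TestWilcoxon:
    def test_identical_samples_rejected(self):
        v = np.arange(6, dtype=float)
        with pytest.raises(ValueError, match="zero"):
            paired_wilcoxon(v, v)

    def test_matches_exhaustive_enumeration_for_n6(self, rng):
        for _ in range(5):
            a = rng.normal(0, 1, 6)
            b = a + rng.normal(0.5, 1, 6)
            if np.any(a == b):
                continue
            _, p = paired_wilcoxon(a, b)
            assert p == pytest.approx(exact_wilcoxon_p(a - b), abs=1e-9)

    def test_swapping_samples_flips_statistic_sign(self, rng):
        a = rng.normal(0, 1, 10)
        b = a + rng.normal(0.3, 0.5, 10)
        s1, p1 = paired_wilcoxon(a, b)
        s2, p2 = paired_wilcoxon(b, a)
        assert s1 == -s2
        assert p1 == pytest.approx(p2)


class TestOutlierScan:
    def test_identical_values_no_flags(self):
        flags = outlier_scan({"a": np.ones(10)})
        assert not flags["a"].any()

    def test_gross_outlier_flagged(self, rng):
        vals = np.r_[rng.normal(0, 1, 20), 50.0]
        flags = outlier_scan({"a": vals})
        assert flags["a"][-1]
        assert flags["a"].sum() == 1

    def test_flags_invariant_to_affine_rescale(self, rng):
        vals = np.r_[rng.normal(0, 1, 15), 8.0]
        f1 = outlier_scan({"a": vals})["a"]
        f2 = outlier_scan({"a": vals * 3.5 + 100})["a"]
        assert np.array_equal(f1, f2)
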