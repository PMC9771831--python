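import numpy as np
import pytest

from cerebseg.augmentation import (
    AffineParams,
    apply_affine_inplane,
    apply_bias,
    apply_displacement,
    build_static_deformed_set,
    random_lr_flip,
    sample_affine,
    sample_bias_field,
    BIAS_EXPONENTS,
)
from cerebseg.core import LabelMap, Volume
from cerebseg.phantom import DisplacementField, generate_displacement_field


class TestAffine:
    def test_identity_params_are_bit_exact_noop(self, rng):
        img = rng.random((7, 16, 16)).astype(np.float32)
        lab = rng.integers(0, 5, (16, 16)).astype(np.int32)
        out_img, out_lab = apply_affine_inplane(
            img, lab, AffineParams((0.0, 0.0), 1.0, 0.0)
        )
        assert out_img is img and out_lab is lab

    def test_integer_translation_shifts_labels_exactly(self, rng):
        lab = np.zeros((16, 16), np.int32)
        lab[5:8, 6:9] = 3
        img = lab.astype(np.float32)
        params = AffineParams((2.0, -3.0), 1.0, 0.0)  # +2 rows, -3 cols at 1mm
        _, out_lab = apply_affine_inplane(img, lab, params)
        expected = np.zeros_like(lab)
        expected[7:10, 3:6] = 3
        assert np.array_equal(out_lab, expected)

    def test_four_quarter_rotations_restore_labels(self, rng):
        lab = rng.integers(0, 4, (20, 20)).astype(np.int32)
        img = rng.random((20, 20)).astype(np.float32)
        params = AffineParams((0.0, 0.0), 1.0, 90.0)
        cur_i, cur_l = img, lab
        for _ in range(4):
            cur_i, cur_l = apply_affine_inplane(cur_i, cur_l, params)
        assert np.array_equal(cur_l, lab)

    def test_labels_never_invented(self, rng):
        lab = rng.integers(0, 6, (24, 24)).astype(np.int32)
        img = rng.random((24, 24)).astype(np.float32)
        params = sample_affine(rng)
        _, out = apply_affine_inplane(img, lab, params)
        assert set(np.unique(out)) <= set(np.unique(lab)) | {0}

    def test_singular_matrix_rejected(self, rng):
        img = rng.random((8, 8)).astype(np.float32)
        with pytest.raises(ValueError, match="singular"):
            apply_affine_inplane(img, None, AffineParams((1.0, 1.0), 0.0, 0.0))

    def test_sampled_parameters_respect_ranges(self, rng):
        draws = [sample_affine(rng) for _ in range(2000)]
        tx = np.array([d.translation_mm[0] for d in draws])
        ty = np.array([d.translation_mm[1] for d in draws])
        sc = np.array([d.scale for d in draws])
        rot = np.array([d.rotation_deg for d in draws])
        assert tx.min() >= -12 and tx.max() <= 12
        assert ty.min() >= -12 and ty.max() <= 12
        assert sc.min() >= 0.95 and sc.max() <= 1.2
        assert rot.min() >= -20 and rot.max() <= 20
        assert abs(tx.mean()) < 1.0 and abs(rot.mean()) < 1.5


class TestFlip:
    def test_forced_flip_twice_is_identity(self, protocol, small_phantom, rng):
        vol, lab = small_phantom
        v1, l1 = random_lr_flip(vol, lab, protocol, rng, p=1.0)
        v2, l2 = random_lr_flip(v1, l1, protocol, rng, p=1.0)
        assert np.array_equal(v2.data, vol.data)
        assert np.array_equal(l2.data, lab.data)

    def test_left_voxels_land_right_with_right_ids(self, protocol, small_phantom, rng):
        vol, lab = small_phantom
        _, flipped = random_lr_flip(vol, lab, protocol, rng, p=1.0)
        lut = protocol.lr_swap_lut()
        assert np.array_equal(flipped.data, lut[np.flip(lab.data, axis=0)])
        left_id = protocol.ids_of("lobule", "left")[0]
        right_id = protocol.lr_swap(left_id)
        # where the left structure sat, its mirror now carries the right id
        assert np.array_equal(
            flipped.data == right_id, np.flip(lab.data, axis=0) == left_id
        )

    def test_vermis_keeps_ids(self, protocol, small_phantom, rng):
        vol, lab = small_phantom
        _, flipped = random_lr_flip(vol, lab, protocol, rng, p=1.0)
        for vid in protocol.ids_of("vermis"):
            assert (flipped.data == vid).sum() == (lab.data == vid).sum()

    def test_probability_zero_never_flips(self, protocol, small_phantom, rng):
        vol, lab = small_phantom
        v, l = random_lr_flip(vol, lab, protocol, rng, p=0.0)
        assert v is vol and l is lab


class TestBiasField:
    def test_basis_has_20_monomials_up_to_cubic(self):
        assert len(BIAS_EXPONENTS) == 20
        assert all(sum(e) <= 3 for e in BIAS_EXPONENTS)
        assert len(set(BIAS_EXPONENTS)) == 20

    def test_zero_coefficients_are_noop(self, rng):
        vol = Volume(rng.random((8, 8, 8)))
        field = sample_bias_field((8, 8, 8), rng, coeffs=np.zeros(20))
        out = apply_bias(vol, field)
        assert np.array_equal(out.data, vol.data)

    def test_constant_term_adds_offset(self, rng):
        vol = Volume(np.zeros((6, 6, 6), np.float32))
        coeffs = np.zeros(20)
        coeffs[0] = 0.3  # the (0,0,0) monomial
        assert BIAS_EXPONENTS[0] == (0, 0, 0)
        out = apply_bias(vol, sample_bias_field((6, 6, 6), rng, coeffs=coeffs))
        assert np.allclose(out.data, 0.3, atol=1e-6)

    def test_field_bounded_by_coefficient_sum(self, rng):
        for _ in range(5):
            field = sample_bias_field((10, 10, 10), rng)
            assert np.abs(field).max() <= 10.0 + 1e-5  # 20 coeffs x 0.5


class TestDisplacement:
    def test_zero_field_is_noop(self, small_phantom):
        vol, lab = small_phantom
        field = generate_displacement_field(vol.shape, vol.spacing, 0.0, 4.0, 0)
        out_v, out_l = apply_displacement(vol, lab, field)
        assert np.array_equal(out_v.data, vol.data)
        assert np.array_equal(out_l.data, lab.data)

    def test_constant_integer_displacement_is_exact_shift(self):
        lab = np.zeros((12, 12, 12), np.int32)
        lab[4:7, 4:7, 4:7] = 5
        vec = np.zeros((12, 12, 12, 3), np.float32)
        vec[..., 0] = 2.0  # sample from +2 voxels along x
        field = DisplacementField(vec, (1.0, 1.0, 1.0), 2.0, 1.0)
        _, out = apply_displacement(None, LabelMap(lab), field)
        expected = np.zeros_like(lab)
        expected[2:5, 4:7, 4:7] = 5
        assert np.array_equal(out.data, expected)

    def test_warped_labels_subset_of_input(self, protocol, small_phantom):
        vol, lab = small_phantom
        field = generate_displacement_field(vol.shape, vol.spacing, 2.0, 4.0, 3)
        _, out = apply_displacement(vol, lab, field)
        assert set(np.unique(out.data)) <= set(np.unique(lab.data)) | {0}

    def test_grid_mismatch_rejected(self, small_phantom):
        vol, lab = small_phantom
        field = generate_displacement_field((16,) * 3, vol.spacing, 1.0, 4.0, 0)
        with pytest.raises(ValueError, match="grid"):
            apply_displacement(vol, lab, field)


class TestStaticDeformedSet:
    def _cases(self, protocol, n):
        from cerebseg.phantom import PhantomSpec, generate_phantom

        return [
            generate_phantom(PhantomSpec(grid_shape=(24,) * 3, seed=i), protocol)
            for i in range(n)
        ]

    def test_every_case_used_at_least_once(self, protocol):
        cases = self._cases(protocol, 3)
        fields = [
            generate_displacement_field((24,) * 3, (1, 1, 1), 1.0, 4.0, k)
            for k in range(7)
        ]
        out = build_static_deformed_set(cases, fields, np.random.default_rng(0))
        assert len(out) == 7
        used = {case_idx for _, _, (case_idx, _) in out}
        assert used == {0, 1, 2}

    def test_single_case_absorbs_all_fields(self, protocol):
        cases = self._cases(protocol, 1)
        fields = [
            generate_displacement_field((24,) * 3, (1, 1, 1), 1.0, 4.0, k)
            for k in range(3)
        ]
        out = build_static_deformed_set(cases, fields, np.random.default_rng(0))
        assert len(out) == 3
        assert all(case_idx == 0 for _, _, (case_idx, _) in out)

    def test_fixed_seed_reproduces_pairing(self, protocol):
        cases = self._cases(protocol, 2)
        fields = [
            generate_displacement_field((24,) * 3, (1, 1, 1), 1.0, 4.0, k)
            for k in range(5)
        ]
        p1 = [prov for _, _, prov in build_static_deformed_set(
            cases, fields, np.random.default_rng(42))]
        p2 = [prov for _, _, prov in build_static_deformed_set(
            cases, fields, np.random.default_rng(42))]
        assert p1 == p2

    def test_empty_inputs_rejected(self, protocol):
        with pytest.raises(ValueError):
            build_static_deformed_set([], [], np.random.default_rng(0))
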