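"""CURT rank matching, permutation/field conversions, and resampling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from regnull import (
    CurtRegistration,
    IdentityRegistration,
    OracleRegistration,
    curt_register,
    field_to_permutation,
    permutation_to_field,
    reformat_by_field,
    reformat_by_permutation,
)


def _is_permutation(p, n):
    return sorted(p) == list(range(n))


class TestCurtRegister:
    def test_reversed_grid_pairing(self):
        """Rank matching of a reversed 2x2 grid pairs smallest with smallest."""
        fixed = np.array([[1, 2], [3, 4]])
        moving = np.array([[4, 3], [2, 1]])
        p = curt_register(fixed, moving)
        # fixed flat i <-> moving flat p[i]; reversed grid pairs i with 3-i
        assert list(p) == [3, 2, 1, 0]
        assert np.array_equal(reformat_by_permutation(moving, p), fixed)

    def test_identical_distinct_images_give_identity(self, rng):
        img = rng.permutation(64).reshape(8, 8)
        p = curt_register(img, img)
        assert np.array_equal(p, np.arange(64))

    def test_pixel_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="pixel-count"):
            curt_register(np.zeros((2, 2), int), np.zeros((2, 3), int))

    def test_ties_broken_deterministically(self, rng):
        a = rng.integers(0, 4, size=(9, 9))  # heavy ties
        b = rng.integers(0, 4, size=(9, 9))
        assert np.array_equal(curt_register(a, b), curt_register(a, b))

    def test_minimizes_squared_difference_over_permutations(self, rng):
        """CURT attains the rearrangement-inequality optimum (brute force)."""
        for _ in range(20):
            fixed = rng.choice(100, size=6, replace=False).reshape(3, 2)
            moving = rng.choice(100, size=6, replace=False).reshape(3, 2)
            p = curt_register(fixed, moving)
            cost = ((fixed.ravel() - moving.ravel()[p]) ** 2).sum()
            best = min(
                ((fixed.ravel() - moving.ravel()[list(q)]) ** 2).sum()
                for q in itertools.permutations(range(6))
            )
            assert cost == best

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_always_bijective(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(1, 6), rng.integers(1, 6))
        a = rng.integers(0, 8, size=shape)
        b = rng.integers(0, 8, size=shape)
        assert _is_permutation(curt_register(a, b), a.size)


class TestPermutationFieldConversions:
    def test_identity_permutation_gives_zero_field(self):
        field = permutation_to_field(np.arange(12), (3, 4))
        assert field.shape == (3, 4, 2)
        assert not field.any()

    def test_cyclic_row_shift_displacements(self):
        # 1x3 grid, every pixel matched one column right (cyclically)
        p = np.array([1, 2, 0])
        field = permutation_to_field(p, (1, 3))
        assert list(field[0, :, 0]) == [1, 1, -2]
        assert not field[..., 1].any()

    def test_round_trip(self, rng):
        p = rng.permutation(20)
        field = permutation_to_field(p, (4, 5))
        assert np.array_equal(field_to_permutation(field), p)

    def test_non_bijective_rejected(self):
        with pytest.raises(ValueError, match="bijection"):
            permutation_to_field(np.array([0, 0, 1, 2]), (2, 2))

    def test_fractional_field_has_no_permutation(self):
        field = np.full((2, 2, 2), 0.5)
        with pytest.raises(ValueError, match="non-integer"):
            field_to_permutation(field)


class TestReformat:
    def test_identity_permutation_is_noop(self, rng):
        img = rng.integers(0, 256, size=(5, 7))
        assert np.array_equal(reformat_by_permutation(img, np.arange(35)), img)

    def test_histogram_conserved_under_any_permutation(self, rng):
        img = rng.integers(0, 256, size=(6, 6))
        p = rng.permutation(36)
        out = reformat_by_permutation(img, p)
        assert np.array_equal(np.sort(out.ravel()), np.sort(img.ravel()))

    def test_curt_reformat_of_permuted_copy_restores_fixed(self, rng):
        fixed = rng.integers(0, 256, size=(16, 16))
        moving = rng.permutation(fixed.ravel()).reshape(fixed.shape)
        p = curt_register(fixed, moving)
        assert np.array_equal(reformat_by_permutation(moving, p), fixed)

    def test_zero_field_is_noop(self, rng):
        img = rng.integers(0, 256, size=(4, 6))
        assert np.array_equal(reformat_by_field(img, np.zeros((4, 6, 2))), img)

    def test_uniform_shift_field_recovers_fixed_over_region_b(self, small_scene, small_spec):
        """Sampling the moving image at x+shift undoes the paste on B."""
        fixed, moving, truth = small_scene
        field = np.zeros(fixed.shape + (2,))
        field[..., 0] = small_spec.shift
        out = reformat_by_field(moving, field)
        b = truth.region_mask("B")
        assert np.array_equal(out[b], fixed[b])

    def test_degenerate_field_to_origin_gives_constant(self, rng):
        img = rng.integers(0, 256, size=(3, 5))
        yy, xx = np.mgrid[0:3, 0:5]
        field = np.stack([-xx, -yy], axis=2).astype(float)
        out = reformat_by_field(img, field)
        assert (out == img[0, 0]).all()

    def test_out_of_bounds_clamped_and_counted(self):
        img = np.arange(6).reshape(2, 3)
        field = np.zeros((2, 3, 2))
        field[..., 0] = 10  # everything off the right edge
        out, n_oob = reformat_by_field(img, field, return_oob_count=True)
        assert n_oob == 6
        assert np.array_equal(out, img[:, [2, 2, 2]])

    def test_wrap_mode_is_periodic(self):
        img = np.arange(6).reshape(2, 3)
        field = np.zeros((2, 3, 2))
        field[..., 0] = 3
        assert np.array_equal(reformat_by_field(img, field, mode="wrap"), img)

    def test_non_finite_field_rejected(self):
        field = np.zeros((2, 2, 2))
        field[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            reformat_by_field(np.zeros((2, 2), int), field)


class TestEstimators:
    def test_curt_fit_transform_matches_functions(self, small_scene):
        fixed, moving, _ = small_scene
        est = CurtRegistration().fit(fixed, moving)
        assert _is_permutation(est.permutation_, fixed.size)
        assert np.array_equal(
            est.transform(moving),
            reformat_by_permutation(moving, curt_register(fixed, moving)),
        )
        assert est.displacement_field_.shape == fixed.shape + (2,)

    def test_identity_field_is_zero(self, small_scene):
        fixed, moving, _ = small_scene
        est = IdentityRegistration().fit(fixed, moving)
        assert not est.displacement_field_.any()
        assert np.array_equal(est.transform(moving), moving)

    def test_oracle_field_is_admissible_everywhere_defined(self, small_scene, small_spec):
        fixed, moving, truth = small_scene
        est = OracleRegistration(truth=truth).fit(fixed, moving)
        b = truth.region_mask("B")
        assert (est.displacement_field_[b, 0] == small_spec.shift).all()
        assert not est.displacement_field_[~b].any()

    def test_unfitted_transform_raises(self, small_scene):
        with pytest.raises(NotFittedError):
            CurtRegistration().transform(small_scene[1])

    def test_sklearn_params_protocol(self, small_scene):
        _, _, truth = small_scene
        est = OracleRegistration(truth=truth)
        assert est.get_params()["truth"] is truth
        cloned = clone(est)
        assert np.array_equal(cloned.truth.labels, truth.labels)
        assert cloned.truth.shift == truth.shift
        est.set_params(truth=None)
        with pytest.raises(ValueError, match="requires truth"):
            est.fit(small_scene[0], small_scene[1])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape mismatch"):
            CurtRegistration().fit(
                rng.integers(0, 9, (3, 4)), rng.integers(0, 9, (4, 3))
            )
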