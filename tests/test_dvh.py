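import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosekit.dvh import (
    INDEX_ORDER,
    ErrorReport,
    best_model_fraction,
    cumulative_dvh,
    delta_errors,
    dose_at_volume,
    index_set,
    volume_at_dose,
)


class TestCumulativeDvh:
    def test_uniform_dose_is_a_step_function(self):
        dvh = cumulative_dvh(np.full((4, 4, 2), 50.4), np.ones((4, 4, 2), bool))
        assert dvh.volume(50.4) == 1.0
        assert dvh.volume(10.0) == 1.0
        assert dvh.volume(50.41) == 0.0

    def test_two_voxel_enumeration(self):
        dose = np.array([[[10.0, 30.0]]])
        dvh = cumulative_dvh(dose, np.ones_like(dose, bool))
        assert dvh.volume(10.0) == 1.0
        assert dvh.volume(30.0) == 0.5

    def test_empty_mask_error_names_structure(self):
        with pytest.raises(ValueError, match="rectum"):
            cumulative_dvh(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool), name="rectum")

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 8))
    def test_matches_brute_force_threshold_counting(self, seed, n):
        """Sort-based curve equals exhaustive threshold counting on
        every grid up to 16^3 and arbitrary query doses."""
        r = np.random.default_rng(seed)
        dose = r.uniform(0, 60, size=(n, n, n))
        mask = r.random((n, n, n)) < 0.7
        if not mask.any():
            mask[0, 0, 0] = True
        dvh = cumulative_dvh(dose, mask)
        queries = np.concatenate([dose[mask], r.uniform(0, 60, 10)])
        vals = dose[mask]
        for q in queries:
            assert dvh.volume(q) == pytest.approx((vals >= q).sum() / len(vals))

    def test_order_statistic_dp_oracle(self):
        """100 voxels with doses 1..100: D95 is the 6th smallest, since 95
        voxels receive at least 6 Gy."""
        dose = np.arange(1.0, 101.0).reshape(10, 10, 1)
        dvh = cumulative_dvh(dose, np.ones_like(dose, bool))
        assert dose_at_volume(dvh, 95) == 6.0
        assert dose_at_volume(dvh, 50) == 51.0
        assert dose_at_volume(dvh, 100) == 1.0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_dp_monotone_in_p(self, seed):
        r = np.random.default_rng(seed)
        dose = r.gamma(2.0, 10.0, size=(8, 8, 4))
        dvh = cumulative_dvh(dose, np.ones_like(dose, bool))
        assert dose_at_volume(dvh, 50) >= dose_at_volume(dvh, 95)

    def test_volume_at_dose_cases(self):
        uniform = cumulative_dvh(np.full((3, 3, 3), 50.4), np.ones((3, 3, 3), bool))
        assert volume_at_dose(uniform, 30.0) == 100.0
        low = cumulative_dvh(np.full((3, 3, 3), 10.0), np.ones((3, 3, 3), bool))
        assert volume_at_dose(low, 30.0) == 0.0
        half = np.array([40.0] * 6 + [20.0] * 6).reshape(3, 2, 2)
        dvh = cumulative_dvh(half, np.ones_like(half, bool))
        assert volume_at_dose(dvh, 30.0) == 50.0


class TestIndexSet:
    def test_exactly_fourteen_indices(self, small_phantom, seven_beam_plan):
        from dosekit.phantom import synth_dose

        dose = synth_dose(small_phantom, seven_beam_plan)
        idx = index_set(dose, small_phantom.structures)
        assert len(idx.values) == 14
        assert tuple(idx.values) == INDEX_ORDER

    def test_uniform_dose_recovers_constant(self, small_phantom):
        idx = index_set(np.full(small_phantom.grid.shape, 42.0), small_phantom.structures)
        for (struct, name), v in idx.values.items():
            if name.startswith("D"):
                assert v == 42.0
            else:  # V30 at uniform 42 Gy
                assert v == 100.0

    def test_per_structure_uniform_doses_recovered(self, small_phantom):
        # PTV painted last: adjacent structures may share boundary voxels
        levels = {"bladder": 28.0, "rectum": 35.0, "spinal_cord": 10.0,
                  "femoral_head_l": 15.0, "femoral_head_r": 18.0, "ptv": 50.0}
        dose = np.zeros(small_phantom.grid.shape)
        for s, v in levels.items():
            dose[small_phantom.structures[s]] = v
        idx = index_set(dose, small_phantom.structures)
        assert idx[("ptv", "Dmean")] == 50.0
        # bladder abuts the PTV (target margins overlap it), so its hottest
        # voxels carry the PTV level; the others recover their own constants
        assert idx[("bladder", "Dmax")] == 50.0
        assert idx[("rectum", "V30")] == 100.0
        assert idx[("rectum", "Dmean")] == 35.0
        assert idx[("spinal_cord", "Dmax")] == 10.0
        assert idx[("femoral_head_r", "Dmax")] == 18.0

    def test_voxel_order_invariance(self, small_phantom, rng):
        dose = rng.uniform(0, 60, small_phantom.grid.shape)
        idx = index_set(dose, small_phantom.structures)
        perm = rng.permutation(dose.size)
        # permute dose and every mask identically: indices must not move
        dose_p = dose.ravel()[perm].reshape(dose.shape)
        from dosekit.structures import StructureSet

        masks_p = {
            n: m.ravel()[perm].reshape(m.shape)
            for n, m in small_phantom.structures.masks.items()
        }
        idx_p = index_set(dose_p, StructureSet(masks_p, small_phantom.grid))
        np.testing.assert_allclose(idx_p.as_array(), idx.as_array())


def make_index_set(values_by_key):
    from dosekit.dvh import DVHIndexSet

    base = {k: 40.0 for k in INDEX_ORDER}
    base[("ptv", "D95")] = 38.0
    base[("ptv", "D50")] = 39.0
    base[("bladder", "V30")] = 50.0
    base[("rectum", "V30")] = 50.0
    base.update(values_by_key)
    return DVHIndexSet(values=base)


class TestDeltaErrors:
    def test_identical_sets_give_zero(self):
        a = make_index_set({})
        rep = delta_errors(a, a, 50.4)
        assert rep.as_array().max() == 0.0

    def test_printed_formula_arithmetic(self):
        gt = make_index_set({("ptv", "Dmean"): 30.0})
        pred = make_index_set({("ptv", "Dmean"): 32.0})
        rep = delta_errors(gt, pred, 50.4)
        assert rep.deltas[("ptv", "Dmean")] == pytest.approx(2.0 / 50.4 * 100.0)

    def test_symmetric_in_gt_and_pred(self):
        gt = make_index_set({("rectum", "Dmax"): 45.0})
        pred = make_index_set({("rectum", "Dmax"): 41.0})
        np.testing.assert_allclose(
            delta_errors(gt, pred, 50.4).as_array(),
            delta_errors(pred, gt, 50.4).as_array(),
        )

    def test_scales_inversely_with_prescription(self):
        gt = make_index_set({("bladder", "Dmean"): 20.0})
        pred = make_index_set({("bladder", "Dmean"): 25.0})
        d1 = delta_errors(gt, pred, 50.4).as_array()
        d2 = delta_errors(gt, pred, 2 * 50.4).as_array()
        np.testing.assert_allclose(d1, 2 * d2)


def report_from_deltas(deltas):
    return ErrorReport(
        deltas=dict(zip(INDEX_ORDER, deltas)),
        prescription_gy=50.4,
        overall_mean=float(np.mean(deltas)),
        overall_sd=float(np.std(deltas)),
    )


class TestBestModelFraction:
    def test_strict_winner_takes_all(self):
        good = [report_from_deltas([1.0] * 14)]
        bad = [report_from_deltas([2.0] * 14)]
        frac = best_model_fraction({"good": good, "bad": bad})
        assert frac == {"good": 1.0, "bad": 0.0}

    def test_ties_credit_all_models(self):
        same = [report_from_deltas([1.0] * 14)]
        frac = best_model_fraction({"a": same, "b": [report_from_deltas([1.0] * 14)]})
        assert frac == {"a": 1.0, "b": 1.0}

    def test_hand_built_7_4_3_split(self):
        base = np.full(14, 5.0)
        a, b, c = base.copy(), base.copy(), base.copy()
        a[:7] = 1.0  # model a best on 7 indices
        b[7:11] = 1.0  # model b best on 4
        c[11:] = 1.0  # model c best on 3
        frac = best_model_fraction(
            {"a": [report_from_deltas(a)], "b": [report_from_deltas(b)], "c": [report_from_deltas(c)]}
        )
        assert frac == {"a": 7 / 14, "b": 4 / 14, "c": 3 / 14}
        assert sum(frac.values()) == pytest.approx(1.0)  # no ties: fractions partition
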