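"""Defect classification and outcome scoring on integrated fields."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_field
from vftrial.grid import (
    FieldLocation,
    RegionSpec,
    common_frame_locations,
    region_members,
)
from vftrial.scoring import (
    classify_vfd,
    defect_mask,
    improved_area,
    mtd,
    score_patient,
)

LEFT = region_members(RegionSpec.hemifield("left"))
UL = region_members(RegionSpec.quadrant("UL"))
LL = region_members(RegionSpec.quadrant("LL"))


def _field_with_probs(flagged, prob=2.0, pid="P001"):
    probs = {
        loc: (prob if loc in set(flagged) else 100.0)
        for loc in common_frame_locations()
    }
    return make_field(20.0, patient_id=pid, prob=probs)


class TestDefectMask:
    def test_category_below_five_percent_is_defective(self):
        field = _field_with_probs([FieldLocation(-9, 9)], prob=2.0)
        assert region_members(defect_mask(field)) == [FieldLocation(-9, 9)]

    def test_category_five_is_not_defective(self):
        """The threshold is strict: the 5% category itself stays out."""
        field = _field_with_probs([FieldLocation(-9, 9)], prob=5.0)
        assert region_members(defect_mask(field)) == []

    def test_all_normal_field_gives_empty_mask(self):
        assert region_members(defect_mask(make_field(30.0))) == []


class TestClassifyVfd:
    def test_full_left_hemifield_is_left_hemianopia(self):
        cls = classify_vfd(RegionSpec.mask(LEFT))
        assert (cls.side, cls.vfd_type) == ("left", "hemianopia")
        assert cls.quadrant is None

    def test_single_quadrant_is_quadrantanopia(self):
        cls = classify_vfd(RegionSpec.mask(UL))
        assert (cls.side, cls.vfd_type, cls.quadrant) == (
            "left", "quadrantanopia", "UL"
        )

    def test_small_spillover_stays_quadrantanopia(self):
        # 2/13 < 25% occupancy of LL: not enough for a hemianopia call
        cls = classify_vfd(RegionSpec.mask(UL + LL[:2]))
        assert (cls.side, cls.vfd_type, cls.quadrant) == (
            "left", "quadrantanopia", "UL"
        )

    def test_quarter_occupancy_of_both_quadrants_is_hemianopia(self):
        cls = classify_vfd(RegionSpec.mask(UL[:4] + LL[:4]))
        assert (cls.side, cls.vfd_type) == ("left", "hemianopia")

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_vfd(RegionSpec.mask([]))

    def test_unlateralized_tie_rejected(self):
        mirror = [FieldLocation(-p.x_deg, p.y_deg) for p in UL]
        with pytest.raises(ValueError, match="un-lateralized"):
            classify_vfd(RegionSpec.mask(UL + mirror))


class TestImprovedArea:
    def test_two_points_gain_gives_72(self):
        pre = make_field(10.0)
        post_map = {loc: 10.0 for loc in common_frame_locations()}
        for loc in LEFT[:2]:
            post_map[loc] = 16.0
        post = make_field(post_map, visit="week12")
        assert improved_area(pre, post, RegionSpec.hemifield("left")) == 72.0
        assert improved_area(pre, post, RegionSpec.whole()) == 72.0

    def test_three_points_gain_gives_108(self):
        pre = make_field(10.0)
        post_map = {loc: 10.0 for loc in common_frame_locations()}
        for loc in LEFT[:3]:
            post_map[loc] = 18.0
        post = make_field(post_map, visit="week12")
        assert improved_area(pre, post, RegionSpec.whole()) == 108.0

    def test_gain_below_threshold_counts_zero(self):
        pre = make_field(10.0)
        post = make_field(15.9, visit="week12")
        assert improved_area(pre, post, RegionSpec.whole()) == 0.0

    def test_five_points_from_deep_baseline(self):
        pre = make_field(4.0)
        post_map = {loc: 4.0 for loc in common_frame_locations()}
        for loc in LEFT[:5]:
            post_map[loc] = 14.0
        post = make_field(post_map, visit="week12")
        assert improved_area(pre, post, RegionSpec.hemifield("left")) == 180.0

    def test_already_normal_points_excluded_by_30_db_cap(self):
        pre = make_field(31.0)
        post = make_field(40.0, visit="week12")
        assert improved_area(pre, post, RegionSpec.whole()) == 0.0
        assert improved_area(
            pre, post, RegionSpec.whole(), normal_cap_db=None
        ) == 52 * 36.0

    def test_region_nesting_whole_dominates_hemifield(self, rng):
        pre_map = {loc: rng.uniform(0, 28) for loc in common_frame_locations()}
        post_map = {
            loc: np.clip(v + rng.normal(0, 5), 0, 50)
            for loc, v in pre_map.items()
        }
        pre = make_field(pre_map)
        post = make_field(post_map, visit="week12")
        whole = improved_area(pre, post, RegionSpec.whole())
        for side in ("left", "right"):
            assert whole >= improved_area(pre, post, RegionSpec.hemifield(side))

    def test_monotone_in_threshold_and_post_sensitivity(self, rng):
        pre_map = {loc: rng.uniform(0, 28) for loc in common_frame_locations()}
        post_map = {
            loc: np.clip(v + rng.normal(0, 5), 0, 50)
            for loc, v in pre_map.items()
        }
        pre = make_field(pre_map)
        post = make_field(post_map, visit="week12")
        areas = [
            improved_area(pre, post, RegionSpec.whole(), delta_db=d)
            for d in (2, 4, 6, 8, 10)
        ]
        assert areas == sorted(areas, reverse=True)
        raised = make_field(
            {loc: min(50.0, v + 3.0) for loc, v in post_map.items()},
            visit="week12",
        )
        assert improved_area(pre, raised, RegionSpec.whole()) >= areas[2]

    def test_patient_mismatch_rejected(self):
        with pytest.raises(ValueError, match="patient"):
            improved_area(
                make_field(10.0, patient_id="P001"),
                make_field(10.0, patient_id="P002"),
                RegionSpec.whole(),
            )


class TestMtd:
    def test_constant_td(self):
        assert mtd(make_field(10.0, td=-20.0), RegionSpec.whole()) == -20.0

    def test_hemifield_mixture_averages(self):
        td_map = {
            loc: (-30.0 if loc.x_deg < 0 else -10.0)
            for loc in common_frame_locations()
        }
        field = make_field(10.0, td=td_map)
        assert mtd(field, RegionSpec.whole()) == pytest.approx(-20.0)
        assert mtd(field, RegionSpec.hemifield("left")) == pytest.approx(-30.0)

    @given(shift=st.floats(-10, 10, allow_nan=False))
    def test_shift_linearity(self, shift):
        td_map = {
            loc: -0.3 * abs(loc.x_deg) - 0.1 * loc.y_deg
            for loc in common_frame_locations()
        }
        base = mtd(make_field(10.0, td=td_map), RegionSpec.whole())
        shifted = mtd(
            make_field(10.0, td={k: v + shift for k, v in td_map.items()}),
            RegionSpec.whole(),
        )
        assert shifted == pytest.approx(base + shift, abs=1e-9)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mtd(make_field(10.0), RegionSpec.mask([]))


class TestScorePatient:
    def _pre(self):
        sens = {
            loc: (5.0 if loc.x_deg < 0 else 30.0)
            for loc in common_frame_locations()
        }
        td = {loc: s - 32.0 for loc, s in sens.items()}
        prob = {
            loc: (0.5 if loc.x_deg < 0 else 100.0)
            for loc in common_frame_locations()
        }
        return make_field(sens, td=td, prob=prob)

    def test_no_change_scores_zero_and_nonresponder(self):
        pre = self._pre()
        post = make_field(
            {loc: d.sensitivity_db for loc, d in pre.values.items()},
            td={loc: d.td_db for loc, d in pre.values.items()},
            visit="week12",
        )
        rec = score_patient(pre, post, arm="NV")
        assert rec.vfd_side == "left" and rec.vfd_type == "hemianopia"
        assert rec.improved_area_hemi_deg2 == rec.improved_area_whole_deg2 == 0.0
        assert rec.mtd_delta_hemi == rec.mtd_delta_whole == 0.0
        assert not rec.responder_hemi and not rec.responder_whole

    def test_programmed_three_point_gain(self):
        pre = self._pre()
        sens = {loc: d.sensitivity_db for loc, d in pre.values.items()}
        td = {loc: d.td_db for loc, d in pre.values.items()}
        for loc in LEFT[:3]:
            sens[loc] += 8.0
            td[loc] += 8.0
        post = make_field(sens, td=td, visit="week12")
        rec = score_patient(pre, post, arm="NV")
        assert rec.improved_area_hemi_deg2 == 108.0
        assert rec.improved_area_whole_deg2 == 108.0
        # MTD delta is the regional mean of the TD changes
        assert rec.mtd_delta_hemi == pytest.approx(3 * 8.0 / 26)
        assert rec.mtd_delta_whole == pytest.approx(3 * 8.0 / 52)
        assert rec.responder_hemi and rec.responder_whole

    def test_defective_hemifield_is_the_full_hemifield(self):
        """Gains on non-mask points of the defective side still count."""
        pre_sens = {
            loc: (5.0 if loc in set(UL) else 25.0)
            for loc in common_frame_locations()
        }
        prob = {
            loc: (0.5 if loc in set(UL) else 100.0)
            for loc in common_frame_locations()
        }
        pre = make_field(pre_sens, prob=prob)
        sens = dict(pre_sens)
        for loc in LL[:2]:  # improvements outside the defect mask, same side
            sens[loc] += 7.0
        post = make_field(sens, visit="week12")
        rec = score_patient(pre, post, arm="NV")
        assert rec.vfd_type == "quadrantanopia"
        assert rec.improved_area_hemi_deg2 == 72.0
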