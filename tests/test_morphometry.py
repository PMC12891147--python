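import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from olvf.morphometry import (
    ESQ_SCORES,
    EsqGrade,
    ReferenceLevelError,
    VertebraFinding,
    VertebraHeights,
    VertebralLevel,
    assign_esq_grade,
    estimate_height_loss,
)

T = VertebralLevel


class TestVertebralLevel:
    def test_fifteen_levels_in_order(self):
        levels = list(T)
        assert len(levels) == 15
        assert levels[0] is T.T3 and levels[-1] is T.L5
        assert all(int(b) - int(a) == 1 for a, b in zip(levels, levels[1:]))

    def test_t12_l1_adjacent(self):
        assert T.T12.is_adjacent_to(T.L1)
        assert not T.T12.is_adjacent_to(T.L2)

    @pytest.mark.parametrize("label,expected", [("T3", T.T3), ("l4", T.L4), (" t12 ", T.T12)])
    def test_from_label(self, label, expected):
        assert T.from_label(label) is expected

    @pytest.mark.parametrize("label", ["T1", "T2", "L6", "C7", "x"])
    def test_from_label_rejects_outside_range(self, label):
        with pytest.raises(ValueError):
            T.from_label(label)


class TestGradeScoreBijection:
    def test_fixed_mapping(self):
        assert EsqGrade.NONE.score == 0.0
        assert EsqGrade.MINIMAL.score == -0.5
        assert EsqGrade.MILD.score == -1.0
        assert EsqGrade.MODERATE.score == -1.5
        assert EsqGrade.MODERATELY_SEVERE.score == -2.0
        assert EsqGrade.SEVERE.score == -2.5
        assert EsqGrade.COLLAPSED.score == -3.0

    def test_roundtrip(self):
        for grade in EsqGrade:
            assert EsqGrade.from_score(grade.score) is grade

    def test_from_score_rejects_others(self):
        with pytest.raises(ValueError):
            EsqGrade.from_score(-0.25)


def _spine(heights_by_level):
    return [VertebraHeights(lvl, *h) for lvl, h in heights_by_level.items()]


class TestEstimateHeightLoss:
    def test_interpolation_between_flat_neighbours(self):
        # Expected anterior at L1 interpolates T11..L2 to 30 mm; 20 mm -> 1/3.
        spine = _spine({
            T.T11: (30.0, 28.0, 29.0),
            T.L1: (20.0, 30.0, 29.5),
            T.L2: (30.0, 31.0, 29.75),
        })
        loss = estimate_height_loss(spine, T.L1, {T.T11, T.L2})
        assert loss == pytest.approx(1.0 / 3.0, abs=1e-4)

    def test_no_deformity(self):
        spine = _spine({
            T.T7: (30.0, 30.0, 30.0),
            T.T8: (30.0, 30.0, 30.0),
            T.T9: (30.0, 30.0, 30.0),
        })
        assert estimate_height_loss(spine, T.T8, {T.T7, T.T9}) == 0.0

    def test_symmetric_neighbours_average(self):
        spine = _spine({
            T.T7: (28.0, 28.0, 28.0),
            T.T8: (10.0, 30.0, 30.0),
            T.T9: (32.0, 32.0, 32.0),
        })
        loss = estimate_height_loss(spine, T.T8, {T.T7, T.T9})
        assert loss == pytest.approx(1.0 - 10.0 / 30.0, abs=1e-4)

    def test_single_sided_reference_carried(self):
        spine = _spine({T.T7: (30.0, 30.0, 30.0), T.T8: (15.0, 30.0, 30.0)})
        assert estimate_height_loss(spine, T.T8, {T.T7}) == pytest.approx(0.5)

    def test_loss_floored_at_zero(self):
        spine = _spine({T.T7: (30.0, 30.0, 30.0), T.T8: (35.0, 36.0, 37.0)})
        assert estimate_height_loss(spine, T.T8, {T.T7}) == 0.0

    def test_no_reference_raises(self):
        spine = _spine({T.T8: (30.0, 30.0, 30.0)})
        with pytest.raises(ReferenceLevelError):
            estimate_height_loss(spine, T.T8, set())

    def test_missing_target_raises(self):
        spine = _spine({T.T7: (30.0, 30.0, 30.0)})
        with pytest.raises(ValueError, match="not present"):
            estimate_height_loss(spine, T.T8, {T.T7})

    def test_duplicate_level_raises(self):
        spine = _spine({T.T7: (30.0, 30.0, 30.0), T.T8: (30.0, 30.0, 30.0)})
        spine.append(VertebraHeights(T.T7, 29.0, 29.0, 29.0))
        with pytest.raises(ValueError, match="duplicate"):
            estimate_height_loss(spine, T.T8, {T.T7})

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance(self, scale):
        base = {
            T.T7: (28.0, 28.5, 29.0),
            T.T8: (18.0, 27.0, 28.0),
            T.T9: (32.0, 31.0, 30.0),
        }
        original = estimate_height_loss(_spine(base), T.T8, {T.T7, T.T9})
        scaled_spine = _spine(
            {lvl: tuple(scale * v for v in h) for lvl, h in base.items()}
        )
        scaled = estimate_height_loss(scaled_spine, T.T8, {T.T7, T.T9})
        assert scaled == pytest.approx(original, rel=1e-9)


class TestAssignGrade:
    @pytest.mark.parametrize(
        "loss,fracture_like,expected",
        [
            (0.22, True, EsqGrade.MILD),
            (0.10, False, EsqGrade.NONE),
            (0.70, True, EsqGrade.COLLAPSED),
            (0.0, True, EsqGrade.NONE),
            (0.10, True, EsqGrade.MINIMAL),
            (0.28, False, EsqGrade.MODERATE),
            (0.36, False, EsqGrade.MODERATELY_SEVERE),
            (0.50, False, EsqGrade.SEVERE),
            (1.0, False, EsqGrade.COLLAPSED),
        ],
    )
    def test_examples(self, loss, fracture_like, expected):
        finding = VertebraFinding(T.T8, loss, fracture_like=fracture_like)
        assert assign_esq_grade(finding) is expected

    def test_non_fracture_cause_forces_none(self):
        finding = VertebraFinding(T.T8, 0.30, fracture_like=True, non_fracture_cause=True)
        assert assign_esq_grade(finding) is EsqGrade.NONE

    @pytest.mark.parametrize(
        "edge,expected",
        [
            (0.20, EsqGrade.MILD),
            (0.25, EsqGrade.MODERATE),
            (1.0 / 3.0, EsqGrade.MODERATELY_SEVERE),
            (0.40, EsqGrade.SEVERE),
            (2.0 / 3.0, EsqGrade.COLLAPSED),
        ],
    )
    def test_boundaries_fall_in_upper_bin(self, edge, expected):
        # Band edges are closed on the left, mirroring the ">=" notation.
        finding = VertebraFinding(T.T8, edge, fracture_like=False)
        assert assign_esq_grade(finding) is expected

    def test_invalid_height_loss_rejected(self):
        with pytest.raises(ValueError):
            VertebraFinding(T.T8, 1.2)
        with pytest.raises(ValueError):
            VertebraFinding(T.T8, -0.1)

    @given(
        losses=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20
        )
    )
    def test_monotone_in_height_loss(self, losses):
        losses = sorted(losses)
        scores = [
            assign_esq_grade(VertebraFinding(T.T8, loss, fracture_like=True)).score
            for loss in losses
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    @given(
        loss=st.floats(min_value=0.0, max_value=1.0),
        fracture_like=st.booleans(),
        non_fracture_cause=st.booleans(),
    )
    def test_score_always_in_fixed_set(self, loss, fracture_like, non_fracture_cause):
        grade = assign_esq_grade(
            VertebraFinding(T.T8, loss, fracture_like, non_fracture_cause)
        )
        assert grade.score in ESQ_SCORES

    def test_heights_must_be_positive(self):
        with pytest.raises(ValueError):
            VertebraHeights(T.T8, 0.0, 30.0, 30.0)
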