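import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sibamod import (
    OptimisticModel,
    Visit,
    detrend,
    extend_labels,
    optimistic_predict,
    retrend,
    retrend_labels,
)


def decay_oracle(madrs, lam, dt):
    """Repeated multiplication, the independent oracle for the decay formula."""
    value = float(madrs)
    for _ in range(dt):
        value *= 1.0 - lam / 100.0
    return value


class TestExtendLabels:
    def test_plus_minus_window_labels_eleven_days(self):
        ext = extend_labels([Visit(30, 25)], n_days=180, window=5)
        assert ext.days == list(range(25, 36))
        assert all(ext.entries[d].madrs == 25 for d in ext.days)

    def test_truncated_at_study_boundaries(self):
        ext = extend_labels([Visit(2, 30)], n_days=180, window=5)
        assert ext.days == list(range(0, 8))
        ext = extend_labels([Visit(178, 30)], n_days=180, window=5)
        assert ext.days == list(range(173, 180))

    def test_overlap_resolved_to_nearest_visit_tie_to_earlier(self):
        ext = extend_labels([Visit(10, 40), Visit(18, 10)], n_days=30, window=5)
        assert ext.entries[13].source_visit.day == 10
        assert ext.entries[14].source_visit.day == 10  # equidistant -> earlier
        assert ext.entries[15].source_visit.day == 18

    def test_labeled_day_count_on_constructed_schedule(self):
        # windows 25..35, 55..65, 85..95: 3 disjoint windows of 11 days
        visits = [Visit(30, 30), Visit(60, 20), Visit(90, 10)]
        assert len(extend_labels(visits, 180, 5)) == 33
        # overlapping: 10..20 and 14..24 merge into 10..24
        assert len(extend_labels([Visit(15, 9), Visit(19, 9)], 180, 5)) == 15


class TestOptimisticModel:
    def test_zero_rate_is_carry_forward(self):
        assert optimistic_predict(OptimisticModel(0.0), Visit(0, 30), 10) == 30

    def test_zero_dt_returns_visit_score(self):
        assert optimistic_predict(OptimisticModel(1.6), Visit(5, 30), 5) == 30

    def test_decay_matches_repeated_multiplication_oracle(self):
        got = optimistic_predict(OptimisticModel(1.6), Visit(0, 30), 10)
        assert got == pytest.approx(decay_oracle(30, 1.6, 10), abs=1e-12)

    def test_day_before_anchor_rejected(self):
        with pytest.raises(ValueError, match="before the anchor"):
            optimistic_predict(OptimisticModel(1.6), Visit(10, 30), 5)

    @pytest.mark.parametrize("lam", [-0.1, 100.0, 150.0])
    def test_invalid_rate_rejected(self, lam):
        with pytest.raises(ValueError):
            OptimisticModel(lam)

    def test_linear_form_sheds_fixed_fraction_per_day(self):
        model = OptimisticModel(2.0, form="linear")
        # 30 - 30*0.02*10 = 24
        assert optimistic_predict(model, Visit(0, 30), 10) == pytest.approx(24.0)
        # floored at the decay target, never negative
        assert optimistic_predict(model, Visit(0, 30), 100) == 0.0
        assert optimistic_predict(OptimisticModel(2.0, decay_target=6.0, form="linear"), Visit(0, 30), 100) == 6.0

    def test_unknown_decay_form_rejected(self):
        with pytest.raises(ValueError, match="decay form"):
            OptimisticModel(1.6, form="quadratic")

    def test_monotone_nonincreasing_in_dt(self):
        model = OptimisticModel(2.4)
        preds = [optimistic_predict(model, Visit(0, 42), d) for d in range(120)]
        assert all(b <= a for a, b in zip(preds, preds[1:]))


class TestDetrendRetrend:
    def test_residual_value_matches_decay_oracle(self):
        visits = [Visit(0, 30), Visit(30, 20)]
        model = OptimisticModel(1.6)
        ext = extend_labels(visits, 180, 0)
        res = detrend(ext, visits, model)
        # day 30 label 20, anchored at the baseline visit (day 0, 30)
        assert res.entries[30].residual == pytest.approx(20 - decay_oracle(30, 1.6, 30), abs=1e-9)

    def test_baseline_window_residuals_are_zero(self):
        visits = [Visit(0, 30), Visit(30, 25)]
        ext = extend_labels(visits, 180, 5)
        res = detrend(ext, visits, OptimisticModel(1.6))
        assert res.entries[0].residual == 0.0  # anchored at itself, dt=0

    def test_observed_equals_optimistic_gives_zero_residuals(self):
        # daily visits halving exactly: 40 -> 20 -> 10 -> 5 at lam = 50 %/day
        model = OptimisticModel(50.0)
        visits = [Visit(0, 40), Visit(1, 20), Visit(2, 10), Visit(3, 5)]
        ext = extend_labels(visits, 10, 0)
        res = detrend(ext, visits, model)
        np.testing.assert_allclose(res.values(), 0.0, atol=1e-12)

    def test_round_trip_is_exact(self, rng):
        for _ in range(50):
            days = np.sort(rng.choice(np.arange(0, 170, 5), size=5, replace=False))
            visits = [Visit(int(d), int(rng.integers(0, 61))) for d in days]
            model = OptimisticModel(float(rng.uniform(0, 3)))
            ext = extend_labels(visits, 180, 5)
            back = retrend_labels(detrend(ext, visits, model), model)
            for day in ext.days:
                assert back[day] == pytest.approx(ext.entries[day].madrs, abs=1e-12)

    def test_zero_rate_reduces_to_last_observation_carried_forward(self):
        visits = [Visit(0, 30), Visit(40, 18)]
        pred = retrend({d: 0.0 for d in range(60)}, visits, OptimisticModel(0.0))
        assert all(pred[d] == 30 for d in range(40))
        assert all(pred[d] == 18 for d in range(40, 60))

    def test_retrend_clips_to_madrs_range(self):
        visits = [Visit(0, 2)]
        pred = retrend({5: -5.0, 6: 80.0}, visits, OptimisticModel(1.6))
        assert pred[5] == 0.0
        assert pred[6] == 60.0

    def test_zero_residual_retrend_equals_optimistic_curve(self):
        visits = [Visit(0, 35), Visit(30, 25)]
        model = OptimisticModel(1.2)
        pred = retrend({d: 0.0 for d in range(60)}, visits, model)
        for d in range(30, 60):
            assert pred[d] == pytest.approx(decay_oracle(25, 1.2, d - 30), abs=1e-9)


@given(
    st.lists(st.integers(0, 60), min_size=2, max_size=6),
    st.floats(0.0, 3.0),
    st.integers(0, 5),
)
@settings(max_examples=60, deadline=None)
def test_detrend_retrend_identity_property(scores, lam, window):
    visits = [Visit(30 * i, m) for i, m in enumerate(scores)]
    n_days = visits[-1].day + 20
    model = OptimisticModel(lam)
    ext = extend_labels(visits, n_days, window)
    back = retrend_labels(detrend(ext, visits, model), model)
    assert all(back[d] == pytest.approx(ext.entries[d].madrs, abs=1e-12) for d in ext.days)
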