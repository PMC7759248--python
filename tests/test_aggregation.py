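"""Valid-day filtering, interval building, medians and CLR aggregation."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coqol.aggregation import (
    AggregateInterval,
    absolute_aggregate,
    build_intervals,
    clr_transform,
    daily_clr_matrix,
    flag_valid_days,
    relative_aggregate,
    replace_zeros,
)


def make_daily(rows, pid="P1", start=date(2018, 1, 1)):
    """rows: list of dicts overriding a plain full-wear day."""
    base = {
        "wear_min": 1440.0,
        "energy_kcal": 2000.0,
        "steps": 8000.0,
        "heart_rate_bpm": 60.0,
        "sedentary_min": 700.0,
        "light_min": 200.0,
        "fair_min": 30.0,
        "vigorous_min": 10.0,
        "sleep_min": 420.0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"participant_id": pid, "date": start + timedelta(days=i), **base, **row}
        out.append(rec)
    return pd.DataFrame(out)


class TestValidDays:
    @pytest.mark.parametrize(
        "wear,expected", [(1260.0, True), (1259.9, False), (0.0, False), (1440.0, True)]
    )
    def test_21_hour_threshold_is_inclusive(self, wear, expected):
        df = make_daily([{"wear_min": wear}])
        assert bool(flag_valid_days(df).iloc[0]) is expected

    def test_zero_threshold_accepts_all_monitored_days(self):
        df = make_daily([{"wear_min": w} for w in (0.0, 100.0, 1440.0)])
        assert flag_valid_days(df, min_wear_hours=0).all()


class TestIntervals:
    def test_validity_fraction_gate(self):
        """5/7 valid qualifies (0.714 >= 0.7); 4/7 (0.571) does not."""
        df5 = make_daily([{"wear_min": 1300.0}] * 5 + [{"wear_min": 100.0}] * 2)
        (iv,) = build_intervals(df5, date(2018, 1, 7), durations=(7,))
        assert iv.n_valid_days == 5 and iv.qualifies
        df4 = make_daily([{"wear_min": 1300.0}] * 4 + [{"wear_min": 100.0}] * 3)
        (iv,) = build_intervals(df4, date(2018, 1, 7), durations=(7,))
        assert not iv.qualifies

    def test_all_valid_all_durations_qualify(self):
        df = make_daily([{}] * 120)
        intervals = build_intervals(df, date(2018, 1, 1) + timedelta(days=119))
        assert len(intervals) == 7 and all(iv.qualifies for iv in intervals)

    def test_end_before_monitoring_is_empty(self):
        df = make_daily([{}] * 10)
        assert build_intervals(df, date(2017, 12, 31)) == []

    def test_raising_valid_fraction_never_adds_intervals(self):
        rng = np.random.default_rng(2)
        df = make_daily([{"wear_min": float(rng.choice([1300.0, 200.0]))} for _ in range(60)])
        end = date(2018, 1, 1) + timedelta(days=59)
        qualifying = {}
        for frac in (0.5, 0.7, 0.9):
            ivs = build_intervals(df, end, min_valid_fraction=frac)
            qualifying[frac] = {iv.duration_days for iv in ivs if iv.qualifies}
        assert qualifying[0.9] <= qualifying[0.7] <= qualifying[0.5]


class TestAbsoluteAggregate:
    def test_single_valid_day_is_identity(self):
        df = make_daily([{}] * 7)
        (iv,) = build_intervals(df, date(2018, 1, 7), durations=(7,))
        raw, processed = absolute_aggregate(iv, df)
        assert raw.values == {"energy": 2000.0, "steps": 8000.0, "heart_rate": 60.0}
        assert processed.values["light_fair"] == 230.0
        assert processed.values["active"] == 240.0

    def test_cumulative_variables_are_per_day_before_median(self):
        """median(light+fair per day) != median(light)+median(fair) in general."""
        df = make_daily(
            [
                {"light_min": 20.0, "fair_min": 10.0},   # light+fair 30
                {"light_min": 40.0, "fair_min": 5.0},    # 45
                {"light_min": 10.0, "fair_min": 50.0},   # 60
            ]
            + [{}] * 4
        )
        (iv,) = build_intervals(df, date(2018, 1, 7), durations=(7,))
        _, processed = absolute_aggregate(iv, df)
        days = df.iloc[:3]
        assert processed.values["fair"] == float(np.median(df["fair_min"]))
        per_day = (df["light_min"] + df["fair_min"]).to_numpy()
        assert processed.values["light_fair"] == float(np.median(per_day))

    def test_invalid_days_never_contribute(self):
        df = make_daily([{}] * 6 + [{"wear_min": 10.0, "steps": 10 ** 6}])
        (iv,) = build_intervals(df, date(2018, 1, 7), durations=(7,))
        raw, _ = absolute_aggregate(iv, df)
        assert raw.values["steps"] == 8000.0

    def test_all_missing_variable_is_absent_not_zero(self):
        df = make_daily([{"heart_rate_bpm": np.nan}] * 7)
        (iv,) = build_intervals(df, date(2018, 1, 7), durations=(7,))
        raw, _ = absolute_aggregate(iv, df)
        assert "heart_rate" not in raw.values

    def test_nonqualifying_interval_rejected(self):
        df = make_daily([{"wear_min": 100.0}] * 7)
        (iv,) = build_intervals(df, date(2018, 1, 7), durations=(7,))
        with pytest.raises(ValueError):
            absolute_aggregate(iv, df)


class TestCLR:
    def test_equal_components_give_zero_vector(self):
        np.testing.assert_allclose(clr_transform([5.0, 5.0, 5.0]), 0.0, atol=1e-12)

    def test_geometric_progression_closed_form(self):
        e = np.e
        np.testing.assert_allclose(clr_transform([1.0, e, e ** 2]), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_scale_invariance(self):
        x = np.array([700.0, 200.0, 30.0, 10.0])
        np.testing.assert_allclose(clr_transform(x), clr_transform(x * 1440), atol=1e-12)

    @pytest.mark.parametrize("bad", [[1.0, 0.0, 2.0], [1.0, -1.0, 2.0], [1.0, np.nan, 2.0]])
    def test_nonpositive_components_rejected(self, bad):
        with pytest.raises(ValueError):
            clr_transform(bad)

    def test_zero_replacement_preserves_total(self):
        x = np.array([700.0, 0.0, 30.0, 0.0])
        out = replace_zeros(x, delta=1.0)
        assert out.sum() == pytest.approx(x.sum())
        assert (out > 0).all() and out[1] == 1.0 and out[3] == 1.0


class TestCLRProperties:
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=8)
    )
    @settings(max_examples=200, deadline=None)
    def test_zero_sum_and_scale_invariance(self, comp):
        out = clr_transform(comp)
        assert abs(out.sum()) < 1e-9
        np.testing.assert_allclose(out, clr_transform(np.asarray(comp) * 3.7), atol=1e-9)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e3), min_size=3, max_size=6).filter(
            lambda xs: sum(xs) > 2 * len(xs)
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_zero_replacement_preserves_total_and_positivity(self, comp):
        out = replace_zeros(comp, delta=1.0)
        assert out.sum() == pytest.approx(sum(comp), rel=1e-9)
        assert (out > 0).all()


class TestRelativeAggregate:
    def test_single_day_equals_that_days_clr(self):
        df = make_daily([{}] * 7)
        (iv,) = build_intervals(df, date(2018, 1, 7), durations=(7,))
        vec = relative_aggregate(iv, df, include_sleep=True)
        expected = clr_transform([700.0, 200.0, 30.0, 10.0, 420.0])
        np.testing.assert_allclose(list(vec.values.values()), expected, atol=1e-12)

    def test_relative_vectors_sum_to_zero(self):
        rng = np.random.default_rng(0)
        rows = [
            {
                "sedentary_min": float(rng.uniform(300, 900)),
                "light_min": float(rng.uniform(50, 300)),
                "fair_min": float(rng.uniform(0, 60)),
                "vigorous_min": float(rng.uniform(0, 30)),
                "sleep_min": float(rng.uniform(300, 500)),
            }
            for _ in range(14)
        ]
        df = make_daily(rows)
        (iv,) = build_intervals(df, date(2018, 1, 14), durations=(14,))
        for include_sleep in (False, True):
            vec = relative_aggregate(iv, df, include_sleep)
            assert abs(sum(vec.values.values())) < 1e-9

    def test_mean_of_daily_clrs_identity(self):
        """Two days with CLR-fair -x and +x aggregate to CLR-fair 0."""
        a = [600.0, 200.0, 20.0, 10.0]
        # day2 swaps fair's log-ratio sign by construction: use reciprocal ratios
        g = np.exp(-clr_transform(a))
        df = make_daily(
            [
                dict(zip(["sedentary_min", "light_min", "fair_min", "vigorous_min"], a)),
                dict(zip(["sedentary_min", "light_min", "fair_min", "vigorous_min"], 100 * g)),
            ]
        )
        (iv,) = build_intervals(df, date(2018, 1, 2), durations=(7,), min_valid_fraction=0.2)
        vec = relative_aggregate(iv, df, include_sleep=False)
        np.testing.assert_allclose(list(vec.values.values()), 0.0, atol=1e-9)

    def test_geometric_mean_equals_mean_of_clrs(self):
        """CLR(componentwise geometric mean) == mean of daily CLR rows."""
        rng = np.random.default_rng(42)
        comps = rng.uniform(1.0, 800.0, size=(50, 5))
        df = make_daily(
            [
                dict(zip(
                    ["sedentary_min", "light_min", "fair_min", "vigorous_min", "sleep_min"], c
                ))
                for c in comps
            ]
        )
        mat = daily_clr_matrix(df, include_sleep=True)
        gm = np.exp(np.log(comps).mean(axis=0))
        np.testing.assert_allclose(mat.mean(axis=0), clr_transform(gm), atol=1e-9)

    def test_no_complete_day_returns_none(self):
        df = make_daily([{"fair_min": np.nan}] * 7)
        (iv,) = build_intervals(df, date(2018, 1, 7), durations=(7,))
        assert relative_aggregate(iv, df, include_sleep=False) is None
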