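"""Data-preparation rules: flooring, sample independence, behaviour
windows, hunt correction/smoothing, GPS QC, cull/hunt trend."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from condorlead import filtering
from condorlead.filtering import (bioyear, classify_foraging,
                                  compute_behavior_metrics,
                                  correct_and_smooth_hunts, cull_hunt_trend,
                                  floor_detection_limit, qc_gps_fixes,
                                  select_independent_samples)
from conftest import make_samples


class TestDetectionFloor:
    @pytest.mark.parametrize("value,expected,censored", [
        (6.2, 6.2, False),   # above the floor: unchanged
        (5.0, 2.5, True),    # boundary inclusive
        (0.8, 2.5, True),
        (5.0001, 5.0001, False),
        (0.0, 2.5, True),
    ])
    def test_floor_rule(self, value, expected, censored):
        v, c = floor_detection_limit(value)
        assert v == pytest.approx(expected)
        assert c is censored

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            floor_detection_limit(-1.0)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_identity_above_floor(self, a, b):
        fa, fb = floor_detection_limit(a)[0], floor_detection_limit(b)[0]
        if a <= b:
            assert fa <= fb
        if a > 5:
            assert fa == a

    def test_vectorised_matches_scalar(self):
        df = pd.DataFrame({"value": [0.8, 5.0, 6.2, 44.0]})
        out = filtering.apply_detection_floor(df)
        assert out["value"].tolist() == [2.5, 2.5, 6.2, 44.0]
        assert out["censored"].tolist() == [True, True, False, False]


class TestSampleIndependence:
    def test_single_sample_retained(self):
        out = select_independent_samples(make_samples([0], [10]))
        assert len(out) == 1

    def test_exception_band_and_long_gap(self):
        # 30 d gap with +15 triggers the rising-exposure exception;
        # 70 d gap from the last retained passes the >56 d rule
        out = select_independent_samples(
            make_samples([0, 30, 100], [10, 25, 12]))
        assert len(out) == 3

    def test_same_event_replacement(self):
        # <14 d and higher: the later sample replaces the earlier
        out = select_independent_samples(make_samples([0, 10], [10, 40]))
        assert len(out) == 1
        assert out["value"].iloc[0] == 40

    def test_lower_repeat_within_14d_dropped(self):
        out = select_independent_samples(make_samples([0, 10], [40, 10]))
        assert out["value"].tolist() == [40]

    def test_exception_band_requires_rise_above_10(self):
        out = select_independent_samples(make_samples([0, 30], [10, 20]))
        assert out["value"].tolist() == [10]  # +10 exactly is not enough
        out = select_independent_samples(make_samples([0, 30], [10, 20.5]))
        assert len(out) == 2

    def test_replacement_chains_left_to_right(self):
        # each replacement becomes the comparator for the next sample
        out = select_independent_samples(
            make_samples([0, 5, 10], [10, 20, 30]))
        assert out["value"].tolist() == [30]

    def test_care_and_pen_exclusions(self):
        df = make_samples([0, 100, 200], [10, 20, 30])
        df["days_in_care"] = [0, 4, 0]
        df["days_in_pen"] = [0, 0, 30]
        out = select_independent_samples(df)
        assert out["value"].tolist() == [10]

    def test_unsorted_input_rejected(self):
        df = make_samples([50, 0], [10, 20])
        with pytest.raises(ValueError):
            select_independent_samples(df)

    @given(st.lists(st.tuples(st.integers(0, 400), st.floats(0.1, 80)),
                    min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_spacing_invariant(self, pairs):
        days = sorted(p[0] for p in pairs)
        values = [p[1] for p in pairs]
        df = make_samples(days, values)
        once = select_independent_samples(df).reset_index(drop=True)
        twice = select_independent_samples(once).reset_index(drop=True)
        pd.testing.assert_frame_equal(once, twice)
        # every retained consecutive pair: >56 d apart or +10 exception
        d = once["date"].to_numpy()
        v = once["value"].to_numpy()
        for i in range(1, len(once)):
            gap = (d[i] - d[i - 1]) / np.timedelta64(1, "D")
            assert gap > 56 or (gap >= 14 and v[i] > v[i - 1] + 10)


class TestBehaviorMetrics:
    @staticmethod
    def _daily(flags):
        base = pd.Timestamp("2010-01-01")
        n = len(flags["free_flying"])
        return pd.DataFrame({
            "ID": "A",
            "date": [base + pd.Timedelta(days=i) for i in range(n)],
            **{k: np.asarray(v, bool) for k, v in flags.items()},
        })

    def test_all_proffered(self):
        daily = self._daily({"free_flying": [True] * 180,
                             "detected": [True] * 180,
                             "proffered": [True] * 180,
                             "coastal": [False] * 180})
        beh = compute_behavior_metrics(
            daily, "A", pd.Timestamp("2010-01-01") + pd.Timedelta(days=180))
        assert beh.proffered == 1.0
        assert beh.free_fly == 1.0
        assert beh.presence == 0.0  # proffered days excluded from Presence

    def test_proportion_arithmetic(self):
        ff = [i % 2 == 0 for i in range(180)]  # 90 free-flying days
        prof = [ff[i] and i < 18 for i in range(180)]  # 9 of them proffered
        daily = self._daily({"free_flying": ff, "detected": ff,
                             "proffered": prof, "coastal": [False] * 180})
        beh = compute_behavior_metrics(
            daily, "A", pd.Timestamp("2010-01-01") + pd.Timedelta(days=180))
        assert beh.proffered == pytest.approx(9 / 90)
        assert beh.free_fly == pytest.approx(0.5)

    def test_no_free_flying_days_undefined(self):
        daily = self._daily({"free_flying": [False] * 30,
                             "detected": [False] * 30,
                             "proffered": [False] * 30,
                             "coastal": [False] * 30})
        assert compute_behavior_metrics(
            daily, "A", pd.Timestamp("2010-03-01")) is None

    def test_matches_bruteforce_window_count(self):
        rng = np.random.default_rng(5)
        n = 400
        flags = {k: rng.random(n) < p for k, p in
                 [("free_flying", 0.8), ("detected", 0.7),
                  ("proffered", 0.3), ("coastal", 0.2)]}
        flags["detected"] &= flags["free_flying"]
        flags["proffered"] &= flags["detected"]
        flags["coastal"] &= flags["detected"]
        daily = self._daily(flags)
        asof = pd.Timestamp("2010-01-01") + pd.Timedelta(days=300)
        beh = compute_behavior_metrics(daily, "A", asof)
        lo = asof - pd.Timedelta(days=180)
        win = daily[(daily["date"] >= lo) & (daily["date"] < asof)]
        ffd = win["free_flying"].sum()
        assert beh.free_flying_days == ffd
        assert beh.proffered == pytest.approx(
            (win["proffered"] & win["free_flying"]).sum() / ffd)
        assert beh.presence == pytest.approx(
            (win["detected"] & ~win["proffered"]
             & win["free_flying"]).sum() / ffd)


def _hunt_frame(years, species="deer", count=100.0):
    rows = [{"region": "R", "species": species, "year": y, "month": m,
             "count": count} for y in years for m in range(1, 13)]
    return pd.DataFrame(rows)


class TestHuntSeries:
    def test_deer_correction_before_2015(self):
        df = _hunt_frame([2014, 2015])
        out = correct_and_smooth_hunts(df)
        oct14 = out[(out["year"] == 2014) & (out["month"] == 10)]
        oct15 = out[(out["year"] == 2015) & (out["month"] == 10)]
        assert oct14["corrected"].iloc[0] == pytest.approx(153.0)
        assert oct15["corrected"].iloc[0] == pytest.approx(100.0)

    def test_pig_counts_never_corrected(self):
        out = correct_and_smooth_hunts(_hunt_frame([2014], species="pig"))
        assert (out["corrected"] == 100.0).all()

    def test_constant_series_standardises_to_one(self):
        out = correct_and_smooth_hunts(_hunt_frame([2016, 2017]))
        assert np.allclose(out["bimonthly"], 100.0)
        assert np.allclose(out["standardized"], 1.0)

    def test_bimonthly_is_two_month_mean(self):
        df = _hunt_frame([2016])
        df.loc[df["month"] == 5, "count"] = 300.0
        out = correct_and_smooth_hunts(df)
        june = out[out["month"] == 6]["bimonthly"].iloc[0]
        assert june == pytest.approx((300.0 + 100.0) / 2)

    def test_missing_month_raises_with_location(self):
        df = _hunt_frame([2016])
        df = df[df["month"] != 6]
        with pytest.raises(ValueError, match="missing months"):
            correct_and_smooth_hunts(df)

    def test_length_preserved_nonnegative(self):
        rng = np.random.default_rng(0)
        df = _hunt_frame([2015, 2016])
        df["count"] = rng.uniform(0, 500, len(df))
        out = correct_and_smooth_hunts(df)
        assert len(out) == len(df)
        assert (out[["corrected", "bimonthly", "standardized"]] >= 0
                ).all().all()


class TestCullHuntTrend:
    def test_constant_ratio_zero_slope(self):
        df = pd.DataFrame({"bioyear": range(2016, 2023),
                           "cull": [200.0] * 7, "hunt": [100.0] * 7})
        assert cull_hunt_trend(df)["slope"] == pytest.approx(0.0)

    def test_linear_ratio_recovered_exactly(self):
        years = np.arange(2016, 2023)
        ratio = 0.5 + 0.1 * (years - 2016)
        df = pd.DataFrame({"bioyear": years, "hunt": 100.0,
                           "cull": ratio * 100.0})
        fit = cull_hunt_trend(df)
        assert fit["slope"] == pytest.approx(0.1)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        years = np.arange(2016, 2023, dtype=float)
        ratio = rng.uniform(0.5, 3.0, 7)
        df = pd.DataFrame({"bioyear": years, "hunt": 100.0,
                           "cull": ratio * 100.0})
        fit = cull_hunt_trend(df)
        X = np.column_stack([np.ones(7), years])
        slope_or = np.linalg.solve(X.T @ X, X.T @ ratio)[1]
        assert fit["slope"] == pytest.approx(slope_or, abs=1e-9)

    def test_zero_hunt_year_rejected(self):
        df = pd.DataFrame({"bioyear": [2016, 2017], "cull": [1.0, 1.0],
                           "hunt": [10.0, 0.0]})
        with pytest.raises(ValueError, match="2017"):
            cull_hunt_trend(df)

    def test_first_bioyear_truncated_to_jan_aug(self):
        monthly = pd.DataFrame(
            [{"year": y, "month": m} for y in (2016, 2017, 2018)
             for m in range(1, 13)])
        out = filtering.truncate_first_cull_bioyear(monthly)
        b16 = out[(out["year"] == 2017) & (out["month"] <= 8)]
        assert len(b16) == 8  # Jan-Aug 2017 only for Bioyear 2016
        assert not ((out["year"] == 2016) & (out["month"] >= 9)).any()


class TestGpsRules:
    @staticmethod
    def _fix(**kw):
        base = dict(ID="A", timestamp=pd.Timestamp("2020-06-01 12:00"),
                    fix_quality="3D", hdop=2.0, vdop=2.0, altitude_m=500.0,
                    agl_m=10.0, speed_kph=2.0)
        base.update(kw)
        return pd.DataFrame([base])

    @pytest.mark.parametrize("kw,kept", [
        ({}, True),
        ({"fix_quality": "2D"}, False),
        ({"hdop": 11.0}, False),
        ({"vdop": 11.0}, False),
        ({"vdop": np.nan}, True),      # missing VDOP passes
        ({"altitude_m": 4500.0}, False),
        ({"agl_m": -60.0}, False),
        ({"agl_m": -49.0}, True),
    ])
    def test_qc_rules(self, kw, kept):
        assert len(qc_gps_fixes(self._fix(**kw))) == (1 if kept else 0)

    def test_subsample_to_15_minutes(self):
        ts = pd.date_range("2020-06-01 10:00", periods=30, freq="1min")
        df = pd.concat([self._fix(timestamp=t) for t in ts],
                       ignore_index=True)
        out = qc_gps_fixes(df)
        assert len(out) == 2  # 10:00 and 10:15

    @pytest.mark.parametrize("kw,foraging", [
        ({}, True),  # midday, slow, low: foraging
        ({"speed_kph": 6.0}, False),
        ({"agl_m": 80.0}, False),
        ({"timestamp": pd.Timestamp("2020-06-01 03:00")}, False),  # night
    ])
    def test_foraging_classification(self, kw, foraging):
        assert len(classify_foraging(self._fix(**kw))) == \
            (1 if foraging else 0)


class TestBioyear:
    @pytest.mark.parametrize("date,expected", [
        ("2020-09-01", 2020), ("2021-08-31", 2020), ("2021-09-15", 2021),
        ("2020-01-01", 2019),
    ])
    def test_september_august_convention(self, date, expected):
        assert bioyear(pd.Timestamp(date)) == expected

    def test_spring_summer_is_march_to_august(self):
        months = {m: filtering.is_spring_summer(pd.Timestamp(2020, m, 15))
                  for m in range(1, 13)}
        assert [m for m, v in months.items() if v] == [3, 4, 5, 6, 7, 8]
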