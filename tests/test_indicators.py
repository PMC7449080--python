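import numpy as np
import pandas as pd
import pytest

from qocprofile.config import IndicatorParams
from qocprofile.errors import DataIntegrityError
from qocprofile.indicators import (aggregate, compute_failure_flags,
                                   eval_mms_appropriate, eval_retention_6m,
                                   eval_test_and_start, eval_timely_pickup,
                                   eval_vl_up_to_date)


class TestTestAndStart:
    def test_within_window(self):
        assert eval_test_and_start("2017-05-01", "2017-05-20") is False

    def test_same_day(self):
        assert eval_test_and_start("2017-05-01", "2017-05-01") is False

    def test_61_days_late(self):
        # 2017-05-01 .. 2017-07-01 is 61 days > 30
        assert eval_test_and_start("2017-05-01", "2017-07-01") is True

    def test_boundary_inclusive(self):
        assert eval_test_and_start("2017-05-01", "2017-05-31") is False
        assert eval_test_and_start("2017-05-01", "2017-06-01") is True

    def test_never_started(self):
        assert eval_test_and_start("2017-05-01", None) is True

    def test_start_before_diagnosis_rejected(self):
        with pytest.raises(DataIntegrityError):
            eval_test_and_start("2017-05-01", "2017-04-30")


class TestVlUpToDate:
    def test_stale_test(self):
        # 546 days before the as-of date > 365-day window
        assert eval_vl_up_to_date("2016-01-01", ["2016-10-01"],
                                  "2018-03-31") is True

    def test_test_on_asof_date(self):
        assert eval_vl_up_to_date("2016-01-01", ["2018-03-31"],
                                  "2018-03-31") is False

    def test_not_yet_eligible(self):
        # 75 days on ART < 180-day lag
        assert eval_vl_up_to_date("2018-01-15", [], "2018-03-31") is None

    def test_pre_start_tests_ignored(self, caplog):
        with caplog.at_level("WARNING"):
            res = eval_vl_up_to_date("2016-01-01", ["2015-06-01"],
                                     "2018-03-31")
        assert res is True
        assert "before ART start" in caplog.text


class TestMmsAppropriate:
    def test_unstable_mms_fails(self):
        assert eval_mms_appropriate(True, False) is True

    def test_stable_mms_ok(self):
        assert eval_mms_appropriate(True, True) is False

    def test_single_month_not_applicable(self):
        assert eval_mms_appropriate(False, False) is None


class TestTimelyPickup:
    def test_on_time(self):
        assert eval_timely_pickup("2017-03-01", "2017-03-25") is False

    def test_pickup_on_expected_date(self):
        assert eval_timely_pickup("2017-03-01", "2017-03-01") is False

    def test_35_days_late(self):
        assert eval_timely_pickup("2017-03-01", "2017-04-05") is True

    def test_no_pickup(self):
        assert eval_timely_pickup("2017-03-01", None) is True

    def test_grace_boundary_inclusive(self):
        assert eval_timely_pickup("2017-03-01", "2017-03-31") is False
        assert eval_timely_pickup("2017-03-01", "2017-04-01") is True


class TestRetention6m:
    def test_no_events_is_failure(self):
        assert eval_retention_6m("2017-01-01", []) is True

    def test_continuous_90_day_refills(self):
        # timely renewal chain covering day 182 + grace
        events = [("2017-01-01", 90), ("2017-04-01", 90), ("2017-06-30", 90)]
        assert eval_retention_6m("2017-01-01", events) is False

    def test_missed_critical_refill(self):
        # expecteds: 31, 61, ..., 181 (nearest to 182), no pickup after 151
        events = [(f"2017-01-{d:02d}", 30) for d in (1,)] + \
            [("2017-01-31", 30), ("2017-03-02", 30), ("2017-04-01", 30),
             ("2017-05-01", 30), ("2017-05-31", 30)]
        assert eval_retention_6m("2017-01-01", events) is True

    def test_bad_supply_rejected(self):
        with pytest.raises(DataIntegrityError):
            eval_retention_6m("2017-01-01", [("2017-01-01", 0)])


class TestAggregate:
    def _flags(self, rows):
        return pd.DataFrame(rows, columns=["facility_id", "patient_id",
                                           "indicator", "failure"])

    def test_counting(self):
        flags = self._flags([("A", f"p{i}", 1, f)
                             for i, f in enumerate([True, True, False,
                                                    False, False])])
        agg, _ = aggregate(flags)
        row = agg[(agg["facility_id"] == "A") & (agg["indicator"] == 1)]
        assert row["failures"].iloc[0] == 2
        assert row["denominator"].iloc[0] == 5
        assert row["proportion"].iloc[0] == pytest.approx(0.4)

    def test_pooled_pi0(self):
        rows = [("A", f"a{i}", 1, i < 2) for i in range(5)] + \
               [("B", f"b{i}", 1, i < 1) for i in range(5)]
        _, pi0 = aggregate(self._flags(rows))
        assert pi0.loc[1] == pytest.approx(0.3)

    def test_empty_facility_has_zero_denominator(self):
        flags = self._flags([("A", "p1", 1, True)])
        roster = pd.DataFrame({"facility_id": ["A", "B"]})
        agg, pi0 = aggregate(flags, roster)
        row = agg[(agg["facility_id"] == "B") & (agg["indicator"] == 1)]
        assert row["denominator"].iloc[0] == 0
        assert np.isnan(row["proportion"].iloc[0])
        assert pi0.loc[1] == pytest.approx(1.0)  # pooled over A only


class TestEngineInvariants:
    def test_conservation(self, small_flags, small_aggregates):
        agg, _ = small_aggregates
        for k in range(1, 7):
            assert agg.loc[agg["indicator"] == k, "failures"].sum() == \
                small_flags[(small_flags["indicator"] == k)
                            & small_flags["failure"]].shape[0]
            assert agg.loc[agg["indicator"] == k, "denominator"].sum() == \
                (small_flags["indicator"] == k).sum()

    def test_retention_denominators_partition(self, small_flags,
                                              small_dataset):
        """Indicators 5 and 6 are disjoint and together cover exactly the
        new-ART patients with ascertainable 6-month outcomes (recomputed
        independently from the patients table)."""
        p5 = set(small_flags.loc[small_flags["indicator"] == 5, "patient_id"])
        p6 = set(small_flags.loc[small_flags["indicator"] == 6, "patient_id"])
        assert not p5 & p6
        patients = small_dataset["patients"]
        params = IndicatorParams()
        ws = np.datetime64(params.window_start)
        we = np.datetime64(params.window_end)
        start = pd.to_datetime(patients["art_start_date"].replace("", pd.NaT))
        horizon = params.retention_days + params.retention_ascertainment_days
        elig = (start.notna() & (start >= ws)
                & (start + pd.Timedelta(days=horizon) <= we))
        expected = set(patients.loc[elig, "patient_id"])
        # censored critical refills may be excluded; on generated data none are
        assert (p5 | p6) == expected
        routed6 = patients["patient_id"].isin(p6)
        assert (patients.loc[routed6, "pregnant_at_art_start"] == 1).all()

    def test_indicator3_counts_mms_events(self, small_flags, small_dataset):
        d = small_dataset["dispenses"]
        n_mms = int((d["multi_month"] == 1).sum())
        assert (small_flags["indicator"] == 3).sum() == n_mms

    def test_indicator4_counts_expected_refills(self, small_flags,
                                                small_dataset):
        d = small_dataset["dispenses"]
        params = IndicatorParams()
        we = np.datetime64(params.window_end)
        expected = (pd.to_datetime(d["pickup_date"])
                    + pd.to_timedelta(d["days_supplied"], unit="D"))
        ascertainable = (expected
                         + pd.Timedelta(days=params.refill_grace_days)) <= we
        assert (small_flags["indicator"] == 4).sum() == int(
            ascertainable.sum())


class TestVectorScalarAgreement:
    """The vectorized engine must agree with the scalar reference ops."""

    def test_indicator_1_2_and_retention(self, small_flags, small_dataset):
        patients = small_dataset["patients"]
        labs = small_dataset["labs"]
        dispenses = small_dataset["dispenses"]
        params = IndicatorParams()
        labs_by_pat = labs.groupby("patient_id")["test_date"].agg(list)
        disp_by_pat = {
            pid: list(zip(g["pickup_date"], g["days_supplied"]))
            for pid, g in dispenses.groupby("patient_id")}
        rng = np.random.default_rng(7)
        sample = patients.sample(n=250, random_state=1)
        flag_map = {
            (r["patient_id"], r["indicator"]): r["failure"]
            for _, r in small_flags.iterrows()}
        for _, row in sample.iterrows():
            pid = row["patient_id"]
            start = row["art_start_date"] or None
            # indicator 1
            key = (pid, 1)
            if key in flag_map:
                assert flag_map[key] == eval_test_and_start(
                    row["hiv_diagnosis_date"], start,
                    params.start_window_days), pid
            # indicator 2
            key = (pid, 2)
            if key in flag_map:
                got = eval_vl_up_to_date(
                    start, labs_by_pat.get(pid, []), params.window_end,
                    params.vl_eligibility_days, params.vl_recency_days)
                assert flag_map[key] == got, pid
            # retention
            for k in (5, 6):
                key = (pid, k)
                if key in flag_map:
                    got = eval_retention_6m(
                        start, disp_by_pat.get(pid, []),
                        params.refill_grace_days, params.retention_days)
                    assert flag_map[key] == got, pid

    def test_indicator_4_brute_force(self, small_flags, small_dataset):
        dispenses = small_dataset["dispenses"]
        params = IndicatorParams()
        we = np.datetime64(params.window_end).astype("int64")
        flags4 = small_flags[small_flags["indicator"] == 4]
        counts = flags4.groupby("patient_id")["failure"].agg(["sum", "count"])
        pids = list(counts.index[:150])
        for pid, g in dispenses[dispenses["patient_id"].isin(pids)] \
                .groupby("patient_id"):
            days = pd.to_datetime(g["pickup_date"]).astype("int64") \
                // 86_400_000_000_000
            days = days.to_numpy()
            sup = g["days_supplied"].to_numpy()
            fails = trials = 0
            for e in days + sup:
                if e + params.refill_grace_days <= we:
                    trials += 1
                    fails += not np.any(
                        (days >= e) & (days <= e + params.refill_grace_days))
            assert trials == counts.loc[pid, "count"], pid
            assert fails == counts.loc[pid, "sum"], pid


class TestDataIntegrity:
    def test_start_before_diagnosis_vectorized(self, small_dataset):
        patients = small_dataset["patients"].copy()
        patients.loc[patients.index[0], "hiv_diagnosis_date"] = "2030-01-01"
        patients.loc[patients.index[0], "art_start_date"] = "2017-01-01"
        with pytest.raises(DataIntegrityError, match="precedes"):
            compute_failure_flags(patients, small_dataset["dispenses"],
                                  small_dataset["labs"], IndicatorParams())

    def test_nonpositive_supply_rejected(self, small_dataset):
        d = small_dataset["dispenses"].copy()
        d.loc[d.index[0], "days_supplied"] = 0
        with pytest.raises(DataIntegrityError, match="days_supplied"):
            compute_failure_flags(small_dataset["patients"], d,
                                  small_dataset["labs"], IndicatorParams())
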