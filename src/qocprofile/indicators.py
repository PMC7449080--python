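"""Evaluation of the six quality-of-care indicators.

Every indicator is a *failure* proportion: 1 = care out of compliance /
patient not retained. Three process indicators (1-3) and three continuity
indicators (4-6):

1. ART not started within 30 days of HIV diagnosis (patients).
2. Not up to date with viral-load testing (patients on ART).
3. Multi-month script dispensed to a non-stable patient (MMS events).
4. ART refill not picked up within 30 days of the expected date
   (expected refills).
5. Not retained 6 months after starting ART - non-pregnant adults (patients).
6. Not retained 6 months after starting ART - women pregnant/post-partum at
   initiation (patients).

Scalar ``eval_*`` functions implement the per-unit rules on plain dates and
are the reference semantics; ``compute_failure_flags`` applies the same
rules vectorized over the full tables. Units whose outcome cannot be
ascertained within the observation window are excluded from denominators,
never counted as failures.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import INDICATORS, IndicatorParams
from .errors import DataIntegrityError

logger = logging.getLogger(__name__)

_DAY_KEY = 10 ** 6  # composite-key stride; all day offsets are < this


def _to_day(value) -> float:
    """Parse a date-like value to integer days since epoch (NaN if absent)."""
    if value is None or (isinstance(value, float) and np.isnan(value)) \
            or value == "":
        return np.nan
    return float(np.datetime64(str(value), "D").astype("int64"))


# ---------------------------------------------------------------------------
# scalar reference implementations
# ---------------------------------------------------------------------------

def eval_test_and_start(diagnosis_date, art_start_date=None,
                        window_days: int = 30) -> bool:
    """Indicator 1: failure iff ART was not started within ``window_days``
    of diagnosis (or never started)."""
    d = _to_day(diagnosis_date)
    if np.isnan(d):
        raise DataIntegrityError("diagnosis date is required")
    s = _to_day(art_start_date)
    if np.isnan(s):
        return True
    if s < d:
        raise DataIntegrityError("ART start date precedes HIV diagnosis date")
    return s - d > window_days


def eval_vl_up_to_date(art_start_date, test_dates: Iterable, as_of_date,
                       eligibility_lag_days: int = 180,
                       recency_window_days: int = 365):
    """Indicator 2: failure iff no viral-load test within the recency window
    ending at ``as_of_date``. Returns ``None`` when the patient has been on
    ART for less than the eligibility lag."""
    s = _to_day(art_start_date)
    asof = _to_day(as_of_date)
    if asof < s:
        raise DataIntegrityError("as-of date precedes ART start date")
    if asof - s < eligibility_lag_days:
        return None
    days = []
    for t in test_dates:
        td = _to_day(t)
        if td < s:
            logger.warning("ignoring viral-load test dated before ART start")
            continue
        days.append(td)
    return not any(asof - recency_window_days <= t <= asof for t in days)


def eval_mms_appropriate(multi_month: bool, stable: bool):
    """Indicator 3: failure iff a multi-month script went to a non-stable
    patient; ``None`` (not applicable) for single-month dispenses."""
    if not multi_month:
        return None
    return not stable


def eval_timely_pickup(expected_refill_date, next_pickup_date=None,
                       grace_days: int = 30) -> bool:
    """Indicator 4: failure iff no pickup within ``grace_days`` (inclusive)
    of the expected refill date."""
    e = _to_day(expected_refill_date)
    p = _to_day(next_pickup_date)
    if np.isnan(p):
        return True
    return not (e <= p <= e + grace_days)


def eval_retention_6m(art_start_date,
                      dispense_events: Sequence[tuple],
                      grace_days: int = 30,
                      retention_days: int = 182) -> bool:
    """Indicators 5/6: failure iff the expected refill nearest to ART start
    + ``retention_days`` has no pickup within its grace window.

    ``dispense_events`` is a sequence of ``(pickup_date, days_supplied)``
    sorted by pickup date; with no events at all the patient never returned
    and the outcome is a failure.
    """
    s = _to_day(art_start_date)
    if not len(dispense_events):
        return True
    pickups, expecteds = [], []
    for pickup, supplied in dispense_events:
        if supplied <= 0:
            raise DataIntegrityError("days supplied must be positive")
        p = _to_day(pickup)
        pickups.append(p)
        expecteds.append(p + supplied)
    target = s + retention_days
    dist = [abs(e - target) for e in expecteds]
    crit = expecteds[int(np.argmin(dist))]  # ties -> earliest
    return not any(crit <= p <= crit + grace_days for p in pickups)


# ---------------------------------------------------------------------------
# vectorized evaluation over full tables
# ---------------------------------------------------------------------------

def _day_col(frame: pd.DataFrame, col: str) -> np.ndarray:
    ts = pd.to_datetime(frame[col], format="%Y-%m-%d", errors="coerce")
    arr = ts.to_numpy("datetime64[D]")
    out = arr.astype("float64")
    out[np.isnat(arr)] = np.nan
    return out


def _check_dispenses(pid_codes: np.ndarray, days: np.ndarray,
                     supplied: np.ndarray) -> None:
    if np.any(supplied <= 0):
        raise DataIntegrityError("days_supplied must be positive")
    same = pid_codes[1:] == pid_codes[:-1]
    if np.any(same & (np.diff(days) <= 0)):
        raise DataIntegrityError(
            "pickup dates must be strictly increasing within patient")


def _has_pickup_within(pid_codes: np.ndarray, days: np.ndarray,
                       q_codes: np.ndarray, q_lo: np.ndarray,
                       grace: int) -> np.ndarray:
    """For each query (patient, window start), is there a pickup in
    [lo, lo+grace]? Arrays must be sorted by (patient, day)."""
    key = pid_codes.astype("int64") * _DAY_KEY + days.astype("int64")
    q = q_codes.astype("int64") * _DAY_KEY + q_lo.astype("int64")
    pos = np.searchsorted(key, q, side="left")
    ok = pos < len(key)
    found = np.zeros(len(q), dtype=bool)
    found[ok] = key[pos[ok]] <= q[ok] + grace
    return found


def compute_failure_flags(patients: pd.DataFrame, dispenses: pd.DataFrame,
                          labs: pd.DataFrame, params: IndicatorParams
                          ) -> pd.DataFrame:
    """Evaluate all six indicators and return one row per unit.

    Columns: ``facility_id, patient_id, indicator, failure``. The unit is a
    patient for indicators 1, 2, 5, 6, an MMS dispense for indicator 3 and
    an expected refill for indicator 4.
    """
    params.validate()
    ws = _to_day(params.window_start)
    we = _to_day(params.window_end)
    grace = params.refill_grace_days

    pid = patients["patient_id"].to_numpy()
    fac = patients["facility_id"].to_numpy()
    diag = _day_col(patients, "hiv_diagnosis_date")
    start = _day_col(patients, "art_start_date")
    if np.any(start - diag < 0):
        raise DataIntegrityError("ART start date precedes HIV diagnosis date")

    out = []

    # -- indicator 1 ------------------------------------------------------
    elig1 = (diag >= ws) & (diag + params.start_window_days <= we)
    f1 = np.where(np.isnan(start), True,
                  start - diag > params.start_window_days)
    out.append(pd.DataFrame({"facility_id": fac[elig1],
                             "patient_id": pid[elig1],
                             "indicator": 1, "failure": f1[elig1]}))

    # -- indicator 2 ------------------------------------------------------
    elig2 = ~np.isnan(start) & (we - start >= params.vl_eligibility_days)
    lab_pid = labs["patient_id"].to_numpy() if len(labs) else np.array([])
    if len(labs):
        test = _day_col(labs, "test_date")
        ldf = pd.DataFrame({"patient_id": lab_pid, "test_day": test})
        ldf = ldf.merge(
            pd.DataFrame({"patient_id": pid, "_start": start}),
            on="patient_id", how="left")
        before = ldf["test_day"] < ldf["_start"]
        if before.any():
            logger.warning("ignoring %d viral-load tests dated before ART "
                           "start", int(before.sum()))
            ldf = ldf[~before]
        recent = ldf[(ldf["test_day"] >= we - params.vl_recency_days)
                     & (ldf["test_day"] <= we)]
        has_recent = set(recent["patient_id"])
    else:
        has_recent = set()
    f2 = np.array([p not in has_recent for p in pid])
    out.append(pd.DataFrame({"facility_id": fac[elig2],
                             "patient_id": pid[elig2],
                             "indicator": 2, "failure": f2[elig2]}))

    # -- dispense-based indicators ---------------------------------------
    pat_index = pd.DataFrame({"patient_id": pid, "facility_id": fac,
                              "_start": start, "_preg":
                              patients["pregnant_at_art_start"].to_numpy()})
    if len(dispenses):
        d = dispenses.merge(pat_index, on="patient_id", how="left")
        codes, _ = pd.factorize(d["patient_id"], sort=True)
        day = _day_col(d, "pickup_date")
        supplied = d["days_supplied"].to_numpy()
        order = np.lexsort((day, codes))
        d = d.iloc[order].reset_index(drop=True)
        codes, day, supplied = codes[order], day[order], supplied[order]
        _check_dispenses(codes, day, supplied)
        mm = d["multi_month"].to_numpy().astype(bool)
        stable = d["stable"].to_numpy().astype(bool)

        # indicator 3: one unit per multi-month dispense in the window
        in_win = (day >= ws) & (day <= we)
        sel3 = mm & in_win
        out.append(pd.DataFrame({
            "facility_id": d.loc[sel3, "facility_id"].to_numpy(),
            "patient_id": d.loc[sel3, "patient_id"].to_numpy(),
            "indicator": 3, "failure": ~stable[sel3]}))

        # indicator 4: one unit per ascertainable expected refill
        expected = day + supplied
        trial = expected + grace <= we
        found = _has_pickup_within(codes, day, codes[trial],
                                   expected[trial], grace)
        out.append(pd.DataFrame({
            "facility_id": d.loc[trial, "facility_id"].to_numpy(),
            "patient_id": d.loc[trial, "patient_id"].to_numpy(),
            "indicator": 4, "failure": ~found}))
    else:
        codes = day = supplied = None
        d = None

    # -- indicators 5/6 ---------------------------------------------------
    horizon = params.retention_days + params.retention_ascertainment_days
    elig_ret = ~np.isnan(start) & (start >= ws) & (start + horizon <= we)
    ret = pd.DataFrame({
        "patient_id": pid[elig_ret],
        "facility_id": fac[elig_ret],
        "target": start[elig_ret] + params.retention_days,
        "indicator": np.where(
            patients["pregnant_at_art_start"].to_numpy()[elig_ret] == 1,
            6, 5),
    })
    if len(ret):
        if d is not None and len(d):
            sub = d.merge(ret[["patient_id", "target"]], on="patient_id",
                          how="inner")
            sub_codes, _ = pd.factorize(sub["patient_id"], sort=True)
            sub_day = _day_col(sub, "pickup_date")
            sub_exp = sub_day + sub["days_supplied"].to_numpy()
            dist = np.abs(sub_exp - sub["target"].to_numpy())
            sub = sub.assign(_exp=sub_exp, _dist=dist, _day=sub_day)
            crit = (sub.sort_values(["patient_id", "_dist", "_exp"])
                    .groupby("patient_id", as_index=False).first()
                    [["patient_id", "_exp"]])
            crit_codes = np.searchsorted(
                np.unique(sub["patient_id"]), crit["patient_id"].to_numpy())
            picked = _has_pickup_within(
                sub_codes, sub_day, crit_codes,
                crit["_exp"].to_numpy(), grace)
            crit = crit.assign(_picked=picked)
            ret = ret.merge(crit[["patient_id", "_exp", "_picked"]],
                            on="patient_id", how="left")
        else:
            ret = ret.assign(_exp=np.nan, _picked=False)
        no_events = ret["_exp"].isna()
        censored = ~no_events & (ret["_exp"] + grace > we)
        if censored.any():
            logger.info("excluding %d retention outcomes censored at window "
                        "end", int(censored.sum()))
        ret = ret[~censored]
        picked = ret["_picked"].to_numpy()
        picked = np.where(pd.isna(picked), False, picked).astype(bool)
        ret = ret.assign(failure=np.where(ret["_exp"].isna(), True, ~picked))
        out.append(ret[["facility_id", "patient_id", "indicator", "failure"]])

    flags = pd.concat(out, ignore_index=True)
    flags["failure"] = flags["failure"].astype(bool)
    flags["indicator"] = flags["indicator"].astype(int)
    return flags


def aggregate(flags: pd.DataFrame, roster: pd.DataFrame | None = None):
    """Aggregate unit flags to per-facility counts and pooled targets.

    Returns
    -------
    aggregates : DataFrame with columns ``facility_id, indicator, failures,
        denominator, proportion`` (one row per facility x indicator;
        facilities with no eligible unit carry denominator 0 and NaN
        proportion).
    pi0 : Series indexed by indicator - the pooled national failure
        proportion used as the funnel target.
    """
    grp = (flags.groupby(["facility_id", "indicator"])["failure"]
           .agg(failures="sum", denominator="count").reset_index())
    facilities = (roster["facility_id"] if roster is not None
                  else flags["facility_id"].drop_duplicates())
    full = pd.MultiIndex.from_product(
        [facilities, list(INDICATORS)], names=["facility_id", "indicator"])
    grp = (grp.set_index(["facility_id", "indicator"])
           .reindex(full, fill_value=0).reset_index())
    grp["failures"] = grp["failures"].astype(int)
    grp["denominator"] = grp["denominator"].astype(int)
    with np.errstate(invalid="ignore"):
        grp["proportion"] = np.where(
            grp["denominator"] > 0,
            grp["failures"] / grp["denominator"].replace(0, np.nan), np.nan)
    pooled = grp.groupby("indicator")[["failures", "denominator"]].sum()
    pi0 = pooled["failures"] / pooled["denominator"]
    pi0.name = "pi0"
    return grp, pi0
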