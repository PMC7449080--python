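"""Synthetic EMR generator with known ground truth.

Produces four patient-level tables (patients, dispense events, lab events,
facilities) plus a ground-truth table of true per-facility failure
probabilities, so that every downstream profiling stage can be validated
against planted facility effects, case-mix confounding and over-dispersion.

Construction guarantees
-----------------------
* Facility effects are additive on the logit scale (logit-normal mixing),
  so planted shifts compose linearly with case-mix effects.
* Dispense events form a renewal process (each pickup schedules an expected
  refill at pickup + days supplied); per-event lateness carries a
  patient-level random effect so the timely-pickup indicator exhibits
  intra-patient correlation.
* For retention-eligible patients the refill chain is forced around the
  6-month mark so that the engine-evaluated retention outcome equals the
  Bernoulli draw from the configured logistic model *exactly*.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .config import (DEFAULT_CASEMIX_EFFECTS, INDICATORS, SimulationConfig)
from .errors import ConfigError

_EPOCH = np.datetime64("1970-01-01", "D")


def _to_day(date_str: str) -> int:
    return int(np.datetime64(date_str, "D").astype("int64"))


def _day_to_iso(days: np.ndarray) -> np.ndarray:
    return (_EPOCH + days.astype("int64")).astype(str)


def _categorical(rng, probs: dict, size: int) -> np.ndarray:
    keys = np.array(list(probs.keys()))
    p = np.asarray(list(probs.values()), dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), size=size, p=p)]


def facility_effects(config: SimulationConfig, rng: np.random.Generator
                     ) -> np.ndarray:
    """(n_facilities, 6) matrix of logit-scale shifts: random effect + planted."""
    u = rng.normal(0.0, config.overdispersion_sd,
                   size=(config.n_facilities, 6))
    for po in config.planted_outliers:
        u[po.facility, po.indicator - 1] += po.shift
    return u


def generate_facilities(config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Generate the facility roster (id, department, category, travel time,
    slope, volume)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cov = config.merged_covariates()
    n = config.n_facilities
    lo, hi = config.volume_range
    volumes = rng.integers(lo, hi + 1, size=n)
    for f, v in config.volume_overrides.items():
        volumes[int(f)] = int(v)
    a_t = (1.0 - cov["travel_time_mean"]) / cov["travel_time_sd"]
    travel = truncnorm.rvs(a_t, np.inf, loc=cov["travel_time_mean"],
                           scale=cov["travel_time_sd"], size=n,
                           random_state=rng)
    a_s = (0.1 - cov["slope_mean"]) / cov["slope_sd"]
    slope = truncnorm.rvs(a_s, np.inf, loc=cov["slope_mean"],
                          scale=cov["slope_sd"], size=n, random_state=rng)
    return pd.DataFrame({
        "facility_id": [f"F{i + 1:03d}" for i in range(n)],
        "department": _categorical(rng, cov["department_probs"], n),
        "category": _categorical(rng, cov["category_probs"], n),
        "travel_time_minutes": np.round(travel, 1),
        "slope": np.round(slope, 2),
        "volume": volumes,
    })


def _casemix_linear_predictor(effects: dict, age, female, pregnant, bmi,
                              who, travel, slope) -> np.ndarray:
    """Linear predictor of the configured case-mix effects on standardized
    covariates (keys documented in :data:`DEFAULT_CASEMIX_EFFECTS`)."""
    lp = np.zeros(age.shape[0])
    get = effects.get
    if get("age_z"):
        lp += get("age_z") * (age - 36.7) / 13.3
    if get("female"):
        lp += get("female") * female
    if get("pregnant"):
        lp += get("pregnant") * pregnant
    if get("bmi_z"):
        lp += get("bmi_z") * (bmi - 22.1) / 4.1
    if get("who_stage"):
        lp += get("who_stage") * (who - 2.5)
    if get("travel_time_z"):
        lp += get("travel_time_z") * (travel - 67.6) / 67.3
    if get("slope_z"):
        lp += get("slope_z") * (slope - 3.2) / 2.2
    return lp


def generate_patients(roster: pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator | None = None):
    """Generate patient, dispense and lab tables plus ground truth.

    Returns
    -------
    patients, dispenses, labs, truth : pandas.DataFrame
    """
    config.validate()
    if roster.empty:
        raise ConfigError("roster must be nonempty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cov = config.merged_covariates()
    F = len(roster)
    volumes = roster["volume"].to_numpy()
    N = int(volumes.sum())
    fidx = np.repeat(np.arange(F), volumes)

    ws = _to_day(config.window_start)
    we = _to_day(config.window_end)
    if we - ws < 300:
        raise ConfigError("window_end must be at least 300 days after window_start")

    u = facility_effects(config, rng)
    eta0 = logit(np.asarray(config.baseline_rates))[None, :] + u  # (F, 6)

    # ---- covariates -----------------------------------------------------
    h = config.casemix_heterogeneity
    age_shift = rng.normal(0.0, 5.0 * h, size=F)
    who_tilt = rng.normal(0.0, h, size=F)

    mean_age = cov["age_mean"] + age_shift[fidx]
    a = (cov["age_min"] - mean_age) / cov["age_sd"]
    age = truncnorm.rvs(a, np.inf, loc=mean_age, scale=cov["age_sd"],
                        size=N, random_state=rng)
    gender = _categorical(rng, cov["gender_probs"], N)
    female = gender == "female"
    marital = _categorical(rng, cov["marital_probs"], N).astype(int)
    bmi = np.clip(rng.normal(cov["bmi_mean"], cov["bmi_sd"], N), 12.0, None)

    who_base = np.array([cov["who_probs"][k] for k in (1, 2, 3, 4)])
    tilt = np.exp(np.outer(who_tilt, np.array([1, 2, 3, 4]) - 2.5))
    who_p = who_base[None, :] * tilt
    who_p /= who_p.sum(axis=1, keepdims=True)
    cum = np.cumsum(who_p, axis=1)[fidx]
    who = (rng.random(N)[:, None] > cum).sum(axis=1) + 1

    pregnant = female & (rng.random(N) < cov["pregnant_frac"])
    travel = roster["travel_time_minutes"].to_numpy()[fidx]
    slope = roster["slope"].to_numpy()[fidx]

    x_cm = _casemix_linear_predictor(dict(config.casemix_effects),
                                     age, female.astype(float),
                                     pregnant.astype(float), bmi,
                                     who.astype(float), travel, slope)

    # ---- cohorts and ART initiation (indicator 1) -----------------------
    is_new = rng.random(N) < config.new_patient_frac
    diag = np.empty(N, dtype="int64")
    start = np.full(N, -1, dtype="int64")  # -1: never started

    n_new = int(is_new.sum())
    diag[is_new] = rng.integers(ws, we - 260 + 1, size=n_new)

    p1 = expit(eta0[fidx, 0])
    fail1 = np.zeros(N, dtype=bool)
    fail1[is_new] = rng.random(n_new) < p1[is_new]
    no_start = is_new & fail1 & (rng.random(N) < config.art_start_missing_frac)
    late_start = is_new & fail1 & ~no_start
    ok_start = is_new & ~fail1
    start[ok_start] = diag[ok_start] + rng.integers(0, 31, int(ok_start.sum()))
    start[late_start] = diag[late_start] + rng.integers(
        31, 201, int(late_start.sum()))

    est = ~is_new
    n_est = int(est.sum())
    year = _categorical(rng, cov["established_year_probs"], n_est).astype(int)
    ystart = np.array([_to_day(f"{y}-01-01") for y in range(2004, 2018)])
    lo_day = ystart[year - 2004]
    hi_day = np.minimum(ystart[year - 2004 + 1], ws - 30)
    start[est] = lo_day + (rng.random(n_est) * (hi_day - lo_day)).astype("int64")
    diag[est] = start[est] - rng.integers(0, 366, n_est)

    on_art = start >= 0
    year_art = np.where(
        on_art, (start.astype("datetime64[D]").astype("datetime64[Y]")
                 .astype(int) + 1970), 0)

    # ---- indicator 2: viral load testing --------------------------------
    elig2 = on_art & (we - start >= config.vl_eligibility_days)
    p2 = expit(eta0[fidx, 1])
    fail2 = elig2 & (rng.random(N) < p2)
    ok2 = elig2 & ~fail2
    test_day = np.full(N, -1, dtype="int64")
    lo2 = np.maximum(start, we - config.vl_recency_days)
    test_day[ok2] = lo2[ok2] + (rng.random(int(ok2.sum()))
                                * (we - lo2[ok2] + 1)).astype("int64")
    # half of the failures have an out-of-date test, when one fits pre-window
    old_ok = fail2 & (start <= we - config.vl_recency_days - 1) \
        & (rng.random(N) < 0.5)
    test_day[old_ok] = start[old_ok] + (
        rng.random(int(old_ok.sum()))
        * (we - config.vl_recency_days - start[old_ok])).astype("int64")

    # ---- retention targets (indicators 5 and 6) -------------------------
    # the refill nearest the 6-month mark can be scheduled up to ~150 days
    # after it, so the outcome is ascertainable only when start+362 <= we
    T = start + 182
    elig_ret = on_art & is_new & (T + 180 <= we)
    col56 = np.where(pregnant, 5, 4)  # 0-based column into eta0
    p56 = expit(eta0[fidx, col56] + x_cm)
    ret_fail = elig_ret & (rng.random(N) < p56)
    no_pickup = ret_fail & (rng.random(N) < config.no_pickup_frac)

    # ---- dispense chains (indicators 3 and 4) ---------------------------
    a_pat = rng.normal(0.0, config.patient_effect_sd, N)
    p4 = expit(eta0[fidx, 3] + x_cm + a_pat)
    p3 = expit(eta0[fidx, 2])

    cur = np.where(is_new, start,
                   ws + rng.integers(0, 30, N)).astype("int64")
    alive = on_art & ~no_pickup
    triggered = np.zeros(N, dtype=bool)
    ev_pid, ev_day, ev_supply, ev_mm, ev_stable = [], [], [], [], []
    max_it = (we - ws) // 30 + 4
    for _ in range(max_it):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        m = idx.size
        cur_a = cur[idx]
        mms_ok = (cur_a - start[idx]) >= 150
        mm = mms_ok & (rng.random(m) < config.mms_frac)
        supply = np.where(mm, 90, 30)
        fail3 = mm & (rng.random(m) < p3[idx])
        ev_pid.append(idx)
        ev_day.append(cur_a)
        ev_supply.append(supply)
        ev_mm.append(mm)
        ev_stable.append(~fail3)

        expected = cur_a + supply
        timely = rng.random(m) < (1.0 - p4[idx])
        er = elig_ret[idx]
        # retained patients: force timeliness through the critical window
        force_ok = er & ~ret_fail[idx] & (expected <= T[idx] + 150)
        fail_t = er & ret_fail[idx] & ~triggered[idx]
        pre = fail_t & (expected < T[idx] - 60)
        trig = fail_t & (expected >= T[idx] - 60)
        timely = (timely | force_ok | pre) & ~trig
        delay = np.where(timely, rng.integers(0, 31, m),
                         rng.integers(31, 121, m))
        # the critical refill is missed: drop out or return very late
        drop = trig & (rng.random(m) < config.dropout_frac)
        delay = np.where(trig, rng.integers(91, 161, m), delay)
        triggered[idx] |= trig
        nxt = expected + delay
        alive[idx] = (nxt <= we) & ~drop
        cur[idx] = nxt

    pid_arr = np.concatenate(ev_pid) if ev_pid else np.array([], dtype=int)
    order = np.lexsort((np.concatenate(ev_day) if ev_day else
                        np.array([], dtype=int), pid_arr))

    pids = np.array([f"P{i + 1:07d}" for i in range(N)])
    fac_ids = roster["facility_id"].to_numpy()

    if config.missing_rate > 0:
        bmi = np.where(rng.random(N) < config.missing_rate, np.nan, bmi)

    patients = pd.DataFrame({
        "patient_id": pids,
        "facility_id": fac_ids[fidx],
        "age_at_diagnosis": np.round(age, 1),
        "gender": gender,
        "marital_status": marital,
        "pregnant_at_art_start": pregnant.astype(int),
        "bmi": np.round(bmi, 1),
        "who_stage": who,
        "hiv_diagnosis_date": _day_to_iso(diag),
        "art_start_date": np.where(on_art, _day_to_iso(start), ""),
        "year_art_start": np.where(on_art, year_art, pd.NA),
    })

    dispenses = pd.DataFrame({
        "patient_id": pids[pid_arr[order]],
        "pickup_date": _day_to_iso(np.concatenate(ev_day)[order])
        if ev_day else np.array([], dtype=str),
        "days_supplied": np.concatenate(ev_supply)[order]
        if ev_supply else np.array([], dtype=int),
        "multi_month": np.concatenate(ev_mm)[order].astype(int)
        if ev_mm else np.array([], dtype=int),
        "stable": np.concatenate(ev_stable)[order].astype(int)
        if ev_stable else np.array([], dtype=int),
    })

    has_test = test_day >= 0
    labs = pd.DataFrame({
        "patient_id": pids[has_test],
        "test_date": _day_to_iso(test_day[has_test]),
    })

    truth = ground_truth(roster, config, eta0)
    return patients, dispenses, labs, truth


def ground_truth(roster: pd.DataFrame, config: SimulationConfig,
                 eta0: np.ndarray) -> pd.DataFrame:
    """True failure probabilities (at reference covariates) and outlier labels."""
    shift = np.zeros((config.n_facilities, 6))
    for po in config.planted_outliers:
        shift[po.facility, po.indicator - 1] += po.shift
    rows = []
    for f in range(len(roster)):
        for k in INDICATORS:
            s = shift[f, k - 1]
            label = ("low_performer" if s > 0
                     else "high_performer" if s < 0 else "none")
            rows.append((roster["facility_id"].iloc[f], k,
                         float(expit(eta0[f, k - 1])), label))
    return pd.DataFrame(
        rows, columns=["facility_id", "indicator", "true_prob", "label"])


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: roster + all patient-level tables from one seed."""
    rng = np.random.default_rng(config.seed)
    roster = generate_facilities(config, rng)
    patients, dispenses, labs, truth = generate_patients(roster, config, rng)
    return roster, patients, dispenses, labs, truth


def write_dataset(outdir, roster, patients, dispenses, labs, truth) -> None:
    """Write the five generator CSVs with fixed column order."""
    import os
    os.makedirs(outdir, exist_ok=True)
    roster.to_csv(os.path.join(outdir, "facilities.csv"), index=False)
    patients.to_csv(os.path.join(outdir, "patients.csv"), index=False)
    dispenses.to_csv(os.path.join(outdir, "dispenses.csv"), index=False)
    labs.to_csv(os.path.join(outdir, "labs.csv"), index=False)
    truth.to_csv(os.path.join(outdir, "ground_truth.csv"), index=False)
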