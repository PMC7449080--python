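"""Case-mix adjustment for the continuity-of-care indicators (4-6).

A national logistic regression (binomial GLM) links unit-level failure to
patient demographics, baseline clinical covariates and facility-level
context covariates; facility identity is deliberately *not* a predictor.
Indirect standardization then compares each facility's observed failure
proportion to the proportion expected from its own patients, on the logit
scale:

    y_i = logit(p_i) - logit(E_i),   s_i = 1 / sqrt(n_i * E_i * (1 - E_i))

with a continuity correction applied only when the observed count sits on
the boundary (0 or n failures). Positive ``y`` means *worse than expected*
throughout (failure scale).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit as _logit

from .config import CONTINUITY_INDICATORS
from .errors import EstimationError

logger = logging.getLogger(__name__)

NUMERIC_COVARIATES = ("age_at_diagnosis", "bmi", "travel_time_minutes",
                      "slope")
CATEGORICAL_COVARIATES = ("gender", "marital_status", "who_stage",
                          "year_art_start", "department", "category")


@dataclass
class CovariateEncoder:
    """Fixed design-matrix encoding (reference = first training level)."""

    numeric: tuple[str, ...] = NUMERIC_COVARIATES
    categorical: tuple[str, ...] = CATEGORICAL_COVARIATES
    levels: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    extra_binary: tuple[str, ...] = ()

    def fit(self, df: pd.DataFrame) -> "CovariateEncoder":
        for col in self.categorical:
            self.levels[col] = sorted(df[col].dropna().unique().tolist())
        for col in self.numeric:
            self.means[col] = float(pd.to_numeric(df[col]).mean())
        return self

    def column_names(self) -> list[str]:
        names = ["intercept"] + list(self.numeric) + list(self.extra_binary)
        for col in self.categorical:
            names += [f"{col}[{lv}]" for lv in self.levels[col][1:]]
        return names

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(df))]
        for col in self.numeric:
            x = pd.to_numeric(df[col]).to_numpy(dtype=float)
            x = np.where(np.isnan(x), self.means[col], x)  # mean-impute
            cols.append(x)
        for col in self.extra_binary:
            cols.append(pd.to_numeric(df[col]).to_numpy(dtype=float))
        for col in self.categorical:
            vals = df[col].to_numpy()
            known = set(self.levels[col])
            unseen = [v for v in pd.unique(vals)
                      if v not in known and not pd.isna(v)]
            if unseen:
                logger.warning("mapping unseen %s level(s) %s to reference",
                               col, unseen)
            for lv in self.levels[col][1:]:
                cols.append((vals == lv).astype(float))
        return np.column_stack(cols)


@dataclass
class CaseMixModel:
    """Fitted national case-mix model for one continuity indicator."""

    indicator: int
    encoder: CovariateEncoder
    params: pd.Series
    ridge_used: bool = False
    kept_columns: tuple[int, ...] | None = None  # after constant-column drop

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = self.encoder.transform(df)
        if self.kept_columns is not None:
            X = X[:, list(self.kept_columns)]
        eta = X @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def fit_casemix(units: pd.DataFrame, indicator: int,
                ridge_alpha: float = 1e-4) -> CaseMixModel:
    """Fit the national failure model for one indicator.

    ``units`` carries one row per patient with ``failures``/``trials``
    counts (trials = 1 for indicators 5 and 6; indicator 4 aggregates each
    patient's expected refills into a single weighted binomial observation)
    plus the covariate columns.
    """
    if indicator not in CONTINUITY_INDICATORS:
        raise ValueError(f"indicator must be one of {CONTINUITY_INDICATORS}")
    fails = units["failures"].to_numpy(dtype=float)
    trials = units["trials"].to_numpy(dtype=float)
    total_f, total_t = fails.sum(), trials.sum()
    if total_f == 0 or total_f == total_t:
        raise EstimationError(
            f"indicator {indicator}: all units share the same outcome")
    encoder = CovariateEncoder(
        extra_binary=("pregnant_at_art_start",) if indicator == 4 else ())
    encoder.fit(units)
    X_full = encoder.transform(units)
    names = np.array(encoder.column_names())
    # drop constant columns (beyond the intercept): they are collinear with
    # it and stall the IRLS iterations
    keep = np.r_[True, X_full[:, 1:].std(axis=0) > 0]
    X = X_full[:, keep]
    endog = np.column_stack([fails, trials - fails])
    ridge_used = False
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        params = np.asarray(res.params)
        if not res.converged or not np.all(np.isfinite(params)) \
                or np.abs(params).max() > 1e3:
            raise ValueError("non-finite or diverging coefficients")
    except Exception as exc:  # separation / convergence failure
        logger.warning("indicator %d: ML fit failed (%s); falling back to a "
                       "ridge penalty alpha=%g", indicator, exc, ridge_alpha)
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit_regularized(
            alpha=ridge_alpha, L1_wt=0.0)
        params = np.asarray(res.params)
        ridge_used = True
    return CaseMixModel(indicator=indicator, encoder=encoder,
                        params=pd.Series(params, index=names[keep]),
                        ridge_used=ridge_used,
                        kept_columns=tuple(np.flatnonzero(keep)))


def expected_facility_proportion(model: CaseMixModel, units: pd.DataFrame
                                 ) -> pd.DataFrame:
    """Indirectly standardized expectation per facility: the trial-weighted
    mean of unit-level predicted failure probabilities."""
    mu = model.predict(units)
    w = units["trials"].to_numpy(dtype=float)
    df = pd.DataFrame({"facility_id": units["facility_id"].to_numpy(),
                       "_num": mu * w, "_den": w})
    agg = df.groupby("facility_id", as_index=False).sum()
    agg["expected"] = agg["_num"] / agg["_den"]
    return agg[["facility_id", "expected"]]


def logit_contrast(failures, n, expected, c: float = 0.5):
    """Per-facility adjusted contrast ``y`` and its standard error ``s``.

    The continuity correction ``c`` is applied only when the observed count
    is 0 or n, keeping interior facilities unbiased while keeping ``y``
    finite at the boundary.
    """
    failures = np.asarray(failures, dtype=float)
    n = np.asarray(n, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1 (exclude empty facilities upstream)")
    if np.any((expected <= 0) | (expected >= 1)):
        raise ValueError("expected proportions must lie in (0, 1)")
    p = failures / n
    boundary = (failures == 0) | (failures == n)
    p_tilde = np.where(boundary, (failures + c) / (n + 2 * c), p)
    y = _logit(p_tilde) - _logit(expected)
    s = 1.0 / np.sqrt(n * expected * (1.0 - expected))
    return y, s


def _continuity_units(flags: pd.DataFrame, covariates: pd.DataFrame,
                      indicator: int) -> pd.DataFrame:
    sub = flags[flags["indicator"] == indicator]
    if indicator == 4:
        units = (sub.groupby(["facility_id", "patient_id"])["failure"]
                 .agg(failures="sum", trials="count").reset_index())
    else:
        units = sub[["facility_id", "patient_id"]].copy()
        units["failures"] = sub["failure"].to_numpy().astype(int)
        units["trials"] = 1
    return units.merge(covariates, on="patient_id", how="left")


def adjusted_contrasts(flags: pd.DataFrame, patients: pd.DataFrame,
                       roster: pd.DataFrame, ridge_alpha: float = 1e-4,
                       continuity_c: float = 0.5):
    """Fit the three case-mix models and derive per-facility contrasts.

    Returns
    -------
    contrasts : DataFrame with columns ``facility_id, indicator, failures,
        n, observed, expected, y, s``.
    models : dict mapping indicator -> :class:`CaseMixModel`.
    """
    covariates = patients.merge(
        roster[["facility_id", "department", "category",
                "travel_time_minutes", "slope"]],
        on="facility_id", how="left").drop(columns=["facility_id"])
    rows, models = [], {}
    for k in CONTINUITY_INDICATORS:
        units = _continuity_units(flags, covariates, k)
        if units.empty:
            logger.warning("indicator %d: no eligible units; skipped", k)
            continue
        model = fit_casemix(units, k, ridge_alpha=ridge_alpha)
        models[k] = model
        expected = expected_facility_proportion(model, units)
        fac = (units.groupby("facility_id", as_index=False)
               [["failures", "trials"]].sum()
               .merge(expected, on="facility_id"))
        y, s = logit_contrast(fac["failures"], fac["trials"],
                              fac["expected"], c=continuity_c)
        rows.append(pd.DataFrame({
            "facility_id": fac["facility_id"],
            "indicator": k,
            "failures": fac["failures"].astype(int),
            "n": fac["trials"].astype(int),
            "observed": fac["failures"] / fac["trials"],
            "expected": fac["expected"],
            "y": y,
            "s": s,
        }))
    contrasts = (pd.concat(rows, ignore_index=True) if rows
                 else pd.DataFrame(columns=["facility_id", "indicator",
                                            "failures", "n", "observed",
                                            "expected", "y", "s"]))
    return contrasts, models
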