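"""Facility-level hypothesis tests, over-dispersion and outlier flags.

Indicators 1-3 are tested against a binomial null with the pooled national
failure proportion as target; indicators 4-6 against a normal null on the
case-mix-adjusted logit contrasts. Over-dispersion is handled either
multiplicatively (standard errors inflated by sqrt(phi), with phi the
winsorized mean-square of the null z-scores, null-bias corrected and
floored at 1) or additively (between-facility variance tau2 estimated by
the method of moments). Flags use a Bonferroni-corrected threshold
alpha / I with strict inequality.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (CONTINUITY_INDICATORS, PROCESS_INDICATORS,
                     ProfilingParams)

__all__ = [
    "binom_pvalue", "normal_pvalue", "estimate_phi", "estimate_tau2",
    "flag_outliers", "profile_indicators", "PhiEstimate",
]


def binom_pvalue(x, n, pi0, side: str = "two_sided"):
    """Exact binomial tail probability including the observed point.

    ``upper`` is P(X >= x), ``lower`` is P(X <= x) under Bin(n, pi0);
    ``two_sided`` doubles the smaller tail, capped at 1.
    """
    x = np.asarray(x)
    n = np.asarray(n)
    if np.any((x < 0) | (x > n)):
        raise ValueError("x must lie in 0..n")
    if np.any((np.asarray(pi0) <= 0) | (np.asarray(pi0) >= 1)):
        raise ValueError("pi0 must lie in (0, 1)")
    upper = stats.binom.sf(x - 1, n, pi0)
    lower = stats.binom.cdf(x, n, pi0)
    if side == "upper":
        return upper
    if side == "lower":
        return lower
    if side == "two_sided":
        return np.minimum(1.0, 2.0 * np.minimum(upper, lower))
    raise ValueError(f"side must be upper/lower/two_sided, got {side!r}")


def normal_pvalue(y, s, phi: float = 1.0, tau2: float | None = None):
    """Two-sided normal p-value and z for an adjusted contrast.

    Multiplicative inflation uses ``z = y / (s * sqrt(phi))``; passing
    ``tau2`` switches to the additive model ``z = y / sqrt(s^2 + tau2)``.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("s must be positive")
    if tau2 is not None:
        z = y / np.sqrt(s ** 2 + tau2)
    else:
        z = y / (s * np.sqrt(phi))
    return z, 2.0 * stats.norm.sf(np.abs(z))


@dataclass(frozen=True)
class PhiEstimate:
    """Winsorized over-dispersion estimate and the inflate decision."""

    phi_raw: float   # null-bias-corrected winsorized mean square
    phi: float       # max(1, phi_raw)
    inflate: bool    # phi_raw beyond 1 + 2*sqrt(2/I)
    n: int

    @property
    def effective_phi(self) -> float:
        return self.phi if self.inflate else 1.0


def _winsor_null_factor(winsor: float) -> float:
    """E[clip(Z, -c, c)^2] for Z ~ N(0,1) with c the (1 - winsor) quantile;
    divides the winsorized mean square so the estimator is ~unbiased under
    the null (equals 1 when winsor = 0)."""
    if winsor <= 0:
        return 1.0
    c = stats.norm.ppf(1.0 - winsor)
    return float((1 - 2 * stats.norm.sf(c)) - 2 * c * stats.norm.pdf(c)
                 + 2 * c ** 2 * stats.norm.sf(c))


def estimate_phi(z, winsor: float = 0.1) -> PhiEstimate:
    """Over-dispersion factor from unadjusted facility z-scores.

    z-scores are winsorized at the ``winsor`` and ``1 - winsor`` empirical
    quantiles before taking the mean square, so a couple of extreme
    facilities cannot dominate the estimate.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 2:
        raise ValueError("need at least 2 facilities to estimate phi")
    if winsor > 0:
        lo, hi = np.quantile(z, [winsor, 1.0 - winsor])
        zw = np.clip(z, lo, hi)
    else:
        zw = z
    phi_raw = float(np.mean(zw ** 2)) / _winsor_null_factor(winsor)
    threshold = 1.0 + 2.0 * np.sqrt(2.0 / z.size)
    return PhiEstimate(phi_raw=phi_raw, phi=max(1.0, phi_raw),
                       inflate=phi_raw > threshold, n=z.size)


def estimate_tau2(y, s) -> float:
    """Method-of-moments between-facility variance (floored at 0)."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 facilities to estimate tau2")
    w = 1.0 / s ** 2
    ybar = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - ybar) ** 2)
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    return max(0.0, float((q - (y.size - 1)) / denom))


def flag_outliers(p_values, directions, alpha: float = 0.05,
                  I: int | None = None) -> np.ndarray:
    """Bonferroni-corrected flags: ``low_performer`` when significantly more
    failure than the null, ``high_performer`` when significantly less."""
    p = np.asarray(p_values, dtype=float)
    d = np.asarray(directions, dtype=float)
    if I is None:
        I = p.size
    thr = alpha / I
    flags = np.full(p.size, "none", dtype=object)
    sig = p < thr  # strict: boundary ties are not flagged
    flags[sig & (d > 0)] = "low_performer"
    flags[sig & (d < 0)] = "high_performer"
    return flags


def _profile_binomial(sub: pd.DataFrame, pi0: float,
                      params: ProfilingParams) -> pd.DataFrame:
    n = sub["denominator"].to_numpy(dtype=float)
    x = sub["failures"].to_numpy(dtype=float)
    p = x / n
    se0 = np.sqrt(pi0 * (1 - pi0) / n)
    z_raw = (p - pi0) / se0
    out = sub[["facility_id", "indicator"]].copy()
    if params.method == "additive":
        tau2 = estimate_tau2(p - pi0, se0)
        z, pv = normal_pvalue(p - pi0, se0, tau2=tau2)
        out["phi"] = np.nan
        out["phi_eff"] = np.nan
        out["tau2"] = tau2
    else:
        est = estimate_phi(z_raw, winsor=params.winsor_fraction)
        if est.inflate:
            z, pv = normal_pvalue(p - pi0, se0, phi=est.phi)
        else:
            # no inflation: keep the exact binomial tails
            z = z_raw
            pv = binom_pvalue(x.astype(int), n.astype(int), pi0,
                              side="two_sided")
        out["phi"] = est.phi
        out["phi_eff"] = est.effective_phi
        out["tau2"] = np.nan
    out["z"] = z
    out["p_value"] = pv
    out["p_exact"] = binom_pvalue(x.astype(int), n.astype(int), pi0,
                                  side="two_sided")
    out["direction"] = np.sign(p - pi0)
    return out


def _profile_normal(sub: pd.DataFrame, params: ProfilingParams
                    ) -> pd.DataFrame:
    y = sub["y"].to_numpy(dtype=float)
    s = sub["s"].to_numpy(dtype=float)
    out = sub[["facility_id", "indicator"]].copy()
    if params.method == "additive":
        tau2 = estimate_tau2(y, s)
        z, pv = normal_pvalue(y, s, tau2=tau2)
        out["phi"] = np.nan
        out["phi_eff"] = np.nan
        out["tau2"] = tau2
    else:
        est = estimate_phi(y / s, winsor=params.winsor_fraction)
        z, pv = normal_pvalue(y, s, phi=est.effective_phi)
        out["phi"] = est.phi
        out["phi_eff"] = est.effective_phi
        out["tau2"] = np.nan
    out["z"] = z
    out["p_value"] = pv
    out["p_exact"] = np.nan
    out["direction"] = np.sign(y)
    return out


def profile_indicators(aggregates: pd.DataFrame, pi0: pd.Series,
                       contrasts: pd.DataFrame,
                       params: ProfilingParams | None = None) -> pd.DataFrame:
    """Run the per-facility tests for all six indicators.

    Returns one row per facility x indicator actually tested, with columns
    ``facility_id, indicator, z, p_value, p_exact, phi, tau2, direction,
    flag, method, alpha, n_tested``.
    """
    params = params or ProfilingParams()
    params.validate()
    pieces = []
    for k in PROCESS_INDICATORS:
        sub = aggregates[(aggregates["indicator"] == k)
                         & (aggregates["denominator"] > 0)]
        if len(sub) >= 2:
            pieces.append(_profile_binomial(sub, float(pi0.loc[k]), params))
    for k in CONTINUITY_INDICATORS:
        sub = contrasts[contrasts["indicator"] == k]
        if len(sub) >= 2:
            pieces.append(_profile_normal(sub, params))
    if not pieces:
        raise ValueError("nothing to profile: no indicator has >= 2 facilities")
    prof = pd.concat(pieces, ignore_index=True)
    prof["method"] = params.method
    prof["alpha"] = params.alpha
    prof["n_tested"] = prof.groupby("indicator")["facility_id"] \
        .transform("count")
    prof["flag"] = "none"
    for k, sub in prof.groupby("indicator"):
        prof.loc[sub.index, "flag"] = flag_outliers(
            sub["p_value"], sub["direction"], alpha=params.alpha,
            I=len(sub))
    return prof
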