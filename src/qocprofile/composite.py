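"""Composite facility performance score.

The six indicator z-scores (positive = more failure, for all six) are
capped at +/- 3, combined as a relevance-weighted sum divided by
sqrt(w' R w) — the standard deviation of the weighted sum under the
empirical correlation R of the capped z-scores — and finally re-standardized
so the composite behaves as a regular z-score: mean 0, sd 1 across the
included facilities. Facilities with more than two missing indicators are
excluded; for the rest, the sum and the quadratic form are restricted to
the available indicators.

Classification: composite Z > threshold => low performer (poor care),
Z < -threshold => high performer, strict inequalities.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import INDICATORS, CompositeParams

logger = logging.getLogger(__name__)

__all__ = ["indicator_zscores", "cap_zscores", "correlation_matrix",
           "composite_scores", "classify", "build_composite"]


def indicator_zscores(profile: pd.DataFrame) -> pd.DataFrame:
    """Facility x indicator matrix of z-scores (columns z1..z6).

    Uses the profiling-stage z-scores, which already embed the
    over-dispersion treatment; facilities missing an indicator (zero
    denominator) carry NaN.
    """
    wide = profile.pivot(index="facility_id", columns="indicator",
                         values="z")
    wide = wide.reindex(columns=list(INDICATORS))
    wide.columns = [f"z{k}" for k in INDICATORS]
    return wide


def cap_zscores(z, bound: float = 3.0):
    """Cap z-scores to +/- bound (idempotent)."""
    if bound <= 0:
        raise ValueError("bound must be positive")
    return np.clip(z, -bound, bound)


def correlation_matrix(zcap: pd.DataFrame) -> np.ndarray:
    """Pairwise-complete correlation of capped z-scores, PSD-repaired.

    Non-PSD pairwise matrices are repaired by clipping negative eigenvalues
    at zero and re-scaling the diagonal back to 1.
    """
    R = zcap.corr(min_periods=2).to_numpy()
    R = np.where(np.isnan(R), 0.0, R)
    np.fill_diagonal(R, 1.0)
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < -1e-10:
        vals = np.clip(vals, 0.0, None)
        R = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R


def composite_scores(zcap: pd.DataFrame, weights, R: np.ndarray | None = None,
                     min_indicators: int = 4) -> pd.DataFrame:
    """Raw and standardized composite per facility.

    raw_i = sum_k w_k z*_ik / sqrt(w' R w), both restricted to the
    facility's available indicators; the final composite re-standardizes
    raw to mean 0 / sd 1 (ddof=1) across included facilities.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) != zcap.shape[1]:
        raise ValueError("weights length must match the z columns")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if R is None:
        R = correlation_matrix(zcap)
    Z = zcap.to_numpy(dtype=float)
    avail = ~np.isnan(Z)
    n_avail = avail.sum(axis=1)
    included = n_avail >= min_indicators
    if (~included).any():
        logger.info("excluding %d facilities with fewer than %d indicators",
                    int((~included).sum()), min_indicators)
    raw = np.full(len(zcap), np.nan)
    for i in np.flatnonzero(included):
        a = avail[i]
        wa = w[a]
        denom = float(np.sqrt(wa @ R[np.ix_(a, a)] @ wa))
        raw[i] = float(wa @ Z[i, a]) / denom
    out = pd.DataFrame(index=zcap.index)
    out["n_available"] = n_avail
    out["included"] = included
    out["raw_composite"] = raw
    inc = out["included"]
    vals = out.loc[inc, "raw_composite"]
    if inc.sum() < 2:
        raise ValueError("need at least 2 included facilities to standardize")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate composite: zero variance across facilities")
    out["composite"] = np.nan
    out.loc[inc, "composite"] = (vals - vals.mean()) / sd
    return out


def classify(composite, threshold: float = 2.0) -> np.ndarray:
    """Performance class from the standardized composite (strict bounds)."""
    c = np.asarray(composite, dtype=float)
    cls = np.full(c.shape, "typical", dtype=object)
    cls[c > threshold] = "low_performer"
    cls[c < -threshold] = "high_performer"
    cls[np.isnan(c)] = "excluded"
    return cls


def build_composite(profile: pd.DataFrame,
                    params: CompositeParams | None = None) -> pd.DataFrame:
    """Full composite stage: z matrix -> cap -> weight/correlate -> classify.

    Returns one row per facility: capped z1..z6, n_available, raw and final
    composite, and the performance class (``excluded`` when fewer than
    ``min_indicators`` indicators are available).
    """
    params = params or CompositeParams()
    params.validate()
    zmat = indicator_zscores(profile)
    zcap = pd.DataFrame(cap_zscores(zmat.to_numpy(), params.cap),
                        index=zmat.index, columns=zmat.columns)
    res = composite_scores(zcap, params.weights,
                           min_indicators=params.min_indicators)
    res["performance_class"] = classify(res["composite"], params.threshold)
    return pd.concat([zcap, res], axis=1).reset_index()
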