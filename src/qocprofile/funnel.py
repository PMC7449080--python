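"""Funnel-plot targets, control limits and facility placement.

For indicators 1-3 the performance axis is the raw failure proportion and
precision is the denominator; limits follow the normal approximation to the
binomial around the pooled target, optionally inflated by sqrt(phi) (which
keeps the curves consistent with the z-score construction used for
over-dispersion and the composite). For indicators 4-6 the axis is the
adjusted logit contrast y, precision is 1/s, and the target is 0.

Two limit levels are emitted per variant: the conventional 95% and the
Bonferroni-corrected level 1 - alpha/I. The ``plain`` variant always uses
phi = 1 / tau2 = 0; the ``overdispersed`` variant uses the estimates from
the profiling stage.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTINUITY_INDICATORS, PROCESS_INDICATORS

__all__ = ["binomial_limits", "normal_limits", "build_curves",
           "place_facilities"]


def _zstar(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    return float(stats.norm.ppf(0.5 + level / 2.0))


def binomial_limits(pi0: float, n_grid, level: float = 0.95,
                    phi: float = 1.0) -> pd.DataFrame:
    """Control limits for a proportion funnel, truncated to [0, 1]."""
    if not 0.0 < pi0 < 1.0:
        raise ValueError("pi0 must lie in (0, 1)")
    n = np.asarray(n_grid, dtype=float)
    if np.any(n < 1):
        raise ValueError("precision grid must be >= 1")
    half = _zstar(level) * np.sqrt(phi) * np.sqrt(pi0 * (1 - pi0) / n)
    return pd.DataFrame({
        "precision": n,
        "target": pi0,
        "lower": np.clip(pi0 - half, 0.0, 1.0),
        "upper": np.clip(pi0 + half, 0.0, 1.0),
        "level": level,
    })


def normal_limits(rho_grid, level: float = 0.95, phi: float = 1.0,
                  tau2: float | None = None) -> pd.DataFrame:
    """Control limits for an adjusted-contrast funnel (target 0).

    ``rho`` is the precision 1/s. With ``tau2`` the additive-model limits
    +/- z* sqrt(1/rho^2 + tau2) are returned (asymptoting at +/- z*·tau as
    precision grows) instead of the multiplicative +/- z* sqrt(phi)/rho.
    """
    rho = np.asarray(rho_grid, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("precision grid must be positive")
    if tau2 is not None:
        half = _zstar(level) * np.sqrt(1.0 / rho ** 2 + tau2)
    else:
        half = _zstar(level) * np.sqrt(phi) / rho
    return pd.DataFrame({
        "precision": rho,
        "target": 0.0,
        "lower": -half,
        "upper": half,
        "level": level,
    })


def build_curves(profile: pd.DataFrame, pi0: pd.Series,
                 aggregates: pd.DataFrame, contrasts: pd.DataFrame,
                 alpha: float = 0.05, n_points: int = 200) -> pd.DataFrame:
    """Plottable limit curves for every profiled indicator.

    Emits, per indicator, the plain and over-dispersed variants at both the
    conventional 95% level and the Bonferroni-corrected level 1 - alpha/I.
    """
    out = []
    for k, sub in profile.groupby("indicator"):
        I = int(sub["n_tested"].iloc[0])
        levels = {"conventional": 0.95, "bonferroni": 1.0 - alpha / I}
        phi = (float(sub["phi_eff"].iloc[0])
               if sub["phi_eff"].notna().any() else None)
        tau2 = (float(sub["tau2"].iloc[0])
                if sub["tau2"].notna().any() else None)
        if k in PROCESS_INDICATORS:
            n = aggregates.loc[(aggregates["indicator"] == k)
                               & (aggregates["denominator"] > 0),
                               "denominator"]
            grid = np.linspace(max(1.0, n.min() * 0.8), n.max() * 1.05,
                               n_points)
            for lname, level in levels.items():
                for variant in ("plain", "overdispersed"):
                    if variant == "plain":
                        cur = binomial_limits(pi0.loc[k], grid, level, 1.0)
                    elif tau2 is not None:
                        half = _zstar(level) * np.sqrt(
                            pi0.loc[k] * (1 - pi0.loc[k]) / grid + tau2)
                        cur = pd.DataFrame({
                            "precision": grid, "target": pi0.loc[k],
                            "lower": np.clip(pi0.loc[k] - half, 0, 1),
                            "upper": np.clip(pi0.loc[k] + half, 0, 1),
                            "level": level})
                    else:
                        cur = binomial_limits(pi0.loc[k], grid, level, phi)
                    cur["indicator"] = k
                    cur["variant"] = variant
                    cur["level_name"] = lname
                    out.append(cur)
        else:
            s = contrasts.loc[contrasts["indicator"] == k, "s"]
            rho = 1.0 / s
            grid = np.linspace(rho.min() * 0.8, rho.max() * 1.05, n_points)
            for lname, level in levels.items():
                for variant in ("plain", "overdispersed"):
                    if variant == "plain":
                        cur = normal_limits(grid, level, 1.0)
                    elif tau2 is not None:
                        cur = normal_limits(grid, level, tau2=tau2)
                    else:
                        cur = normal_limits(grid, level, phi)
                    cur["indicator"] = k
                    cur["variant"] = variant
                    cur["level_name"] = lname
                    out.append(cur)
    return pd.concat(out, ignore_index=True)


def _classify(value, target, half):
    return np.where(value > target + half, "high",
                    np.where(value < target - half, "low", "inside"))


def place_facilities(profile: pd.DataFrame, pi0: pd.Series,
                     aggregates: pd.DataFrame, contrasts: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Facility plot coordinates and in/out-of-funnel status per variant.

    Status columns hold ``inside``, ``low`` (below the lower limit, fewer
    failures than the null) or ``high`` (above the upper limit). The
    ``overdispersed`` status at the Bonferroni level reproduces, by
    construction, the inflation-matched normal test of the profiling stage.
    """
    rows = []
    for k, sub in profile.groupby("indicator"):
        I = int(sub["n_tested"].iloc[0])
        z_conv = _zstar(0.95)
        z_bonf = _zstar(1.0 - alpha / I)
        phi = (float(sub["phi_eff"].iloc[0])
               if sub["phi_eff"].notna().any() else None)
        tau2 = (float(sub["tau2"].iloc[0])
                if sub["tau2"].notna().any() else None)
        if k in PROCESS_INDICATORS:
            m = sub.merge(aggregates, on=["facility_id", "indicator"])
            value = m["proportion"].to_numpy(dtype=float)
            prec = m["denominator"].to_numpy(dtype=float)
            target = float(pi0.loc[k])
            s_eff = np.sqrt(target * (1 - target) / prec)
        else:
            m = sub.merge(contrasts, on=["facility_id", "indicator"])
            value = m["y"].to_numpy(dtype=float)
            s_eff = m["s"].to_numpy(dtype=float)
            prec = 1.0 / s_eff
            target = 0.0
        if tau2 is not None:
            s_od = np.sqrt(s_eff ** 2 + tau2)
        else:
            s_od = s_eff * np.sqrt(phi)
        res = pd.DataFrame({
            "facility_id": m["facility_id"],
            "indicator": k,
            "precision": prec,
            "value": value,
            "status_plain_95": _classify(value, target, z_conv * s_eff),
            "status_plain_bonf": _classify(value, target, z_bonf * s_eff),
            "status_od_95": _classify(value, target, z_conv * s_od),
            "status_od_bonf": _classify(value, target, z_bonf * s_od),
        })
        rows.append(res)
    return pd.concat(rows, ignore_index=True)


def render_funnels(curves: pd.DataFrame, placed: pd.DataFrame, outdir,
                   pi0: pd.Series | None = None) -> list:
    """Optional rendering: one figure per indicator (points, target, two
    funnels per variant at the Bonferroni level). Returns written paths."""
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .config import INDICATOR_NAMES
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for k, pts in placed.groupby("indicator"):
        fig, ax = plt.subplots(figsize=(7, 4.5))
        sub = curves[(curves["indicator"] == k)
                     & (curves["level_name"] == "bonferroni")]
        for variant, style in (("plain", "-"), ("overdispersed", "--")):
            cv = sub[sub["variant"] == variant].sort_values("precision")
            ax.plot(cv["precision"], cv["lower"], style, color="grey", lw=1)
            ax.plot(cv["precision"], cv["upper"], style, color="grey", lw=1)
        ax.axhline(sub["target"].iloc[0], color="black", lw=1)
        flagged = pts["status_od_bonf"] != "inside"
        ax.plot(pts.loc[~flagged, "precision"], pts.loc[~flagged, "value"],
                "o", ms=3, color="tab:blue")
        ax.plot(pts.loc[flagged, "precision"], pts.loc[flagged, "value"],
                "v", ms=5, color="tab:red")
        ax.set_xlabel("precision")
        ax.set_ylabel("failure proportion" if k <= 3 else "logit contrast y")
        ax.set_title(f"Indicator {k}: {INDICATOR_NAMES[k]}")
        path = os.path.join(outdir, f"funnel_indicator_{k}.png")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
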