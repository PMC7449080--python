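"""Configuration objects for simulation and the profiling pipeline.

All defaults that correspond to a printed constant in the study design
(significance level, z-score cap, classification threshold, relevance
weights, observation window) are set to those values here and are
overridable from a YAML config file or keyword arguments.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError

INDICATORS = (1, 2, 3, 4, 5, 6)
#: indicators evaluated as raw facility proportions against a binomial null
PROCESS_INDICATORS = (1, 2, 3)
#: indicators evaluated as case-mix-adjusted logit contrasts against a normal null
CONTINUITY_INDICATORS = (4, 5, 6)

INDICATOR_NAMES = {
    1: "ART initiation within 30 days of diagnosis",
    2: "viral load testing up to date",
    3: "appropriate multi-month scripting",
    4: "timely ART pick-up",
    5: "6-month retention (non-pregnant adults)",
    6: "6-month retention (pregnant/post-partum women)",
}

DEPARTMENTS = (
    "Ouest", "Nord", "Sud", "Artibonite", "Nord Ouest",
    "Nippes", "Sud Est", "Nord Est", "Grand Anse",
)
FACILITY_CATEGORIES = (
    "Univ Hosp", "Dep Hosp", "Other Hosp", "HCR", "CAL", "CSL/disp",
)

#: Covariate distribution targets for the generator; every entry is
#: overridable through ``SimulationConfig.covariates``.
DEFAULT_COVARIATES: dict = {
    "age_mean": 36.7,
    "age_sd": 13.3,
    "age_min": 15.0,
    "gender_probs": {"female": 0.635, "male": 0.364, "missing": 0.001},
    "marital_probs": {0: 0.503, 1: 0.130, 2: 0.182, 3: 0.185},
    "bmi_mean": 22.1,
    "bmi_sd": 4.1,
    "who_probs": {1: 0.281, 2: 0.217, 3: 0.225, 4: 0.277},
    "pregnant_frac": 0.46,  # among women, at ART initiation
    "travel_time_mean": 67.6,
    "travel_time_sd": 67.3,
    "slope_mean": 3.2,
    "slope_sd": 2.2,
    "department_probs": {
        "Ouest": 0.416, "Nord": 0.192, "Sud": 0.093, "Artibonite": 0.090,
        "Nord Ouest": 0.064, "Nippes": 0.040, "Sud Est": 0.031,
        "Nord Est": 0.044, "Grand Anse": 0.030,
    },
    "category_probs": {
        "Univ Hosp": 0.076, "Dep Hosp": 0.418, "Other Hosp": 0.010,
        "HCR": 0.200, "CAL": 0.281, "CSL/disp": 0.015,
    },
    # year-of-start distribution for patients already on ART at window open
    "established_year_probs": {
        2004: 0.001, 2005: 0.005, 2006: 0.013, 2007: 0.022, 2008: 0.036,
        2009: 0.038, 2010: 0.036, 2011: 0.057, 2012: 0.086, 2013: 0.107,
        2014: 0.129, 2015: 0.126, 2016: 0.344,
    },
}

#: Default coefficients linking (standardized) covariates to the logit of
#: failure for the continuity indicators (4-6). Keys are interpreted by
#: :func:`qocprofile.simulate._casemix_linear_predictor`.
DEFAULT_CASEMIX_EFFECTS: dict = {
    "age_z": 0.15,        # (age - 36.7) / 13.3
    "female": -0.10,
    "pregnant": 0.10,
    "bmi_z": -0.10,       # (bmi - 22.1) / 4.1
    "who_stage": 0.20,    # stage - 2.5
    "travel_time_z": 0.25,  # (travel - 67.6) / 67.3
    "slope_z": 0.05,      # (slope - 3.2) / 2.2
}


@dataclass(frozen=True)
class PlantedOutlier:
    """A deliberate shift of one facility on one indicator (logit scale)."""

    facility: int       # 0-based facility index
    indicator: int      # 1..6
    shift: float        # >0 pushes failure up (low performer)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic EMR generator."""

    n_facilities: int = 90
    volume_range: tuple[int, int] = (150, 1300)
    baseline_rates: tuple[float, ...] = (0.25, 0.55, 0.15, 0.25, 0.20, 0.25)
    overdispersion_sd: float = 0.4
    patient_effect_sd: float = 0.3
    casemix_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CASEMIX_EFFECTS))
    casemix_heterogeneity: float = 0.3
    planted_outliers: tuple[PlantedOutlier, ...] = ()
    new_patient_frac: float = 0.45
    mms_frac: float = 0.30
    dropout_frac: float = 0.6     # retention failures who never return
    no_pickup_frac: float = 0.1   # retention failures with no dispense at all
    art_start_missing_frac: float = 0.3  # indicator-1 failures never starting
    window_start: str = "2016-06-01"
    window_end: str = "2018-03-31"
    vl_eligibility_days: int = 180
    vl_recency_days: int = 365
    missing_rate: float = 0.0     # MAR missingness applied to BMI
    covariates: Mapping = field(default_factory=dict)
    volume_overrides: Mapping[int, int] = field(default_factory=dict)
    seed: int = 0

    def merged_covariates(self) -> dict:
        merged = dict(DEFAULT_COVARIATES)
        merged.update(self.covariates)
        return merged

    def validate(self) -> None:
        if self.n_facilities < 1:
            raise ConfigError("n_facilities must be >= 1")
        lo, hi = self.volume_range
        if lo < 1 or hi < lo:
            raise ConfigError("volume_range must satisfy 1 <= min <= max")
        if len(self.baseline_rates) != 6:
            raise ConfigError("baseline_rates must have 6 entries")
        for k, r in zip(INDICATORS, self.baseline_rates):
            if not 0.0 < r < 1.0:
                raise ConfigError(
                    f"baseline_rates[{k}] must lie in (0, 1), got {r}")
        if self.overdispersion_sd < 0:
            raise ConfigError("overdispersion_sd must be >= 0")
        if self.patient_effect_sd < 0:
            raise ConfigError("patient_effect_sd must be >= 0")
        for po in self.planted_outliers:
            if not 0 <= po.facility < self.n_facilities:
                raise ConfigError(
                    f"planted_outliers facility index {po.facility} out of range")
            if po.indicator not in INDICATORS:
                raise ConfigError(
                    f"planted_outliers indicator {po.indicator} not in 1..6")
        for frac_name in ("new_patient_frac", "mms_frac", "dropout_frac",
                          "no_pickup_frac", "art_start_missing_frac",
                          "missing_rate"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{frac_name} must lie in [0, 1], got {v}")
        for f in self.volume_overrides:
            if not 0 <= int(f) < self.n_facilities:
                raise ConfigError(
                    f"volume_overrides facility index {f} out of range")


@dataclass
class IndicatorParams:
    """Evaluation windows and grace periods for the six indicators."""

    window_start: str = "2016-06-01"
    window_end: str = "2018-03-31"
    start_window_days: int = 30      # "within 1 month" of diagnosis
    vl_eligibility_days: int = 180   # time on ART before VL testing applies
    vl_recency_days: int = 365       # a test within this window counts
    refill_grace_days: int = 30
    retention_days: int = 182        # 6 months after ART start
    #: extra follow-up (beyond retention_days) required for the 6-month
    #: outcome to be ascertainable: the critical refill may be scheduled up
    #: to ~150 days after the 6-month mark, plus its grace window
    retention_ascertainment_days: int = 180

    def validate(self) -> None:
        for name in ("start_window_days", "vl_eligibility_days",
                     "vl_recency_days", "refill_grace_days", "retention_days"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class ProfilingParams:
    alpha: float = 0.05
    method: str = "multiplicative"   # or "additive"
    winsor_fraction: float = 0.1
    ridge_alpha: float = 1e-4        # fallback penalty on separation

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.method not in ("multiplicative", "additive"):
            raise ConfigError(
                f"method must be 'multiplicative' or 'additive', got {self.method!r}")
        if not 0.0 <= self.winsor_fraction < 0.5:
            raise ConfigError("winsor_fraction must lie in [0, 0.5)")


@dataclass
class CompositeParams:
    weights: tuple[float, ...] = (1.5, 1.5, 1.5, 0.5, 0.5, 1.0)
    cap: float = 3.0
    threshold: float = 2.0
    min_indicators: int = 4

    def validate(self) -> None:
        if len(self.weights) != 6:
            raise ConfigError("weights must have 6 entries")
        if any(w <= 0 for w in self.weights):
            raise ConfigError("weights must be positive")
        if self.cap <= 0:
            raise ConfigError("cap must be positive")
        if self.threshold <= 0:
            raise ConfigError("threshold must be positive")
        if not 1 <= self.min_indicators <= 6:
            raise ConfigError("min_indicators must lie in 1..6")


@dataclass
class PipelineConfig:
    """Top-level configuration tying all stages together."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    indicators: IndicatorParams = field(default_factory=IndicatorParams)
    profiling: ProfilingParams = field(default_factory=ProfilingParams)
    composite: CompositeParams = field(default_factory=CompositeParams)
    input_dir: str | None = None   # read CSVs instead of simulating
    seed: int | None = None        # overrides simulate.seed when set

    def validate(self) -> None:
        self.simulate.validate()
        self.indicators.validate()
        self.profiling.validate()
        self.composite.validate()

    def resolved(self) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        if cfg.seed is not None:
            cfg.simulate = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        # keep simulation and evaluation windows aligned
        cfg.indicators = dataclasses.replace(
            cfg.indicators,
            window_start=cfg.simulate.window_start,
            window_end=cfg.simulate.window_end,
            vl_eligibility_days=cfg.simulate.vl_eligibility_days,
            vl_recency_days=cfg.simulate.vl_recency_days,
        )
        return cfg


def _build(cls, data: Mapping, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown config key {path}{key}")
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: Mapping) -> PipelineConfig:
    """Construct a validated :class:`PipelineConfig` from nested mappings."""
    data = dict(data or {})
    sim = dict(data.pop("simulate", {}))
    planted = [
        po if isinstance(po, PlantedOutlier) else PlantedOutlier(**po)
        for po in sim.pop("planted_outliers", [])
    ]
    if "volume_range" in sim:
        sim["volume_range"] = tuple(sim["volume_range"])
    if "baseline_rates" in sim:
        sim["baseline_rates"] = tuple(sim["baseline_rates"])
    if "volume_overrides" in sim:
        sim["volume_overrides"] = {
            int(k): int(v) for k, v in dict(sim["volume_overrides"]).items()}
    sim_cfg = _build(SimulationConfig, sim, "simulate.")
    sim_cfg = dataclasses.replace(sim_cfg, planted_outliers=tuple(planted))

    comp = dict(data.pop("composite", {}))
    if "weights" in comp:
        comp["weights"] = tuple(comp["weights"])
    cfg = PipelineConfig(
        simulate=sim_cfg,
        indicators=_build(IndicatorParams, data.pop("indicators", {}),
                          "indicators."),
        profiling=_build(ProfilingParams, data.pop("profiling", {}),
                         "profiling."),
        composite=_build(CompositeParams, comp, "composite."),
        input_dir=data.pop("input_dir", None),
        seed=data.pop("seed", None),
    )
    if data:
        raise ConfigError(f"unknown config key {sorted(data)[0]}")
    cfg.validate()
    return cfg


def load_config(path: str) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError("config file must contain a mapping at top level")
    return config_from_dict(data)


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Round-trippable plain-dict form of a config (for manifests/YAML)."""
    out = dataclasses.asdict(cfg)
    out["simulate"]["planted_outliers"] = [
        dataclasses.asdict(po) for po in cfg.simulate.planted_outliers]
    out["simulate"]["volume_range"] = list(cfg.simulate.volume_range)
    out["simulate"]["baseline_rates"] = list(cfg.simulate.baseline_rates)
    out["composite"]["weights"] = list(cfg.composite.weights)
    return out
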