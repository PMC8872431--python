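"""Synthetic administrative cohort generator.

Emulates a visit-level all-payor extract for a single disease cohort: one
row per in-patient visit with a binary outcome-resource indicator, seven
correlated competing-resource indicators, demographic/payor/comorbidity
covariates, length of stay, and a facility identifier.  The outcome truly
follows a logistic law in the configured coefficients, competing resources
are generated by thresholding a latent Gaussian vector (so their pairwise
tetrachoric correlations equal the configured latent correlations), and
facility volumes follow a right-skewed log-normal law.  Selected
facilities can be planted as utilization outliers by multiplying (or
dividing) their visits' outcome odds, leaving case mix untouched — the
ground truth that downstream outlier-recovery tests check against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for configs)
from scipy.stats import norm

from .schema import RESOURCES, CohortSchema, default_vocabularies


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass(frozen=True)
class PlantedOutlier:
    """A facility whose visits' outcome odds are shifted by a known factor.

    ``mode="over"`` multiplies the odds (excess utilization);
    ``mode="under"`` divides them (deficit).  ``odds_multiplier`` must
    exceed 1 so the direction is unambiguous.
    """

    facility_id: str
    mode: str  # {"over", "under"}
    odds_multiplier: float

    def __post_init__(self) -> None:
        if self.mode not in ("over", "under"):
            raise ConfigurationError(f"outlier mode must be over/under, got {self.mode!r}")
        if not self.odds_multiplier > 1:
            raise ConfigurationError("odds_multiplier must be > 1")

    @property
    def log_odds_shift(self) -> float:
        shift = float(np.log(self.odds_multiplier))
        return shift if self.mode == "over" else -shift


@dataclass
class SyntheticConfig:
    """Generator truth for a synthetic cohort.

    Coefficient keys follow the design-column convention: ``"var=level"``
    for a categorical level, the bare column name for a binary flag or
    competing resource, and the column name for continuous terms.
    """

    n_facilities: int = 1056
    total_visits_target: int = 51111
    volume_log_mean: float = 3.2
    volume_log_sd: float = 1.0
    true_intercept: float = -3.88
    true_coefficients: dict[str, float] | None = None
    resource_prevalences: dict[str, float] | None = None
    resource_dependence: np.ndarray | None = None
    covariate_marginals: dict[str, dict[str, float]] | None = None
    flag_prevalences: dict[str, float] | None = None
    los_mean: float = 4.57
    los_sd: float = 5.44
    outlier_plan: list[PlantedOutlier] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resource_prevalences is None:
            self.resource_prevalences = dict(DEFAULT_RESOURCE_PREVALENCES)
        if self.resource_dependence is None:
            self.resource_dependence = default_resource_dependence()
        self.resource_dependence = np.asarray(self.resource_dependence, dtype=float)
        if self.covariate_marginals is None:
            self.covariate_marginals = {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
        if self.flag_prevalences is None:
            self.flag_prevalences = dict(DEFAULT_FLAG_PREVALENCES)
        if self.true_coefficients is None:
            self.true_coefficients = dict(DEFAULT_COEFFICIENTS)
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.n_facilities < 2:
            raise ConfigurationError("n_facilities must be >= 2")
        if not self.volume_log_sd > 0:
            raise ConfigurationError("volume_log_sd must be > 0")
        R = self.resource_dependence
        k = len(RESOURCES)
        if R.shape != (k, k):
            raise ConfigurationError(f"resource_dependence must be {k}x{k}")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ConfigurationError("resource_dependence must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ConfigurationError("resource_dependence must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ConfigurationError("resource_dependence must be positive semidefinite")
        for r in RESOURCES:
            p = self.resource_prevalences.get(r)
            if p is None or not 0 < p < 1:
                raise ConfigurationError(f"resource prevalence for {r} must be in (0,1)")
        for var, marg in self.covariate_marginals.items():
            probs = np.array(list(marg.values()), dtype=float)
            if np.any(probs <= 0) or np.any(probs >= 1):
                raise ConfigurationError(f"marginal probabilities for {var} must be in (0,1)")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"marginal for {var} must sum to 1 (got {probs.sum()})")
        for flag, p in self.flag_prevalences.items():
            if not 0 < p < 1:
                raise ConfigurationError(f"flag prevalence for {flag} must be in (0,1)")

    # -- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["resource_dependence"] = self.resource_dependence.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "outlier_plan" in d:
            d["outlier_plan"] = [
                o if isinstance(o, PlantedOutlier) else PlantedOutlier(**o)
                for o in d["outlier_plan"]
            ]
        if d.get("resource_dependence") is not None:
            d["resource_dependence"] = np.asarray(d["resource_dependence"], dtype=float)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "seed" not in d:
            raise ConfigurationError("synthetic config requires an explicit seed")
        return cls.from_dict(d)


# Marginals follow the descriptive profile of a 2019 U.S. prostate-cancer
# in-patient cohort (~51k visits): dominant Medicare Traditional payor,
# ~72% of patients over 65, ~72% White, X-rays the most common competing
# modality.
DEFAULT_RESOURCE_PREVALENCES = {
    "ct_other": 0.3645,
    "miscellaneous": 0.0165,
    "mri_mra": 0.1009,
    "nuclear_medicine": 0.0553,
    "special_imaging": 0.0662,
    "ultrasound": 0.1270,
    "xray": 0.5668,
}

DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "age_group": {
        "<=45": 0.0033, "46-50": 0.0117, "51-55": 0.0387, "56-60": 0.0862,
        "61-65": 0.1365, "66-70": 0.1611, "71-75": 0.1598, "76-80": 0.1429,
        "81-85": 0.1204, ">85": 0.1394,
    },
    "race": {
        "american_indian": 0.0040, "asian": 0.0182, "black": 0.1677,
        "pacific_islander": 0.0039, "unknown": 0.0203, "white": 0.7210,
        "other": 0.0649,
    },
    "payor": {
        "charity": 0.0013, "indigent": 0.0001, "commercial_indemnity": 0.0529,
        "direct_employer": 0.0019, "managed_care_capitated": 0.0033,
        "managed_care_noncapitated": 0.1609, "medicaid_mc_capitated": 0.0052,
        "medicaid_mc_noncapitated": 0.0237, "medicaid_traditional": 0.0140,
        "medicare_mc_capitated": 0.0660, "medicare_mc_noncapitated": 0.1881,
        "medicare_traditional": 0.4319, "other_government": 0.0244,
        "self_pay": 0.0086, "workers_comp": 0.0012, "other": 0.0165,
    },
    "discharge_status": {
        "home": 0.5777, "home_health": 0.1513, "snf": 0.1267, "expired": 0.0327,
        "hospice_home": 0.0277, "rehab_facility": 0.0249, "hospice_facility": 0.0215,
        "other_facility": 0.0139, "ltch": 0.0046, "ama": 0.0047, "icf": 0.0036,
        "swing_bed": 0.0024, "court_law": 0.0013, "other": 0.0070,
    },
}

DEFAULT_FLAG_PREVALENCES = {
    "icd_principal": 0.2899,
    "malignancy_history": 0.0543,
    "cm_congestive_heart_failure": 0.1940,
    "cm_fluid_electrolyte": 0.3345,
    "cm_hypertension_uncomplicated": 0.4269,
    "cm_metastatic_cancer": 0.2985,
    "cm_renal_failure": 0.2410,
}

# Moderate positive co-use among imaging modalities; the latent (tetrachoric)
# correlation of every pair is 0.25 under the copula.
DEFAULT_RESOURCE_RHO = 0.25


def default_resource_dependence() -> np.ndarray:
    k = len(RESOURCES)
    R = np.full((k, k), DEFAULT_RESOURCE_RHO)
    np.fill_diagonal(R, 1.0)
    return R


# Outcome log-odds: competing resources carry most of the signal, with
# additional case-mix effects; the intercept is calibrated so the marginal
# outcome prevalence sits near 11.7%.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "ct_other": 0.9, "xray": 0.5, "ultrasound": 0.3, "mri_mra": 0.3,
    "nuclear_medicine": 0.4, "special_imaging": 0.3, "miscellaneous": 0.2,
    "icd_principal": 0.6, "malignancy_history": 0.2,
    "cm_metastatic_cancer": 0.7, "cm_fluid_electrolyte": 0.3,
    "cm_renal_failure": 0.2, "cm_congestive_heart_failure": -0.1,
    "race=black": -0.25, "race=other": -0.1,
    "age_group=46-50": 0.10, "age_group=51-55": 0.15, "age_group=56-60": 0.20,
    "age_group=61-65": 0.25, "age_group=66-70": 0.30, "age_group=71-75": 0.30,
    "age_group=76-80": 0.25, "age_group=81-85": 0.20, "age_group=>85": 0.10,
    "payor=medicare_mc_noncapitated": 0.10,
    "payor=managed_care_noncapitated": 0.15,
    "payor=commercial_indemnity": 0.20,
    "los_days": 0.03,
}


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def generate_facility_volumes(config: SyntheticConfig) -> pd.DataFrame:
    """Draw right-skewed facility volumes summing (almost) to the target.

    Log-normal weights are converted to integer volumes by proportional
    allocation with largest-remainder rounding, then clamped to >= 1, so
    the total matches ``total_visits_target`` to within ``n_facilities``
    and the degenerate limit log-sd -> 0 yields equal volumes up to
    rounding.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_facilities
    weights = rng.lognormal(mean=config.volume_log_mean, sigma=config.volume_log_sd, size=n)
    probs = weights / weights.sum()
    raw = probs * config.total_visits_target
    volumes = np.floor(raw).astype(int)
    remainder = config.total_visits_target - volumes.sum()
    if remainder > 0:
        frac = raw - np.floor(raw)
        top = np.argsort(-frac, kind="stable")[:remainder]
        volumes[top] += 1
    volumes = np.maximum(volumes, 1)
    ids = [f"F{i:04d}" for i in range(n)]
    return pd.DataFrame({"facility_id": ids, "volume": volumes})


def _latent_transform(R: np.ndarray) -> np.ndarray:
    """Matrix L with LL' = R, tolerant of semidefinite R."""
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)


def true_linear_predictor(cohort: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    """Outcome log-odds from the generator truth, excluding outlier shifts."""
    eta = np.full(len(cohort), config.true_intercept, dtype=float)
    for key, beta in config.true_coefficients.items():
        if "=" in key:
            var, level = key.split("=", 1)
            eta += beta * (cohort[var].to_numpy() == level)
        else:
            eta += beta * cohort[key].to_numpy(dtype=float)
    return eta


def generate_visits(config: SyntheticConfig, volumes: pd.DataFrame) -> pd.DataFrame:
    """Generate the visit-level cohort for the given facility volumes.

    Covariates are drawn i.i.d. from the configured marginals, competing
    resources by thresholding a correlated latent Gaussian at quantiles
    matching their prevalences, and the outcome from a Bernoulli with
    logistic probability, with planted facilities' odds shifted by their
    multiplier.
    """
    config.validate()
    if {"facility_id", "volume"} - set(volumes.columns):
        raise ValueError("volumes table must have facility_id and volume columns")
    if len(volumes) != config.n_facilities:
        raise ValueError(
            f"volumes has {len(volumes)} facilities, config expects {config.n_facilities}"
        )
    rng = _rng(config, 1)
    n = int(volumes["volume"].sum())
    facility = np.repeat(volumes["facility_id"].to_numpy(), volumes["volume"].to_numpy())

    cohort = pd.DataFrame({
        "visit_id": [f"V{i:07d}" for i in range(n)],
        "patient_id": [f"P{i:07d}" for i in range(n)],
        "facility_id": facility,
    })
    # discharge dates spread over the study year
    day = rng.integers(0, 365, size=n)
    cohort["discharge_date"] = pd.to_datetime("2019-01-01") + pd.to_timedelta(day, unit="D")
    cohort["discharge_date"] = cohort["discharge_date"].dt.strftime("%Y-%m-%d")

    for var, marg in config.covariate_marginals.items():
        levels = list(marg)
        probs = np.array([marg[l] for l in levels], dtype=float)
        probs = probs / probs.sum()
        cohort[var] = rng.choice(levels, size=n, p=probs)

    for flag, p in config.flag_prevalences.items():
        cohort[flag] = (rng.random(n) < p).astype(int)

    # Gaussian-copula competing resources
    L = _latent_transform(config.resource_dependence)
    Z = rng.standard_normal((n, len(RESOURCES))) @ L.T
    for j, r in enumerate(RESOURCES):
        tau = norm.ppf(1.0 - config.resource_prevalences[r])
        cohort[r] = (Z[:, j] > tau).astype(int)

    # length of stay: gamma matched to the configured mean/sd
    shape = (config.los_mean / config.los_sd) ** 2
    scale = config.los_sd ** 2 / config.los_mean
    cohort["los_days"] = np.round(rng.gamma(shape, scale, size=n), 2)

    eta = true_linear_predictor(cohort, config)
    shift = pd.Series(0.0, index=volumes["facility_id"])
    for out in config.outlier_plan:
        if out.facility_id not in shift.index:
            raise ConfigurationError(f"planted outlier {out.facility_id} not in volumes")
        shift[out.facility_id] = out.log_odds_shift
    eta = eta + shift.loc[cohort["facility_id"]].to_numpy()
    cohort["outcome_used"] = (rng.random(n) < expit(eta)).astype(int)

    schema = CohortSchema()
    ordered = [c for c in schema.columns if c in cohort.columns]
    ordered += [c for c in cohort.columns if c not in ordered]
    return cohort[ordered]


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: volumes + visits in one call."""
    volumes = generate_facility_volumes(config)
    return generate_visits(config, volumes), volumes


def ground_truth_labels(
    cohort: pd.DataFrame, config: SyntheticConfig, threshold: float
) -> np.ndarray:
    """True expected-use flag: generator probability (without any planted
    outlier shift) at or above the threshold.  Deterministic."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    p = expit(true_linear_predictor(cohort, config))
    return (p >= threshold).astype(int)


# ----------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------

def write_cohort(
    cohort: pd.DataFrame, config: SyntheticConfig, path: str | Path
) -> Path:
    """Write the cohort CSV plus a JSON truth sidecar (config echo and
    per-facility odds multipliers)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    truth = {
        "config": config.to_dict(),
        "facility_log_odds_shift": {
            o.facility_id: o.log_odds_shift for o in config.outlier_plan
        },
    }
    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2, default=str))
    return path
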