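"""Synthetic PASSI-like survey populations with known ground truth.

Generates respondent records shaped like the Italian behavioural-risk-factor
surveillance of adults aged 18-69: five self-reported chronic conditions
(diabetes, kidney failure, respiratory disease, heart disease, tumor),
perceived health on a 1-5 ordinal scale, socio-demographic covariates, region
(19 NUTS-2 units), survey year 2008-2019 and four behavioural risk factors.

The generative mechanism mirrors the measurement model used downstream: a
latent multimorbidity trait ``z`` is standard normal marginally; covariates,
survey year and region shift its conditional mean, after which the sample is
re-standardised so the marginal stays N(0, 1) — the identification the
two-parameter latent-trait estimator assumes. Each disease indicator is then
Bernoulli with logit ``beta0_i + beta1_i * z``, and perceived health follows
a proportional-odds model in ``z``.

Defaults reproduce the published survey composition (53.18% female, 60.17%
high education, 52.77% economic difficulties) and the published item
parameters of the five conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .disability_index import DISEASES, DisabilityWeightSet

__all__ = [
    "LatentEffects",
    "PerceivedHealthModel",
    "BehaviorModel",
    "PopulationConfig",
    "DEFAULT_ITEM_PARAMS",
    "DEFAULT_WEIGHT_CATALOGUE",
    "TRUTH_COLUMNS",
    "generate_population",
    "generate_weight_catalogue",
    "write_population",
    "config_to_yaml",
    "config_from_yaml",
]

#: Published point estimates of the five-item 2PL measurement model
#: (intercept beta0 on the logit scale, positive slope beta1).
DEFAULT_ITEM_PARAMS: dict[str, tuple[float, float]] = {
    "diabetes": (-3.571, 1.340),
    "kidney": (-6.082, 2.077),
    "respiratory": (-2.880, 0.974),
    "heart": (-3.924, 1.647),
    "tumor": (-3.198, 0.840),
}

BEHAVIORS = ("smoking", "alcohol", "poor_diet", "inactivity")

#: Columns that are ground truth of the generator, never visible to estimators.
TRUTH_COLUMNS = ("z_true", "region_effect_true")


@dataclass(frozen=True)
class LatentEffects:
    """Covariate shifts of the latent-trait conditional mean (pre-standardisation).

    Continuous covariates are scaled so each coefficient is interpretable:
    ``age_per_decade`` applies to (age - 43.5)/10, ``per_year`` to
    (year - first year). The marginal of the trait is re-standardised after
    the shift, so these act as relative orderings, not absolute SD units.
    """

    female: float = -0.03
    age_per_decade: float = 0.35
    high_education: float = -0.12
    econ_difficulties: float = 0.12
    per_year: float = -0.015
    male_age_per_decade: float = 0.05


@dataclass(frozen=True)
class PerceivedHealthModel:
    """Proportional-odds link from the latent trait to the 1-5 health rating.

    P(H <= h | z) = expit(cutpoint_h - slope * z); higher z (sicker) pushes
    ratings toward 5 (very bad). Cutpoint defaults give marginal shares of
    roughly 27/50/18/4/1 percent for ratings 1..5.
    """

    cutpoints: tuple[float, float, float, float] = (-1.0, 1.2, 2.8, 4.2)
    slope: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("perceived-health cutpoints must be strictly increasing")


@dataclass(frozen=True)
class BehaviorModel:
    """Per-behavior Bernoulli logits with mild regional and secular gradients.

    logit P = intercept + region_slope * (region - (K+1)/2) / K
            + year_slope * (year - first year).
    Intercept defaults target realistic adult prevalences (smoking ~30%,
    risky alcohol ~17%, poor diet ~50%, physical inactivity ~35%).
    """

    intercepts: tuple[float, float, float, float] = (-0.85, -1.60, 0.0, -0.60)
    region_slopes: tuple[float, float, float, float] = (0.6, -0.6, 0.3, 0.8)
    year_slopes: tuple[float, float, float, float] = (-0.02, -0.01, -0.005, 0.0)


@dataclass(frozen=True)
class PopulationConfig:
    """Full description of a synthetic survey population."""

    n_respondents: int = 10_000
    n_regions: int = 19
    years: tuple[int, int] = (2008, 2019)
    share_female: float = 0.5318
    share_high_education: float = 0.6017
    share_econ_difficulties: float = 0.5277
    latent_effects: LatentEffects = field(default_factory=LatentEffects)
    item_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_PARAMS)
    )
    region_effect_sd: float = 0.10
    behavior_model: BehaviorModel = field(default_factory=BehaviorModel)
    perceived_health_model: PerceivedHealthModel = field(
        default_factory=PerceivedHealthModel
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be positive")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.years[1] < self.years[0]:
            raise ValueError("year range is empty")
        for name in ("share_female", "share_high_education", "share_econ_difficulties"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.region_effect_sd < 0:
            raise ValueError("region_effect_sd must be nonnegative")
        if set(self.item_params) != set(DISEASES):
            raise ValueError(f"item_params must cover exactly {DISEASES}")


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw a respondent table under ``config``; deterministic given the seed.

    Returns one row per respondent with the survey columns plus the
    ground-truth columns listed in :data:`TRUTH_COLUMNS`; use
    :func:`write_population` to persist survey data and truth separately.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    y0, y1 = config.years

    region = rng.integers(1, config.n_regions + 1, size=n)
    year = rng.integers(y0, y1 + 1, size=n)
    age = rng.integers(18, 70, size=n)
    female = rng.random(n) < config.share_female
    high_edu = rng.random(n) < config.share_high_education
    econ_diff = rng.random(n) < config.share_econ_difficulties

    eff = config.latent_effects
    age_c = (age - 43.5) / 10.0
    shift = (
        eff.female * female
        + eff.age_per_decade * age_c
        + eff.high_education * high_edu
        + eff.econ_difficulties * econ_diff
        + eff.per_year * (year - y0)
        + eff.male_age_per_decade * age_c * (~female)
    )
    region_effects = rng.normal(0.0, config.region_effect_sd, size=config.n_regions)
    shift = shift + region_effects[region - 1]

    z = rng.standard_normal(n) + shift
    # re-standardise so the marginal matches the estimator's N(0,1) prior
    z = (z - z.mean()) / z.std()

    data = {
        "id": np.arange(n),
        "region": region,
        "year": year,
        "age": age,
        "sex": np.where(female, "female", "male"),
        "education": np.where(high_edu, "high", "low"),
        "economic": np.where(econ_diff, "difficulties", "none"),
    }

    for disease in DISEASES:
        b0, b1 = config.item_params[disease]
        data[disease] = (rng.random(n) < _expit(b0 + b1 * z)).astype(np.int8)

    ph = config.perceived_health_model
    cum = _expit(np.subtract.outer(np.asarray(ph.cutpoints), ph.slope * z))  # (4, n)
    u = rng.random(n)
    data["perceived_health"] = (1 + (u[None, :] > cum).sum(axis=0)).astype(np.int8)

    bm = config.behavior_model
    region_scaled = (region - (config.n_regions + 1) / 2.0) / config.n_regions
    for b, behavior in enumerate(BEHAVIORS):
        logit = (
            bm.intercepts[b]
            + bm.region_slopes[b] * region_scaled
            + bm.year_slopes[b] * (year - y0)
        )
        data[behavior] = (rng.random(n) < _expit(logit)).astype(np.int8)

    data["z_true"] = z
    data["region_effect_true"] = region_effects[region - 1]
    return pd.DataFrame(data)


def generate_weight_catalogue(seed: int | None = None) -> DisabilityWeightSet:
    """Return a disability-weight catalogue: the fixed packaged default, or
    a random one for simulation studies when ``seed`` is given.

    The default is a synthetic stand-in for a GBD-derived catalogue — severity
    orderings and magnitudes are plausible for the five conditions but are
    not the GBD health-state values.
    """
    if seed is None:
        return DEFAULT_WEIGHT_CATALOGUE
    rng = np.random.default_rng(seed)
    weights = {}
    for disease in DISEASES:
        k = int(rng.integers(3, 7))
        cand = np.sort(rng.beta(1.5, 5.0, size=k))
        cand = np.clip(cand, 1e-4, 1 - 1e-4)
        # enforce strict ascent after clipping
        cand = np.maximum.accumulate(cand + np.arange(k) * 1e-6)
        weights[disease] = tuple(float(w) for w in cand)
    return DisabilityWeightSet(weights=weights, version=f"random-{seed}")


#: Fixed packaged catalogue (synthetic stand-in for a GBD-matched set),
#: 4-5 ascending severity levels per condition.
DEFAULT_WEIGHT_CATALOGUE = DisabilityWeightSet(
    weights={
        "diabetes": (0.049, 0.133, 0.184, 0.280),
        "kidney": (0.104, 0.250, 0.431, 0.571),
        "respiratory": (0.019, 0.112, 0.225, 0.408),
        "heart": (0.033, 0.080, 0.167, 0.179, 0.250),
        "tumor": (0.049, 0.200, 0.288, 0.451, 0.540),
    },
    version="synthetic-catalogue-1",
)


def write_population(
    population: pd.DataFrame, path: str, truth_path: str | None = None
) -> None:
    """Write the survey CSV; ground-truth columns go to a sidecar file.

    ``truth_path`` defaults to ``<path stem>.truth.csv``. Keeping truth out
    of the main file prevents accidental leakage into estimation stages.
    """
    truth_cols = [c for c in TRUTH_COLUMNS if c in population.columns]
    population.drop(columns=truth_cols).to_csv(path, index=False)
    if truth_cols:
        if truth_path is None:
            stem = path[:-4] if path.endswith(".csv") else path
            truth_path = f"{stem}.truth.csv"
        population[["id", *truth_cols]].to_csv(truth_path, index=False)


def _asdict(config: PopulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["item_params"] = {k: list(v) for k, v in d["item_params"].items()}
    return d


def config_to_yaml(config: PopulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_asdict(config), fh, sort_keys=False)


def config_from_yaml(path: str) -> PopulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key, cls in (
        ("latent_effects", LatentEffects),
        ("behavior_model", BehaviorModel),
        ("perceived_health_model", PerceivedHealthModel),
    ):
        if key in raw and isinstance(raw[key], dict):
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in raw[key].items()
            }
            raw[key] = cls(**sub)
    if "item_params" in raw:
        raw["item_params"] = {k: tuple(v) for k, v in raw["item_params"].items()}
    if "years" in raw:
        raw["years"] = tuple(raw["years"])
    return PopulationConfig(**raw)
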