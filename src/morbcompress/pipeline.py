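"""End-to-end morbidity-compression analysis.

Chains the stages: synthetic population (or respondent CSV) → composite
disability weights → weighted 2PL latent-trait fit → EAP scores rescaled to
[0, 1] → full-population ordered beta regression with a regional random
intercept → per-risk-class refits without random effects → population-level
prediction grids and regional BLUPs. The compression question is read off
the survey-year coefficient of the conditional model: a negative year effect
means the multimorbidity burden at fixed age and socio-economic profile is
falling over time.

Risk classes stratify respondents by the cumulative count (0-4) of four
behavioural risk factors (smoking, alcohol, poor diet, physical inactivity);
refitting the regression inside each class checks whether compression
persists once behaviour is held fixed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .disability_index import DISEASES, compute_composite_weights
from .latent_trait import LatentFit, fit_weighted_2pl, rescale_unit
from .ordered_beta import (
    ModelSpec,
    OrderedBetaFit,
    blup,
    coefficient_table,
    fit_ordered_beta,
    predict_population,
)
from .synthetic_data import (
    BEHAVIORS,
    PopulationConfig,
    generate_population,
    generate_weight_catalogue,
    write_population,
)

logger = logging.getLogger("morbcompress")

__all__ = [
    "PipelineConfig",
    "CompressionReport",
    "risk_class",
    "risk_classes",
    "run_pipeline",
    "conditional_behavior_frequencies",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    respondents_csv: str | None = None  # load instead of simulate when given
    catalogue_seed: int | None = None  # None -> fixed packaged catalogue
    variant: str = "hurdle"
    grid_ages: tuple[int, ...] = (20, 30, 40, 50, 60, 69)
    grid_years: tuple[int, ...] | None = None  # None -> every survey year
    out_dir: str | None = None


@dataclass
class CompressionReport:
    """All pipeline outputs plus enough metadata to re-run bit-identically."""

    item_params: pd.DataFrame
    latent_fit: LatentFit
    population_fit: OrderedBetaFit
    class_fits: dict[int, OrderedBetaFit]
    year_effects: pd.DataFrame
    predictions: pd.DataFrame
    blup_table: pd.DataFrame
    behavior_frequencies: pd.DataFrame
    scores: pd.DataFrame
    metadata: dict

    def report_hash(self) -> str:
        """SHA-256 over the numeric content of every reported table."""
        h = hashlib.sha256()
        for frame in (
            self.item_params,
            self.year_effects,
            self.predictions,
            self.blup_table,
            self.behavior_frequencies,
            self.scores,
        ):
            h.update(frame.to_csv(index=False, float_format="%.12g").encode())
        return h.hexdigest()


def risk_class(behaviors) -> int:
    """Cumulative count of present risk behaviours (0 = optimal, 4 = worst)."""
    arr = np.asarray(behaviors)
    if arr.shape != (4,):
        raise ValueError("expected exactly 4 behaviour flags")
    if np.any(pd.isna(arr)):
        raise ValueError("missing behaviour flag")
    arr = arr.astype(float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("behaviour flags must be binary")
    return int(arr.sum())


def risk_classes(data: pd.DataFrame) -> pd.Series:
    """Vectorised risk class for a respondent table."""
    sub = data[list(BEHAVIORS)]
    if sub.isna().any().any():
        raise ValueError("missing behaviour flag")
    arr = sub.to_numpy(float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("behaviour flags must be binary")
    return pd.Series(arr.sum(axis=1).astype(int), index=data.index, name="risk_class")


def conditional_behavior_frequencies(data: pd.DataFrame) -> pd.DataFrame:
    """Risk-class shares per (year, region), plus national per-year averages.

    Within each (year, region) cell the five class frequencies sum to 1;
    empty cells simply do not appear (logged at debug level).
    """
    df = data.copy()
    df["risk_class"] = risk_classes(df)
    rows = []
    for (year, region), group in df.groupby(["year", "region"]):
        counts = group["risk_class"].value_counts()
        for cls in range(5):
            rows.append(
                {
                    "year": int(year),
                    "region": str(region),
                    "risk_class": cls,
                    "frequency": float(counts.get(cls, 0)) / len(group),
                }
            )
    n_cells = df.groupby(["year", "region"]).ngroups
    possible = df["year"].nunique() * df["region"].nunique()
    if n_cells < possible:
        logger.debug("omitted %d empty (year, region) cells", possible - n_cells)
    for year, group in df.groupby("year"):
        counts = group["risk_class"].value_counts()
        for cls in range(5):
            rows.append(
                {
                    "year": int(year),
                    "region": "national",
                    "risk_class": cls,
                    "frequency": float(counts.get(cls, 0)) / len(group),
                }
            )
    return pd.DataFrame(rows)


def _item_param_table(latent_fit: LatentFit) -> pd.DataFrame:
    """Item parameters in the published layout (disease, -beta0, beta1)."""
    p = latent_fit.params
    return pd.DataFrame(
        {
            "disease": list(p.items),
            "neg_beta0": -p.beta0,
            "beta1": p.beta1,
            "se_beta0": latent_fit.se_beta0,
            "se_beta1": latent_fit.se_beta1,
        }
    )


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> CompressionReport:
    """Execute the full compression analysis; deterministic under fixed seed."""
    t_all = time.perf_counter()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "simulate/load"
    try:
        t = _stage(stage)
        if config.respondents_csv is not None:
            population = pd.read_csv(config.respondents_csv)
        else:
            population = generate_population(config.population)
        if out_dir and config.respondents_csv is None:
            write_population(population, str(out_dir / "population.csv"))
        logger.info("stage %s done in %.2fs (n=%d)", stage, time.perf_counter() - t, len(population))

        stage = "disability weights"
        t = _stage(stage)
        catalogue = generate_weight_catalogue(config.catalogue_seed)
        weights = compute_composite_weights(population, catalogue)
        if out_dir:
            weights.table.to_csv(out_dir / "weights.csv", index=False)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t)

        stage = "latent trait fit"
        t = _stage(stage)
        X = population[list(DISEASES)].to_numpy()
        latent_fit = fit_weighted_2pl(X, weights.w)
        item_params = _item_param_table(latent_fit)
        scores = pd.DataFrame(
            {
                "id": population["id"],
                "z": latent_fit.z,
                "y": rescale_unit(latent_fit.z),
            }
        )
        if out_dir:
            item_params.to_csv(out_dir / "item_params.csv", index=False)
            scores.to_csv(out_dir / "scores.csv", index=False)
        logger.info("stage %s done in %.2fs (loglik=%.2f)", stage, time.perf_counter() - t, latent_fit.loglik)

        stage = "ordered beta (full population)"
        t = _stage(stage)
        reg_data = population[
            ["region", "year", "age", "sex", "education", "economic"]
        ].copy()
        reg_data["y"] = scores["y"].to_numpy()
        spec_full = ModelSpec(variant=config.variant, random_effect="region")
        full_fit = fit_ordered_beta(reg_data, spec_full, components="auto")
        if out_dir:
            coefficient_table(full_fit).to_csv(out_dir / "population_fit.csv", index=False)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t)

        stage = "risk-class refits"
        t = _stage(stage)
        classes = risk_classes(population)
        spec_cls = ModelSpec(variant=config.variant, random_effect="none")
        class_fits: dict[int, OrderedBetaFit] = {}
        year_rows = [
            {
                "stratum": "full population",
                "estimate": float(full_fit.coef["Year"]),
                "se": float(full_fit.se["Year"]),
            }
        ]
        for cls in range(5):
            sub = reg_data[classes.to_numpy() == cls]
            if len(sub) == 0:
                logger.warning("risk class %d empty; refit skipped", cls)
                continue
            fit_c = fit_ordered_beta(sub, spec_cls, components="auto")
            class_fits[cls] = fit_c
            year_rows.append(
                {
                    "stratum": f"risk class {cls}",
                    "estimate": float(fit_c.coef["Year"]),
                    "se": float(fit_c.se["Year"]),
                }
            )
        year_effects = pd.DataFrame(year_rows)
        year_effects["t"] = year_effects["estimate"] / year_effects["se"]
        if out_dir:
            year_effects.to_csv(out_dir / "year_effects.csv", index=False)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t)

        stage = "predictions and BLUPs"
        t = _stage(stage)
        years = (
            config.grid_years
            if config.grid_years is not None
            else tuple(range(int(population["year"].min()), int(population["year"].max()) + 1))
        )
        grid = pd.DataFrame(
            [
                {"sex": s, "age": a, "education": e, "economic": c, "year": yr}
                for s in ("female", "male")
                for a in config.grid_ages
                for e in ("high", "low")
                for c in ("difficulties", "none")
                for yr in years
            ]
        )
        predictions = predict_population(full_fit, grid).table
        blup_table = blup(full_fit)
        freqs = conditional_behavior_frequencies(population)
        if out_dir:
            predictions.to_csv(out_dir / "predictions.csv", index=False)
            blup_table.to_csv(out_dir / "blup.csv", index=False)
            freqs.to_csv(out_dir / "behavior_frequencies.csv", index=False)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    config_digest = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True, default=list).encode()
    ).hexdigest()
    metadata = {
        "seed": config.population.seed,
        "config_hash": config_digest,
        "catalogue_version": catalogue.version,
        "n_respondents": int(len(population)),
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    report = CompressionReport(
        item_params=item_params,
        latent_fit=latent_fit,
        population_fit=full_fit,
        class_fits=class_fits,
        year_effects=year_effects,
        predictions=predictions,
        blup_table=blup_table,
        behavior_frequencies=freqs,
        scores=scores,
        metadata=metadata,
    )
    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(
                {
                    "metadata": metadata,
                    "report_hash": report.report_hash(),
                    "year_effects": year_effects.to_dict(orient="records"),
                },
                fh,
                indent=2,
            )
    logger.info("pipeline done in %.2fs", time.perf_counter() - t_all)
    return report
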