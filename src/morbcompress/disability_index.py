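"""Composite disability weights and likelihood sampling weights.

The multimorbidity burden of a respondent is summarised by a cumulative
disability weight ``D_j``: each reported chronic condition contributes a
GBD-style severity weight ``W_ij`` in (0, 1), and the weights combine
multiplicatively,

    D_j = 1 - prod_i (1 - W_ij),

so that the burden saturates below 1 and is symmetric in the conditions.
Which candidate weight is used for a condition depends on the respondent's
self-perceived health (1 = excellent ... 5 = very bad): good perceived
health selects the mildest candidate, rating 4 the average, rating 5 the
most severe.

The cumulative weights then enter the latent-trait likelihood as sampling
weights

    w_j = (D_j + 1) * N / (sum_j D_j + N),

which average to 1 over the sample and up-weight respondents living with a
heavier disease burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DISEASES = ("diabetes", "kidney", "respiratory", "heart", "tumor")

__all__ = [
    "DISEASES",
    "DisabilityWeightSet",
    "CompositeWeights",
    "select_weight",
    "composite_disability",
    "sampling_weights",
    "compute_composite_weights",
]


@dataclass(frozen=True)
class DisabilityWeightSet:
    """Candidate disability weights per disease, each ascending in (0, 1)."""

    weights: Mapping[str, tuple[float, ...]]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for disease, cand in self.weights.items():
            if len(cand) == 0:
                raise ValueError(f"empty candidate weight list for {disease!r}")
            arr = np.asarray(cand, dtype=float)
            if np.any(arr <= 0.0) or np.any(arr >= 1.0):
                raise ValueError(
                    f"candidate weights for {disease!r} must lie strictly in (0, 1)"
                )
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"candidate weights for {disease!r} must be ascending")

    def __getitem__(self, disease: str) -> tuple[float, ...]:
        return tuple(self.weights[disease])

    def diseases(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"disease": d, "weight": w}
            for d, cands in self.weights.items()
            for w in cands
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, version: str = "file") -> "DisabilityWeightSet":
        """Load a two-column (disease, weight) catalogue, sorting within disease."""
        weights = {
            str(disease): tuple(sorted(group["weight"].astype(float)))
            for disease, group in frame.groupby("disease", sort=True)
        }
        return cls(weights=weights, version=version)


@dataclass
class CompositeWeights:
    """Per-respondent selected weights, cumulative disability D and sampling weight w."""

    selected: pd.DataFrame  # one column per disease; NaN when disease absent
    D: np.ndarray
    w: np.ndarray
    table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.table = self.selected.copy()
        self.table["D"] = self.D
        self.table["w"] = self.w


def select_weight(candidates: Sequence[float], perceived_health: int) -> float:
    """Pick one disability weight from an ascending candidate list.

    Perceived health 1–3 selects the minimum candidate, 4 the arithmetic
    mean, 5 the maximum.
    """
    if len(candidates) == 0:
        raise ValueError("candidate weight list is empty")
    ph = int(perceived_health)
    if ph not in (1, 2, 3, 4, 5):
        raise ValueError(f"perceived_health must be in 1..5, got {perceived_health}")
    arr = np.asarray(candidates, dtype=float)
    if ph <= 3:
        return float(arr.min())
    if ph == 4:
        return float(arr.mean())
    return float(arr.max())


def composite_disability(selected_weights: Iterable[float]) -> float:
    """Cumulative disability D = 1 - prod(1 - W) over the reported conditions."""
    weights = np.asarray(list(selected_weights), dtype=float)
    if weights.size == 0:
        return 0.0
    if np.any(weights < 0.0) or np.any(weights >= 1.0):
        raise ValueError("disability weights must lie in [0, 1)")
    return float(1.0 - np.prod(1.0 - weights))


def sampling_weights(D: Sequence[float] | np.ndarray) -> np.ndarray:
    """Likelihood weights w_j = (D_j + 1) N / (sum D + N); they sum to N."""
    arr = np.asarray(D, dtype=float)
    if arr.size == 0:
        raise ValueError("disability vector is empty")
    if np.any(arr < 0.0) or np.any(arr >= 1.0):
        raise ValueError("cumulative disability values must lie in [0, 1)")
    n = arr.size
    return (arr + 1.0) * n / (arr.sum() + n)


def compute_composite_weights(
    population: pd.DataFrame, catalogue: DisabilityWeightSet
) -> CompositeWeights:
    """Apply the selection rule and Eq-style combination to a respondent table.

    ``population`` needs one binary column per disease in the catalogue plus
    ``perceived_health``. Selection depends only on perceived health, so the
    per-disease selected weight is computed once per health rating and
    broadcast.
    """
    ph = population["perceived_health"].to_numpy()
    if not np.isin(ph, (1, 2, 3, 4, 5)).all():
        raise ValueError("perceived_health must be in 1..5")
    selected = {}
    one_minus = np.ones(len(population))
    for disease in catalogue.diseases():
        present = population[disease].to_numpy().astype(bool)
        by_rating = np.array(
            [select_weight(catalogue[disease], r) for r in (1, 2, 3, 4, 5)]
        )
        w_i = np.where(present, by_rating[ph - 1], np.nan)
        selected[disease] = w_i
        one_minus = one_minus * np.where(present, 1.0 - by_rating[ph - 1], 1.0)
    D = 1.0 - one_minus
    # guard against FP dust for the no-disease rows
    no_disease = ~population[list(catalogue.diseases())].to_numpy().astype(bool).any(axis=1)
    D[no_disease] = 0.0
    w = sampling_weights(D)
    return CompositeWeights(
        selected=pd.DataFrame(selected, index=population.index), D=D, w=w
    )
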