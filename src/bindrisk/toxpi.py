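"""ToxPi-style weighted-slice risk integration and ranking.

The Toxicological Prioritization Index aggregates heterogeneous endpoints
into one score per chemical:

1. each raw metric is *transformed* so that larger = higher concern
   (identity; negation for binding energies, where more negative raw values
   mean stronger binding; absolute difference from a control for
   conformational fractions);
2. each transformed metric is *scaled* across chemicals to [0, 1]
   (min–max by default; an x/max option is available). A metric constant
   across all chemicals is degenerate and scores 0 for everyone;
3. metrics are grouped into named *classes* (slices); a slice score is the
   arithmetic mean of its scaled metrics;
4. the overall score is the weighted sum of slice scores (weights must sum
   to 1; uniform by default), and chemicals are ranked by descending
   overall score with lexicographic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MetricSpec",
    "MetricTable",
    "ToxPiResult",
    "ToxPiScorer",
    "minmax_scale",
    "rank_profiles",
    "toxpi_scores",
    "transform_metric",
]

Transform = Literal["identity", "negate", "absdiff_vs_control"]


@dataclass(frozen=True)
class MetricSpec:
    """How one metric enters the score: slice membership and orientation.

    ``verified`` marks whether the stored value set comes from an
    authoritative source; fixture slots filled from plots or imputation
    carry ``verified=False``.
    """

    class_name: str
    transform: Transform = "identity"
    control_value: float | None = None
    verified: bool = True

    def __post_init__(self) -> None:
        if self.transform == "absdiff_vs_control" and self.control_value is None:
            raise ValueError("absdiff_vs_control requires a control_value")


@dataclass(frozen=True)
class MetricTable:
    """Chemicals × metrics with per-metric transform and class assignment.

    ``values`` is a DataFrame indexed by chemical with one column per
    metric; ``specs`` maps each column to its :class:`MetricSpec`. Every
    metric must have a value for every chemical.
    """

    values: pd.DataFrame
    specs: dict[str, MetricSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.values.columns) != set(self.specs):
            raise ValueError("specs must cover exactly the metric columns")
        if self.values.isna().any().any():
            raise ValueError("every metric needs a value for every chemical")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate chemical names")

    @property
    def chemicals(self) -> list[str]:
        return list(self.values.index)

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for spec in self.specs.values():
            seen.setdefault(spec.class_name, None)
        return list(seen)


@dataclass(frozen=True)
class ToxPiResult:
    """Per-chemical slice scores, overall score and rank."""

    chemical: str
    slice_scores: dict[str, float]
    overall: float
    rank: int


def transform_metric(
    values: Mapping[str, float],
    transform: Transform,
    control_value: float | None = None,
) -> dict[str, float]:
    """Orient a raw metric so that larger = higher concern.

    identity: unchanged. negate: −v (for binding energies/docking scores).
    absdiff_vs_control: |v − control| (for conformational fractions, where
    any departure from the control state is the signal).
    """
    if transform == "identity":
        return dict(values)
    if transform == "negate":
        return {k: -v for k, v in values.items()}
    if transform == "absdiff_vs_control":
        if control_value is None:
            raise ValueError("absdiff_vs_control requires a control_value")
        return {k: abs(v - control_value) for k, v in values.items()}
    raise ValueError(f"unknown transform {transform!r}")


def minmax_scale(values: Mapping[str, float]) -> dict[str, float]:
    """Scale a metric to [0, 1] across chemicals: (v − min)/(max − min).

    A constant metric is degenerate (no information to rank on) and maps
    every chemical to 0. Needs at least 2 chemicals.
    """
    if len(values) < 2:
        raise ValueError("min–max scaling needs at least 2 chemicals")
    vals = np.array(list(values.values()), dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return {k: 0.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def _max_scale(values: Mapping[str, float]) -> dict[str, float]:
    """Alternative x/max scaling (requires non-negative transformed values)."""
    if len(values) < 2:
        raise ValueError("scaling needs at least 2 chemicals")
    vals = np.array(list(values.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError("x/max scaling requires non-negative transformed values")
    hi = float(vals.max())
    if hi == 0:
        return {k: 0.0 for k in values}
    return {k: v / hi for k, v in values.items()}


class ToxPiScorer(BaseEstimator, TransformerMixin):
    """ToxPi weighted-slice scoring as a scikit-learn transformer.

    ``fit(table)`` accepts a :class:`MetricTable` (or a plain DataFrame,
    in which case every column is an identity metric in one default class).
    ``transform`` returns a DataFrame of slice scores plus ``overall`` and
    ``rank`` columns.

    Parameters
    ----------
    weights : mapping class -> weight, optional
        Must cover every class in the table and sum to 1 (within 1e-9).
        Default: uniform across classes.
    scaling : {"minmax", "max"}
        Uniform-scaling rule applied per metric across chemicals.

    Attributes (after fit): ``transformed_``, ``scaled_``, ``slice_scores_``,
    ``overall_``, ``ranks_``, ``results_``.
    """

    def __init__(self, weights: Mapping[str, float] | None = None,
                 scaling: Literal["minmax", "max"] = "minmax"):
        self.weights = weights
        self.scaling = scaling

    @staticmethod
    def _as_table(X) -> MetricTable:
        if isinstance(X, MetricTable):
            return X
        df = pd.DataFrame(X)
        specs = {c: MetricSpec(class_name="all") for c in df.columns}
        return MetricTable(values=df, specs=specs)

    def fit(self, X, y=None):
        table = self._as_table(X)
        classes = table.classes
        if self.weights is None:
            weights = {c: 1.0 / len(classes) for c in classes}
        else:
            weights = {str(k): float(v) for k, v in self.weights.items()}
            missing = [c for c in classes if c not in weights]
            if missing:
                raise ValueError(f"classes missing from weights: {missing}")
            if abs(sum(weights[c] for c in classes) - 1.0) > 1e-9:
                raise ValueError("class weights must sum to 1")
        scale = minmax_scale if self.scaling == "minmax" else _max_scale

        transformed: dict[str, dict[str, float]] = {}
        scaled: dict[str, dict[str, float]] = {}
        for metric in table.values.columns:
            spec = table.specs[metric]
            raw = table.values[metric].to_dict()
            transformed[metric] = transform_metric(raw, spec.transform, spec.control_value)
            scaled[metric] = scale(transformed[metric])

        chemicals = table.chemicals
        slice_scores = pd.DataFrame(index=chemicals, columns=classes, dtype=float)
        for cls in classes:
            members = [m for m, s in table.specs.items() if s.class_name == cls]
            for chem in chemicals:
                slice_scores.loc[chem, cls] = float(
                    np.mean([scaled[m][chem] for m in members])
                )
        overall = sum(weights[c] * slice_scores[c] for c in classes)

        order = sorted(chemicals, key=lambda c: (-overall[c], c))
        ranks = pd.Series({c: i + 1 for i, c in enumerate(order)}, name="rank")

        self.weights_ = weights
        self.transformed_ = pd.DataFrame(transformed).loc[chemicals]
        self.scaled_ = pd.DataFrame(scaled).loc[chemicals]
        self.slice_scores_ = slice_scores
        self.overall_ = overall.rename("overall")
        self.ranks_ = ranks.loc[chemicals]
        self.results_ = [
            ToxPiResult(
                chemical=c,
                slice_scores=slice_scores.loc[c].to_dict(),
                overall=float(overall[c]),
                rank=int(ranks[c]),
            )
            for c in chemicals
        ]
        return self

    def transform(self, X=None):
        # X is accepted for scikit-learn API compatibility and ignored; the
        # scores are computed in fit from the full table.
        out = self.slice_scores_.copy()
        out["overall"] = self.overall_
        out["rank"] = self.ranks_
        return out


def toxpi_scores(
    table: MetricTable, weights: Mapping[str, float] | None = None
) -> list[ToxPiResult]:
    """Compute ToxPi results for every chemical in the table.

    Thin wrapper over :class:`ToxPiScorer` with min–max scaling.
    """
    scorer = ToxPiScorer(weights=weights).fit(table)
    return scorer.results_


def rank_profiles(results: Sequence[ToxPiResult]) -> list[ToxPiResult]:
    """Order results by descending overall score (ties: lexicographic name).

    Ranks are (re)assigned 1..n in the returned order.
    """
    ordered = sorted(results, key=lambda r: (-r.overall, r.chemical))
    return [
        ToxPiResult(chemical=r.chemical, slice_scores=r.slice_scores,
                    overall=r.overall, rank=i + 1)
        for i, r in enumerate(ordered)
    ]
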