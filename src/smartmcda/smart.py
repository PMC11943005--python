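"""SMART (Simple Multi-Attribute Rating Technique) decision core.

Candidate strategies are scored against criteria grouped into weighted
dimensions. Each (strategy, attribute) cell holds an importance rank; the
attribute's value is rank × dimension weight, a dimension's score is the sum
of its attribute values, and the global utility of strategy j is the linear
additive form

    U_j = sum_k w_k * u_jk

with normalized dimension weights w_k (sum 1) and dimension scores u_jk.
The strategy with maximal U_j is the recommended alternative. A one-at-a-time
weight-perturbation sensitivity analysis reports whether and when the
recommendation reverses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

__all__ = [
    "Dimension",
    "Attribute",
    "Alternative",
    "DecisionModel",
    "UtilityResult",
    "SensitivityRecord",
    "SensitivityReport",
    "smart_normalize_weights",
    "rank_alternatives",
    "attribute_value",
    "dimension_score",
    "performance_matrix",
    "additive_utility",
    "select_optimal",
    "sensitivity_analysis",
    "evaluate_model",
    "load_decision_model",
    "SmartDecision",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class Dimension:
    """A criterion grouping (e.g. budget allocation) with normalized weight."""

    id: str
    label: str
    weight: float
    attributes: tuple[str, ...]
    alt_label: str | None = None  # alternate published naming, metadata only

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"dimension {self.id}: weight must be in (0, 1]")
        if not self.attributes:
            raise ValueError(f"dimension {self.id}: needs at least one attribute")


@dataclass(frozen=True)
class Attribute:
    id: str
    dimension_id: str
    label: str = ""


@dataclass(frozen=True)
class Alternative:
    id: str
    label: str
    strategy_weight: float = 0.35
    importance_rank: int = 1

    def __post_init__(self) -> None:
        if self.importance_rank < 1:
            raise ValueError(f"alternative {self.id}: importance_rank must be >= 1")
        if self.strategy_weight <= 0:
            raise ValueError(f"alternative {self.id}: strategy_weight must be positive")


@dataclass(frozen=True)
class UtilityResult:
    dimension_scores: pd.DataFrame  # alternatives × dimensions (u_jk)
    performance_totals: pd.Series  # sum_k u_jk per alternative
    utilities: pd.Series  # U_j per alternative
    ranking: tuple[str, ...]  # best first
    optimal: str
    tie_flag: bool


def smart_normalize_weights(raw_scores: Sequence[float]) -> np.ndarray:
    """Normalize SMART importance scores (each in [10, 100]) to weights summing to 1."""
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one dimension score")
    if ((raw < 10.0) | (raw > 100.0)).any():
        raise ValueError("SMART scores must lie in [10, 100]")
    return raw / raw.sum()


def rank_alternatives(alternatives: Sequence[Alternative]) -> pd.Series:
    """Total ranking value per alternative: importance_rank × strategy_weight."""
    return pd.Series(
        {a.id: a.importance_rank * a.strategy_weight for a in alternatives}, name="total"
    )


def attribute_value(rank: int, w_dim: float) -> float:
    """Weighted value of one attribute cell: importance rank × dimension weight."""
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    if not 0.0 < w_dim <= 1.0:
        raise ValueError(f"dimension weight must be in (0, 1], got {w_dim}")
    return rank * w_dim


def dimension_score(attribute_values: Sequence[float]) -> float:
    """Dimension score u_jk: sum of the attribute values in that dimension."""
    vals = list(attribute_values)
    if not vals:
        raise ValueError("dimension has no attribute values")
    return float(sum(vals))


def additive_utility(
    dimension_scores: pd.DataFrame, weights: Mapping[str, float] | pd.Series
) -> pd.Series:
    """Linear additive utility U_j = sum_k w_k * u_jk per alternative."""
    w = pd.Series(dict(weights), dtype=float)
    missing = set(dimension_scores.columns).symmetric_difference(w.index)
    if missing:
        raise ValueError(f"weights and dimension scores disagree on dimensions {sorted(missing)}")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"dimension weights must sum to 1, got {w.sum()}")
    return (dimension_scores * w).sum(axis=1).rename("utility")


def select_optimal(utilities: pd.Series | Mapping[str, float]) -> tuple[str, bool]:
    """Argmax by utility; exact ties break toward the lowest alternative id (flagged)."""
    u = pd.Series(dict(utilities) if not isinstance(utilities, pd.Series) else utilities)
    if u.empty:
        raise ValueError("no utilities to select from")
    best = u.max()
    winners = sorted(u.index[np.isclose(u.to_numpy(float), best, rtol=0.0, atol=_WEIGHT_TOL)])
    return winners[0], len(winners) > 1


@dataclass
class DecisionModel:
    """Full SMART decision configuration: dimensions, attributes, alternatives, ranks.

    ``ranks`` is an alternatives × attributes DataFrame of importance ranks
    (integers >= 1). If ``rank_total`` is set, every alternative's ranks must
    sum to it — the elicitation constraint that keeps strategies comparable.
    """

    dimensions: tuple[Dimension, ...]
    attributes: tuple[Attribute, ...]
    alternatives: tuple[Alternative, ...]
    ranks: pd.DataFrame
    rank_total: int | None = None
    name: str = "decision-model"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dim_ids = [d.id for d in self.dimensions]
        if len(set(dim_ids)) != len(dim_ids):
            raise ValueError("duplicate dimension ids")
        total_w = sum(d.weight for d in self.dimensions)
        if abs(total_w - 1.0) > 1e-6:
            raise ValueError(f"dimension weights must sum to 1, got {total_w}")
        attr_dims = {}
        for a in self.attributes:
            if a.id in attr_dims:
                raise ValueError(f"attribute {a.id} assigned to more than one dimension")
            if a.dimension_id not in dim_ids:
                raise ValueError(f"attribute {a.id} references unknown dimension {a.dimension_id}")
            attr_dims[a.id] = a.dimension_id
        for d in self.dimensions:
            for aid in d.attributes:
                if attr_dims.get(aid) != d.id:
                    raise ValueError(f"dimension {d.id} lists attribute {aid} not assigned to it")
        alt_ids = [a.id for a in self.alternatives]
        missing_cells = []
        for alt in alt_ids:
            for attr in attr_dims:
                if alt not in self.ranks.index or attr not in self.ranks.columns or pd.isna(
                    self.ranks.at[alt, attr]
                ):
                    missing_cells.append((alt, attr))
        if missing_cells:
            raise ValueError(f"rank assignment incomplete; missing cells {missing_cells}")
        self.ranks = self.ranks.loc[alt_ids, list(attr_dims)].astype(int)
        if (self.ranks.to_numpy() < 1).any():
            raise ValueError("importance ranks must be >= 1")
        if self.rank_total is not None:
            totals = self.ranks.sum(axis=1)
            bad = totals[totals != self.rank_total]
            if not bad.empty:
                raise ValueError(
                    f"rank totals must equal {self.rank_total}; "
                    f"offending alternatives: {dict(bad)}"
                )

    @property
    def weights(self) -> pd.Series:
        return pd.Series({d.id: d.weight for d in self.dimensions}, name="weight")

    @property
    def attribute_dimensions(self) -> dict[str, str]:
        return {a.id: a.dimension_id for a in self.attributes}

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "DecisionModel":
        dims_cfg = cfg["dimensions"]
        raw_scores = [d.get("raw_score") for d in dims_cfg]
        if any(s is not None for s in raw_scores):
            if any(s is None for s in raw_scores):
                raise ValueError("give either raw_score for every dimension or weight for every dimension")
            weights = smart_normalize_weights(raw_scores)
        else:
            weights = [float(d["weight"]) for d in dims_cfg]
        attrs = tuple(
            Attribute(id=a["id"], dimension_id=a["dimension"], label=a.get("label", ""))
            for a in cfg["attributes"]
        )
        by_dim: dict[str, list[str]] = {}
        for a in attrs:
            by_dim.setdefault(a.dimension_id, []).append(a.id)
        dims = tuple(
            Dimension(
                id=d["id"],
                label=d.get("label", d["id"]),
                weight=float(w),
                attributes=tuple(by_dim.get(d["id"], ())),
                alt_label=d.get("alt_label"),
            )
            for d, w in zip(dims_cfg, weights)
        )
        alts = tuple(
            Alternative(
                id=a["id"],
                label=a.get("label", a["id"]),
                strategy_weight=float(a.get("strategy_weight", 0.35)),
                importance_rank=int(a.get("importance_rank", i + 1)),
            )
            for i, a in enumerate(cfg["alternatives"])
        )
        ranks = pd.DataFrame.from_dict(cfg["ranks"], orient="index")
        return cls(
            dimensions=dims,
            attributes=attrs,
            alternatives=alts,
            ranks=ranks,
            rank_total=cfg.get("rank_total"),
            name=cfg.get("name", "decision-model"),
            metadata=dict(cfg.get("metadata", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DecisionModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_decision_model(path: str | Path | None = None) -> DecisionModel:
    """Load a decision model config; default: the packaged pandemic-resilience model."""
    if path is not None:
        return DecisionModel.from_yaml(path)
    ref = resources.files("smartmcda.data").joinpath("pandemic_resilience.yaml")
    return DecisionModel.from_dict(yaml.safe_load(ref.read_text()))


def performance_matrix(model: DecisionModel) -> UtilityResult:
    """Build the performance matrix and complete utilities for a decision model."""
    est = SmartDecision(
        dimension_weights=dict(model.weights),
        attribute_dimensions=model.attribute_dimensions,
        expected_rank_total=model.rank_total,
    ).fit(model.ranks)
    return est.result_


def evaluate_model(model: DecisionModel) -> UtilityResult:
    """Alias of :func:`performance_matrix`; runs the full SMART evaluation."""
    return performance_matrix(model)


@dataclass(frozen=True)
class SensitivityRecord:
    dimension_id: str
    delta: float
    direction: int  # +1 or -1
    utilities: pd.Series | None
    optimal: str | None
    reversed: bool
    note: str | None = None


@dataclass(frozen=True)
class SensitivityReport:
    baseline_optimal: str
    records: tuple[SensitivityRecord, ...]
    min_reversal_delta: dict[str, float | None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "dimension": r.dimension_id,
                "delta": r.delta,
                "direction": r.direction,
                "optimal": r.optimal,
                "reversed": r.reversed,
                "note": r.note,
            }
            if r.utilities is not None:
                row.update({f"U_{k}": v for k, v in r.utilities.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _perturbed_weights(weights: pd.Series, dim: str, delta: float, direction: int) -> pd.Series | None:
    """Shift one weight by ±delta and renormalize the others proportionally."""
    w = weights.astype(float).copy()
    new_k = w[dim] + direction * delta
    rest = w.drop(dim)
    if new_k <= 0.0 or new_k >= 1.0 or rest.sum() <= 0:
        return None
    scaled = rest * (1.0 - new_k) / rest.sum()
    if (scaled < 0).any():
        return None
    w[dim] = new_k
    w.update(scaled)
    return w


def sensitivity_analysis(
    model: DecisionModel, deltas: Sequence[float] | None = None
) -> SensitivityReport:
    """One-at-a-time weight perturbation with proportional renormalization.

    For each dimension k and each delta in the grid, w_k is shifted by ±delta,
    the remaining weights are rescaled so the total stays 1, the whole SMART
    evaluation (attribute values, dimension scores, utilities) is recomputed,
    and a reversal is recorded whenever the optimal alternative changes from
    the baseline. Perturbations that would drive a weight out of (0, 1) are
    skipped with a note.
    """
    if deltas is None:
        deltas = np.round(np.arange(0.01, 1.0, 0.01), 2)
    for d in deltas:
        if not 0.0 <= d < 1.0:
            raise ValueError(f"delta must be in [0, 1), got {d}")
    base = performance_matrix(model)
    weights = model.weights
    records: list[SensitivityRecord] = []
    min_reversal: dict[str, float | None] = {}
    attr_dims = model.attribute_dimensions
    for dim in weights.index:
        found: float | None = None
        for delta in sorted(deltas):
            for direction in (+1, -1):
                if delta == 0.0 and direction == -1:
                    continue
                w_new = _perturbed_weights(weights, dim, float(delta), direction)
                if w_new is None:
                    records.append(
                        SensitivityRecord(
                            dimension_id=dim,
                            delta=float(delta),
                            direction=direction,
                            utilities=None,
                            optimal=None,
                            reversed=False,
                            note="skipped: weight would leave (0, 1)",
                        )
                    )
                    continue
                est = SmartDecision(
                    dimension_weights=dict(w_new), attribute_dimensions=attr_dims
                ).fit(model.ranks)
                rev = est.optimal_ != base.optimal
                records.append(
                    SensitivityRecord(
                        dimension_id=dim,
                        delta=float(delta),
                        direction=direction,
                        utilities=est.utilities_,
                        optimal=est.optimal_,
                        reversed=rev,
                    )
                )
                if rev and found is None:
                    found = float(delta)
        min_reversal[dim] = found
    return SensitivityReport(
        baseline_optimal=base.optimal, records=tuple(records), min_reversal_delta=min_reversal
    )


class SmartDecision(BaseEstimator):
    """SMART additive-utility scorer in scikit-learn estimator form.

    Parameters
    ----------
    dimension_weights : mapping of dimension id -> weight
        Normalized criterion weights; must sum to 1. Raw SMART importance
        scores (10–100) can be normalized first via
        :func:`smart_normalize_weights`.
    attribute_dimensions : mapping of attribute id -> dimension id
        Which dimension each rank column belongs to.
    expected_rank_total : int, optional
        If set, every alternative's ranks must sum to this constant.

    ``fit(X)`` takes an alternatives × attributes DataFrame of importance
    ranks and computes the fitted attributes ``dimension_scores_``,
    ``performance_totals_``, ``utilities_``, ``ranking_``, ``optimal_``,
    ``tie_flag_`` and ``result_``. ``transform(X)`` maps a rank matrix to
    utilities using the configured weights.
    """

    def __init__(
        self,
        dimension_weights: Mapping[str, float] | None = None,
        attribute_dimensions: Mapping[str, str] | None = None,
        expected_rank_total: int | None = None,
    ):
        self.dimension_weights = dimension_weights
        self.attribute_dimensions = attribute_dimensions
        self.expected_rank_total = expected_rank_total

    def _validate_setup(self, X: pd.DataFrame) -> tuple[pd.Series, dict[str, str]]:
        if self.dimension_weights is None or self.attribute_dimensions is None:
            raise ValueError("dimension_weights and attribute_dimensions are required")
        w = pd.Series(dict(self.dimension_weights), dtype=float)
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"dimension weights must sum to 1, got {w.sum()}")
        if ((w <= 0) | (w > 1)).any():
            raise ValueError("each dimension weight must lie in (0, 1]")
        attr_dims = dict(self.attribute_dimensions)
        unknown = set(attr_dims.values()) - set(w.index)
        if unknown:
            raise ValueError(f"attributes reference unknown dimensions {sorted(unknown)}")
        missing = [
            (alt, attr)
            for attr in attr_dims
            for alt in X.index
            if attr not in X.columns or pd.isna(X.at[alt, attr])
        ]
        if missing:
            raise ValueError(f"rank assignment incomplete; missing cells {missing}")
        return w, attr_dims

    def _score(self, X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
        w, attr_dims = self._validate_setup(X)
        ranks = X[list(attr_dims)].astype(float)
        if (ranks.to_numpy() < 1).any():
            raise ValueError("importance ranks must be >= 1")
        if self.expected_rank_total is not None:
            totals = ranks.sum(axis=1)
            bad = totals[totals != self.expected_rank_total]
            if not bad.empty:
                raise ValueError(
                    f"rank totals must equal {self.expected_rank_total}; "
                    f"offending alternatives: {dict(bad)}"
                )
        # u_jk: rank × dimension weight per cell, summed within each dimension
        cell_values = ranks * pd.Series({a: w[d] for a, d in attr_dims.items()})
        dim_scores = cell_values.T.groupby(pd.Series(attr_dims)).sum().T
        dim_scores = dim_scores[[d for d in w.index if d in dim_scores.columns]]
        return dim_scores, w

    def fit(self, X: pd.DataFrame, y=None) -> "SmartDecision":
        dim_scores, w = self._score(X)
        utilities = additive_utility(dim_scores, w)
        optimal, tie = select_optimal(utilities)
        ranking = tuple(sorted(utilities.index, key=lambda a: (-utilities[a], a)))
        self.dimension_scores_ = dim_scores
        self.performance_totals_ = dim_scores.sum(axis=1).rename("performance_total")
        self.utilities_ = utilities
        self.ranking_ = ranking
        self.optimal_ = optimal
        self.tie_flag_ = tie
        self.result_ = UtilityResult(
            dimension_scores=dim_scores,
            performance_totals=self.performance_totals_,
            utilities=utilities,
            ranking=ranking,
            optimal=optimal,
            tie_flag=tie,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        dim_scores, w = self._score(X)
        return additive_utility(dim_scores, w)

    def predict(self, X: pd.DataFrame) -> str:
        """Return the optimal alternative id for a rank matrix."""
        return select_optimal(self.transform(X))[0]
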