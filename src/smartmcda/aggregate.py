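"""Weighted aggregation of Likert responses into per-item summaries.

Stage 1 of the analysis: each questionnaire item is summarised under the
respondents' composite expertise weights — weighted mean, population-weighted
standard deviation, a percentage-scaled weighted index, the preferred (modal
by weighted mass) response, and weighted quartiles — then items are ranked
and mapped onto the decision criteria used by the SMART stage.

Conventions (fixed for reproducibility on discrete scales):

* weighted_index = weighted_mean / scale_max × 100, a percentage in [0, 100]
  comparable across items with different scale lengths;
* the weighted SD divides by the total weight (population convention), which
  makes it invariant to rescaling all weights by a constant;
* weighted quantiles use the left-continuous inverse CDF (type 1), i.e. the
  lowest scale point whose cumulative weight share reaches the probability;
* modal ties break toward the LOWER scale point and set a tie flag, so
  "strong agreement" is never overstated by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .survey import LikertItem

__all__ = [
    "ResponseMatrix",
    "ItemSummary",
    "RankedItem",
    "CriterionEvidence",
    "weighted_item_summary",
    "summarize_items",
    "rank_items",
    "extract_criteria",
    "LikertAggregator",
]


@dataclass
class ResponseMatrix:
    """Respondents × items grid of Likert responses with per-respondent weights.

    ``values`` is a float DataFrame (NaN marks a missing answer) whose index
    holds respondent ids and whose columns are item ids, aligned with
    ``items``; ``weights`` is one positive composite weight per respondent.
    """

    items: Sequence[LikertItem]
    values: pd.DataFrame
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        item_ids = [it.item_id for it in self.items]
        if list(self.values.columns) != item_ids:
            raise ValueError("response columns do not match the item list")
        if len(self.weights) != len(self.values):
            raise ValueError(
                f"{len(self.weights)} weights for {len(self.values)} respondents"
            )
        if len(self.values) and (self.weights <= 0).any():
            raise ValueError("composite weights must be strictly positive")
        for it in self.items:
            col = self.values[it.item_id].dropna()
            if len(col) and ((col < it.scale_min) | (col > it.scale_max)).any():
                raise ValueError(f"responses for {it.item_id} outside its scale bounds")

    @property
    def respondent_ids(self) -> list:
        return list(self.values.index)

    def item(self, item_id: str) -> LikertItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"unknown item {item_id!r}")

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "weight", self.weights)
        out.to_csv(path, index_label="respondent_id")

    @classmethod
    def from_csv(cls, path: str | Path, items: Sequence[LikertItem]) -> "ResponseMatrix":
        df = pd.read_csv(path, index_col="respondent_id")
        weights = df.pop("weight").to_numpy(dtype=float) if "weight" in df.columns else np.ones(len(df))
        item_ids = [it.item_id for it in items]
        return cls(items=items, values=df[item_ids].astype(float), weights=weights)


@dataclass(frozen=True)
class ItemSummary:
    item_id: str
    weighted_index: float
    weighted_pct_preferred: float
    preferred_response: int
    preferred_tie: bool
    weighted_mean: float
    sd: float
    iqr: tuple[int, int]
    n_responses: int
    n_missing: int


@dataclass(frozen=True)
class RankedItem:
    rank: int
    summary: ItemSummary
    tied: bool


@dataclass(frozen=True)
class CriterionEvidence:
    """One decision attribute with its supporting stage-1 item summaries."""

    attribute_id: str
    items: tuple[ItemSummary, ...]
    salience: float  # mean weighted_index of the source items


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, prob: float) -> float:
    """Type-1 (left-continuous inverse CDF) weighted quantile on discrete data."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cdf, prob - 1e-12, side="left"))
    return float(v[min(idx, len(v) - 1)])


def weighted_item_summary(matrix: ResponseMatrix, item_id: str) -> ItemSummary:
    """Summarise one item under the respondent weights.

    Missing responses are excluded listwise for this item only: they enter
    neither the numerator nor the denominator of any weighted statistic.
    """
    item = matrix.item(item_id)
    col = matrix.values[item_id].to_numpy(dtype=float)
    mask = ~np.isnan(col)
    if not mask.any():
        raise ValueError(f"item {item_id!r} has no non-missing responses")
    x = col[mask]
    w = matrix.weights[mask]
    total_w = w.sum()

    wmean = float(np.sum(w * x) / total_w)
    sd = float(np.sqrt(np.sum(w * (x - wmean) ** 2) / total_w))

    # weighted mass per scale point; modal ties break toward the lower point
    points = item.scale_points
    mass = np.array([w[x == s].sum() for s in points])
    best = int(np.argmax(mass))
    preferred = int(points[best])
    tie = bool(np.sum(np.isclose(mass, mass[best], rtol=0.0, atol=1e-12)) > 1)

    return ItemSummary(
        item_id=item_id,
        weighted_index=wmean / item.scale_max * 100.0,
        weighted_pct_preferred=float(mass[best] / total_w * 100.0),
        preferred_response=preferred,
        preferred_tie=tie,
        weighted_mean=wmean,
        sd=sd,
        iqr=(int(_weighted_quantile(x, w, 0.25)), int(_weighted_quantile(x, w, 0.75))),
        n_responses=int(mask.sum()),
        n_missing=int((~mask).sum()),
    )


def summarize_items(matrix: ResponseMatrix) -> list[ItemSummary]:
    return [weighted_item_summary(matrix, it.item_id) for it in matrix.items]


def rank_items(
    summaries: Sequence[ItemSummary], key: str = "weighted_index"
) -> list[RankedItem]:
    """Order items descending by ``key`` (weighted_index or weighted_mean).

    The sort is stable; exact ties are additionally broken by item_id
    lexicographic order and flagged on every member of the tied group.
    """
    if key not in ("weighted_index", "weighted_mean"):
        raise ValueError(f"unsupported ranking key {key!r}")
    if not summaries:
        raise ValueError("cannot rank an empty summary list")
    ordered = sorted(summaries, key=lambda s: (-getattr(s, key), s.item_id))
    values = [getattr(s, key) for s in ordered]
    out = []
    for i, s in enumerate(ordered):
        tied = (i > 0 and np.isclose(values[i], values[i - 1])) or (
            i + 1 < len(values) and np.isclose(values[i], values[i + 1])
        )
        out.append(RankedItem(rank=i + 1, summary=s, tied=tied))
    return out


def extract_criteria(
    summaries: Sequence[ItemSummary], mapping: Mapping[str, Sequence[str]]
) -> list[CriterionEvidence]:
    """Group stage-1 item summaries under the configured decision attributes.

    ``mapping`` assigns each attribute id the item ids that evidence it; the
    attribute's salience is the mean weighted index of those items.
    """
    by_id = {s.item_id: s for s in summaries}
    out = []
    for attr_id, item_ids in mapping.items():
        if not item_ids:
            raise ValueError(f"attribute {attr_id!r} has an empty item mapping")
        unknown = [i for i in item_ids if i not in by_id]
        if unknown:
            raise ValueError(f"attribute {attr_id!r} references unknown items {unknown}")
        items = tuple(by_id[i] for i in item_ids)
        out.append(
            CriterionEvidence(
                attribute_id=attr_id,
                items=items,
                salience=float(np.mean([s.weighted_index for s in items])),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[ItemSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "item_id": s.item_id,
                "weighted_index": s.weighted_index,
                "weighted_pct_preferred": s.weighted_pct_preferred,
                "preferred_response": s.preferred_response,
                "preferred_tie": s.preferred_tie,
                "weighted_mean": s.weighted_mean,
                "sd": s.sd,
                "q25": s.iqr[0],
                "q75": s.iqr[1],
                "n_responses": s.n_responses,
                "n_missing": s.n_missing,
            }
        )
    return pd.DataFrame(rows).set_index("item_id")


class LikertAggregator(BaseEstimator, TransformerMixin):
    """Transformer from a respondents × items response table to item summaries.

    Parameters
    ----------
    items : sequence of LikertItem or of (item_id, scale_min, scale_max)
        Scale metadata for every column of the response table.

    ``fit(X, sample_weight=...)`` accepts the response DataFrame (NaN =
    missing) and optional composite weights (default: uniform), and exposes
    ``summaries_`` (list of :class:`ItemSummary`) and ``summary_frame_``.
    ``transform`` aggregates a response table to its summary frame using the
    weights passed at fit time only if shapes match, else uniform weights.
    """

    def __init__(self, items: Sequence[LikertItem | tuple] | None = None):
        self.items = items

    def _item_objects(self) -> list[LikertItem]:
        if self.items is None:
            raise ValueError("LikertAggregator requires item scale metadata")
        out = []
        for it in self.items:
            out.append(it if isinstance(it, LikertItem) else LikertItem(*it))
        return out

    def _to_matrix(self, X: pd.DataFrame, sample_weight) -> ResponseMatrix:
        items = self._item_objects()
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=[i.item_id for i in items])
        w = np.ones(len(X)) if sample_weight is None else np.asarray(sample_weight, float)
        return ResponseMatrix(items=items, values=X.astype(float), weights=w)

    def fit(self, X, y=None, sample_weight=None) -> "LikertAggregator":
        matrix = self._to_matrix(X, sample_weight)
        self.matrix_ = matrix
        self.summaries_ = summarize_items(matrix)
        self.summary_frame_ = summaries_to_frame(self.summaries_)
        self.n_features_in_ = matrix.values.shape[1]
        return self

    def transform(self, X, sample_weight=None) -> pd.DataFrame:
        return summaries_to_frame(summarize_items(self._to_matrix(X, sample_weight)))
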