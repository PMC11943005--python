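"""End-to-end orchestration: simulate → aggregate → criteria → SMART → report.

A :class:`PipelineConfig` describes the whole run declaratively — the survey
(either a synthetic spec or externally supplied responses), the mapping from
questionnaire items to decision attributes, and the decision model.
Validation is all-or-nothing: unknown keys, dangling references and malformed
sections abort before any computation, and partial outputs are never written
(everything is computed in memory first, then flushed).

The stage-1 → stage-2 linkage in the underlying study is narrative rather
than algorithmic; the ``criteria`` mapping makes that linkage explicit and
auditable, and stage 2 can run standalone from a decision-model config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .aggregate import (
    CriterionEvidence,
    ResponseMatrix,
    extract_criteria,
    summaries_to_frame,
    summarize_items,
)
from .simulate import SurveySpec, default_survey_spec, generate_survey
from .smart import DecisionModel, UtilityResult, load_decision_model, performance_matrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "default_pipeline_config"]

logger = logging.getLogger("smartmcda")

#: Default item → attribute evidence mapping: overload/workload items back the
#: staffing attribute, access and telemedicine items back service planning,
#: the underfunding and legal-framework items back their own dimensions.
DEFAULT_CRITERIA_MAPPING: dict[str, list[str]] = {
    "A1": ["Q1.1", "Q1.4", "Q1.5", "Q1.12"],
    "A2.1": ["Q2.1", "Q1.6", "Q1.7"],
    "A2.2": ["Q3.1", "Q3.5"],
    "A2.3": ["Q2.3", "Q2.5"],
    "A2.4": ["Q2.4", "Q2.6", "Q2.7", "Q2.8", "Q2.10"],
    "A3": ["Q3.4", "Q2.2"],
    "A4": ["Q3.8", "Q3.3"],
}


class PipelineConfig(BaseModel):
    """Declarative configuration of a full or stage-2-only run."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    seed: int = 0
    survey: SurveySpec | None = None
    criteria: dict[str, list[str]] | None = None
    decision: DecisionModel = Field(default_factory=load_decision_model)

    @model_validator(mode="before")
    @classmethod
    def _coerce_sections(cls, data):
        if isinstance(data, dict):
            data = dict(data)
            if isinstance(data.get("survey"), dict):
                data["survey"] = SurveySpec.from_dict(data["survey"])
            if isinstance(data.get("decision"), dict):
                data["decision"] = DecisionModel.from_dict(data["decision"])
        return data

    @model_validator(mode="after")
    def _cross_references(self) -> "PipelineConfig":
        if self.criteria is not None:
            if self.survey is None:
                raise ValueError("criteria mapping given but no survey section to source items from")
            item_ids = {it.item_id for it in self.survey.items}
            attr_ids = {a.id for a in self.decision.attributes}
            for attr, items in self.criteria.items():
                if attr not in attr_ids:
                    raise ValueError(f"criteria.{attr}: unknown decision attribute")
                if not items:
                    raise ValueError(f"criteria.{attr}: empty item list")
                dangling = sorted(set(items) - item_ids)
                if dangling:
                    raise ValueError(f"criteria.{attr}: dangling item references {dangling}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def canonical_hash(self) -> str:
        """Stable hash of the configuration for the run manifest."""
        payload = {
            "seed": self.seed,
            "survey": self.survey.model_dump() if self.survey else None,
            "criteria": self.criteria,
            "decision": {
                "name": self.decision.name,
                "weights": {d.id: d.weight for d in self.decision.dimensions},
                "ranks": {a: dict(r) for a, r in self.decision.ranks.iterrows()},
                "rank_total": self.decision.rank_total,
            },
        }
        blob = json.dumps(payload, sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()


def default_pipeline_config(seed: int = 0) -> PipelineConfig:
    """Packaged default: synthetic 412-respondent survey feeding the packaged model."""
    return PipelineConfig(
        seed=seed,
        survey=default_survey_spec(),
        criteria=DEFAULT_CRITERIA_MAPPING,
        decision=load_decision_model(),
    )


@dataclass
class PipelineResult:
    summaries: pd.DataFrame | None
    criteria: list[CriterionEvidence] | None
    utility: UtilityResult
    manifest: dict


def _criteria_frame(criteria: list[CriterionEvidence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "attribute_id": c.attribute_id,
                "salience": c.salience,
                "source_items": ";".join(s.item_id for s in c.items),
            }
            for c in criteria
        ]
    ).set_index("attribute_id")


def run_pipeline(
    config: PipelineConfig,
    survey_data: ResponseMatrix | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the two-stage analysis and optionally write the artifact bundle.

    ``survey_data`` overrides simulation: when given, stage 1 runs on it
    directly; when absent and the config has a survey spec, a synthetic
    survey is generated under the run seed; with neither, only stage 2 runs.
    Outputs (CSV/JSON tables plus a run manifest with config hash, seed and
    version) are written only after every stage has succeeded.
    """
    run_seed = config.seed if seed is None else seed

    summaries_frame = None
    criteria = None
    if survey_data is None and config.survey is not None:
        logger.info("simulating survey '%s' (n=%d, seed=%d)", config.survey.name,
                    config.survey.n_respondents, run_seed)
        _, survey_data = generate_survey(config.survey, seed=run_seed)
    if survey_data is not None:
        summaries = summarize_items(survey_data)
        summaries_frame = summaries_to_frame(summaries)
        logger.info("stage 1: %d items summarised over %d respondents",
                    len(summaries), len(survey_data.values))
        if config.criteria is not None:
            criteria = extract_criteria(summaries, config.criteria)
            logger.info("criteria: %d attributes with stage-1 evidence", len(criteria))

    utility = performance_matrix(config.decision)
    if utility.tie_flag:
        logger.warning("utility tie: optimal alternative resolved by id order")
    logger.info("stage 2: optimal alternative %s (U=%.4f)",
                utility.optimal, utility.utilities[utility.optimal])

    manifest = {
        "config_hash": config.canonical_hash(),
        "seed": run_seed,
        "package": "smartmcda",
        "version": __version__,
        "stages": {
            "stage1": summaries_frame is not None,
            "criteria": criteria is not None,
            "stage2": True,
        },
        "optimal_alternative": utility.optimal,
    }
    result = PipelineResult(
        summaries=summaries_frame, criteria=criteria, utility=utility, manifest=manifest
    )

    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    u = result.utility
    files: dict[str, str] = {}
    files["performance_matrix.csv"] = u.dimension_scores.assign(
        performance_total=u.performance_totals
    ).to_csv(index_label="alternative")
    files["utilities.csv"] = u.utilities.to_frame().assign(
        rank=[u.ranking.index(a) + 1 for a in u.utilities.index]
    ).to_csv(index_label="alternative")
    files["report.json"] = json.dumps(
        {
            "utilities": {k: float(v) for k, v in u.utilities.items()},
            "performance_totals": {k: float(v) for k, v in u.performance_totals.items()},
            "ranking": list(u.ranking),
            "optimal": u.optimal,
            "tie_flag": u.tie_flag,
        },
        indent=2,
        sort_keys=True,
    )
    if result.summaries is not None:
        files["item_summaries.csv"] = result.summaries.to_csv()
        files["item_summaries.json"] = result.summaries.reset_index().to_json(
            orient="records", indent=2
        )
    if result.criteria is not None:
        files["criteria.csv"] = _criteria_frame(result.criteria).to_csv()
    files["manifest.json"] = json.dumps(result.manifest, indent=2, sort_keys=True)
    # all content rendered before anything touches disk
    for name, content in files.items():
        (out_dir / name).write_text(content)
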