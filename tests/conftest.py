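import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from smartmcda import (
    LikertItem,
    ResponseMatrix,
    default_survey_spec,
    load_decision_model,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def decision_model():
    """The packaged pandemic-resilience decision model."""
    return load_decision_model()


@pytest.fixture(scope="session")
def survey_spec():
    """The packaged 412-respondent synthetic-survey specification."""
    return default_survey_spec()


@pytest.fixture
def small_matrix():
    """A hand-checkable 4x2 response matrix with one missing cell."""
    items = [LikertItem("Q1", 1, 5), LikertItem("Q2", 1, 6)]
    values = pd.DataFrame(
        {"Q1": [1.0, 5.0, 4.0, np.nan], "Q2": [6.0, 6.0, 5.0, 2.0]},
        index=pd.Index(["r1", "r2", "r3", "r4"], name="respondent_id"),
    )
    return ResponseMatrix(items=items, values=values, weights=np.array([1.0, 3.0, 2.0, 1.0]))


def expanded_oracle(values: np.ndarray, weights: np.ndarray, scale_min: int, scale_max: int):
    """Unweighted re-computation after replicating respondent i weights[i] times.

    Independent brute-force oracle for the integer-weight case: exact for the
    weighted mean, SD, index, mode (lowest tie), preferred share and type-1
    quantiles.
    """
    mask = ~np.isnan(values)
    x = np.repeat(values[mask], weights[mask].astype(int))
    mean = float(np.mean(x))
    sd = float(np.std(x))  # population convention
    counts = np.array([(x == s).sum() for s in range(scale_min, scale_max + 1)])
    mode = int(scale_min + int(np.argmax(counts)))
    pct = float(counts.max() / len(x) * 100.0)
    xs = np.sort(x)

    def q(p):
        return float(xs[max(int(np.ceil(p * len(xs))) - 1, 0)])

    return {
        "weighted_mean": mean,
        "sd": sd,
        "weighted_index": mean / scale_max * 100.0,
        "preferred_response": mode,
        "weighted_pct_preferred": pct,
        "q25": q(0.25),
        "q75": q(0.75),
    }


def brute_force_utilities(ranks: pd.DataFrame, weights: dict, attr_dims: dict) -> dict:
    """Plain-loop recomputation of U_j = sum_k w_k * sum_{a in k} rank_a * w_k."""
    out = {}
    for alt in ranks.index:
        total = 0.0
        for dim, w in weights.items():
            score = sum(
                ranks.at[alt, a] * w for a, d in attr_dims.items() if d == dim
            )
            total += w * score
        out[alt] = total
    return out
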