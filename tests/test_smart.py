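"""SMART decision core: weight normalization, performance matrix, utilities,
optimal selection and weight-perturbation sensitivity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smartmcda import (
    Alternative,
    DecisionModel,
    SmartDecision,
    additive_utility,
    attribute_value,
    dimension_score,
    load_decision_model,
    performance_matrix,
    rank_alternatives,
    select_optimal,
    sensitivity_analysis,
    smart_normalize_weights,
)
from smartmcda.smart import _perturbed_weights

from conftest import brute_force_utilities


class TestNormalizeWeights:
    def test_symmetric_scores(self):
        np.testing.assert_allclose(smart_normalize_weights([10, 10, 10, 10]), [0.25] * 4)

    def test_reference_weight_vector(self):
        np.testing.assert_allclose(
            smart_normalize_weights([70, 60, 40, 30]), [0.35, 0.30, 0.20, 0.15]
        )

    def test_single_dimension(self):
        np.testing.assert_allclose(smart_normalize_weights([55]), [1.0])

    @pytest.mark.parametrize("bad", [[5, 50], [50, 101], []])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            smart_normalize_weights(bad)

    @given(st.lists(st.floats(10, 100), min_size=1, max_size=8))
    def test_always_sums_to_one(self, raw):
        assert smart_normalize_weights(raw).sum() == pytest.approx(1.0, abs=1e-9)


class TestElementaryOps:
    @pytest.mark.parametrize(
        "rank, weight, expected",
        [(3, 0.35, 1.05), (1, 0.35, 0.35), (2, 0.5, 1.0)],
    )
    def test_rank_alternatives(self, rank, weight, expected):
        alts = [Alternative("S", "s", strategy_weight=weight, importance_rank=rank)]
        assert rank_alternatives(alts)["S"] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "rank, w, expected", [(3, 0.3, 0.9), (1, 0.2, 0.2), (2, 0.35, 0.7)]
    )
    def test_attribute_value(self, rank, w, expected):
        assert attribute_value(rank, w) == pytest.approx(expected)

    def test_attribute_value_domain(self):
        with pytest.raises(ValueError):
            attribute_value(0, 0.3)
        with pytest.raises(ValueError):
            attribute_value(2, 1.5)

    def test_dimension_score_sums(self):
        assert dimension_score([0.6, 0.6, 0.3, 0.9]) == pytest.approx(2.4)
        assert dimension_score([0.35]) == pytest.approx(0.35)
        # ranks (1, 3, 2, 1) at shared weight 0.3
        assert dimension_score([attribute_value(r, 0.3) for r in (1, 3, 2, 1)]) == pytest.approx(2.1)
        with pytest.raises(ValueError):
            dimension_score([])


class TestPackagedModel:
    def test_performance_totals(self, decision_model):
        res = performance_matrix(decision_model)
        np.testing.assert_allclose(
            res.performance_totals[["S1", "S2", "S3"]], [3.70, 3.80, 3.90], atol=0.005
        )

    def test_utilities_and_optimal(self, decision_model):
        res = performance_matrix(decision_model)
        np.testing.assert_allclose(
            res.utilities[["S1", "S2", "S3"]], [1.04, 1.09, 1.14], atol=0.005
        )
        assert res.optimal == "S3"
        assert res.ranking == ("S3", "S2", "S1")
        assert not res.tie_flag

    def test_rank_totals_constrained(self, decision_model):
        assert decision_model.rank_total == 14
        assert (decision_model.ranks.sum(axis=1) == 14).all()

    def test_weights_normalized(self, decision_model):
        assert decision_model.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_total_alternative_ranking_values(self, decision_model):
        totals = rank_alternatives(decision_model.alternatives)
        np.testing.assert_allclose(totals[["S1", "S2", "S3"]], [0.35, 0.70, 1.05])

    def test_rank_total_violation_names_alternative(self, decision_model):
        ranks = decision_model.ranks.copy()
        ranks.loc["S2", "A1"] += 1
        with pytest.raises(ValueError, match="S2"):
            SmartDecision(
                dimension_weights=dict(decision_model.weights),
                attribute_dimensions=decision_model.attribute_dimensions,
                expected_rank_total=14,
            ).fit(ranks)

    def test_incomplete_assignment_lists_missing_cells(self, decision_model):
        ranks = decision_model.ranks.drop(columns=["A4"])
        with pytest.raises(ValueError, match="A4"):
            SmartDecision(
                dimension_weights=dict(decision_model.weights),
                attribute_dimensions=decision_model.attribute_dimensions,
            ).fit(ranks)


class TestAdditiveUtility:
    def test_weighted_sum_examples(self):
        scores = pd.DataFrame(
            {"K1": [1.05, 0.35], "K2": [2.10, 2.70], "K3": [0.60, 0.20], "K4": [0.15, 0.45]},
            index=["S3", "S1"],
        )
        w = {"K1": 0.35, "K2": 0.30, "K3": 0.20, "K4": 0.15}
        u = additive_utility(scores, w)
        assert u["S3"] == pytest.approx(1.14, abs=5e-3)
        assert u["S1"] == pytest.approx(1.04, abs=5e-3)

    def test_basis_weight_vector_selects_one_dimension(self):
        scores = pd.DataFrame({"K1": [2.0], "K2": [9.0]}, index=["S1"])
        u = additive_utility(scores, {"K1": 1.0, "K2": 1e-12})
        assert u["S1"] == pytest.approx(2.0, abs=1e-9)

    def test_weight_mismatch_rejected(self):
        scores = pd.DataFrame({"K1": [1.0]}, index=["S1"])
        with pytest.raises(ValueError, match="disagree"):
            additive_utility(scores, {"K1": 0.5, "KX": 0.5})

    @given(
        scores=st.lists(
            st.tuples(st.floats(0, 5), st.floats(0, 5), st.floats(0, 5)),
            min_size=2,
            max_size=4,
        ),
        c=st.floats(-2, 2),
    )
    def test_constant_shift_structure(self, scores, c):
        # with sum(w)=1, adding c to every dimension score shifts every U_j by c
        df = pd.DataFrame(scores, columns=["K1", "K2", "K3"])
        w = {"K1": 0.5, "K2": 0.3, "K3": 0.2}
        base = additive_utility(df, w)
        shifted = additive_utility(df + c, w)
        np.testing.assert_allclose(shifted, base + c, atol=1e-9)
        assert list(base.sort_values().index) == list(shifted.sort_values().index)


class TestSelectOptimal:
    def test_argmax(self):
        alt, tie = select_optimal({"S1": 1.04, "S2": 1.09, "S3": 1.14})
        assert (alt, tie) == ("S3", False)

    def test_singleton(self):
        assert select_optimal({"S1": 0.2}) == ("S1", False)

    def test_exact_tie_flags_and_breaks_low(self):
        assert select_optimal({"S2": 1.0, "S1": 1.0}) == ("S1", True)


def _random_model(rng, n_alts=3, n_attrs=4):
    dims = [f"K{i}" for i in range(1, rng.integers(2, n_attrs + 1) + 1)]
    attr_dims = {f"A{j}": dims[rng.integers(len(dims))] for j in range(n_attrs)}
    # every dimension must own at least one attribute
    for i, d in enumerate(dims):
        attr_dims[f"A{i % n_attrs}"] = d
    raw = rng.uniform(10, 100, size=len(dims))
    weights = dict(zip(dims, smart_normalize_weights(raw)))
    ranks = pd.DataFrame(
        rng.integers(1, 4, size=(n_alts, n_attrs)),
        index=[f"S{i + 1}" for i in range(n_alts)],
        columns=list(attr_dims),
    )
    return weights, attr_dims, ranks


class TestDecisionProperties:
    def test_argmax_agrees_with_brute_force_exhaustive_2x3(self):
        weights = {"K1": 0.6, "K2": 0.4}
        attr_dims = {"A1": "K1", "A2": "K2", "A3": "K2"}
        for combo in itertools.product([1, 2, 3], repeat=6):
            ranks = pd.DataFrame(
                np.array(combo).reshape(2, 3), index=["S1", "S2"], columns=["A1", "A2", "A3"]
            )
            est = SmartDecision(dimension_weights=weights, attribute_dimensions=attr_dims).fit(ranks)
            bf = brute_force_utilities(ranks, weights, attr_dims)
            np.testing.assert_allclose(est.utilities_[list(bf)], list(bf.values()), atol=1e-12)
            best = min(sorted(bf), key=lambda a: (-bf[a], a))
            assert est.optimal_ == best

    def test_argmax_agrees_with_brute_force_random_3x4(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            weights, attr_dims, ranks = _random_model(rng)
            est = SmartDecision(dimension_weights=weights, attribute_dimensions=attr_dims).fit(ranks)
            bf = brute_force_utilities(ranks, weights, attr_dims)
            np.testing.assert_allclose(est.utilities_[list(bf)], list(bf.values()), atol=1e-12)
            assert est.optimal_ == min(sorted(bf), key=lambda a: (-bf[a], a))

    def test_increasing_a_rank_strictly_increases_utility(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            weights, attr_dims, ranks = _random_model(rng)
            est = SmartDecision(dimension_weights=weights, attribute_dimensions=attr_dims)
            u0 = est.transform(ranks)
            alt = ranks.index[rng.integers(len(ranks))]
            attr = ranks.columns[rng.integers(ranks.shape[1])]
            bumped = ranks.copy()
            bumped.at[alt, attr] += 1
            u1 = est.transform(bumped)
            assert u1[alt] > u0[alt]
            others = [a for a in ranks.index if a != alt]
            assert (u1[others] == u0[others]).all()
            # final rank position never worsens
            pos0 = sorted(ranks.index, key=lambda a: (-u0[a], a)).index(alt)
            pos1 = sorted(ranks.index, key=lambda a: (-u1[a], a)).index(alt)
            assert pos1 <= pos0

    def test_dominance_implies_strictly_greater_utility(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            weights, attr_dims, ranks = _random_model(rng, n_alts=2)
            dominant = ranks.iloc[0] + rng.integers(0, 2, size=ranks.shape[1])
            if (dominant == ranks.iloc[0]).all():
                dominant = dominant.copy()
                dominant.iloc[rng.integers(len(dominant))] += 1
            ranks.iloc[1] = dominant  # S2 dominates S1
            est = SmartDecision(dimension_weights=weights, attribute_dimensions=attr_dims).fit(ranks)
            assert est.utilities_["S2"] > est.utilities_["S1"]


class TestSensitivity:
    def test_zero_delta_changes_nothing(self, decision_model):
        report = sensitivity_analysis(decision_model, deltas=[0.0])
        assert report.baseline_optimal == "S3"
        base_u = performance_matrix(decision_model).utilities
        for rec in report.records:
            assert not rec.reversed
            np.testing.assert_allclose(rec.utilities[base_u.index], base_u, atol=1e-12)

    def test_grid_agrees_with_enumeration_oracle(self, decision_model):
        deltas = np.round(np.arange(0.01, 1.0, 0.01), 2)
        report = sensitivity_analysis(decision_model, deltas=deltas)
        weights = decision_model.weights
        attr_dims = decision_model.attribute_dimensions
        for dim in weights.index:
            found = None
            for d in deltas:
                for sign in (+1, -1):
                    w_new = _perturbed_weights(weights, dim, float(d), sign)
                    if w_new is None:
                        continue
                    bf = brute_force_utilities(decision_model.ranks, dict(w_new), attr_dims)
                    best = min(sorted(bf), key=lambda a: (-bf[a], a))
                    if best != report.baseline_optimal and found is None:
                        found = float(d)
                if found is not None:
                    break
            assert report.min_reversal_delta[dim] == found

    def test_dominant_alternative_never_reverses(self):
        model = DecisionModel.from_dict(
            {
                "dimensions": [
                    {"id": "K1", "weight": 0.5},
                    {"id": "K2", "weight": 0.5},
                ],
                "attributes": [
                    {"id": "A1", "dimension": "K1"},
                    {"id": "A2", "dimension": "K2"},
                ],
                "alternatives": [{"id": "S1"}, {"id": "S2"}],
                "ranks": {"S1": {"A1": 3, "A2": 3}, "S2": {"A1": 1, "A2": 1}},
            }
        )
        report = sensitivity_analysis(model, deltas=np.round(np.arange(0.01, 1.0, 0.01), 2))
        assert report.baseline_optimal == "S1"
        assert all(d is None for d in report.min_reversal_delta.values())

    def test_out_of_range_perturbations_skipped_with_note(self, decision_model):
        report = sensitivity_analysis(decision_model, deltas=[0.9])
        skipped = [r for r in report.records if r.note is not None]
        assert skipped and all("skipped" in r.note for r in skipped)
        with pytest.raises(ValueError):
            sensitivity_analysis(decision_model, deltas=[1.0])


class TestModelValidation:
    def test_weights_must_sum_to_one(self, decision_model):
        with pytest.raises(ValueError, match="sum to 1"):
            SmartDecision(
                dimension_weights={"K1": 0.5, "K2": 0.6},
                attribute_dimensions={"A1": "K1", "A2": "K2"},
            ).fit(pd.DataFrame({"A1": [1], "A2": [1]}, index=["S1"]))

    def test_yaml_round_trip(self, tmp_path, decision_model):
        import yaml

        cfg = {
            "name": "toy",
            "dimensions": [{"id": "K1", "weight": 0.4}, {"id": "K2", "weight": 0.6}],
            "attributes": [{"id": "A1", "dimension": "K1"}, {"id": "A2", "dimension": "K2"}],
            "alternatives": [{"id": "S1"}, {"id": "S2", "importance_rank": 2}],
            "ranks": {"S1": {"A1": 1, "A2": 2}, "S2": {"A1": 2, "A2": 1}},
        }
        p = tmp_path / "toy.yaml"
        p.write_text(yaml.safe_dump(cfg))
        model = DecisionModel.from_yaml(p)
        assert model.weights.sum() == pytest.approx(1.0)
        res = performance_matrix(model)
        # S1: 0.4*(1*0.4) + 0.6*(2*0.6) = 0.16 + 0.72
        assert res.utilities["S1"] == pytest.approx(0.88)

    def test_raw_scores_normalized_at_load(self):
        model = DecisionModel.from_dict(
            {
                "dimensions": [
                    {"id": "K1", "raw_score": 70},
                    {"id": "K2", "raw_score": 30},
                ],
                "attributes": [
                    {"id": "A1", "dimension": "K1"},
                    {"id": "A2", "dimension": "K2"},
                ],
                "alternatives": [{"id": "S1"}],
                "ranks": {"S1": {"A1": 1, "A2": 1}},
            }
        )
        np.testing.assert_allclose(model.weights, [0.7, 0.3])

    def test_sklearn_param_round_trip(self, decision_model):
        est = SmartDecision(
            dimension_weights=dict(decision_model.weights),
            attribute_dimensions=decision_model.attribute_dimensions,
            expected_rank_total=14,
        )
        clone_params = SmartDecision(**est.get_params()).get_params()
        assert clone_params == est.get_params()
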