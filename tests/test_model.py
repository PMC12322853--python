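import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pymacbeth import (
    CardinalScale,
    CriterionSpec,
    FrameworkModel,
    InvalidInputError,
    JudgmentMatrix,
    ReferenceLevels,
    ValueFunction,
    WeightVector,
    build_value_function,
    derive_weights,
    evaluate_value,
    generate_consistent_judgments,
    score_alternative,
)
from pymacbeth.model import read_model_json, write_model_json

MPFS = CriterionSpec("mpfs", "median PFS", "benefit", units="months")


def _scale(vals):
    return CardinalScale(
        values={f"L{k+1}": v for k, v in enumerate(vals)},
        anchors=("L1", "L5"),
        thresholds=(1, 2, 3, 4, 5, 6),
    )


class TestValueFunction:
    def test_interpolates_between_breakpoints(self):
        levels = ReferenceLevels(MPFS, (50.2, 40, 25, 10, 5))
        fn = build_value_function(levels, _scale([100, 80, 60, 20, 0]))
        # slope between 40 and 25 months is (80-60)/(40-25)
        slope = (evaluate_value(fn, 40) - evaluate_value(fn, 25)) / (40 - 25)
        assert slope == pytest.approx((80 - 60) / (40 - 25))
        for x, v in fn.breakpoints:
            assert evaluate_value(fn, x) == pytest.approx(v)

    def test_flat_segments_allowed(self):
        levels = ReferenceLevels(MPFS, (50, 40, 25, 10, 5))
        fn = build_value_function(levels, _scale([100, 60, 60, 20, 0]))
        assert evaluate_value(fn, 30) == pytest.approx(60)

    def test_clamped_outside_elicited_range(self):
        levels = ReferenceLevels(MPFS, (50, 40, 25, 10, 5))
        fn = build_value_function(levels, _scale([100, 80, 60, 20, 0]))
        assert evaluate_value(fn, 80) == 100.0
        assert evaluate_value(fn, 1) == 0.0

    @settings(max_examples=40, deadline=None)
    @given(st.floats(min_value=-50, max_value=200, allow_nan=False))
    def test_never_outside_0_100(self, x):
        levels = ReferenceLevels(MPFS, (50, 40, 25, 10, 5))
        fn = build_value_function(levels, _scale([100, 80, 60, 20, 0]))
        assert 0.0 <= evaluate_value(fn, x) <= 100.0

    def test_harm_criterion_layout(self):
        harm = CriterionSpec("sae", "serious AEs", "harm", units="%")
        levels = ReferenceLevels(harm, (4, 5, 25, 60, 72))
        fn = build_value_function(levels, _scale([100, 80, 50, 20, 0]))
        assert evaluate_value(fn, 4) == pytest.approx(100)
        assert evaluate_value(fn, 72) == pytest.approx(0)
        assert evaluate_value(fn, 15) > evaluate_value(fn, 40)

    def test_wrong_scale_items_rejected(self):
        levels = ReferenceLevels(MPFS, (50, 40, 25, 10, 5))
        bad = CardinalScale({"A": 100.0, "B": 0.0}, ("A", "B"), (1, 2, 3, 4, 5, 6))
        with pytest.raises(InvalidInputError):
            build_value_function(levels, bad)

    def test_categorical_lookup_and_unknown_category(self):
        cat = CriterionSpec("route", "administration", "benefit", "categorical")
        fn = ValueFunction(criterion=cat, category_map={"oral": 100.0, "iv": 0.0})
        assert evaluate_value(fn, "oral") == 100.0
        with pytest.raises(InvalidInputError):
            evaluate_value(fn, "intrathecal")

    def test_non_finite_performance_rejected(self):
        levels = ReferenceLevels(MPFS, (50, 40, 25, 10, 5))
        fn = build_value_function(levels, _scale([100, 80, 60, 20, 0]))
        with pytest.raises(InvalidInputError):
            evaluate_value(fn, float("nan"))


class TestWeights:
    def test_symmetric_swings_get_equal_weights(self):
        m = JudgmentMatrix(
            ["sw_a", "sw_b", "sw_c", "base"],
            {
                ("sw_a", "sw_b"): 0,
                ("sw_a", "sw_c"): 0,
                ("sw_b", "sw_c"): 0,
                ("sw_a", "base"): 4,
                ("sw_b", "base"): 4,
                ("sw_c", "base"): 4,
            },
        )
        wv = derive_weights(m, {"sw_a": "a", "sw_b": "b", "sw_c": "c"}, baseline="base")
        assert wv.weights == pytest.approx({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3})

    def test_stronger_swing_gets_larger_weight(self):
        m = JudgmentMatrix(
            ["sw_a", "sw_b", "base"],
            {("sw_a", "sw_b"): 3, ("sw_a", "base"): 5, ("sw_b", "base"): 2},
        )
        wv = derive_weights(m, {"sw_a": "a", "sw_b": "b"}, baseline="base")
        assert wv["a"] > wv["b"]
        assert sum(wv.weights.values()) == pytest.approx(1.0)

    def test_noiseless_swing_round_trip(self, swing_truth):
        m = generate_consistent_judgments(swing_truth)
        wv = derive_weights(
            m, {"sw_a": "a", "sw_b": "b", "sw_c": "c"}, baseline="baseline"
        )
        true_w = {"a": 0.5, "b": 0.3, "c": 0.2}
        assert sorted(wv.weights, key=wv.weights.get) == sorted(true_w, key=true_w.get)
        resolution = (100.0 / 7.0) / 200.0  # one category width over total swing value
        for cid, w in true_w.items():
            assert abs(wv[cid] - w) <= resolution

    def test_baseline_preferred_over_swing_rejected(self):
        m = JudgmentMatrix(["sw_a", "base"], {("base", "sw_a"): 2})
        with pytest.raises(InvalidInputError):
            derive_weights(m, {"sw_a": "a"}, baseline="base")

    def test_weight_vector_validation(self):
        with pytest.raises(InvalidInputError):
            WeightVector({"a": 0.7, "b": 0.4})
        with pytest.raises(InvalidInputError):
            WeightVector({"a": 1.2, "b": -0.2})


def _toy_model():
    c1 = CriterionSpec("eff", "efficacy", "benefit")
    c2 = CriterionSpec("tox", "toxicity", "harm")
    fn1 = ValueFunction(criterion=c1, breakpoints=((100, 100.0), (80, 75.0), (60, 50.0), (40, 25.0), (20, 0.0)))
    fn2 = ValueFunction(criterion=c2, breakpoints=((0, 100.0), (10, 75.0), (20, 50.0), (30, 25.0), (40, 0.0)))
    return FrameworkModel(
        criteria=(c1, c2),
        value_functions={"eff": fn1, "tox": fn2},
        weights=WeightVector({"eff": 0.5, "tox": 0.5}),
    )


class TestScoring:
    def test_best_levels_score_100(self):
        model = _toy_model()
        assert model.score({"eff": 100, "tox": 0}).overall == pytest.approx(100.0)

    def test_worst_levels_score_0(self):
        model = _toy_model()
        assert model.score({"eff": 20, "tox": 40}).overall == pytest.approx(0.0)

    def test_equal_weights_average_the_value_scores(self):
        model = _toy_model()
        bd = model.score({"eff": 80, "tox": 30})  # values 75 and 25
        assert bd.overall == pytest.approx(50.0)
        assert bd.values == pytest.approx({"eff": 75.0, "tox": 25.0})

    def test_overall_is_weighted_sum_of_values(self):
        model = _toy_model()
        bd = model.score({"eff": 73.5, "tox": 12.0})
        expected = sum(model.weights[cid] * v for cid, v in bd.values.items())
        assert bd.overall == pytest.approx(expected, abs=1e-9)
        assert 0.0 <= bd.overall <= 100.0

    def test_missing_criterion_listed_in_error(self):
        model = _toy_model()
        with pytest.raises(InvalidInputError, match="tox"):
            score_alternative(model, {"eff": 80})

    def test_breakdown_frame_has_one_row_per_criterion(self):
        bd = _toy_model().score({"eff": 80, "tox": 30})
        assert list(bd.to_frame()["criterion_id"]) == ["eff", "tox"]


def test_model_json_round_trip(tmp_path, lymphoma_model):
    path = tmp_path / "model.json"
    write_model_json(lymphoma_model, path)
    back = read_model_json(path)
    assert [c.id for c in back.criteria] == [c.id for c in lymphoma_model.criteria]
    assert back.weights.weights == pytest.approx(lymphoma_model.weights.weights)
    perf = {
        "qaly": 5.0, "mpfs": 25.7, "orr": 70.0, "sae": 20.0, "ae_tdr": 8.0,
        "admc": 150e3, "dosage_admin": "outpatient infusion",
        "n_alternatives": "2", "mortality": 45.0,
    }
    assert back.score(perf).overall == pytest.approx(
        lymphoma_model.score(perf).overall, abs=1e-9
    )
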