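import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pymacbeth import (
    ConsistencyError,
    InvalidInputError,
    JudgmentMatrix,
    check_consistency,
    derive_scale,
    rescale,
)
from pymacbeth.elicitation import _canonical_solution
from pymacbeth.synthetic import GroundTruth, generate_consistent_judgments

from _oracles import brute_force_consistent, random_judgment_case


class TestCheckConsistency:
    def test_symmetric_chain_is_consistent(self, three_item_matrix):
        # A>B weak, B>C weak, A>C strong admits a scale (e.g. 0/2/4 with
        # unit-spaced thresholds), confirmed by the brute-force oracle
        assert brute_force_consistent(
            three_item_matrix.items, three_item_matrix.judgments
        )
        report = check_consistency(three_item_matrix)
        assert report.consistent and report.witness == ()

    def test_equality_judgment_is_consistent(self):
        m = JudgmentMatrix(["A", "B"], {("A", "B"): 0})
        assert check_consistency(m).consistent

    def test_compressed_long_gap_is_inconsistent(self):
        # two strong sub-differences cannot add up to a very weak one
        m = JudgmentMatrix(["A", "B", "C"], {("A", "B"): 4, ("B", "C"): 4, ("A", "C"): 1})
        assert not brute_force_consistent(m.items, m.judgments)
        report = check_consistency(m)
        assert not report.consistent
        assert len(report.witness) >= 1

    def test_cyclic_strict_preference_reported_not_raised(self):
        m = JudgmentMatrix(["A", "B", "C"], {("A", "B"): 2, ("B", "C"): 2, ("C", "A"): 2})
        report = check_consistency(m)
        assert not report.consistent

    def test_empty_matrix_is_invalid(self):
        with pytest.raises(InvalidInputError):
            check_consistency(JudgmentMatrix(["A", "B"], {}))

    def test_witness_removal_restores_feasibility(self):
        m = JudgmentMatrix(["A", "B", "C"], {("A", "B"): 4, ("B", "C"): 4, ("A", "C"): 1})
        report = check_consistency(m)
        repaired = m.without(report.witness)
        assert check_consistency(repaired).consistent

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_feasibility_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        items, judgments = random_judgment_case(rng)
        if not judgments:
            return
        m = JudgmentMatrix(items, judgments)
        assert check_consistency(m).consistent == brute_force_consistent(items, judgments)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_removing_any_judgment_keeps_consistency(self, seed):
        rng = np.random.default_rng(seed)
        items, judgments = random_judgment_case(rng)
        if not judgments:
            return
        m = JudgmentMatrix(items, judgments)
        if not check_consistency(m).consistent:
            return
        for pair in list(m.judgments):
            sub = m.without([pair])
            if sub.judgments:
                assert check_consistency(sub).consistent


class TestDeriveScale:
    def test_two_items_anchor_at_100_and_0(self):
        m = JudgmentMatrix(["A", "B"], {("A", "B"): 3})
        s = derive_scale(m, "A", "B")
        assert s.values == {"A": 100.0, "B": 0.0}

    def test_symmetric_gaps_put_middle_item_at_50(self, three_item_matrix):
        s = derive_scale(three_item_matrix, "A", "C")
        assert s.values["B"] == pytest.approx(50.0, abs=1e-9)

    def test_thresholds_strictly_increasing(self, three_item_matrix):
        s = derive_scale(three_item_matrix, "A", "C")
        assert all(a < b for a, b in zip(s.thresholds, s.thresholds[1:]))

    def test_deterministic_bitwise(self, three_item_matrix):
        s1 = derive_scale(three_item_matrix, "A", "C")
        s2 = derive_scale(three_item_matrix, "A", "C")
        assert s1.values == s2.values
        assert s1.thresholds == s2.thresholds

    def test_inconsistent_matrix_raises_with_report(self):
        m = JudgmentMatrix(["A", "B", "C"], {("A", "B"): 4, ("B", "C"): 4, ("A", "C"): 1})
        with pytest.raises(ConsistencyError) as exc:
            derive_scale(m, "A", "C")
        assert exc.value.report is not None and not exc.value.report.consistent

    def test_equal_anchors_rejected(self, three_item_matrix):
        with pytest.raises(InvalidInputError):
            derive_scale(three_item_matrix, "A", "A")

    def test_dominated_top_rejected(self, three_item_matrix):
        with pytest.raises(InvalidInputError):
            derive_scale(three_item_matrix, "B", "C")

    def test_four_item_round_trip_within_one_category_width(self):
        truth = GroundTruth(values={"a": 100.0, "b": 70.0, "c": 30.0, "d": 0.0})
        m = generate_consistent_judgments(truth)
        s = derive_scale(m, "a", "d")
        order = sorted(truth.values, key=lambda it: -truth.values[it])
        recovered = sorted(s.values, key=lambda it: -s.values[it])
        assert recovered == order
        category_width = 100.0 / 7.0
        for item, v in truth.values.items():
            assert abs(s.values[item] - v) <= category_width

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_noiseless_generation_recovers_true_ranking(self, seed):
        # true values separated by at least one category width, so every
        # pair gets a strict category and the ranking must come back exact
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        min_gap = 100.0 / 7.0
        gaps = min_gap + rng.uniform(
            0, (100.0 - min_gap * (n - 1)) / (n - 1), size=n - 1
        )
        vals = np.concatenate([[100.0], 100.0 - np.cumsum(gaps)])
        truth = GroundTruth(values={f"x{k}": float(v) for k, v in enumerate(vals)})
        m = generate_consistent_judgments(truth)
        assert check_consistency(m).consistent
        s = derive_scale(m, "x0", f"x{n-1}")
        for a in range(n):
            for b in range(a + 1, n):
                assert s.values[f"x{a}"] > s.values[f"x{b}"]

    def test_scale_invariants_hold_on_random_consistent_matrices(self, rng):
        checked = 0
        while checked < 25:
            items, judgments = random_judgment_case(rng)
            if not judgments:
                continue
            m = JudgmentMatrix(items, judgments)
            if not check_consistency(m).consistent:
                continue
            raw, _ = _canonical_solution(m)
            top = max(raw, key=raw.get)
            bottom = min(raw, key=raw.get)
            if raw[top] - raw[bottom] <= 1e-9:
                continue
            s = derive_scale(m, top, bottom)
            assert s.values[top] == 100.0 and s.values[bottom] == 0.0
            assert all(-1e-9 <= v <= 100 + 1e-9 for v in s.values.values())
            for (i, j), cat in m.judgments.items():
                if cat > 0:
                    assert s.values[i] > s.values[j]
                else:
                    assert abs(s.values[i] - s.values[j]) < 1e-6
            checked += 1


class TestRescale:
    def test_identity(self, three_item_matrix):
        s = derive_scale(three_item_matrix, "A", "C")
        s2 = rescale(s, 100.0, 0.0)
        assert s2.values == pytest.approx(s.values)

    def test_unit_interval(self):
        from pymacbeth.elicitation import CardinalScale

        s = CardinalScale({"A": 100.0, "B": 50.0, "C": 0.0}, ("A", "C"), (1, 2, 3, 4, 5, 6))
        s2 = rescale(s, 1.0, 0.0)
        assert s2.values == pytest.approx({"A": 1.0, "B": 0.5, "C": 0.0})

    def test_difference_ratios_invariant(self, three_item_matrix):
        s = derive_scale(three_item_matrix, "A", "C")
        s2 = rescale(s, 7.0, 2.0)
        r1 = (s.values["A"] - s.values["B"]) / (s.values["B"] - s.values["C"])
        r2 = (s2.values["A"] - s2.values["B"]) / (s2.values["B"] - s2.values["C"])
        assert r1 == pytest.approx(r2)

    def test_invalid_interval_rejected(self, three_item_matrix):
        s = derive_scale(three_item_matrix, "A", "C")
        with pytest.raises(InvalidInputError):
            rescale(s, 0.0, 0.0)
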