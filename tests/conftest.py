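import numpy as np
import pytest

from pymacbeth import (
    GroundTruth,
    JudgmentMatrix,
    packaged_lymphoma_model,
)


@pytest.fixture
def three_item_matrix() -> JudgmentMatrix:
    """A small consistent matrix with symmetric gaps (A-B and B-C both weak)."""
    return JudgmentMatrix(
        ["A", "B", "C"], {("A", "B"): 2, ("B", "C"): 2, ("A", "C"): 4}
    )


@pytest.fixture
def lymphoma_model():
    return packaged_lymphoma_model()


@pytest.fixture
def swing_truth() -> GroundTruth:
    """Swing-weighting ground truth for criterion weights 0.5 / 0.3 / 0.2."""
    return GroundTruth(
        values={"sw_a": 100.0, "sw_b": 60.0, "sw_c": 40.0, "baseline": 0.0}
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
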