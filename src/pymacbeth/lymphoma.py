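"""The packaged nine-criterion lymphoma value framework.

This module ships the published framework as a ready-to-use
:class:`~pymacbeth.model.FrameworkModel`: nine criteria covering efficacy
(QALYs, median progression-free survival, objective response rate), safety
(serious adverse events grade 3-4, treatment discontinuation due to adverse
events), economics (annual direct medical costs), feasibility (dosage and
administration), innovation (number of alternative medicines with the same
indication and mechanism) and disease severity (mortality of disease),
with the published mean stakeholder weights.

Only the mPFS value function's central linear segment is published
(``v = 1.58 x + 20.75`` value points per month around 25.7 months); it is
stored exactly, with the surrounding breakpoints chosen as configuration so
that the 20-30 month segment reproduces that line.  The remaining eight
value functions were elicited from stakeholder panels whose judgment
matrices are not public, so the packaged ones are clearly flagged
``placeholder``; the elicitation engine re-derives real ones from new
judgment matrices.

The two-stage criteria selection that produced the framework is also
replayable: :func:`candidate_criteria` carries the 25 candidates in their
published importance ranking (mean scores are synthetic stand-ins chosen
only to respect that ranking and the 3.5 exclusion threshold), and
:func:`selection_ledger` the published exclusions and substitutions.
"""

from __future__ import annotations

from .levels import CriterionSpec
from .model import FrameworkModel, ValueFunction, WeightVector
from .selection import CandidateCriterion, SelectionLedger

__all__ = [
    "packaged_lymphoma_model",
    "candidate_criteria",
    "selection_ledger",
    "FINAL_CRITERIA_NAMES",
]

# criterion specs, in the order the framework reports them
_CRITERIA = (
    CriterionSpec("qaly", "quality-adjusted life years (QALYs)", "benefit", "numeric", "QALYs"),
    CriterionSpec("mpfs", "median progression-free survival", "benefit", "numeric", "months"),
    CriterionSpec("orr", "objective response rate", "benefit", "numeric", "%"),
    CriterionSpec("sae", "incidence of serious adverse events (grade 3-4)", "harm", "numeric", "%"),
    CriterionSpec("ae_tdr", "treatment discontinuation rate due to adverse events", "harm", "numeric", "%"),
    CriterionSpec("admc", "annual direct medical costs", "harm", "numeric", "CNY/year"),
    CriterionSpec("dosage_admin", "dosage and administration", "benefit", "categorical"),
    CriterionSpec("n_alternatives", "number of alternative medicines with the same indication and mechanism", "harm", "categorical"),
    CriterionSpec("mortality", "mortality of disease", "benefit", "numeric", "%"),
)

# published mean stakeholder weights, in basis points of 1 (they sum to 10000)
_WEIGHTS_BP = {
    "qaly": 1743,
    "mpfs": 1611,
    "orr": 1439,
    "sae": 1354,
    "ae_tdr": 1183,
    "admc": 1130,
    "dosage_admin": 708,
    "n_alternatives": 459,
    "mortality": 373,
}

# mPFS breakpoints: the 20-30 month segment is the published line
# v = 1.58 x + 20.75 (52.35 value points at 20 months, 68.15 at 30);
# the outer breakpoints are configuration, not published values.
_MPFS_BREAKPOINTS = ((50.0, 100.0), (40.0, 85.0), (30.0, 68.15), (20.0, 52.35), (5.0, 0.0))

# placeholder breakpoints for the eight criteria whose elicited functions
# are not public: plausible reference levels with equally spaced values
_PLACEHOLDER_BREAKPOINTS = {
    "qaly": ((9.6, 100.0), (8.0, 75.0), (5.0, 50.0), (2.0, 25.0), (1.6, 0.0)),
    "orr": ((96.0, 100.0), (80.0, 75.0), (65.0, 50.0), (40.0, 25.0), (32.0, 0.0)),
    "sae": ((4.0, 100.0), (5.0, 75.0), (25.0, 50.0), (60.0, 25.0), (72.0, 0.0)),
    "ae_tdr": ((1.6, 100.0), (2.0, 75.0), (10.0, 50.0), (30.0, 25.0), (36.0, 0.0)),
    "admc": ((40e3, 100.0), (50e3, 75.0), (200e3, 50.0), (800e3, 25.0), (960e3, 0.0)),
    "mortality": ((84.0, 100.0), (70.0, 75.0), (40.0, 50.0), (10.0, 25.0), (8.0, 0.0)),
}

_PLACEHOLDER_CATEGORIES = {
    "dosage_admin": {
        "oral, at home": 100.0,
        "oral with routine monitoring": 75.0,
        "outpatient infusion": 50.0,
        "inpatient infusion": 25.0,
        "inpatient, complex administration": 0.0,
    },
    "n_alternatives": {
        "none": 100.0,
        "1": 75.0,
        "2": 50.0,
        "3": 25.0,
        "4 or more": 0.0,
    },
}


def packaged_lymphoma_model() -> FrameworkModel:
    """The nine-criterion lymphoma framework with published weights.

    The weight vector and the central mPFS segment are published values;
    every other value function is a flagged placeholder that users should
    replace by re-eliciting with their own stakeholder panel.
    """
    vfs: dict[str, ValueFunction] = {}
    notes: dict[str, str] = {"weights": "printed"}
    for spec in _CRITERIA:
        if spec.id == "mpfs":
            vfs[spec.id] = ValueFunction(
                criterion=spec, breakpoints=_MPFS_BREAKPOINTS, provenance="printed",
            )
            notes[spec.id] = (
                "printed central segment (slope 1.58, intercept 20.75, "
                "20-30 months); outer breakpoints are configuration"
            )
        elif spec.kind == "categorical":
            vfs[spec.id] = ValueFunction(
                criterion=spec,
                category_map=_PLACEHOLDER_CATEGORIES[spec.id],
                provenance="placeholder",
            )
            notes[spec.id] = "placeholder categories; published ones unavailable"
        else:
            vfs[spec.id] = ValueFunction(
                criterion=spec,
                breakpoints=_PLACEHOLDER_BREAKPOINTS[spec.id],
                provenance="placeholder",
            )
            notes[spec.id] = "placeholder breakpoints; published ones unavailable"
    total = sum(_WEIGHTS_BP.values())
    weights = WeightVector({cid: bp / total for cid, bp in _WEIGHTS_BP.items()})
    return FrameworkModel(
        criteria=_CRITERIA, value_functions=vfs, weights=weights, notes=notes,
    )


# The 25 candidate criteria in their published importance ranking (most to
# least important).  The published survey reports only this ranking and
# which candidates cleared the 3.5 threshold (the first 18); the mean
# scores attached here are SYNTHETIC stand-ins, linearly spaced so that
# exactly the first 18 exceed 3.5.
_CANDIDATES_RANKED = (
    "median overall survival",
    "annual direct medical costs",
    "health-related quality of life",
    "improvement in tumor-related symptoms",
    "clinical irreplaceability",
    "median progression-free survival",
    "treatment discontinuation rate due to adverse events",
    "objective response rate",
    "complete response",
    "cost-utility",
    "duration of response",
    "incidence of serious adverse events (grade 3-4)",
    "unmet clinical needs",
    "severity of disease",
    "treatment-free interval",
    "tail of the curve",
    "innovation in therapeutic mechanisms",
    "changes in drug delivery modalities",
    "sequence of clinical treatments",
    "budget impact",
    "prevalence",
    "burden on caregivers",
    "equity",
    "increase in social productivity",
    "incidence of adverse events (grade 1-2)",
)

_N_RETAINED = 18


def candidate_criteria() -> list[CandidateCriterion]:
    """The 25 ranked candidates with synthetic mean importance scores."""
    candidates = []
    for rank, name in enumerate(_CANDIDATES_RANKED):
        if rank < _N_RETAINED:
            score = 4.8 - rank * (4.8 - 3.6) / (_N_RETAINED - 1)
        else:
            k = rank - _N_RETAINED
            score = 3.5 - k * (3.5 - 2.3) / (len(_CANDIDATES_RANKED) - _N_RETAINED - 1)
        candidates.append(CandidateCriterion(name=name, mean_score=round(score, 3)))
    return candidates


def selection_ledger() -> SelectionLedger:
    """Published exclusions and substitutions applied after the score filter."""
    return SelectionLedger(
        exclusions=(
            ("median overall survival", "data-unavailable"),
            ("improvement in tumor-related symptoms", "data-unavailable"),
            ("duration of response", "data-unavailable"),
            ("treatment-free interval", "data-unavailable"),
            ("complete response", "redundant"),
            ("cost-utility", "redundant"),
            ("unmet clinical needs", "undefined/unquantifiable"),
            ("tail of the curve", "confounded"),
            ("innovation in therapeutic mechanisms", "undefined/unquantifiable"),
        ),
        substitutions=(
            ("health-related quality of life", "quality-adjusted life years (QALYs)"),
            ("changes in drug delivery modalities", "dosage and administration"),
            ("severity of disease", "mortality of disease"),
            (
                "clinical irreplaceability",
                "number of alternative medicines with the same indication and mechanism",
            ),
        ),
    )


#: The nine criteria of the final framework value tree.
FINAL_CRITERIA_NAMES = frozenset(
    {
        "quality-adjusted life years (QALYs)",
        "median progression-free survival",
        "objective response rate",
        "incidence of serious adverse events (grade 3-4)",
        "treatment discontinuation rate due to adverse events",
        "annual direct medical costs",
        "dosage and administration",
        "number of alternative medicines with the same indication and mechanism",
        "mortality of disease",
    }
)
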