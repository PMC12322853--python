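# pymacbeth

A toolkit for MACBETH-based multi-criteria value assessment of health
technologies, packaged with a reusable nine-criterion additive value
framework for lymphoma therapies.

MACBETH (Measuring Attractiveness by a Categorical Based Evaluation
Technique) elicits preferences without asking anyone for numbers: a
stakeholder compares pairs of options and states the *difference of
attractiveness* on a seven-category semantic scale (no difference, very
weak, weak, moderate, strong, very strong, extreme). A linear program then
converts those ordinal judgments into a cardinal interval scale — or
reports exactly which judgments are mutually inconsistent.

The package is aimed at health-technology-assessment and health-economics
researchers who want to build or apply multi-attribute value models
(MAVT/MCDA) with qualitative elicitation, and at anyone who wants to score
lymphoma therapies with the packaged framework.

## The model

A therapy's overall value is the weighted sum of per-criterion value
scores:

```
V(drug) = Σ_j  w_j · v_j(x_j),      Σ_j w_j = 1,  w_j ≥ 0,
```

where `x_j` is the drug's performance on criterion *j* (e.g. months of
median progression-free survival) and `v_j` is a piecewise-linear value
function through five performance reference levels `L1 … L5` (best to
worst), anchored at `v_j(L1) = 100` and `v_j(L5) = 0`. Levels 2/3/4 are
the best, median and worst observed performances across comparator drugs,
and L1/L5 bracket the observed range by ±20 %.

The engine provides:

- **`derive_scale`** — the MACBETH LP: find item values `v_i ≥ 0` and
  thresholds `t_1 < … < t_6` such that a category-`k` judgment on `(i, j)`
  places `v_i − v_j` inside `[t_k, t_{k+1})` (category 6: `≥ t_6`;
  category 0: equality). The canonical solution (min-max objective plus
  lexicographic tie-break) is deterministic; it is rescaled so chosen
  anchors sit at 100 and 0.
- **`check_consistency`** — LP feasibility, with a greedy minimal witness
  of conflicting judgments when infeasible.
- **`derive_weights`** — qualitative swing weighting: a judgment matrix
  over hypothetical alternatives (each swings one criterion from its lower
  to its upper reference level) yields weights proportional to the derived
  scale values above the all-lower baseline.
- **`icc`** — two-way random-effects, absolute-agreement intraclass
  correlation (average- or single-measures) with F-based confidence
  intervals, for panel inter-rater reliability (< 0.4 poor, > 0.75 good).
- **`packaged_lymphoma_model`** — the published framework: QALYs (17.43 %),
  median PFS (16.11 %), objective response rate (14.39 %), serious adverse
  events grade 3–4 (13.54 %), AE-related treatment discontinuation
  (11.83 %), annual direct medical costs (11.30 %), dosage and
  administration (7.08 %), number of alternative medicines (4.59 %), and
  mortality of disease (3.73 %). Only the central mPFS value-function
  segment (`v = 1.58 x + 20.75`) is published; the other value functions
  are flagged placeholders that you should re-elicit with your own panel.

## Worked example

Score a hypothetical therapy with the packaged framework:

```python
from pymacbeth import packaged_lymphoma_model

model = packaged_lymphoma_model()
breakdown = model.score({
    "qaly": 5.0, "mpfs": 25.7, "orr": 70.0, "sae": 20.0, "ae_tdr": 8.0,
    "admc": 150e3, "dosage_admin": "outpatient infusion",
    "n_alternatives": "2", "mortality": 45.0,
})
print(breakdown.to_frame().to_string(index=False))
print(f"overall = {breakdown.overall:.3f}")
```

prints

```
  criterion_id         performance  value_score  weighted_contribution
          qaly                 5.0    50.000000               8.715000
          mpfs                25.7    61.356000               9.884452
           orr                70.0    58.333333               8.394167
           sae                20.0    56.250000               7.616250
        ae_tdr                 8.0    56.250000               6.654375
          admc            150000.0    58.333333               6.591667
  dosage_admin outpatient infusion    50.000000               3.540000
n_alternatives                   2    50.000000               2.295000
     mortality                45.0    54.166667               2.020417
overall = 55.711
```

Each row shows the raw performance, its 0–100 value score from that
criterion's value function, and the score times the criterion weight; the
overall 0–100 value is their sum. The mPFS row is the published worked
example: 25.7 months scores 1.58 × 25.70 + 20.75 = 61.356 value points.
Remember that all rows except mPFS use placeholder value functions, so the
overall number illustrates the mechanics, not a published valuation.

The same pipeline is scriptable from a shell: `pymacbeth simulate` writes
a synthetic worked dataset, and `pymacbeth check / derive / weights /
levels / score / icc` run each stage on CSV/JSON files (`pymacbeth --help`).

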