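# fallsim

Tools for conceptualizing and exercising a health-economic model of fall
prevention in older adults (≥ 65 years): a modified-Delphi consensus
analysis that selects the model's health states, events, and patient
attributes from expert-panel rating tables, and a six-state individual-level
state-transition (microsimulation) engine built on that structure, with a
synthetic parameterization layer and incremental cost-effectiveness outputs.

## Who this is for

Health-economic modellers and methodologists who want a transparent,
testable implementation of the fall-model conceptualization pipeline:
from aggregate survey ratings, through a validated model schema, to
cost-per-QALY comparisons of fall-prevention intervention arms. The
package ships the published rating tables as data, but **no empirical
parameterization exists for the simulation layer** — every hazard, cost,
utility, and effect size it runs on is a clearly-labelled synthetic
default, so simulation outputs demonstrate machinery, not real-world
cost-effectiveness.

## The model in brief

**Consensus rule.** An item rated 0–5 by a panel of *n* experts (with a
"Don't Know" option) is *included* when

    #\{ratings ≥ 4\} / n_informative ≥ 0.80,

*excluded* when ≥ 80% rate it ≤ 2, and *non-consensus* otherwise, where
`n_informative` excludes Don't Know responses. Comparisons use exact
rational arithmetic (8/10 meets the 0.80 threshold exactly); panel
averages are half-up rounded to two decimals. Non-consensus items are
re-rated in the next round together with newly proposed items.

**Model structure.** Health states are care settings — community,
residential aged care, hospital, rehabilitation hospital, death due to a
fall, death (other cause) — which keeps states mutually exclusive and
exhaustive. Clinical detail (falls; hip, vertebral and wrist fractures;
head injury, i.e. intracranial bleed; moderate and minor injuries; ED
visits; hip-fracture surgery) is carried as tracked events on each
individual's history. Per two-week cycle: at most one fall, at most one
injury per fall; hospital admission from a living setting requires a
same-cycle ED visit; hip surgery requires an admitted hip fracture.

**Economics.** Per cycle *t*, costs and QALYs accrue to the occupied
state plus any events, discounted by d(t) = (1 + r)^(−t·14/365). Arms are
compared on the cost-effectiveness frontier after removing strictly and
extended-dominated arms; ICER = Δcost/ΔQALY between adjacent frontier
arms, NMB = λ·QALY − cost.

## Worked example

Classify the bundled round-1 health-state/event ratings:

```sh
$ fallsim delphi classify --round 1 | head -4
      item_id            item_kind  round  informative_n  fraction_high  fraction_low  panel_average   category
 hip_fracture   health_state_event      1              9       1.000000      0.000000           4.89  inclusion
 hip_fracture_surgery health_state_event 1            10       1.000000      0.000000           4.80  inclusion
 head_injury    health_state_event      1             10       0.900000      0.000000           4.70  inclusion
```

`hip_fracture` was rated by 11 panelists, 2 of whom answered Don't Know:
9 informative respondents, all rating ≥ 4 (fraction_high 1.00 ≥ 0.80 →
inclusion) with mean 44/9 = 4.89. Across both rounds the classification
yields 14 included health states/events and 26 included patient
attributes (`fallsim delphi summary`), of which the model structure
incorporates 12 — five as setting states and seven as tracked events.

Run a cost-effectiveness comparison on the synthetic default scenario
(usual care plus seven intervention bundles, 400 individuals, ten-year
horizon of 260 two-week cycles shortened here to 130 for speed):

```sh
$ fallsim cea run --n 400 --seed 7 --max-cycles 130
# seed=7 n=400 lambda=50000.0 max_cycles=130 provenance=synthetic default
        arm_id   n    mean_cost     se_cost  mean_qalys  se_qalys           nmb
intervention_2 400 34678.791864 3421.106486    3.211160  0.052634 125879.216062
intervention_4 400 34798.231802 3468.338202    3.210906  0.052578 125747.046722
...
    usual_care 400 37654.971761 3787.983228    3.187280  0.052566 121709.007254
frontier: intervention_2 -> intervention_3
  intervention_2: reference
  intervention_3: 184,485 per QALY
  usual_care: strictly dominated by intervention_3: higher cost, no more effect
```

Under these synthetic parameters the fall-prevention arms avert enough
hospital and residential-care costs to dominate usual care; two arms
remain on the frontier, the step between them costing about 184,000
(synthetic currency units) per QALY gained. Every such number is a
property of the synthetic scenario, not an estimate.

## Layout

| Module | Role |
| --- | --- |
| `fallsim.delphi` | consensus classification, round bookkeeping, bundled rating tables |
| `fallsim.schema` | settings, injury/event taxonomy, attribute registry, transition topology |
| `fallsim.engine` | per-cycle microsimulation with named per-individual random substreams |
| `fallsim.scenario` | synthetic parameter sets, populations, intervention arms |
| `fallsim.cea` | discounted cost/QALY accumulation, dominance frontier, ICERs, NMB |
| `fallsim.cli` | `fallsim delphi ...` and `fallsim cea ...` commands |

See `docs/methods.md` for the modelling assumptions, parameter
conventions, and known limitations.
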