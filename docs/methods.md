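# Methods

## Consensus analysis

The consensus layer operates on aggregate rating distributions: for each
item and survey round, counts over the 0–5 scale plus a Don't Know count,
with a panel of 11 respondents in round 1 and 10 in round 2 for the
bundled tables.

Three conventions matter, and each was fixed after checking it against
every bundled table row:

- **Denominator.** Agreement fractions and panel averages exclude Don't
  Know responses. This is the only reading that reproduces the published
  outcomes: vertebral fracture in round 1 is included at 8/10 = 80%
  among informative respondents (8/11 = 72.7% would not be), and the hip
  fracture mean is 44/9 = 4.89.
- **Exact threshold comparison.** Fractions are compared with the 0.80
  threshold as exact rationals (`Fraction(8, 10) >= Fraction(4, 5)`),
  never as binary floats, so boundary cases cannot be lost to rounding.
- **Display rounding.** Panel averages are half-up rounded to two
  decimals (3.875 → 3.88, 4.375 → 4.38); this rule matches every printed
  row, though it is inferred from the printed values rather than stated
  anywhere. Raw rationals are kept internally.

Round mechanics: included and excluded items retire from rating;
non-consensus items are carried forward and re-rated with newly proposed
items; the process stops when nothing is carried forward, at high
agreement, or after a configured maximum of three rounds. Items presented
but not re-rated retain their earlier classification; re-rated items take
their latest one. Cumulative inclusion is the union of per-round
inclusion sets and is monotone in rounds.

Two source quirks are preserved deliberately rather than reconciled:
dementia/cognitive impairment was rated twice (as a biological factor and
as a health condition) and is kept as two distinct item ids; and the
source document's own counts of rated health states/events disagree
internally (23 in one place, 20 + 4 = 24 by the tables). The bundled
tables follow the tables: 24 distinct health-state/event items, 96
item-round rows in total (20 + 38 in round 1, 15 + 23 in round 2). A
checksum test pins the transcriptions.

## Model schema

Six setting states; the two death states (fall vs other cause) are
absorbing and distinct for reporting. Death by other cause was not
selected by the consensus panel but is required for states to be
exhaustive over a lifetime horizon. The default transition topology:
community ↔ residential aged care; community/residential care → hospital,
gated on a same-cycle ED visit; hospital → rehabilitation hospital,
community, or residential care; rehabilitation → community or residential
care; every living state → both death states. Whether residential aged
care → community moves occur in reality is unsettled; the topology
permits them with a probability that defaults near zero and can be set
to zero.

The incorporation report maps the 14 consensus-selected health
states/events onto this structure: 5 become states, 7 become tracked
events, "post-fall" is folded into event history as a recency flag, and
specialized dementia care is folded into the community setting (modelling
one specialized sub-setting and not others would be inconsistent, and
dementia is already carried as a patient attribute). Hence 12 of 14
incorporated.

The attribute registry holds the 26 consensus-selected patient
attributes. Value kinds are not specified by the source process; the
default is binary flags, with age continuous and polypharmacy a
medication count, chosen for parsimony.

## Microsimulation engine

Cycle length is 14 days (the one-fall-per-cycle assumption is literally
"one fall per two weeks"); the horizon is lifetime, capped at age 110,
with an optional cycle cap for bounded experiments. Within a cycle the
draw order is fixed: background mortality; fall; injury; pathway (ED →
admission → surgery); fall death; inpatient discharge; relocation. The
order is a reproducibility requirement, not a clinical claim — the
process being modelled is silent on intra-cycle timing.

- **Fall hazard.** Baseline per-cycle fall probability by setting, with
  multiplicative rate modifiers: probability p0 maps to
  1 − (1 − p0)^m for multiplier product m, exactly the effect of scaling
  the underlying exponential rate, so any positive multiplier keeps the
  probability in [0, 1]. Modifiers cover attribute effects, a per-prior-
  fall factor (capped), and a recent-fall ("post-fall") window of 6
  cycles, all defaulting to neutral (1.0).
- **Falls occur only in community and residential aged care.** In-
  hospital falls are out of scope (the interventions of interest are
  community-based); the eligible-setting set is configuration.
- **One fall per cycle, one injury per fall** are enforced structurally
  (single draws), and independently audited on emitted event logs; the
  multiple-injury share of any engine log is 0 by construction.
- **Injury taxonomy.** Hip/vertebral/wrist fracture, head injury
  (intracranial bleed only), moderate (other dislocations/fractures),
  minor (soft-tissue), or none. Only an admitted hip fracture can lead
  to surgery.
- **Fall death** is drawn conditionally on the injury type, after the
  pathway draws; a fall without injury cannot be fatal (validated).
- **Lengths of stay** are geometric in cycles (memoryless, mean ≥ 1);
  an individual admitted in a cycle is never discharged in that same
  cycle.
- **Background mortality** is a Gompertz-form per-cycle probability
  (hazard h65·e^{g·(age−65)}), calibrated only for plausibility; any
  per-cycle schedule can be substituted. Slope 0 gives the constant-
  hazard special case used in the Markov-limit tests.
- **Randomness.** One named substream per individual per purpose
  (mortality, fall, injury, pathway), derived from the master seed via
  `SeedSequence(seed, spawn_key=(individual, purpose))`. Results are
  independent of iteration order; identical (seed, parameters, cohort)
  gives byte-identical event logs.

**Markov-limit check.** With homogeneous, history-free parameters the
end-of-cycle setting process is a 6-state Markov chain. The test suite
collapses the draw tree analytically into that 6×6 matrix and compares
microsimulation occupancy with matrix powers at cycles 1, 10 and 50,
within 3 binomial standard errors at cohort size 20,000 (4,000 in the
fast unit variant). This is the designed role of the homogeneous limit:
the microsimulation exists to add heterogeneity and history, so with both
switched off it must agree with the cohort model. Cohort sizes (20,000 ×
50 cycles; 10,000 × 20 cycles for the binomial fall-count check) were
chosen to make 3-SE bands decisively tight while keeping the whole
property suite around ten seconds.

## Synthetic scenarios

No empirical parameter values exist for this model; the generator's
defaults are plausibility-scale synthetic numbers, marked
`provenance: synthetic default` in scenario metadata. Orders of
magnitude: community fall probability 0.012/cycle (≈ 0.3 falls/person-
year), several-fold higher in residential care; ~40% of falls injurious,
hip fracture 3% of community falls; hospital cycle cost 7,000 and
community 40 (unit-less synthetic currency); utilities 0.50–0.80 by
setting; annual discount rate 1.5%. Intervention arms are usual care plus
seven bundles (exercise-, environment-, vision-based combinations and a
multifactorial bundle); their rate ratios (0.55–0.90) and costs are drawn
reproducibly from the scenario seed. Intervention effects act only on the
fall hazard, not on injury splits — the simplest mechanism consistent
with fall-rate-ratio evidence — and are homogeneous across attributes,
since nothing specifies effect modification.

Populations start entirely in the community at ages 65 + Gamma(2.2, 4.8)
(mean ≈ 75.6), with independent Bernoulli attribute flags at configured
prevalences and Poisson medication counts. What this deliberately does
not emulate: attribute correlations (frailty and falls history co-occur
in reality), age-dependent prevalences, time-varying attributes (fear of
falling is static), very-frequent-faller subpopulations, and seasonal or
secular trends. Passing tests therefore demonstrate correctness of the
machinery under the stated model, not calibration to any real cohort.

## Cost-effectiveness layer

Start-of-cycle discounting d(t) = (1 + r)^(−t·Δdays/365); r = 0
reproduces undiscounted sums exactly, and a constant stream matches the
geometric-series closed form to 1e-9 relative (tested). No half-cycle
correction: event timing is already cycle-resolved. Each cycle is
attributed to the end-of-cycle setting; injury costs/disutilities, ED and
surgery costs land in their event's cycle; intervention costs accrue
per-cycle while alive plus a one-time cost at entry.

Incremental analysis sorts arms by mean cost (ties broken by effect then
arm id, so results are invariant to relabelling), removes strictly
dominated arms, then applies extended dominance until frontier ICERs are
monotone. Identical-outcome arms are flagged as ties with an undefined
ICER rather than silently dropped. Common random numbers across arms —
identical starting population and per-individual substreams — is the
default variance-reduction policy; with a neutral intervention it yields
exactly identical arm outcomes, a property the tests assert.

## Known limitations

- All simulation-layer magnitudes are synthetic; no output is a
  real-world cost-effectiveness estimate.
- Discharge destination depends on the pre-admission setting only, not
  the injury; the parameter surface allows extension.
- No probabilistic sensitivity analysis, CEACs, or value-of-information
  machinery.
- The engine is a per-individual Python loop: linear in n × cycles, fine
  for 10^6–10^7 person-cycles, not vectorized for much larger studies.
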