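"""Individual-level state-transition engine for the fall pathway model.

Each simulated person is stepped through discrete two-week cycles.  Within
a cycle the draw order is fixed (required for reproducibility and for the
cohort-Markov limit to be well defined):

1. background (non-fall) mortality;
2. a single fall draw, only in community or residential aged care;
3. if a fall occurred, a single injury draw (possibly no injury);
4. the care pathway: ED visit -> hospital admission -> hip surgery,
   each gated on the previous draw and on the transition topology;
5. a fall-death draw conditional on the injury sustained;
6. length-of-stay bookkeeping for hospital / rehabilitation stays
   (individuals who *began* the cycle as inpatients), then residential
   relocation draws for individuals whose setting did not change.

Structural assumptions enforced throughout: at most one fall per cycle and
at most one injury per fall; hospital admission from a living setting
requires an ED visit in the same cycle; hip surgery only follows a hip
fracture with admission; the two death settings are absorbing.

Randomness is organised as one named substream per individual per purpose
(mortality, fall, injury, pathway), each derived from the master seed via
``numpy.random.SeedSequence`` spawn keys, so results do not depend on
iteration order and adding draws to one purpose does not perturb others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import (
    ABSORBING_SETTINGS,
    EventKind,
    InjuryType,
    Setting,
    TrackedEvent,
    TransitionTopology,
)

__all__ = [
    "CyclePlan",
    "BackgroundMortality",
    "HazardModel",
    "PathwayProbabilities",
    "EngineParameters",
    "Individual",
    "Trajectory",
    "CohortResult",
    "validate_parameters",
    "step_cycle",
    "simulate_individual",
    "simulate_cohort",
    "multiple_injury_share",
    "assumption_violations",
    "make_streams",
]

DAYS_PER_YEAR = 365.0

_PURPOSES = ("mortality", "fall", "injury", "pathway")

# Draw order within the injury pathway; stable for reproducibility.
_INJURY_ORDER = (
    InjuryType.HIP_FRACTURE,
    InjuryType.VERTEBRAL_FRACTURE,
    InjuryType.WRIST_FRACTURE,
    InjuryType.HEAD_INJURY,
    InjuryType.MODERATE,
    InjuryType.MINOR,
    InjuryType.NONE,
)


@dataclass(frozen=True)
class CyclePlan:
    """Time discretization: two-week cycles over a lifetime horizon."""

    cycle_length_days: float = 14.0
    max_age_years: float = 110.0
    discount_rate_annual: float = 0.0
    max_cycles: int | None = None

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        if self.discount_rate_annual < 0:
            raise ValueError("discount_rate_annual must be >= 0")

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR


@dataclass(frozen=True)
class BackgroundMortality:
    """Gompertz-form other-cause mortality, h(age) = h65 * exp(g*(age-65)).

    Purely a plausibility-scale synthetic default; any life-table-like
    per-cycle schedule can be substituted through configuration.  Setting
    ``log_slope_per_year`` to 0 gives a constant (memoryless) hazard.
    """

    annual_hazard_at_65: float = 0.01
    log_slope_per_year: float = 0.09

    def per_cycle_prob(self, age_years: float, cycle_length_years: float) -> float:
        hazard = self.annual_hazard_at_65 * math.exp(
            self.log_slope_per_year * (age_years - 65.0)
        )
        return 1.0 - math.exp(-hazard * cycle_length_years)


@dataclass(frozen=True)
class HazardModel:
    """Fall risk per cycle and the conditional injury split.

    The baseline is a per-cycle fall probability by setting.  Individual
    heterogeneity and history enter as multiplicative factors on the
    underlying rate: with product m of multipliers the realized probability
    is 1 - (1 - p0)**m, which stays in [0, 1] for any m > 0.
    """

    baseline_fall_prob: dict[Setting, float]
    injury_split: dict[Setting, dict[InjuryType, float]]
    attribute_multipliers: dict[str, float] = field(default_factory=dict)
    prior_fall_multiplier: float = 1.0
    prior_fall_cap: int = 5
    recent_fall_multiplier: float = 1.0
    recent_fall_window_cycles: int = 6

    def multiplier(self, individual: "Individual", cycle_index: int) -> float:
        m = 1.0
        for attr_id, factor in self.attribute_multipliers.items():
            value = individual.attributes.get(attr_id, 0.0)
            if value:
                m *= factor ** float(value)
        if self.prior_fall_multiplier != 1.0 and individual.n_falls > 0:
            m *= self.prior_fall_multiplier ** min(
                individual.n_falls, self.prior_fall_cap
            )
        if (
            self.recent_fall_multiplier != 1.0
            and individual.last_fall_cycle is not None
            and cycle_index - individual.last_fall_cycle
            <= self.recent_fall_window_cycles
        ):
            m *= self.recent_fall_multiplier
        return m

    def fall_prob(self, individual: "Individual", cycle_index: int) -> float:
        p0 = self.baseline_fall_prob.get(individual.setting, 0.0)
        if p0 <= 0.0:
            return 0.0
        if p0 >= 1.0:
            return 1.0
        m = self.multiplier(individual, cycle_index)
        if m == 1.0:
            return p0
        return 1.0 - (1.0 - p0) ** m


@dataclass(frozen=True)
class PathwayProbabilities:
    """Care-pathway, mortality and stay-length parameters."""

    p_ed_given_injury: dict[InjuryType, float]
    p_admit_given_ed: dict[InjuryType, float]
    p_surgery_given_hip_admission: float
    p_rehab_given_discharge: float
    p_discharge_to_residential_care: dict[Setting, float]
    p_death_fall: dict[InjuryType, float]
    background_mortality: BackgroundMortality
    mean_los_hospital_cycles: float = 2.0
    mean_los_rehab_cycles: float = 3.0
    p_relocate_community_to_rac: float = 0.0
    p_relocate_rac_to_community: float = 0.0


@dataclass(frozen=True)
class EngineParameters:
    hazard: HazardModel
    pathway: PathwayProbabilities
    topology: TransitionTopology = field(default_factory=TransitionTopology.default)


@dataclass
class Individual:
    """One simulated person with full attribute and event history."""

    id: int
    age: float
    attributes: dict[str, float] = field(default_factory=dict)
    setting: Setting = Setting.COMMUNITY
    history: list[TrackedEvent] = field(default_factory=list)
    alive: bool = True
    entry_cycle: int = 0          # cycle the current setting was entered
    pre_admission_setting: Setting = Setting.COMMUNITY
    n_falls: int = 0
    last_fall_cycle: int | None = None


@dataclass
class Trajectory:
    individual: Individual
    events: list[TrackedEvent]
    settings_by_cycle: list[Setting]  # setting occupied at the end of each cycle

    @property
    def n_cycles(self) -> int:
        return len(self.settings_by_cycle)


@dataclass
class CohortResult:
    event_log: pd.DataFrame     # individual_id, cycle, event_kind, detail, setting_after
    occupancy: pd.DataFrame     # cycle x setting counts, rows sum to n
    trajectories: list[Trajectory]


# ---------------------------------------------------------------------------
# Validation


def _check_prob(name: str, value: float, errors: list[str]) -> None:
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        errors.append(f"{name} = {value} outside [0, 1]")


def validate_parameters(params: EngineParameters) -> None:
    """Raise ValueError listing every invalid probability or length of stay."""
    errors: list[str] = []
    hz, pw = params.hazard, params.pathway
    for setting, p in hz.baseline_fall_prob.items():
        _check_prob(f"baseline_fall_prob[{setting.value}]", p, errors)
        if setting not in params.topology.fall_settings:
            errors.append(f"fall probability given for non-fall setting {setting.value}")
    for setting, split in hz.injury_split.items():
        total = 0.0
        for injury, p in split.items():
            _check_prob(f"injury_split[{setting.value}][{injury.value}]", p, errors)
            total += p
        if abs(total - 1.0) > 1e-9:
            errors.append(f"injury_split[{setting.value}] sums to {total}, not 1")
    for factor in hz.attribute_multipliers.values():
        if factor <= 0:
            errors.append(f"attribute multiplier {factor} must be > 0")
    for table_name, table in (
        ("p_ed_given_injury", pw.p_ed_given_injury),
        ("p_admit_given_ed", pw.p_admit_given_ed),
        ("p_death_fall", pw.p_death_fall),
    ):
        for injury, p in table.items():
            _check_prob(f"{table_name}[{injury.value}]", p, errors)
    if pw.p_death_fall.get(InjuryType.NONE, 0.0) != 0.0:
        errors.append("p_death_fall[NONE] must be 0 (fall death requires an injury)")
    _check_prob("p_surgery_given_hip_admission", pw.p_surgery_given_hip_admission, errors)
    _check_prob("p_rehab_given_discharge", pw.p_rehab_given_discharge, errors)
    for setting, p in pw.p_discharge_to_residential_care.items():
        _check_prob(f"p_discharge_to_residential_care[{setting.value}]", p, errors)
    _check_prob("p_relocate_community_to_rac", pw.p_relocate_community_to_rac, errors)
    _check_prob("p_relocate_rac_to_community", pw.p_relocate_rac_to_community, errors)
    for name, los in (
        ("mean_los_hospital_cycles", pw.mean_los_hospital_cycles),
        ("mean_los_rehab_cycles", pw.mean_los_rehab_cycles),
    ):
        if los < 1.0:
            errors.append(f"{name} = {los} must be >= 1 cycle")
    if errors:
        raise ValueError("invalid engine parameters:\n  " + "\n  ".join(errors))


# ---------------------------------------------------------------------------
# Random streams


def make_streams(master_seed: int, individual_index: int) -> dict[str, np.random.Generator]:
    """Named per-purpose generators for one individual."""
    return {
        purpose: np.random.Generator(
            np.random.PCG64(
                np.random.SeedSequence(master_seed, spawn_key=(individual_index, k))
            )
        )
        for k, purpose in enumerate(_PURPOSES)
    }


def _draw_injury(split: dict[InjuryType, float], u: float) -> InjuryType:
    acc = 0.0
    for injury in _INJURY_ORDER:
        acc += split.get(injury, 0.0)
        if u < acc:
            return injury
    return InjuryType.NONE


# ---------------------------------------------------------------------------
# Stepping


def step_cycle(
    individual: Individual,
    params: EngineParameters,
    streams: dict[str, np.random.Generator],
    cycle_index: int,
    plan: CyclePlan,
) -> list[TrackedEvent]:
    """Advance one individual by one cycle in place; return emitted events."""
    if not individual.alive:
        return []
    events: list[TrackedEvent] = []

    def emit(kind: EventKind, detail: str = "") -> None:
        ev = TrackedEvent(event_kind=kind, cycle_index=cycle_index, detail=detail)
        events.append(ev)
        individual.history.append(ev)

    pw = params.pathway
    start_setting = individual.setting
    started_inpatient = (
        start_setting in (Setting.HOSPITAL, Setting.REHAB_HOSPITAL)
        and individual.entry_cycle < cycle_index
    )

    # 1. background (other-cause) mortality
    q = pw.background_mortality.per_cycle_prob(individual.age, plan.cycle_length_years)
    if streams["mortality"].random() < q:
        individual.setting = Setting.DEATH_OTHER
        individual.alive = False
        emit(EventKind.DEATH, "other")
        individual.age += plan.cycle_length_years
        return events

    # 2.-5. fall cascade (community and residential aged care only)
    if start_setting in params.topology.fall_settings:
        p_fall = params.hazard.fall_prob(individual, cycle_index)
        if streams["fall"].random() < p_fall:
            emit(EventKind.FALL)
            individual.n_falls += 1
            individual.last_fall_cycle = cycle_index
            split = params.hazard.injury_split.get(start_setting, {})
            injury = _draw_injury(split, streams["injury"].random())
            if injury is not InjuryType.NONE:
                emit(EventKind.INJURY, injury.value)
                pathway = streams["pathway"]
                if pathway.random() < pw.p_ed_given_injury.get(injury, 0.0):
                    emit(EventKind.ED_VISIT, injury.value)
                    if pathway.random() < pw.p_admit_given_ed.get(injury, 0.0):
                        emit(EventKind.HOSPITAL_ADMISSION, injury.value)
                        individual.pre_admission_setting = start_setting
                        individual.setting = Setting.HOSPITAL
                        individual.entry_cycle = cycle_index
                        if injury is InjuryType.HIP_FRACTURE and (
                            pathway.random() < pw.p_surgery_given_hip_admission
                        ):
                            emit(EventKind.HIP_SURGERY)
                # fall-death draw, conditional on the injury sustained
                if pathway.random() < pw.p_death_fall.get(injury, 0.0):
                    individual.setting = Setting.DEATH_FALL
                    individual.alive = False
                    emit(EventKind.DEATH, "fall")
                    individual.age += plan.cycle_length_years
                    return events

    # 6. inpatient length-of-stay bookkeeping (geometric discharge)
    if started_inpatient:
        pathway = streams["pathway"]
        if start_setting is Setting.HOSPITAL:
            if pathway.random() < 1.0 / pw.mean_los_hospital_cycles:
                if pathway.random() < pw.p_rehab_given_discharge:
                    individual.setting = Setting.REHAB_HOSPITAL
                    individual.entry_cycle = cycle_index
                    emit(EventKind.REHAB_ADMISSION)
                else:
                    _discharge(individual, pw, pathway, cycle_index, emit)
        else:  # rehabilitation hospital
            if pathway.random() < 1.0 / pw.mean_los_rehab_cycles:
                _discharge(individual, pw, pathway, cycle_index, emit)

    # residential relocation, only if the setting did not change this cycle
    if individual.alive and individual.setting is start_setting:
        pathway = streams["pathway"]
        if start_setting is Setting.COMMUNITY and pw.p_relocate_community_to_rac > 0:
            if pathway.random() < pw.p_relocate_community_to_rac:
                individual.setting = Setting.RESIDENTIAL_AGED_CARE
                individual.entry_cycle = cycle_index
                emit(EventKind.RELOCATION, Setting.RESIDENTIAL_AGED_CARE.value)
        elif (
            start_setting is Setting.RESIDENTIAL_AGED_CARE
            and pw.p_relocate_rac_to_community > 0
        ):
            if pathway.random() < pw.p_relocate_rac_to_community:
                individual.setting = Setting.COMMUNITY
                individual.entry_cycle = cycle_index
                emit(EventKind.RELOCATION, Setting.COMMUNITY.value)

    individual.age += plan.cycle_length_years
    return events


def _discharge(individual, pw, pathway, cycle_index, emit) -> None:
    p_rac = pw.p_discharge_to_residential_care.get(
        individual.pre_admission_setting, 0.0
    )
    if pathway.random() < p_rac:
        dest = Setting.RESIDENTIAL_AGED_CARE
    else:
        dest = Setting.COMMUNITY
    individual.setting = dest
    individual.entry_cycle = cycle_index
    emit(EventKind.RELOCATION, dest.value)


def simulate_individual(
    initial: Individual,
    params: EngineParameters,
    plan: CyclePlan,
    seed: int,
    individual_index: int = 0,
    validate: bool = True,
) -> Trajectory:
    """Step one individual until death, the age cap, or the cycle cap."""
    if validate:
        validate_parameters(params)
    streams = make_streams(seed, individual_index)
    person = replace(
        initial,
        history=list(initial.history),
        attributes=dict(initial.attributes),
    )
    events: list[TrackedEvent] = []
    settings: list[Setting] = []
    cycle = 0
    while person.alive and person.age < plan.max_age_years:
        if plan.max_cycles is not None and cycle >= plan.max_cycles:
            break
        events.extend(step_cycle(person, params, streams, cycle, plan))
        settings.append(person.setting)
        cycle += 1
    return Trajectory(individual=person, events=events, settings_by_cycle=settings)


def simulate_cohort(
    individuals: list[Individual],
    params: EngineParameters,
    plan: CyclePlan,
    master_seed: int,
) -> CohortResult:
    """Simulate a cohort; occupancy rows always sum to the cohort size.

    Individuals who die remain in their death setting for all later cycles
    of the occupancy matrix, so each row is a full partition of the cohort.
    """
    if not individuals:
        raise ValueError("cohort must contain at least one individual")
    validate_parameters(params)
    trajectories = [
        simulate_individual(
            person, params, plan, master_seed, individual_index=i, validate=False
        )
        for i, person in enumerate(individuals)
    ]

    rows = []
    for trajectory in trajectories:
        for ev in trajectory.events:
            rows.append(
                (
                    trajectory.individual.id,
                    ev.cycle_index,
                    ev.event_kind.value,
                    ev.detail,
                )
            )
    settings_after = {
        t.individual.id: t.settings_by_cycle for t in trajectories
    }
    log = pd.DataFrame(rows, columns=["individual_id", "cycle", "event_kind", "detail"])
    log["setting_after"] = [
        settings_after[i][c].value for i, c in zip(log["individual_id"], log["cycle"])
    ] if len(log) else pd.Series(dtype=str)

    horizon = max(t.n_cycles for t in trajectories)
    names = [s.value for s in Setting]
    occupancy = np.zeros((horizon, len(names)), dtype=int)
    index_of = {s: k for k, s in enumerate(Setting)}
    for trajectory in trajectories:
        per_cycle = trajectory.settings_by_cycle
        last = per_cycle[-1] if per_cycle else trajectory.individual.setting
        for c in range(horizon):
            setting = per_cycle[c] if c < len(per_cycle) else last
            occupancy[c, index_of[setting]] += 1
    occupancy_df = pd.DataFrame(occupancy, columns=names)
    occupancy_df.index.name = "cycle"
    return CohortResult(event_log=log, occupancy=occupancy_df, trajectories=trajectories)


# ---------------------------------------------------------------------------
# Structural-assumption audits


def assumption_violations(event_log: pd.DataFrame) -> list[str]:
    """Audit a log against the one-fall-per-cycle / one-injury-per-fall rules."""
    violations: list[str] = []
    falls = event_log[event_log["event_kind"] == EventKind.FALL.value]
    multi_falls = falls.groupby(["individual_id", "cycle"]).size()
    for (ind, cycle), k in multi_falls[multi_falls > 1].items():
        violations.append(f"individual {ind} cycle {cycle}: {k} falls in one cycle")
    injuries = event_log[event_log["event_kind"] == EventKind.INJURY.value]
    multi_injuries = injuries.groupby(["individual_id", "cycle"]).size()
    for (ind, cycle), k in multi_injuries[multi_injuries > 1].items():
        violations.append(f"individual {ind} cycle {cycle}: {k} injuries for one fall")
    return violations


def multiple_injury_share(event_log: pd.DataFrame) -> float:
    """Fraction of fallers recorded with more than one injury on any fall.

    Zero by construction under the engine's one-injury-per-fall assumption;
    a positive value indicates a hand-built or corrupted log (see
    :func:`assumption_violations`).
    """
    if event_log is None or len(event_log) == 0:
        raise ValueError("empty event log: multiple-injury share is undefined")
    falls = event_log[event_log["event_kind"] == EventKind.FALL.value]
    fallers = set(falls["individual_id"].unique())
    if not fallers:
        return 0.0
    injuries = event_log[event_log["event_kind"] == EventKind.INJURY.value]
    per_fall = injuries.groupby(["individual_id", "cycle"]).size()
    multi = {ind for (ind, _), k in per_fall.items() if k > 1}
    return len(multi & fallers) / len(fallers)
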