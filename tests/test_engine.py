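"""Engine behaviour: determinism, conservation, structural assumptions,
and agreement with the cohort-Markov limit."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from conftest import SETTING_INDEX, homogeneous_parameters, markov_transition_matrix
from fallsim.engine import (
    BackgroundMortality,
    CyclePlan,
    EngineParameters,
    HazardModel,
    Individual,
    PathwayProbabilities,
    assumption_violations,
    make_streams,
    multiple_injury_share,
    simulate_cohort,
    simulate_individual,
    step_cycle,
    validate_parameters,
)
from fallsim.schema import EventKind, InjuryType, Setting


def quiet_parameters(**overrides) -> EngineParameters:
    """No falls, no deaths: the individual should never move."""
    params = homogeneous_parameters(
        fall_prob_community=0.0, fall_prob_rac=0.0, q_annual=0.0,
        relocation_cr=0.0, relocation_rc=0.0,
    )
    if overrides:
        params = dataclasses.replace(params, **overrides)
    return params


def certain_hip_fracture_parameters(p_death_fall_hip=0.0) -> EngineParameters:
    """Deterministic limit: every cycle a fall, hip fracture, full pathway."""
    base = homogeneous_parameters(q_annual=0.0, relocation_cr=0.0,
                                  relocation_rc=0.0)
    hazard = HazardModel(
        baseline_fall_prob={Setting.COMMUNITY: 1.0,
                            Setting.RESIDENTIAL_AGED_CARE: 1.0},
        injury_split={
            s: {InjuryType.HIP_FRACTURE: 1.0}
            for s in (Setting.COMMUNITY, Setting.RESIDENTIAL_AGED_CARE)
        },
    )
    pathway = dataclasses.replace(
        base.pathway,
        p_ed_given_injury={InjuryType.HIP_FRACTURE: 1.0, InjuryType.NONE: 0.0},
        p_admit_given_ed={InjuryType.HIP_FRACTURE: 1.0, InjuryType.NONE: 0.0},
        p_surgery_given_hip_admission=1.0,
        p_death_fall={InjuryType.HIP_FRACTURE: p_death_fall_hip,
                      InjuryType.NONE: 0.0},
    )
    return EngineParameters(hazard=hazard, pathway=pathway)


def person(age=70.0, setting=Setting.COMMUNITY, pid=0) -> Individual:
    return Individual(id=pid, age=age, setting=setting)


class TestStepCycle:
    def test_quiet_parameters_mean_no_events_ever(self):
        trajectory = simulate_individual(
            person(), quiet_parameters(), CyclePlan(max_cycles=200), seed=5
        )
        assert trajectory.events == []
        assert set(trajectory.settings_by_cycle) == {Setting.COMMUNITY}
        assert trajectory.n_cycles == 200

    def test_deterministic_limit_emits_full_pathway_in_order(self):
        params = certain_hip_fracture_parameters()
        individual = person()
        events = step_cycle(individual, params, make_streams(0, 0), 0,
                            CyclePlan())
        kinds = [e.event_kind for e in events]
        assert kinds == [
            EventKind.FALL, EventKind.INJURY, EventKind.ED_VISIT,
            EventKind.HOSPITAL_ADMISSION, EventKind.HIP_SURGERY,
        ]
        assert individual.setting is Setting.HOSPITAL

    def test_certain_fall_death_ends_first_cycle(self):
        params = certain_hip_fracture_parameters(p_death_fall_hip=1.0)
        trajectory = simulate_individual(person(), params, CyclePlan(), seed=9)
        assert trajectory.individual.setting is Setting.DEATH_FALL
        assert trajectory.n_cycles == 1
        assert trajectory.events[-1].event_kind is EventKind.DEATH
        assert trajectory.events[-1].detail == "fall"

    def test_admission_cycle_never_discharges_same_cycle(self):
        params = certain_hip_fracture_parameters()
        # mean LOS 1 cycle: discharge probability 1, but never before the
        # cycle after admission
        params = EngineParameters(
            hazard=params.hazard,
            pathway=dataclasses.replace(params.pathway,
                                        mean_los_hospital_cycles=1.0,
                                        p_rehab_given_discharge=0.0),
        )
        trajectory = simulate_individual(
            person(), params, CyclePlan(max_cycles=6), seed=2
        )
        admissions = [e.cycle_index for e in trajectory.events
                      if e.event_kind is EventKind.HOSPITAL_ADMISSION]
        discharges = [e.cycle_index for e in trajectory.events
                      if e.event_kind is EventKind.RELOCATION]
        assert admissions and discharges
        assert min(discharges) == min(admissions) + 1


class TestSimulateIndividual:
    def test_zero_cycle_trajectory_at_age_cap(self):
        trajectory = simulate_individual(
            person(age=110.0), quiet_parameters(),
            CyclePlan(max_age_years=110.0), seed=1,
        )
        assert trajectory.n_cycles == 0
        assert trajectory.events == []

    def test_same_seed_reproduces_trajectory_exactly(self):
        params = homogeneous_parameters()
        plan = CyclePlan(max_cycles=120)
        a = simulate_individual(person(), params, plan, seed=42)
        b = simulate_individual(person(), params, plan, seed=42)
        assert a.events == b.events
        assert a.settings_by_cycle == b.settings_by_cycle

    def test_history_cycle_indices_non_decreasing(self):
        trajectory = simulate_individual(
            person(), homogeneous_parameters(), CyclePlan(max_cycles=150),
            seed=11,
        )
        cycles = [e.cycle_index for e in trajectory.individual.history]
        assert cycles == sorted(cycles)


@pytest.fixture(scope="module")
def cohort():
    people = [person(pid=i) for i in range(400)]
    return simulate_cohort(
        people, homogeneous_parameters(), CyclePlan(max_cycles=60),
        master_seed=17,
    )


class TestSimulateCohort:
    def test_occupancy_rows_sum_to_cohort_size(self, cohort):
        assert (cohort.occupancy.sum(axis=1) == 400).all()

    def test_no_events_after_absorption(self, cohort):
        for trajectory in cohort.trajectories:
            if trajectory.individual.alive:
                continue
            death_cycle = trajectory.events[-1].cycle_index
            assert trajectory.events[-1].event_kind is EventKind.DEATH
            assert all(e.cycle_index <= death_cycle for e in trajectory.events)
            tail = trajectory.settings_by_cycle[death_cycle:]
            assert len(set(tail)) == 1  # parked in a single death state

    def test_structural_assumptions_hold_in_log(self, cohort):
        assert assumption_violations(cohort.event_log) == []
        assert multiple_injury_share(cohort.event_log) == 0.0

    def test_single_individual_cohort_matches_direct_simulation(self):
        params = homogeneous_parameters()
        plan = CyclePlan(max_cycles=80)
        direct = simulate_individual(person(), params, plan, seed=23,
                                     individual_index=0)
        cohort = simulate_cohort([person()], params, plan, master_seed=23)
        assert cohort.trajectories[0].events == direct.events
        assert cohort.trajectories[0].settings_by_cycle == direct.settings_by_cycle

    def test_cohort_determinism_byte_for_byte(self):
        people = [person(pid=i) for i in range(50)]
        plan = CyclePlan(max_cycles=40)
        a = simulate_cohort([dataclasses.replace(p) for p in people],
                            homogeneous_parameters(), plan, master_seed=3)
        b = simulate_cohort([dataclasses.replace(p) for p in people],
                            homogeneous_parameters(), plan, master_seed=3)
        assert a.event_log.to_csv() == b.event_log.to_csv()
        assert a.occupancy.equals(b.occupancy)


class TestStatisticalProperties:
    def test_fall_counts_are_binomial(self):
        # no mortality, no injuries, constant p: falls ~ Binomial(K, p)
        p, K, n = 0.10, 20, 4000
        params = quiet_parameters(
            hazard=HazardModel(
                baseline_fall_prob={Setting.COMMUNITY: p,
                                    Setting.RESIDENTIAL_AGED_CARE: p},
                injury_split={
                    s: {InjuryType.NONE: 1.0}
                    for s in (Setting.COMMUNITY, Setting.RESIDENTIAL_AGED_CARE)
                },
            )
        )
        cohort = simulate_cohort(
            [person(pid=i) for i in range(n)], params,
            CyclePlan(max_cycles=K), master_seed=31,
        )
        falls_per_person = (
            cohort.event_log[cohort.event_log.event_kind == "FALL"]
            .groupby("individual_id").size()
            .reindex(range(n), fill_value=0)
        )
        se = math.sqrt(K * p * (1 - p) / n)
        assert abs(falls_per_person.mean() - K * p) < 3 * se

    def test_occupancy_matches_markov_oracle(self):
        n = 4000
        params = homogeneous_parameters()
        plan = CyclePlan(max_cycles=30)
        P = markov_transition_matrix(params, plan)
        cohort = simulate_cohort(
            [person(pid=i) for i in range(n)], params, plan, master_seed=7,
        )
        v = np.zeros(6)
        v[SETTING_INDEX[Setting.COMMUNITY]] = 1.0
        for k in (1, 10, 30):
            expected = v @ np.linalg.matrix_power(P, k)
            observed = cohort.occupancy.iloc[k - 1].to_numpy()
            for j in range(6):
                se = math.sqrt(n * expected[j] * (1 - expected[j]))
                assert abs(observed[j] - n * expected[j]) <= 3 * se + 1e-9, (
                    k, list(Setting)[j]
                )


class TestValidationAndAudits:
    def test_invalid_probability_rejected_before_stepping(self):
        params = homogeneous_parameters()
        bad = EngineParameters(
            hazard=params.hazard,
            pathway=dataclasses.replace(
                params.pathway, p_surgery_given_hip_admission=1.5
            ),
        )
        with pytest.raises(ValueError, match="p_surgery"):
            simulate_individual(person(), bad, CyclePlan(max_cycles=1), seed=0)

    def test_injury_split_must_sum_to_one(self):
        params = homogeneous_parameters()
        bad = EngineParameters(
            hazard=dataclasses.replace(
                params.hazard,
                injury_split={Setting.COMMUNITY: {InjuryType.NONE: 0.9},
                              Setting.RESIDENTIAL_AGED_CARE: {InjuryType.NONE: 1.0}},
            ),
            pathway=params.pathway,
        )
        with pytest.raises(ValueError, match="sums to"):
            validate_parameters(bad)

    def test_length_of_stay_below_one_cycle_rejected(self):
        params = homogeneous_parameters()
        bad = EngineParameters(
            hazard=params.hazard,
            pathway=dataclasses.replace(params.pathway,
                                        mean_los_hospital_cycles=0.5),
        )
        with pytest.raises(ValueError, match="mean_los"):
            validate_parameters(bad)

    def test_fall_death_without_injury_rejected(self):
        params = homogeneous_parameters()
        bad_table = dict(params.pathway.p_death_fall)
        bad_table[InjuryType.NONE] = 0.1
        bad = EngineParameters(
            hazard=params.hazard,
            pathway=dataclasses.replace(params.pathway, p_death_fall=bad_table),
        )
        with pytest.raises(ValueError, match="NONE"):
            validate_parameters(bad)

    def test_hand_built_multi_injury_log_is_flagged(self):
        log = pd.DataFrame(
            [
                (0, 3, "FALL", "", "COMMUNITY"),
                (0, 3, "INJURY", "HIP_FRACTURE", "COMMUNITY"),
                (0, 3, "INJURY", "WRIST_FRACTURE", "COMMUNITY"),
                (1, 2, "FALL", "", "COMMUNITY"),
            ],
            columns=["individual_id", "cycle", "event_kind", "detail",
                     "setting_after"],
        )
        assert multiple_injury_share(log) == 0.5
        assert any("2 injuries" in v for v in assumption_violations(log))

    def test_empty_log_share_is_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            multiple_injury_share(pd.DataFrame())


class TestHazardModel:
    def test_multipliers_keep_probability_in_unit_interval(self):
        hazard = HazardModel(
            baseline_fall_prob={Setting.COMMUNITY: 0.4},
            injury_split={Setting.COMMUNITY: {InjuryType.NONE: 1.0}},
            attribute_multipliers={"frailty": 50.0},
        )
        frail = Individual(id=0, age=80, attributes={"frailty": 1.0})
        assert 0.0 <= hazard.fall_prob(frail, 0) <= 1.0
        assert hazard.fall_prob(frail, 0) > 0.4

    def test_recent_fall_recency_window(self):
        hazard = HazardModel(
            baseline_fall_prob={Setting.COMMUNITY: 0.1},
            injury_split={Setting.COMMUNITY: {InjuryType.NONE: 1.0}},
            recent_fall_multiplier=2.0, recent_fall_window_cycles=6,
        )
        faller = Individual(id=0, age=70, n_falls=1, last_fall_cycle=10)
        inside = hazard.fall_prob(faller, 14)
        outside = hazard.fall_prob(faller, 30)
        assert inside > outside == 0.1

    def test_gompertz_mortality_increases_with_age(self):
        mortality = BackgroundMortality(annual_hazard_at_65=0.01,
                                        log_slope_per_year=0.09)
        dt = 14 / 365
        assert mortality.per_cycle_prob(90, dt) > mortality.per_cycle_prob(65, dt)
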