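"""Shared fixtures: packaged survey tables and a cohort-Markov oracle.

The oracle collapses the engine's within-cycle draw tree, under
homogeneous history-free parameters, into a 6x6 transition matrix over
settings.  Matrix powers then give exact cohort occupancy proportions
against which microsimulation output is checked.
"""

from __future__ import annotations

import numpy as np
import pytest

from fallsim.delphi import ConsensusCriteria, packaged_ratings, summarize_round
from fallsim.engine import (
    BackgroundMortality,
    CyclePlan,
    EngineParameters,
    HazardModel,
    PathwayProbabilities,
)
from fallsim.schema import InjuryType, Setting

SETTING_INDEX = {s: i for i, s in enumerate(Setting)}


@pytest.fixture(scope="session")
def criteria():
    return ConsensusCriteria()


@pytest.fixture(scope="session")
def all_ratings():
    return packaged_ratings()


@pytest.fixture(scope="session")
def round_summaries(all_ratings, criteria):
    """RoundSummary per (item_kind, round) over the packaged tables."""
    out = {}
    for kind in ("health_state_event", "patient_attribute"):
        for rnd in (1, 2):
            dists = [
                d for d in all_ratings
                if d.item_kind == kind and d.round_index == rnd
            ]
            out[(kind, rnd)] = summarize_round(dists, criteria)
    return out


def homogeneous_parameters(
    fall_prob_community: float = 0.10,
    fall_prob_rac: float = 0.15,
    q_annual: float = 0.2,
    relocation_cr: float = 0.02,
    relocation_rc: float = 0.01,
) -> EngineParameters:
    """History-free, attribute-free parameters for the Markov-limit check."""
    split = {
        InjuryType.NONE: 0.50,
        InjuryType.MINOR: 0.20,
        InjuryType.HIP_FRACTURE: 0.10,
        InjuryType.HEAD_INJURY: 0.05,
        InjuryType.WRIST_FRACTURE: 0.05,
        InjuryType.VERTEBRAL_FRACTURE: 0.05,
        InjuryType.MODERATE: 0.05,
    }
    return EngineParameters(
        hazard=HazardModel(
            baseline_fall_prob={
                Setting.COMMUNITY: fall_prob_community,
                Setting.RESIDENTIAL_AGED_CARE: fall_prob_rac,
            },
            injury_split={
                Setting.COMMUNITY: dict(split),
                Setting.RESIDENTIAL_AGED_CARE: dict(split),
            },
        ),
        pathway=PathwayProbabilities(
            p_ed_given_injury={
                InjuryType.HIP_FRACTURE: 1.0,
                InjuryType.HEAD_INJURY: 0.9,
                InjuryType.WRIST_FRACTURE: 0.8,
                InjuryType.VERTEBRAL_FRACTURE: 0.7,
                InjuryType.MODERATE: 0.6,
                InjuryType.MINOR: 0.2,
                InjuryType.NONE: 0.0,
            },
            p_admit_given_ed={
                InjuryType.HIP_FRACTURE: 0.95,
                InjuryType.HEAD_INJURY: 0.85,
                InjuryType.WRIST_FRACTURE: 0.2,
                InjuryType.VERTEBRAL_FRACTURE: 0.5,
                InjuryType.MODERATE: 0.3,
                InjuryType.MINOR: 0.05,
                InjuryType.NONE: 0.0,
            },
            p_surgery_given_hip_admission=0.9,
            p_rehab_given_discharge=0.30,
            p_discharge_to_residential_care={
                # equal across prior settings, keeping the chain memoryless
                Setting.COMMUNITY: 0.25,
                Setting.RESIDENTIAL_AGED_CARE: 0.25,
            },
            p_death_fall={
                InjuryType.HIP_FRACTURE: 0.06,
                InjuryType.HEAD_INJURY: 0.15,
                InjuryType.WRIST_FRACTURE: 0.002,
                InjuryType.VERTEBRAL_FRACTURE: 0.01,
                InjuryType.MODERATE: 0.005,
                InjuryType.MINOR: 0.001,
                InjuryType.NONE: 0.0,
            },
            background_mortality=BackgroundMortality(
                annual_hazard_at_65=q_annual, log_slope_per_year=0.0
            ),
            mean_los_hospital_cycles=2.0,
            mean_los_rehab_cycles=3.0,
            p_relocate_community_to_rac=relocation_cr,
            p_relocate_rac_to_community=relocation_rc,
        ),
    )


def markov_transition_matrix(params: EngineParameters, plan: CyclePlan) -> np.ndarray:
    """6x6 end-of-cycle transition matrix for homogeneous parameters."""
    hz, pw = params.hazard, params.pathway
    q = pw.background_mortality.per_cycle_prob(70.0, plan.cycle_length_years)

    def cascade(setting: Setting) -> tuple[float, float]:
        p_fall = hz.baseline_fall_prob.get(setting, 0.0)
        split = hz.injury_split.get(setting, {})
        to_death = to_hospital = 0.0
        for injury, share in split.items():
            d = pw.p_death_fall.get(injury, 0.0)
            admit = (
                pw.p_ed_given_injury.get(injury, 0.0)
                * pw.p_admit_given_ed.get(injury, 0.0)
            )
            to_death += share * d
            to_hospital += share * admit * (1.0 - d)
        return p_fall * to_death, p_fall * to_hospital

    P = np.zeros((6, 6))
    C, RAC, H, R, DF, DO = (SETTING_INDEX[s] for s in Setting)
    for src, reloc, dest in (
        (Setting.COMMUNITY, pw.p_relocate_community_to_rac, RAC),
        (Setting.RESIDENTIAL_AGED_CARE, pw.p_relocate_rac_to_community, C),
    ):
        i = SETTING_INDEX[src]
        p_df, p_h = cascade(src)
        P[i, DO] = q
        P[i, DF] = (1 - q) * p_df
        P[i, H] = (1 - q) * p_h
        stay = (1 - q) * (1 - p_df - p_h)
        P[i, dest] += stay * reloc
        P[i, i] += stay * (1 - reloc)
    # hospital: geometric discharge, no falls as inpatient
    pi = pw.p_discharge_to_residential_care[Setting.COMMUNITY]
    rho = pw.p_rehab_given_discharge
    disc_h = (1 - q) / pw.mean_los_hospital_cycles
    P[H, DO] = q
    P[H, R] = disc_h * rho
    P[H, RAC] = disc_h * (1 - rho) * pi
    P[H, C] = disc_h * (1 - rho) * (1 - pi)
    P[H, H] = (1 - q) * (1 - 1 / pw.mean_los_hospital_cycles)
    disc_r = (1 - q) / pw.mean_los_rehab_cycles
    P[R, DO] = q
    P[R, RAC] = disc_r * pi
    P[R, C] = disc_r * (1 - pi)
    P[R, R] = (1 - q) * (1 - 1 / pw.mean_los_rehab_cycles)
    P[DF, DF] = 1.0
    P[DO, DO] = 1.0
    assert np.allclose(P.sum(axis=1), 1.0)
    return P
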