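"""Cost-effectiveness accumulation and incremental analysis.

Costs and QALYs are accumulated per cycle with start-of-cycle discounting,
d(t) = (1 + r)^(-t * cycle_days / 365); no half-cycle correction is applied
because event timing is already cycle-resolved in the microsimulation.
Each cycle is attributed to the setting occupied during that cycle (the
end-of-cycle setting emitted by the engine), plus any one-time event costs
and injury QALY decrements incurred in it.

Incremental analysis follows the standard cost-effectiveness frontier
construction: arms sorted by mean cost, strictly dominated arms removed
(more costly, no more effective), then extended dominance (an arm is
removed when the ICER of reaching it exceeds the ICER of skipping past it
to the next arm), leaving a frontier strictly increasing in both cost and
effect with monotone ICERs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    CyclePlan,
    DAYS_PER_YEAR,
    EventKind,
    Trajectory,
    simulate_individual,
)
from .scenario import (
    EconParameters,
    InterventionSpec,
    ScenarioParameters,
    apply_intervention,
    generate_population,
)
from .schema import ABSORBING_SETTINGS, InjuryType

__all__ = [
    "EconOutcome",
    "CEAResult",
    "accumulate_outcomes",
    "incremental_analysis",
    "run_cea",
]


@dataclass(frozen=True)
class EconOutcome:
    individual_id: int
    arm_id: str
    discounted_cost: float
    discounted_qalys: float


@dataclass
class CEAResult:
    arms: pd.DataFrame                  # per-arm means, SEs and NMB
    frontier: list[str]                 # arm ids, increasing cost and effect
    icers: dict[str, float | None]      # ICER vs previous frontier arm
    dominated: dict[str, str]           # arm id -> reason
    lambda_per_qaly: float
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)


def accumulate_outcomes(
    trajectory: Trajectory,
    econ: EconParameters,
    plan: CyclePlan,
    intervention: InterventionSpec | None = None,
    arm_id: str = "",
) -> EconOutcome:
    """Discounted cost and QALY totals for one simulated trajectory."""
    r = plan.discount_rate_annual
    dt_years = plan.cycle_length_years
    events_by_cycle: dict[int, list] = {}
    for ev in trajectory.events:
        events_by_cycle.setdefault(ev.cycle_index, []).append(ev)

    cost = 0.0
    qalys = 0.0
    for t, setting in enumerate(trajectory.settings_by_cycle):
        if setting not in econ.state_cost_per_cycle:
            raise KeyError(f"no cost defined for visited state {setting.value}")
        if setting not in econ.state_utility:
            raise KeyError(f"no utility defined for visited state {setting.value}")
        d = (1.0 + r) ** (-(t * plan.cycle_length_days) / DAYS_PER_YEAR)
        cycle_cost = econ.state_cost_per_cycle[setting]
        cycle_disutility = 0.0
        for ev in events_by_cycle.get(t, ()):
            if ev.event_kind is EventKind.INJURY:
                injury = InjuryType(ev.detail)
                cycle_cost += econ.injury_cost.get(injury, 0.0)
                cycle_disutility += econ.injury_disutility.get(injury, 0.0)
            elif ev.event_kind is EventKind.ED_VISIT:
                cycle_cost += econ.ed_visit_cost
            elif ev.event_kind is EventKind.HIP_SURGERY:
                cycle_cost += econ.surgery_cost
        if intervention is not None:
            if t == 0:
                cycle_cost += intervention.one_time_cost
            if setting not in ABSORBING_SETTINGS:
                cycle_cost += intervention.cost_per_cycle
        cost += cycle_cost * d
        qalys += (econ.state_utility[setting] * dt_years - cycle_disutility) * d
    return EconOutcome(
        individual_id=trajectory.individual.id,
        arm_id=arm_id or (intervention.id if intervention else ""),
        discounted_cost=cost,
        discounted_qalys=qalys,
    )


def _arm_table(outcomes_by_arm: dict[str, list[EconOutcome]]) -> pd.DataFrame:
    rows = []
    for arm_id in sorted(outcomes_by_arm):
        outcomes = outcomes_by_arm[arm_id]
        costs = np.array([o.discounted_cost for o in outcomes], dtype=float)
        qalys = np.array([o.discounted_qalys for o in outcomes], dtype=float)
        n = len(costs)
        rows.append(
            {
                "arm_id": arm_id,
                "n": n,
                "mean_cost": costs.mean(),
                "se_cost": costs.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0,
                "mean_qalys": qalys.mean(),
                "se_qalys": qalys.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def incremental_analysis(
    outcomes_by_arm: dict[str, list[EconOutcome]],
    lambda_per_qaly: float,
) -> CEAResult:
    """Dominance-sorted frontier, pairwise ICERs and net monetary benefit."""
    if len(outcomes_by_arm) < 2:
        raise ValueError("incremental analysis requires at least 2 arms")
    arms = _arm_table(outcomes_by_arm)
    arms["nmb"] = lambda_per_qaly * arms["mean_qalys"] - arms["mean_cost"]
    # deterministic order: by cost, then effect (desc), then arm id
    arms = arms.sort_values(
        ["mean_cost", "mean_qalys", "arm_id"], ascending=[True, False, True]
    ).reset_index(drop=True)

    dominated: dict[str, str] = {}
    candidates: list[dict] = []
    best_effect = -math.inf
    best_arm = None
    for row in arms.to_dict("records"):
        if candidates and (
            row["mean_cost"] == candidates[-1]["mean_cost"]
            and row["mean_qalys"] == candidates[-1]["mean_qalys"]
        ):
            dominated[row["arm_id"]] = (
                f"tie with {candidates[-1]['arm_id']}: identical mean cost and "
                "effect (ICER undefined)"
            )
            continue
        if row["mean_qalys"] <= best_effect:
            dominated[row["arm_id"]] = (
                f"strictly dominated by {best_arm}: higher cost, no more effect"
            )
            continue
        candidates.append(row)
        best_effect = row["mean_qalys"]
        best_arm = row["arm_id"]

    # extended dominance: enforce monotone increasing ICERs along the frontier
    changed = True
    while changed and len(candidates) >= 3:
        changed = False
        for i in range(1, len(candidates) - 1):
            icer_in = _icer(candidates[i - 1], candidates[i])
            icer_out = _icer(candidates[i], candidates[i + 1])
            if icer_in is not None and icer_out is not None and icer_in > icer_out:
                dominated[candidates[i]["arm_id"]] = (
                    "extended dominance: ICER "
                    f"{icer_in:.2f} exceeds next-step ICER {icer_out:.2f}"
                )
                del candidates[i]
                changed = True
                break

    frontier = [row["arm_id"] for row in candidates]
    icers: dict[str, float | None] = {}
    comparison_rows = []
    for i, row in enumerate(candidates):
        if i == 0:
            icers[row["arm_id"]] = None
            continue
        prev = candidates[i - 1]
        delta_cost = row["mean_cost"] - prev["mean_cost"]
        delta_q = row["mean_qalys"] - prev["mean_qalys"]
        icer = _icer(prev, row)
        icers[row["arm_id"]] = icer
        comparison_rows.append(
            {
                "arm_id": row["arm_id"],
                "vs": prev["arm_id"],
                "delta_cost": delta_cost,
                "delta_qalys": delta_q,
                "icer": icer,
            }
        )
    return CEAResult(
        arms=arms,
        frontier=frontier,
        icers=icers,
        dominated=dominated,
        lambda_per_qaly=lambda_per_qaly,
        comparisons=pd.DataFrame(comparison_rows),
    )


def _icer(cheaper: dict, costlier: dict) -> float | None:
    delta_q = costlier["mean_qalys"] - cheaper["mean_qalys"]
    delta_c = costlier["mean_cost"] - cheaper["mean_cost"]
    if delta_q == 0:
        return None
    return delta_c / delta_q


def run_cea(
    scenario: ScenarioParameters,
    n: int | None = None,
    seed: int = 0,
    lambda_per_qaly: float = 50_000.0,
    max_cycles: int | None = None,
) -> CEAResult:
    """Simulate every intervention arm and compare them incrementally.

    Common random numbers: all arms share the same starting population and
    the same per-individual random substreams, so between-arm differences
    reflect the intervention effect rather than sampling noise.
    """
    population_spec = scenario.population
    if n is not None:
        population_spec = type(population_spec)(
            n=n,
            age_min=population_spec.age_min,
            age_gamma_shape=population_spec.age_gamma_shape,
            age_gamma_scale=population_spec.age_gamma_scale,
            attribute_prevalence=population_spec.attribute_prevalence,
            polypharmacy_mean=population_spec.polypharmacy_mean,
        )
    plan = scenario.plan
    if max_cycles is not None:
        plan = CyclePlan(
            cycle_length_days=plan.cycle_length_days,
            max_age_years=plan.max_age_years,
            discount_rate_annual=plan.discount_rate_annual,
            max_cycles=max_cycles,
        )
    population = generate_population(population_spec, seed)
    outcomes_by_arm: dict[str, list[EconOutcome]] = {}
    for spec in scenario.interventions:
        params = apply_intervention(scenario.engine, spec)
        outcomes = []
        for i, person in enumerate(population):
            trajectory = simulate_individual(
                person, params, plan, seed, individual_index=i,
                validate=(i == 0),
            )
            outcomes.append(
                accumulate_outcomes(trajectory, scenario.econ, plan,
                                    intervention=spec)
            )
        outcomes_by_arm[spec.id] = outcomes
    return incremental_analysis(outcomes_by_arm, lambda_per_qaly)
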