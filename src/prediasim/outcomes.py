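"""Valuation of simulated trajectories: survival, QALYs, discounted costs.

Per-cycle accruals (state treatment costs, intervention costs during the
tunnel years, and state utilities) are discounted at the annual rate and
half-cycle corrected with trapezoidal end weights, so a subject dying in
cycle k is credited k - 1/2 life years.  The one-off screening cost is
charged in full at cycle 0.  Remaining survival years are undiscounted.

Headline outcomes follow the study conventions: survival and QALYs are
averaged over the diabetes/IGT subgroup, costs over the configured cost
population, extra time before diabetes onset (or before any
complication) over baseline-IGT subjects with horizon censoring, and the
parenthesised ranges are subject-level 2.5th-97.5th percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .decision_tree import CohortAssignments, InitialAssignment
from .markov_engine import (
    IGT_STATES,
    STATE_GROUP,
    CohortTrajectories,
    IndividualTrajectory,
    State,
)
from .parameters import CostTable, EconSettings, ModelParameters, UtilityTable


def discount_factor(t: int | np.ndarray, rate: float) -> float | np.ndarray:
    """Present-value factor (1+rate)^(-t) for an accrual at cycle t."""
    return (1.0 + rate) ** (-np.asarray(t, dtype=float))


def half_cycle_weight(t: int, horizon: int) -> float:
    """Trapezoidal half-cycle weight: 0.5 at both ends, 1 in between."""
    if not 0 <= t <= horizon:
        raise ValueError(f"cycle {t} outside [0, {horizon}]")
    return 0.5 if t in (0, horizon) else 1.0


def half_cycle_weights(horizon: int) -> np.ndarray:
    w = np.ones(horizon + 1)
    w[0] = w[-1] = 0.5
    return w


def _state_cost_vector(costs: CostTable) -> np.ndarray:
    return np.array([costs.state_cost(STATE_GROUP[s]) for s in State])


def _utility_vector(utilities: UtilityTable, initiation_age: int) -> np.ndarray:
    return np.array([utilities.utility(initiation_age, STATE_GROUP[s])
                     for s in State])


def accrue_subject(traj: IndividualTrajectory, costs: CostTable,
                   utilities: UtilityTable, settings: EconSettings,
                   assignment: InitialAssignment,
                   annual_intervention_cost: float = 0.0,
                   ) -> tuple[float, float, float]:
    """Reference per-subject accrual: (discounted cost, QALYs, life years).

    Scalar counterpart of :func:`accrue_cohort`; used as the oracle the
    vectorised path is checked against.
    """
    horizon = settings.horizon
    states = list(traj.states)
    if len(states) != horizon + 1:
        raise ValueError("trajectory length must equal horizon + 1")
    cost = float(assignment.screening_cost_incurred)
    qalys = 0.0
    years = 0.0
    for t, state in enumerate(states):
        w = half_cycle_weight(t, horizon)
        df = float(discount_factor(t, settings.discount_rate))
        group = STATE_GROUP[State(state)]
        cost += w * df * costs.state_cost(group)
        qalys += w * df * utilities.utility(traj.initiation_age, group)
        years += w * (0.0 if group == "death" else 1.0)
        if (assignment.receives_intervention and 1 <= t <= settings.tunnel_length
                and State(states[t - 1]) in IGT_STATES[:-1]):
            cost += w * df * annual_intervention_cost
    return cost, qalys, years


def accrue_cohort(trajs: CohortTrajectories, assignments: CohortAssignments,
                  params: ModelParameters) -> pd.DataFrame:
    """Per-subject outcomes for one arm as a DataFrame.

    Columns: cost, qalys, survival_years, time_to_onset and
    time_to_complication (horizon-censored), plus baseline/incident
    membership flags for the diabetes/IGT subgroup.
    """
    settings = params.settings
    horizon = settings.horizon
    S = trajs.states
    n = trajs.n
    w = half_cycle_weights(horizon)
    df = discount_factor(np.arange(horizon + 1), settings.discount_rate)
    wdf = w * df

    state_cost = _state_cost_vector(params.costs)
    utility = _utility_vector(params.utilities, trajs.initiation_age)

    cost = (state_cost[S] * wdf).sum(axis=1) + assignments.screening_cost
    qalys = (utility[S] * wdf).sum(axis=1)
    years = (trajs.alive * w).sum(axis=1)

    annual_iv = params.intervention_cost(trajs.strategy_id)
    if annual_iv > 0:
        tunnel = settings.tunnel_length
        # intervention delivered over year t if the subject began it in a
        # tunnel state; charged at cycles 1..tunnel_length
        prev_in_tunnel = (S[:, :tunnel] >= int(State.IGT_1)) & \
                         (S[:, :tunnel] <= int(State.IGT_6))
        charge = prev_in_tunnel * assignments.receives_intervention[:, None]
        cost = cost + annual_iv * (charge * wdf[1:tunnel + 1]).sum(axis=1)

    onset = trajs.time_to_dm_onset
    comp = trajs.time_to_first_complication
    base_igt = assignments.state == "igt"
    base_dm = assignments.state == "onset_dm"
    ever_dm = ~np.isnan(onset)
    return pd.DataFrame({
        "cost": cost,
        "qalys": qalys,
        "survival_years": years,
        "time_to_onset": np.where(np.isnan(onset), float(horizon), onset),
        "time_to_complication": np.where(np.isnan(comp), float(horizon), comp),
        "baseline_igt": base_igt,
        "baseline_dm": base_dm,
        "ever_dm": ever_dm,
        "receives_intervention": assignments.receives_intervention,
    })


@dataclass(frozen=True)
class OutcomeSummary:
    """Per-strategy, per-initiation-age aggregate outcomes."""

    strategy: str
    initiation_age: int
    n_subjects: int
    n_eligible: int
    remaining_years_dm_igt: float
    remaining_years_range: tuple[float, float]
    qalys_dm_igt: float
    qalys_range: tuple[float, float]
    cost_per_subject: float
    cost_range: tuple[float, float]
    cost_all_subjects: float
    saving_vs_control: float
    increment_qalys_vs_control: float
    extra_time_onset: float
    extra_time_complication: float

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        lo, hi = d.pop("remaining_years_range")
        d["remaining_years_lo"], d["remaining_years_hi"] = lo, hi
        lo, hi = d.pop("qalys_range")
        d["qalys_lo"], d["qalys_hi"] = lo, hi
        lo, hi = d.pop("cost_range")
        d["cost_lo"], d["cost_hi"] = lo, hi
        return d


def _range(values: np.ndarray, kind: str) -> tuple[float, float]:
    if len(values) == 0:
        return (float("nan"), float("nan"))
    if kind == "minmax":
        return float(np.min(values)), float(np.max(values))
    return (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))


def summarize(outcomes_by_arm: Mapping[str, pd.DataFrame],
              params: ModelParameters, initiation_age: int) -> pd.DataFrame:
    """Aggregate per-subject outcomes of all arms against the control arm.

    ``outcomes_by_arm`` maps strategy id to the :func:`accrue_cohort`
    frame of that arm; the control arm must be present.  Returns one row
    per arm with means, ranges, savings/increments vs control and the
    extra-time outcomes.
    """
    if "control" not in outcomes_by_arm:
        raise ValueError("summarize requires the control arm")
    conv = params.conventions
    horizon = params.settings.horizon

    def eligible_mask(frame: pd.DataFrame) -> np.ndarray:
        base = frame["baseline_igt"] | frame["baseline_dm"]
        if conv.eligibility == "incident":
            base = base | frame["ever_dm"]
        return base.to_numpy()

    def arm_stats(frame: pd.DataFrame) -> dict:
        elig = eligible_mask(frame)
        if not elig.any():
            warnings.warn("diabetes/IGT subgroup is empty; reporting NaNs")
        sub = frame[elig]
        cost_pop = sub if conv.cost_population == "subgroup" else frame
        igt = frame[frame["baseline_igt"].to_numpy()]
        return {
            "n_subjects": len(frame),
            "n_eligible": int(elig.sum()),
            "years": float(sub["survival_years"].mean()) if len(sub) else np.nan,
            "years_rng": _range(sub["survival_years"].to_numpy(), conv.range_kind),
            "qalys": float(sub["qalys"].mean()) if len(sub) else np.nan,
            "qalys_rng": _range(sub["qalys"].to_numpy(), conv.range_kind),
            "cost": float(cost_pop["cost"].mean()) if len(cost_pop) else np.nan,
            "cost_rng": _range(cost_pop["cost"].to_numpy(), conv.range_kind),
            "cost_all": float(frame["cost"].mean()),
            "onset": float(np.minimum(igt["time_to_onset"], horizon).mean())
                     if len(igt) else np.nan,
            "comp": float(np.minimum(igt["time_to_complication"], horizon).mean())
                    if len(igt) else np.nan,
        }

    control = arm_stats(outcomes_by_arm["control"])
    rows = []
    for arm, frame in outcomes_by_arm.items():
        s = arm_stats(frame) if arm != "control" else control
        rows.append(OutcomeSummary(
            strategy=arm,
            initiation_age=initiation_age,
            n_subjects=s["n_subjects"],
            n_eligible=s["n_eligible"],
            remaining_years_dm_igt=s["years"],
            remaining_years_range=s["years_rng"],
            qalys_dm_igt=s["qalys"],
            qalys_range=s["qalys_rng"],
            cost_per_subject=s["cost"],
            cost_range=s["cost_rng"],
            cost_all_subjects=s["cost_all"],
            saving_vs_control=control["cost"] - s["cost"],
            increment_qalys_vs_control=s["qalys"] - control["qalys"],
            extra_time_onset=s["onset"] - control["onset"],
            extra_time_complication=s["comp"] - control["comp"],
        ).as_dict())
    return pd.DataFrame(rows)
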