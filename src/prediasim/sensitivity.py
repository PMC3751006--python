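"""One-way sensitivity analysis over the model's main assumptions.

Each scenario perturbs exactly one parameter (or one named parameter
group) — +/-20% for screening positivity, diabetes and complication
incidence/mortality, all cost groups, disease utilities and the discount
rate; x3.0 / x0.5 for the incidence of IGT; and 80% / 60% levels for IGT
detection and screening compliance.  Every scenario reruns the full
model under the same master seed (common random numbers), so scenario
deltas are not swamped by Monte-Carlo noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .markov_engine import LifeTable
from .model import run_model
from .parameters import ModelParameters, ParameterError

logger = logging.getLogger(__name__)

_MULT_PATHS = (
    "screening.positive_rates",
    "rates.igt_to_dm",
    "rates.complication_incidence",
    "rates.complication_mortality",
    "costs.screening",
    "costs.intervention",
    "costs.treatment",
    "utilities.disease",
    "settings.discount_rate",
    "shared.normal_to_igt",
)
_REPL_PATHS = ("screening.detection_level", "screening.compliance")


@dataclass(frozen=True)
class SensitivityScenario:
    """A single one-at-a-time perturbation of the parameter set."""

    label: str
    parameter_path: str
    multiplier: float | None = None
    replacement: float | None = None

    def __post_init__(self) -> None:
        if (self.multiplier is None) == (self.replacement is None):
            raise ParameterError(
                "exactly one of multiplier/replacement must be set")
        if self.parameter_path != "baseline" and \
                self.parameter_path not in _MULT_PATHS + _REPL_PATHS:
            raise ParameterError(
                f"unknown parameter path {self.parameter_path!r}")


BASELINE = SensitivityScenario("baseline", "baseline", multiplier=1.0,
                               replacement=None)


def default_scenario_grid() -> list[SensitivityScenario]:
    """The study's one-way grid, baseline row first."""
    grid = [BASELINE]
    for path in ("screening.positive_rates", "rates.igt_to_dm",
                 "rates.complication_incidence", "rates.complication_mortality",
                 "costs.screening", "costs.intervention", "costs.treatment",
                 "utilities.disease", "settings.discount_rate"):
        for m in (0.8, 1.2):
            grid.append(SensitivityScenario(f"{path} x{m}", path, multiplier=m))
    for m in (3.0, 0.5):  # IGT incidence +200% / -50%
        grid.append(SensitivityScenario(f"shared.normal_to_igt x{m}",
                                        "shared.normal_to_igt", multiplier=m))
    for path in ("screening.detection_level", "screening.compliance"):
        for level in (0.8, 0.6):
            grid.append(SensitivityScenario(f"{path}={level}", path,
                                            replacement=level))
    return grid


def _clamp_prob(name: str, value: float) -> float:
    if value > 1.0 or value < 0.0:
        logger.warning("scenario drives %s to %.4f; clamping to [0, 1]",
                       name, value)
    return min(1.0, max(0.0, value))


def apply_scenario(params: ModelParameters,
                   scenario: SensitivityScenario) -> ModelParameters:
    """Return a new parameter set with the scenario's perturbation applied.

    Probability and utility products outside [0, 1] are clamped with a
    logged warning.
    """
    path = scenario.parameter_path
    m = scenario.multiplier

    if path == "baseline":
        return params

    if path in _REPL_PATHS:
        field = path.split(".", 1)[1]
        return replace(params, screening=replace(
            params.screening, **{field: scenario.replacement}))

    if path == "screening.positive_rates":
        s = params.screening
        pos_2hpg = _clamp_prob("2hPG positive rate", (1.0 - s.neg_rate_2hpg) * m)
        ogtt = _clamp_prob("OGTT positive rate", s.ogtt_positive_rate * m)
        return replace(params, screening=replace(
            s, neg_rate_2hpg=1.0 - pos_2hpg, ogtt_positive_rate=ogtt))

    if path == "shared.normal_to_igt":
        return replace(params, shared=replace(
            params.shared,
            normal_to_igt=_clamp_prob("normal->IGT", params.shared.normal_to_igt * m)))

    if path == "rates.igt_to_dm":
        strategies = {
            sid: replace(st, igt_to_dm_rate_by_age={
                age: _clamp_prob(f"{sid} IGT->DM[{age}]", r * m)
                for age, r in st.igt_to_dm_rate_by_age.items()})
            for sid, st in params.strategies.items()}
        return replace(params, strategies=strategies)

    if path == "rates.complication_incidence":
        strategies = {
            sid: replace(st, complication_incidence={
                c: _clamp_prob(f"{sid} incidence[{c}]", r * m)
                for c, r in st.complication_incidence.items()})
            for sid, st in params.strategies.items()}
        return replace(params, strategies=strategies)

    if path == "rates.complication_mortality":
        strategies = {
            sid: replace(st, complication_mortality={
                c: _clamp_prob(f"{sid} mortality[{c}]", r * m)
                for c, r in st.complication_mortality.items()})
            for sid, st in params.strategies.items()}
        return replace(params, strategies=strategies)

    if path == "costs.screening":
        return replace(
            params,
            costs=replace(params.costs, screening=params.costs.screening * m),
            screening=replace(params.screening,
                              screening_cost=params.screening.screening_cost * m))

    if path == "costs.intervention":
        strategies = {
            sid: replace(st, annual_intervention_cost=st.annual_intervention_cost * m)
            for sid, st in params.strategies.items()}
        return replace(
            params, strategies=strategies,
            costs=replace(params.costs,
                          diet_or_exercise=params.costs.diet_or_exercise * m,
                          duo=params.costs.duo * m))

    if path == "costs.treatment":
        c = params.costs
        return replace(params, costs=replace(
            c, onset_dm=c.onset_dm * m, cvd=c.cvd * m, nephropathy=c.nephropathy * m,
            neuropathy=c.neuropathy * m, retinopathy=c.retinopathy * m))

    if path == "utilities.disease":
        by_age = {
            age: {state: (u if state in ("normal", "death")
                          else _clamp_prob(f"utility[{age}][{state}]", u * m))
                  for state, u in row.items()}
            for age, row in params.utilities.by_age_and_state.items()}
        return replace(params, utilities=replace(
            params.utilities, by_age_and_state=by_age))

    if path == "settings.discount_rate":
        return replace(params, settings=replace(
            params.settings, discount_rate=params.settings.discount_rate * m))

    raise ParameterError(f"unhandled parameter path {path!r}")


def run_sensitivity(grid: Sequence[SensitivityScenario], params: ModelParameters,
                    seed: int, life_table: LifeTable | None = None,
                    n: int | None = None, ages: Sequence[int] | None = None,
                    arms: Sequence[str] | None = None) -> pd.DataFrame:
    """Savings and increment QALYs vs control for every scenario x arm x age.

    Every scenario reuses the baseline seed, so the output is
    deterministic given the master seed and differences between
    scenarios reflect the perturbation, not resampling.
    """
    if not grid:
        raise ParameterError("sensitivity grid is empty")
    rows = []
    for scenario in grid:
        perturbed = apply_scenario(params, scenario)
        summary, _ = run_model(perturbed, seed, life_table=life_table, n=n,
                               ages=ages, arms=arms)
        for _, rec in summary.iterrows():
            if rec["strategy"] == "control":
                continue
            rows.append({
                "scenario": scenario.label,
                "parameter_path": scenario.parameter_path,
                "strategy": rec["strategy"],
                "initiation_age": rec["initiation_age"],
                "saving_vs_control": rec["saving_vs_control"],
                "increment_qalys_vs_control": rec["increment_qalys_vs_control"],
            })
    return pd.DataFrame(rows)
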