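"""High-level orchestration: run all arms at one or more initiation ages."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .decision_tree import sample_paired_assignments
from .markov_engine import LifeTable, draw_uniforms, run_microsim
from .outcomes import accrue_cohort, summarize
from .parameters import INITIATION_AGES, STRATEGY_IDS, ModelParameters
from .synthetic_data import default_life_table


def run_age(params: ModelParameters, initiation_age: int, seed: int,
            life_table: LifeTable | None = None, n: int | None = None,
            arms: Sequence[str] | None = None) -> dict[str, pd.DataFrame]:
    """Simulate every requested arm at one initiation age.

    All arms share the latent cohort and the per-cycle uniform deviates
    (common random numbers), so arm contrasts are paired.  Returns the
    per-subject outcome frame of each arm.
    """
    life_table = life_table or default_life_table()
    n = n or params.settings.cohort_size
    arms = tuple(arms) if arms else STRATEGY_IDS
    if "control" not in arms:
        arms = tuple(arms) + ("control",)
    assignments = sample_paired_assignments(params, n, seed, arms=arms)
    uniforms = draw_uniforms(n, params.settings.horizon,
                             int(seed) % (2**31) + initiation_age)
    out: dict[str, pd.DataFrame] = {}
    for arm in arms:
        trajs = run_microsim(assignments[arm], arm, params, initiation_age,
                             life_table, uniforms=uniforms)
        out[arm] = accrue_cohort(trajs, assignments[arm], params)
    return out


def run_model(params: ModelParameters, seed: int,
              life_table: LifeTable | None = None, n: int | None = None,
              ages: Sequence[int] | None = None,
              arms: Sequence[str] | None = None,
              ) -> tuple[pd.DataFrame, Mapping[int, Mapping[str, pd.DataFrame]]]:
    """Full run over initiation ages; returns (summary table, raw outcomes).

    The summary table has one row per arm x age with the headline
    outcomes of :func:`prediasim.outcomes.summarize`.
    """
    ages = tuple(ages) if ages else INITIATION_AGES
    summaries = []
    raw: dict[int, dict[str, pd.DataFrame]] = {}
    for age in ages:
        by_arm = run_age(params, age, seed, life_table=life_table, n=n, arms=arms)
        raw[age] = by_arm
        summaries.append(summarize(by_arm, params, age))
    return pd.concat(summaries, ignore_index=True), raw
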