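"""Nonparametric between-arm comparisons of subject-level outcomes.

Continuous outcomes (QALYs, discounted costs, survival years) are
compared between arms with the two-sided Wilcoxon rank-sum
(Mann-Whitney) test: exact enumeration for small tie-free samples,
otherwise the continuity-corrected normal approximation with midranks
for ties.  Significance is declared at alpha = 0.05, unadjusted.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
_EXACT_MAX_N = 20

OUTCOME_COLUMNS = {"qalys": "qalys", "cost": "cost",
                   "survival_years": "survival_years"}


@dataclass(frozen=True)
class ComparisonResult:
    """Wilcoxon rank-sum comparison of one outcome between two arms."""

    arm_a: str
    arm_b: str
    outcome: str
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float],
                  arm_a: str = "a", arm_b: str = "b",
                  outcome: str = "outcome") -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test on two samples of real values.

    Uses exact enumeration when both samples have at most 20 tie-free
    observations, and the continuity-corrected normal approximation with
    midrank tie handling otherwise.  Two samples with all values
    identical are degenerate and reported as p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(arm_a, arm_b, outcome,
                                statistic=float(len(a) * len(b) / 2.0),
                                p_value=1.0, significant=False, degenerate=True)
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(a) <= _EXACT_MAX_N
                         and len(b) <= _EXACT_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    p = float(min(1.0, res.pvalue))
    return ComparisonResult(arm_a, arm_b, outcome, statistic=float(res.statistic),
                            p_value=p, significant=p < ALPHA)


def compare_arms(outcomes_by_arm: Mapping[str, pd.DataFrame],
                 eligibility: str = "baseline",
                 cost_population: str = "subgroup",
                 outcomes: Sequence[str] = ("qalys", "cost", "survival_years"),
                 ) -> pd.DataFrame:
    """All pairwise arm comparisons for the requested outcomes.

    QALYs and survival are compared on the diabetes/IGT subgroup; costs
    on the configured cost-averaging population, matching the outcome
    definitions used in the summaries.
    """
    def subgroup(frame: pd.DataFrame) -> np.ndarray:
        mask = frame["baseline_igt"] | frame["baseline_dm"]
        if eligibility == "incident":
            mask = mask | frame["ever_dm"]
        return mask.to_numpy()

    rows = []
    for arm_a, arm_b in combinations(outcomes_by_arm, 2):
        fa, fb = outcomes_by_arm[arm_a], outcomes_by_arm[arm_b]
        for outcome in outcomes:
            col = OUTCOME_COLUMNS[outcome]
            if outcome == "cost" and cost_population == "all":
                va, vb = fa[col], fb[col]
            else:
                va, vb = fa[col][subgroup(fa)], fb[col][subgroup(fb)]
            res = rank_sum_test(va, vb, arm_a, arm_b, outcome)
            rows.append(asdict(res))
    return pd.DataFrame(rows)
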