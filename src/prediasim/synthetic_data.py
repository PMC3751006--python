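"""Synthetic inputs: a calibrated life table and reproducible test cohorts.

The national all-cause mortality schedule behind the competing-risk
death transitions is not deposited anywhere, so the package bundles a
parametric Gompertz-Makeham stand-in (synthetic), tabulated per integer
age:  qx(age) = 1 - exp(-(a + b * c**age)).  The default parameters
(a = 5e-4, b = 3e-5, c = 1.094) give residual life expectancies at ages
25/40/60 of roughly 52/38/20 years, plausible for a contemporary Chinese
adult population; they are frozen constants, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .decision_tree import (
    CohortAssignments,
    InitialAssignment,
    initial_distribution,
    sample_cohort,
    sample_paired_assignments,
)
from .markov_engine import LifeTable
from .parameters import ModelParameters, ParameterError

DEFAULT_AGE_RANGE = (20, 100)


@dataclass(frozen=True)
class LifeTableSpec:
    """Parametric mortality model for generating a life-table fixture."""

    model: str = "gompertz_makeham"
    makeham_a: float = 5e-4
    gompertz_b: float = 3e-5
    gompertz_c: float = 1.094
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE

    def __post_init__(self) -> None:
        if self.model != "gompertz_makeham":
            raise ParameterError(f"unsupported life-table model {self.model!r}")
        if self.makeham_a < 0 or self.gompertz_b < 0 or self.gompertz_c <= 0:
            raise ParameterError("life-table hazard parameters must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ParameterError("age_range must be increasing")


def generate_life_table(spec: LifeTableSpec | None = None) -> LifeTable:
    """Tabulate annual death probabilities from the parametric hazard."""
    spec = spec or LifeTableSpec()
    ages = np.arange(spec.age_range[0], spec.age_range[1] + 1)
    hazard = spec.makeham_a + spec.gompertz_b * spec.gompertz_c ** ages
    qx = 1.0 - np.exp(-hazard)
    if np.any((qx <= 0) | (qx >= 1)):
        raise ParameterError("life-table spec yields qx outside (0, 1)")
    return LifeTable(ages=ages, qx=qx)


def default_life_table() -> LifeTable:
    """The frozen life-table fixture bundled with the package."""
    text = resources.files("prediasim").joinpath("data/life_table.csv").read_text()
    import io
    return LifeTable.from_csv(io.StringIO(text))


def write_default_life_table(path: str | Path) -> None:
    """Regenerate the bundled fixture file from the default spec."""
    generate_life_table().to_csv(path)


def expected_survival_years(life_table: LifeTable, start_age: int,
                            horizon: int) -> float:
    """Horizon-capped expected survival of a healthy subject (product-limit).

    Direct sum of cumulative survival probabilities over the horizon;
    serves as the closed-form check on the mortality fixture.
    """
    surv = np.cumprod(1.0 - life_table.qx_slice(start_age, horizon))
    # trapezoid over survival curve: half credit in the year of death
    probs = np.concatenate([[1.0], surv])
    return float((probs[:-1] + probs[1:]).sum() / 2.0)


def generate_test_cohort(n: int, arm: str, params: ModelParameters,
                         seed: int) -> list[InitialAssignment]:
    """One-call cohort fixture: decision-tree distribution plus sampling."""
    dist = initial_distribution(params.strategies[arm], params.screening,
                                params.shared)
    return sample_cohort(dist, n, seed)


def generate_paired_cohorts(params: ModelParameters, n: int, seed: int,
                            arms: tuple[str, ...] | None = None,
                            ) -> dict[str, CohortAssignments]:
    """Common-random-number cohorts for every arm (vectorised)."""
    return sample_paired_assignments(params, n, seed, arms=arms)
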