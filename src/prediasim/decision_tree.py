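"""Screening decision tree: initial state assignment for each arm.

Each simulated adult passes through the screen-entry tree once, at
baseline.  A compliant subject takes the 2-h plasma-glucose test; a
positive result (2-h PG >= 6.67 mmol/L) triggers a confirmatory OGTT,
whose positives split into impaired glucose tolerance (IGT) and
undiagnosed diabetes.  Detected IGT subjects in the diet/exercise/duo
arms enter the 6-year lifestyle intervention.  Noncompliant subjects,
and every subject in the control arm, carry the same latent state
distribution but remain undiagnosed — arms differ only in diagnosis,
intervention and the screening cost, which makes paired
(common-random-number) comparisons across arms meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    INTERVENTION_IDS,
    ModelParameters,
    ParameterError,
    ScreeningProfile,
    SharedRates,
    StrategySpec,
)

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class InitialAssignment:
    """Baseline status of one simulated subject.

    ``screened`` records attendance (and hence whether the subject's
    later complication transitions follow the arm's column or the
    control column); ``diagnosed`` requires a positive OGTT and, for
    IGT, successful detection.
    """

    state: str  # normal | igt | onset_dm
    diagnosed: bool
    receives_intervention: bool
    screening_cost_incurred: float
    screened: bool = False

    def __post_init__(self) -> None:
        if self.state not in ("normal", "igt", "onset_dm"):
            raise ParameterError(f"invalid initial state {self.state!r}")
        if self.receives_intervention and not (self.state == "igt" and self.diagnosed):
            raise ParameterError(
                "receives_intervention requires a diagnosed IGT subject")


def latent_state_probabilities(profile: ScreeningProfile) -> dict[str, float]:
    """Population probabilities of the latent baseline state.

    Derived purely from the screening-yield products: a fraction
    ``1 - neg_rate_2hpg`` screens positive; of those, ``ogtt_positive_rate``
    confirm on OGTT, splitting ``igt_fraction_of_positive`` : remainder
    into IGT and undiagnosed diabetes.  Everyone else is normal.
    """
    p_positive = 1.0 - profile.neg_rate_2hpg
    p_igt = p_positive * profile.ogtt_positive_rate * profile.igt_fraction_of_positive
    p_dm = p_positive * profile.ogtt_positive_rate * (1.0 - profile.igt_fraction_of_positive)
    return {"normal": 1.0 - p_igt - p_dm, "igt": p_igt, "onset_dm": p_dm}


def initial_distribution(strategy: StrategySpec, profile: ScreeningProfile,
                         shared: SharedRates | None = None,
                         ) -> dict[InitialAssignment, float]:
    """Distribution of baseline assignments for one arm.

    Compliant subjects in screening arms incur the screening cost;
    detected IGT subjects enter intervention only in the diet, exercise
    and duo arms.  Noncompliant subjects are assigned exactly as in the
    control arm (but remain members of their arm's cohort).
    """
    latent = latent_state_probabilities(profile)
    dist: dict[InitialAssignment, float] = {}

    def add(assignment: InitialAssignment, prob: float) -> None:
        if prob > 0.0:
            dist[assignment] = dist.get(assignment, 0.0) + prob

    if not strategy.has_screening:
        for state, prob in latent.items():
            add(InitialAssignment(state, False, False, 0.0, screened=False), prob)
    else:
        c = profile.compliance
        d = profile.detection_level
        cost = profile.screening_cost
        intervenes = strategy.id in INTERVENTION_IDS
        for state, prob in latent.items():
            # noncompliant: as control
            add(InitialAssignment(state, False, False, 0.0, screened=False),
                prob * (1.0 - c))
            if state == "normal":
                add(InitialAssignment(state, False, False, cost, screened=True),
                    prob * c)
            elif state == "igt":
                add(InitialAssignment(state, True, intervenes, cost, screened=True),
                    prob * c * d)
                add(InitialAssignment(state, False, False, cost, screened=True),
                    prob * c * (1.0 - d))
            else:  # onset_dm: diagnosed whenever screened
                add(InitialAssignment(state, True, False, cost, screened=True),
                    prob * c)

    total = sum(dist.values())
    if abs(total - 1.0) > _SUM_TOL:
        raise RuntimeError(f"initial distribution sums to {total!r}, not 1")
    return {a: p / total for a, p in dist.items()}


def sample_cohort(dist: dict[InitialAssignment, float], n: int,
                  seed: int) -> list[InitialAssignment]:
    """Draw ``n`` independent baseline assignments (reproducible by seed)."""
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    assignments = list(dist.keys())
    probs = np.array([dist[a] for a in assignments], dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(assignments), size=n, p=probs / probs.sum())
    return [assignments[i] for i in idx]


@dataclass(frozen=True)
class CohortAssignments:
    """Vectorised baseline assignments for one arm (one entry per subject)."""

    state: np.ndarray                 # '<U8' latent state names
    diagnosed: np.ndarray             # bool
    receives_intervention: np.ndarray  # bool
    screened: np.ndarray              # bool
    screening_cost: np.ndarray        # float

    @property
    def n(self) -> int:
        return len(self.state)

    def __getitem__(self, i: int) -> InitialAssignment:
        return InitialAssignment(
            state=str(self.state[i]),
            diagnosed=bool(self.diagnosed[i]),
            receives_intervention=bool(self.receives_intervention[i]),
            screening_cost_incurred=float(self.screening_cost[i]),
            screened=bool(self.screened[i]),
        )


def sample_paired_assignments(params: ModelParameters, n: int, seed: int,
                              arms: tuple[str, ...] | None = None,
                              ) -> dict[str, CohortAssignments]:
    """Baseline assignments for every arm on one shared latent population.

    The latent state, compliance and detection draws are made once per
    subject and reused across arms (common random numbers), so subject
    ``i`` is the same person in every arm and arm contrasts are paired.
    """
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    if arms is None:
        arms = tuple(params.strategies)
    profile = params.screening
    latent = latent_state_probabilities(profile)

    rng = np.random.default_rng([int(seed) % (2**31), 911])
    u_state = rng.random(n)
    u_comply = rng.random(n)
    u_detect = rng.random(n)

    states = np.full(n, "normal", dtype="<U8")
    states[u_state < latent["igt"] + latent["onset_dm"]] = "onset_dm"
    states[u_state < latent["igt"]] = "igt"
    complies = u_comply < profile.compliance
    detected = u_detect < profile.detection_level

    out: dict[str, CohortAssignments] = {}
    for arm in arms:
        strategy = params.strategies[arm]
        if strategy.has_screening:
            screened = complies
            diagnosed = screened & (
                (states == "onset_dm") | ((states == "igt") & detected))
            receives = diagnosed & (states == "igt") & (arm in INTERVENTION_IDS)
            cost = np.where(screened, profile.screening_cost, 0.0)
        else:
            screened = np.zeros(n, dtype=bool)
            diagnosed = np.zeros(n, dtype=bool)
            receives = np.zeros(n, dtype=bool)
            cost = np.zeros(n)
        out[arm] = CohortAssignments(
            state=states.copy(), diagnosed=diagnosed,
            receives_intervention=receives, screened=screened,
            screening_cost=cost,
        )
    return out


def assignments_from_list(cohort: list[InitialAssignment]) -> CohortAssignments:
    """Pack a list of assignments into the vectorised container."""
    return CohortAssignments(
        state=np.array([a.state for a in cohort], dtype="<U8"),
        diagnosed=np.array([a.diagnosed for a in cohort], dtype=bool),
        receives_intervention=np.array(
            [a.receives_intervention for a in cohort], dtype=bool),
        screened=np.array([a.screened for a in cohort], dtype=bool),
        screening_cost=np.array(
            [a.screening_cost_incurred for a in cohort], dtype=float),
    )
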