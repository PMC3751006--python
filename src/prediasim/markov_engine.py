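"""Annual-cycle Markov microsimulation of the natural history of diabetes.

States: normal glucose tolerance; IGT as a chain of six one-year tunnel
states (the lifestyle-intervention years) followed by a post-tunnel IGT
state; onset of diabetes; four mutually exclusive complication states
(CVD, retinopathy, nephropathy, overt neuropathy); and absorbing death.

Within a cycle, all-cause death from the life table is applied first;
disease transitions act conditionally on survival.  CVD and nephropathy
carry complication-specific mortality on top of the life-table hazard;
retinopathy and neuropathy carry background mortality only, as those
complications are not fatal.  The IGT->diabetes transition uses the
arm-specific rate only while the subject is inside the intervention
tunnel (receives_intervention and cycle <= tunnel length); at all other
times the control rate applies.  Complication incidence/mortality follow
the arm's column for screened subjects and the control column otherwise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .decision_tree import CohortAssignments
from .parameters import (
    INITIATION_AGES,
    ModelParameters,
    ParameterError,
    SharedRates,
    StrategySpec,
)

_ROW_TOL = 1e-12


class State(IntEnum):
    """Markov states in the fixed inverse-CDF sampling order."""

    NORMAL = 0
    IGT_1 = 1
    IGT_2 = 2
    IGT_3 = 3
    IGT_4 = 4
    IGT_5 = 5
    IGT_6 = 6
    IGT_POST = 7
    ONSET_DM = 8
    CVD = 9
    RETINOPATHY = 10
    NEPHROPATHY = 11
    NEUROPATHY = 12
    DEATH = 13


IGT_STATES = tuple(State(k) for k in range(State.IGT_1, State.IGT_POST + 1))
COMPLICATION_STATES = (State.CVD, State.RETINOPATHY, State.NEPHROPATHY,
                       State.NEUROPATHY)
#: Markov state -> health-state name used for costs/utilities.
STATE_GROUP = {State.NORMAL: "normal", State.ONSET_DM: "onset_dm",
               State.CVD: "cvd", State.RETINOPATHY: "retinopathy",
               State.NEPHROPATHY: "nephropathy", State.NEUROPATHY: "neuropathy",
               State.DEATH: "death",
               **{s: "igt" for s in IGT_STATES}}

_INITIAL_STATE = {"normal": State.NORMAL, "igt": State.IGT_1,
                  "onset_dm": State.ONSET_DM}


class ConfigurationError(ParameterError):
    """Transition rates leave a negative stay-probability."""


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities qx indexed by integer age."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.qx):
            raise ParameterError("life table ages and qx differ in length")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ParameterError("life-table qx values must lie in [0, 1]")
        if np.any(np.diff(self.ages) != 1):
            raise ParameterError("life-table ages must be consecutive integers")

    def qx_at(self, age: int) -> float:
        i = int(age) - int(self.ages[0])
        if not 0 <= i < len(self.qx):
            raise ParameterError(f"age {age} outside life table "
                                 f"[{self.ages[0]}, {self.ages[-1]}]")
        return float(self.qx[i])

    def qx_slice(self, start_age: int, n_years: int) -> np.ndarray:
        return np.array([self.qx_at(start_age + t) for t in range(n_years)])

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        lines = ["age,qx"] + [f"{int(a)},{float(q)!r}" for a, q in zip(self.ages, self.qx)]
        text = "\n".join(lines) + "\n"
        if isinstance(path, io.TextIOBase):
            path.write(text)
        else:
            Path(path).write_text(text)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "LifeTable":
        text = path.read() if isinstance(path, io.TextIOBase) else Path(path).read_text()
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        header = [h.strip().lower() for h in lines[0].split(",")]
        if header[:2] != ["age", "qx"]:
            raise ParameterError("life-table file must have header 'age,qx'")
        ages, qx = [], []
        for ln in lines[1:]:
            a, q = ln.split(",")[:2]
            ages.append(int(a))
            qx.append(float(q))
        return cls(ages=np.array(ages), qx=np.array(qx))


@dataclass(frozen=True)
class IndividualTrajectory:
    """One subject's annual state sequence with derived event times."""

    states: Sequence[State]
    initiation_age: int
    time_to_dm_onset: int | None
    time_to_first_complication: int | None
    death_cycle: int | None

    @property
    def age_at_cycle(self) -> list[int]:
        return [self.initiation_age + t for t in range(len(self.states))]


@dataclass(frozen=True)
class CohortTrajectories:
    """State paths for a whole simulated arm: ``states[i, t]`` for cycle t."""

    states: np.ndarray  # (n, horizon+1) int8
    initiation_age: int
    strategy_id: str

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1] - 1

    def _first_cycle_at_or_above(self, threshold: int,
                                 upper: int | None = None) -> np.ndarray:
        s = self.states
        hit = (s >= threshold) if upper is None else ((s >= threshold) & (s <= upper))
        any_hit = hit.any(axis=1)
        first = hit.argmax(axis=1).astype(float)
        first[~any_hit] = np.nan
        return first

    @property
    def time_to_dm_onset(self) -> np.ndarray:
        """First cycle in diabetes or beyond (NaN if never)."""
        out = self._first_cycle_at_or_above(State.ONSET_DM, State.NEUROPATHY)
        return out

    @property
    def time_to_first_complication(self) -> np.ndarray:
        return self._first_cycle_at_or_above(State.CVD, State.NEUROPATHY)

    @property
    def death_cycle(self) -> np.ndarray:
        return self._first_cycle_at_or_above(State.DEATH)

    @property
    def alive(self) -> np.ndarray:
        return self.states != int(State.DEATH)

    def __getitem__(self, i: int) -> IndividualTrajectory:
        def _opt(x: float) -> int | None:
            return None if np.isnan(x) else int(x)
        return IndividualTrajectory(
            states=[State(s) for s in self.states[i]],
            initiation_age=self.initiation_age,
            time_to_dm_onset=_opt(self.time_to_dm_onset[i]),
            time_to_first_complication=_opt(self.time_to_first_complication[i]),
            death_cycle=_opt(self.death_cycle[i]),
        )

    def to_long_table(self):
        """Subject-cycle dump as a DataFrame (subject, cycle, age, state)."""
        import pandas as pd
        n, width = self.states.shape
        return pd.DataFrame({
            "subject": np.repeat(np.arange(n), width),
            "cycle": np.tile(np.arange(width), n),
            "age": np.tile(self.initiation_age + np.arange(width), n),
            "state": [State(s).name.lower() for s in self.states.ravel()],
        })


# ---------------------------------------------------------------------------
# Transition rows
# ---------------------------------------------------------------------------

def build_transition_row(state: State, strategy: StrategySpec, shared: SharedRates,
                         age: int, life_table: LifeTable, in_intervention: bool,
                         control_strategy: StrategySpec | None = None,
                         initiation_age: int = 40) -> dict[State, float]:
    """One row of the transition matrix as a state -> probability map.

    All-cause death ``qx(age)`` applies first; disease transitions are
    conditional on surviving it.  The IGT->diabetes probability is the
    strategy's own rate when ``in_intervention`` and otherwise the
    control strategy's (or the strategy's own when no control is given,
    as for the control arm itself).
    """
    state = State(state)
    if state == State.DEATH:
        return {State.DEATH: 1.0}
    qx = life_table.qx_at(age)
    surv = 1.0 - qx
    row: dict[State, float] = {}

    if state == State.NORMAL:
        row[State.IGT_1] = surv * shared.normal_to_igt
        row[State.NORMAL] = surv * (1.0 - shared.normal_to_igt)
        row[State.DEATH] = qx
    elif state in IGT_STATES:
        rates = strategy if (in_intervention or control_strategy is None) \
            else control_strategy
        r = rates.igt_to_dm_rate_by_age[initiation_age]
        stay = 1.0 - shared.igt_to_normal - r
        if stay < 0:
            raise ConfigurationError(
                f"IGT exit probabilities exceed 1 for {strategy.id} "
                f"at initiation age {initiation_age}")
        nxt = State.IGT_POST if state in (State.IGT_6, State.IGT_POST) \
            else State(state + 1)
        row[State.NORMAL] = surv * shared.igt_to_normal
        row[nxt] = surv * stay
        row[State.ONSET_DM] = surv * r
        row[State.DEATH] = qx
    elif state == State.ONSET_DM:
        inc = strategy.complication_incidence
        total = sum(inc.values())
        if total > 1.0:
            raise ConfigurationError(
                f"complication incidences for {strategy.id} sum to {total} > 1")
        row[State.ONSET_DM] = surv * (1.0 - total)
        row[State.CVD] = surv * inc["cvd"]
        row[State.RETINOPATHY] = surv * inc["retinopathy"]
        row[State.NEPHROPATHY] = surv * inc["nephropathy"]
        row[State.NEUROPATHY] = surv * inc["neuropathy"]
        row[State.DEATH] = qx
    elif state in (State.CVD, State.NEPHROPATHY):
        which = "cvd" if state == State.CVD else "nephropathy"
        extra = strategy.complication_mortality[which]
        row[state] = surv * (1.0 - extra)
        row[State.DEATH] = qx + surv * extra
    else:  # retinopathy, neuropathy: background mortality only
        row[state] = surv
        row[State.DEATH] = qx

    total = sum(row.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"transition row for {state.name} sums to {total}")
    return row


def step(current_state: State, row: Mapping[State, float], rng_draw: float) -> State:
    """Sample the next state by inverse CDF over the fixed state ordering."""
    cum = 0.0
    ordered = sorted(row.items(), key=lambda kv: int(kv[0]))
    for state, prob in ordered:
        cum += prob
        if rng_draw < cum:
            return state
    return ordered[-1][0]


def validate_transition_rows(params: ModelParameters, life_table: LifeTable,
                             initiation_age: int) -> None:
    """Check every state x arm transition row sums to 1 over the horizon ages."""
    horizon = params.settings.horizon
    control = params.control
    for arm, strategy in params.strategies.items():
        for state in State:
            for age in (initiation_age, initiation_age + horizon - 1):
                for flag in (False, True):
                    row = build_transition_row(
                        state, strategy, params.shared, age, life_table, flag,
                        control_strategy=control, initiation_age=initiation_age)
                    if abs(sum(row.values()) - 1.0) > _ROW_TOL:
                        raise ConfigurationError(
                            f"row {state.name}/{arm}/age {age} does not sum to 1")


# ---------------------------------------------------------------------------
# Microsimulation
# ---------------------------------------------------------------------------

def draw_uniforms(n: int, horizon: int, seed: int) -> np.ndarray:
    """The (n, horizon) uniform deviates shared across arms and scenarios."""
    rng = np.random.default_rng([int(seed) % (2**31), 4057])
    return rng.random((n, horizon))


def run_microsim(cohort: CohortAssignments, strategy_id: str,
                 params: ModelParameters, initiation_age: int,
                 life_table: LifeTable, seed: int | None = None,
                 uniforms: np.ndarray | None = None) -> CohortTrajectories:
    """Simulate every subject of one arm over the model horizon.

    Either ``seed`` or a precomputed ``uniforms`` matrix must be given;
    passing the same matrix to several arms yields common-random-number
    paired trajectories.
    """
    if initiation_age not in INITIATION_AGES:
        raise ParameterError(f"initiation_age must be one of {INITIATION_AGES}")
    n = cohort.n
    if n < 1:
        raise ParameterError("cohort must be nonempty")
    settings = params.settings
    horizon = settings.horizon
    if uniforms is None:
        if seed is None:
            raise ParameterError("run_microsim needs a seed or a uniforms matrix")
        uniforms = draw_uniforms(n, horizon, seed)
    if uniforms.shape != (n, horizon):
        raise ParameterError("uniforms matrix has wrong shape")

    validate_transition_rows(params, life_table, initiation_age)

    strategy = params.strategies[strategy_id]
    control = params.control
    shared = params.shared
    post_tunnel_arm_rate = params.conventions.post_tunnel_rate == "last_intervention"

    r_arm = strategy.igt_to_dm_rate_by_age[initiation_age]
    r_ctl = control.igt_to_dm_rate_by_age[initiation_age]
    ign = shared.igt_to_normal
    p_ni = shared.normal_to_igt

    states = np.empty((n, horizon + 1), dtype=np.int8)
    states[:, 0] = [int(_INITIAL_STATE[s]) for s in cohort.state]

    arm_col = cohort.screened  # arm's complication column; control otherwise
    receives = cohort.receives_intervention

    # Per-column complication scalars (column order: [arm, control])
    cols = []
    for spec_, mask in ((strategy, arm_col), (control, ~arm_col)):
        inc = spec_.complication_incidence
        cols.append({
            "mask": mask,
            "cvd": inc["cvd"], "ret": inc["retinopathy"],
            "neph": inc["nephropathy"], "neuro": inc["neuropathy"],
            "inc_total": sum(inc.values()),
            "m_cvd": spec_.complication_mortality["cvd"],
            "m_neph": spec_.complication_mortality["nephropathy"],
        })

    for t in range(1, horizon + 1):
        qx = life_table.qx_at(initiation_age + t - 1)
        surv = 1.0 - qx
        cur = states[:, t - 1]
        u = uniforms[:, t - 1]
        nxt = cur.copy()

        m = cur == int(State.NORMAL)
        if m.any():
            a = surv * (1.0 - p_ni)
            b = a + surv * p_ni
            nxt[m] = np.where(u[m] < a, int(State.NORMAL),
                              np.where(u[m] < b, int(State.IGT_1),
                                       int(State.DEATH)))

        igt_m = (cur >= int(State.IGT_1)) & (cur <= int(State.IGT_POST))
        if igt_m.any():
            in_tunnel = cur <= int(State.IGT_6)
            active = receives & igt_m & (
                (in_tunnel & (t <= settings.tunnel_length)) | post_tunnel_arm_rate)
            r = np.where(active, r_arm, r_ctl)
            a = surv * ign
            b = a + surv * (1.0 - ign - r)
            c = b + surv * r
            succ = np.minimum(cur + 1, int(State.IGT_POST))
            sel = np.where(u < a, int(State.NORMAL),
                           np.where(u < b, succ,
                                    np.where(u < c, int(State.ONSET_DM),
                                             int(State.DEATH))))
            nxt[igt_m] = sel[igt_m]

        for col in cols:
            cm = col["mask"]
            m = (cur == int(State.ONSET_DM)) & cm
            if m.any():
                a = surv * (1.0 - col["inc_total"])
                b = a + surv * col["cvd"]
                c = b + surv * col["ret"]
                d = c + surv * col["neph"]
                e = d + surv * col["neuro"]
                um = u[m]
                nxt[m] = np.select(
                    [um < a, um < b, um < c, um < d, um < e],
                    [int(State.ONSET_DM), int(State.CVD), int(State.RETINOPATHY),
                     int(State.NEPHROPATHY), int(State.NEUROPATHY)],
                    default=int(State.DEATH))
            for comp_state, key in ((State.CVD, "m_cvd"),
                                    (State.NEPHROPATHY, "m_neph")):
                m = (cur == int(comp_state)) & cm
                if m.any():
                    stay = surv * (1.0 - col[key])
                    nxt[m] = np.where(u[m] < stay, int(comp_state),
                                      int(State.DEATH))

        for comp_state in (State.RETINOPATHY, State.NEUROPATHY):
            m = cur == int(comp_state)
            if m.any():
                nxt[m] = np.where(u[m] < surv, int(comp_state), int(State.DEATH))

        states[:, t] = nxt

    return CohortTrajectories(states=states, initiation_age=initiation_age,
                              strategy_id=strategy_id)


# ---------------------------------------------------------------------------
# Deterministic cohort trace (expected-value oracle)
# ---------------------------------------------------------------------------

def cohort_trace(params: ModelParameters, strategy_id: str, initiation_age: int,
                 life_table: LifeTable, initial_state: str,
                 screened: bool = False, receives_intervention: bool = False,
                 ) -> np.ndarray:
    """Expected state occupancy (horizon+1, n_states) for one subject profile.

    Evaluates the same transition rows as the microsimulation by matrix
    propagation instead of sampling; microsimulated state frequencies
    should converge to this trace as the cohort grows.
    """
    settings = params.settings
    horizon = settings.horizon
    column = params.strategies[strategy_id] if screened else params.control
    control = params.control
    post_tunnel_arm_rate = params.conventions.post_tunnel_rate == "last_intervention"

    occ = np.zeros((horizon + 1, len(State)))
    occ[0, int(_INITIAL_STATE[initial_state])] = 1.0
    for t in range(1, horizon + 1):
        matrix = np.zeros((len(State), len(State)))
        for state in State:
            if state in IGT_STATES:
                in_tunnel = state <= State.IGT_6
                flag = receives_intervention and (
                    (in_tunnel and t <= settings.tunnel_length)
                    or post_tunnel_arm_rate)
            else:
                flag = False
            row = build_transition_row(
                state, column, params.shared, initiation_age + t - 1,
                life_table, flag, control_strategy=control,
                initiation_age=initiation_age)
            for target, prob in row.items():
                matrix[int(state), int(target)] = prob
        occ[t] = occ[t - 1] @ matrix
    return occ
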