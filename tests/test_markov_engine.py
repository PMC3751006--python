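import numpy as np
import pytest

from prediasim.decision_tree import CohortAssignments
from prediasim.markov_engine import (
    IGT_STATES,
    CohortTrajectories,
    ConfigurationError,
    LifeTable,
    State,
    build_transition_row,
    cohort_trace,
    draw_uniforms,
    run_microsim,
    step,
    validate_transition_rows,
)
from prediasim.parameters import ParameterError, load_parameters
from prediasim.synthetic_data import generate_life_table


def flat_life_table(qx_value, lo=20, hi=100):
    ages = np.arange(lo, hi + 1)
    return LifeTable(ages=ages, qx=np.full(len(ages), float(qx_value)))


def uniform_cohort(n, state="igt", receives=False, screened=False):
    return CohortAssignments(
        state=np.full(n, state, dtype="<U8"),
        diagnosed=np.full(n, receives or screened),
        receives_intervention=np.full(n, receives),
        screened=np.full(n, screened or receives),
        screening_cost=np.zeros(n),
    )


class TestTransitionRows:
    def test_death_absorbing(self, params, life_table):
        row = build_transition_row(State.DEATH, params.control, params.shared,
                                   50, life_table, False)
        assert row == {State.DEATH: 1.0}

    def test_onset_row_control_zero_mortality(self, params):
        lt = flat_life_table(0.0)
        row = build_transition_row(State.ONSET_DM, params.control, params.shared,
                                   40, lt, False)
        assert row[State.ONSET_DM] == pytest.approx(0.9184)
        assert row[State.CVD] == pytest.approx(0.0675)
        assert row[State.NEPHROPATHY] == pytest.approx(0.001)

    def test_igt_row_diet_in_tunnel_age25(self, params):
        lt = flat_life_table(0.0)
        row = build_transition_row(State.IGT_1, params.strategies["diet"],
                                   params.shared, 25, lt, True,
                                   control_strategy=params.control,
                                   initiation_age=25)
        assert row[State.ONSET_DM] == pytest.approx(0.0290)
        assert row[State.NORMAL] == pytest.approx(0.116)
        assert row[State.IGT_2] == pytest.approx(0.855)

    def test_igt_row_out_of_intervention_uses_control_rate(self, params):
        lt = flat_life_table(0.0)
        row = build_transition_row(State.IGT_3, params.strategies["diet"],
                                   params.shared, 25, lt, False,
                                   control_strategy=params.control,
                                   initiation_age=25)
        assert row[State.ONSET_DM] == pytest.approx(0.0644)

    def test_tunnel_six_feeds_post_state(self, params, life_table):
        row = build_transition_row(State.IGT_6, params.control, params.shared,
                                   46, life_table, False, initiation_age=40)
        assert State.IGT_POST in row
        assert State.IGT_1 not in row

    def test_mortality_composition_on_cvd(self, params):
        lt = flat_life_table(0.1)
        row = build_transition_row(State.CVD, params.control, params.shared,
                                   60, lt, False)
        # qx first, complication mortality on the survivors
        assert row[State.DEATH] == pytest.approx(0.1 + 0.9 * 0.0087)
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)

    def test_rows_sum_to_one_everywhere(self, params, life_table):
        for age0 in (25, 40, 60):
            validate_transition_rows(params, life_table, age0)

    def test_negative_residual_raises(self, params):
        lt = flat_life_table(0.0)
        broken = load_parameters(
            {"shared": {"igt_to_normal": 0.9}})  # 0.9 + 0.5778 > 1
        with pytest.raises(ConfigurationError):
            build_transition_row(State.IGT_1, broken.control, broken.shared,
                                 60, lt, False, initiation_age=60)


class TestStep:
    def test_absorbing_death(self):
        assert step(State.DEATH, {State.DEATH: 1.0}, 0.99) == State.DEATH

    def test_cdf_boundary_takes_first_positive_state(self, params):
        lt = flat_life_table(0.0)
        row = build_transition_row(State.IGT_1, params.control, params.shared,
                                   40, lt, False, initiation_age=40)
        assert step(State.IGT_1, row, 0.0) == State.NORMAL

    def test_empirical_frequencies_match_row(self, params):
        lt = flat_life_table(0.05)
        row = build_transition_row(State.ONSET_DM, params.control, params.shared,
                                   40, lt, False)
        rng = np.random.default_rng(77)
        draws = rng.random(100_000)
        counts = {}
        for u in draws:
            nxt = step(State.ONSET_DM, row, u)
            counts[nxt] = counts.get(nxt, 0) + 1
        for state, prob in row.items():
            freq = counts.get(state, 0) / len(draws)
            se = np.sqrt(prob * (1 - prob) / len(draws))
            assert abs(freq - prob) <= 3 * se + 1e-12


class TestMicrosim:
    def test_certain_death_kills_everyone_first_cycle(self, params):
        lt = flat_life_table(1.0 - 1e-12)
        trajs = run_microsim(uniform_cohort(200, "normal"), "control", params,
                             40, lt, seed=1)
        assert (trajs.death_cycle == 1).all()

    def test_zero_dynamics_freeze_initial_state(self, params):
        frozen = load_parameters({
            "shared": {"normal_to_igt": 0.0, "igt_to_normal": 0.0},
            "strategies": {sid: {"igt_to_dm_rate_by_age": {25: 0.0, 40: 0.0, 60: 0.0}}
                           for sid in ("diet", "exercise", "duo", "screen_only",
                                       "control")},
        })
        lt = flat_life_table(0.0)
        trajs = run_microsim(uniform_cohort(100, "normal"), "control", frozen,
                             40, lt, seed=2)
        assert (trajs.states == int(State.NORMAL)).all()

    def test_tunnel_index_increments_and_caps_at_six(self, params, life_table):
        trajs = run_microsim(uniform_cohort(4000, "igt", receives=True), "diet",
                             params, 40, life_table, seed=3)
        S = trajs.states
        # tunnel year k is reachable only from tunnel year k-1
        for k in range(int(State.IGT_2), int(State.IGT_6) + 1):
            entered = S[:, 1:] == k
            assert (S[:, :-1][entered] == k - 1).all()
        # leaving the sixth tunnel year never lands in another tunnel state
        after6 = S[:, 1:][S[:, :-1] == int(State.IGT_6)]
        allowed = {int(State.IGT_POST), int(State.NORMAL),
                   int(State.ONSET_DM), int(State.DEATH)}
        assert set(np.unique(after6)) <= allowed
        # fresh IGT always starts at tunnel year one
        entered1 = S[:, 1:] == int(State.IGT_1)
        assert (S[:, :-1][entered1] == int(State.NORMAL)).all()

    def test_seed_reproducibility_bit_exact(self, params, life_table):
        coh = uniform_cohort(1000, "igt", receives=True)
        a = run_microsim(coh, "diet", params, 25, life_table, seed=42)
        b = run_microsim(coh, "diet", params, 25, life_table, seed=42)
        assert np.array_equal(a.states, b.states)

    def test_microsim_matches_cohort_trace_within_3se(self, params, life_table):
        """Monte-Carlo occupancy converges to the deterministic
        expected-value trace of the same transition matrices."""
        n = 20_000
        coh = uniform_cohort(n, "igt", receives=True)
        trajs = run_microsim(coh, "diet", params, 40, life_table, seed=7)
        occ = cohort_trace(params, "diet", 40, life_table, "igt",
                           screened=True, receives_intervention=True)
        for t in (1, 5, 10, 25, 40):
            freq = np.bincount(trajs.states[:, t], minlength=len(State)) / n
            se = np.sqrt(occ[t] * (1 - occ[t]) / n)
            mask = occ[t] > 0
            assert (np.abs(freq - occ[t])[mask] <= 3 * se[mask] + 1e-9).all()

    def test_monte_carlo_error_scales_inverse_sqrt_n(self, params, life_table):
        """SD of the mean time-to-onset across replicates shrinks like
        1/sqrt(n) (factor-of-two tolerance on the 4x prediction)."""
        def replicate_sd(n, reps=20):
            means = []
            for r in range(reps):
                coh = uniform_cohort(n, "igt")
                trajs = run_microsim(coh, "control", params, 40, life_table,
                                     seed=1000 + r)
                onset = trajs.time_to_dm_onset
                means.append(np.where(np.isnan(onset), 40.0, onset).mean())
            return np.std(means)
        sd_small, sd_large = replicate_sd(500), replicate_sd(8000)
        ratio = sd_small / sd_large
        assert 2.0 < ratio < 8.0  # expect 4 = sqrt(8000/500)

    def test_individual_trajectory_consistency(self, params, life_table):
        trajs = run_microsim(uniform_cohort(300, "igt"), "control", params,
                             60, life_table, seed=5)
        for i in (0, 57, 123):
            traj = trajs[i]
            assert len(traj.states) == params.settings.horizon + 1
            if traj.death_cycle is not None:
                assert traj.states[traj.death_cycle] == State.DEATH
                assert all(s == State.DEATH
                           for s in traj.states[traj.death_cycle:])
            if traj.time_to_dm_onset is not None:
                assert traj.states[traj.time_to_dm_onset] >= State.ONSET_DM

    def test_rejects_bad_inputs(self, params, life_table):
        with pytest.raises(ParameterError):
            run_microsim(uniform_cohort(10), "diet", params, 33, life_table,
                         seed=1)
        with pytest.raises(ParameterError):
            run_microsim(uniform_cohort(10), "diet", params, 40, life_table)


class TestLifeTableIO:
    def test_round_trip(self, tmp_path):
        lt = generate_life_table()
        path = tmp_path / "lt.csv"
        lt.to_csv(path)
        back = LifeTable.from_csv(path)
        assert np.array_equal(lt.ages, back.ages)
        assert np.array_equal(lt.qx, back.qx)

    def test_age_outside_table_raises(self, life_table):
        with pytest.raises(ParameterError):
            life_table.qx_at(200)
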