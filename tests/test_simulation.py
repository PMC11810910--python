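"""Session plans, observer choice behaviour, corrections and reward rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import pareidoscope as ps
from pareidoscope.geometry import StimulusGeometry
from pareidoscope.simulate import DEFAULT_COMPOSITION, TrialPlan

TINY = StimulusGeometry.scaled(0.1)


def _session_counts(plans, session):
    counts = {}
    for p in plans:
        if p.session_index == session:
            counts[p.trial_type] = counts.get(p.trial_type, 0) + 1
    return counts


class TestBuildExperiment:
    def test_full_design_composition(self):
        plans, _ = ps.build_experiment("chimpanzee_face", 25, seed=0)
        assert len(plans) == 1200  # 25 sessions x 48 trials
        assert sum(p.trial_type == "test" for p in plans) == 300
        for s in range(25):
            assert _session_counts(plans, s) == {
                "baseline_easy": 12, "baseline_difficult": 24, "test": 12,
            }

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15)
    def test_composition_conserved_for_any_seed(self, seed):
        plans, _ = ps.build_experiment("letter", 2, seed=seed, geometry=TINY)
        for s in range(2):
            assert _session_counts(plans, s) == dict(DEFAULT_COMPOSITION)

    def test_plans_deterministic_under_seed(self):
        a, _ = ps.build_experiment("human_face", 3, seed=5, geometry=TINY)
        b, _ = ps.build_experiment("human_face", 3, seed=5, geometry=TINY)
        assert a == b

    def test_noise_ids_unique_across_experiment(self):
        plans, _ = ps.build_experiment("human_face", 5, seed=1, geometry=TINY)
        ids = [sid for p in plans for sid in p.stimulus_ids]
        assert len(ids) == len(set(ids))

    def test_baseline_trials_have_one_target(self):
        plans, _ = ps.build_experiment("human_face", 2, seed=1, geometry=TINY)
        for p in plans:
            n_targets = sum(sid.startswith("c") for sid in p.stimulus_ids)
            if p.trial_type == "test":
                assert n_targets == 0 and p.correct_cell is None
            else:
                assert n_targets == 1 and p.correct_cell in p.grid_cells

    def test_grid_cells_distinct(self):
        plans, _ = ps.build_experiment("letter", 4, seed=2, geometry=TINY)
        for p in plans:
            assert len(set(p.grid_cells)) == 3

    def test_position_counterbalancing(self):
        # 3 of 6 cells per trial -> each cell used with frequency ~1/2
        plans, _ = ps.build_experiment("letter", 25, seed=3, geometry=TINY)
        usage = np.zeros(6)
        for p in plans:
            usage[list(p.grid_cells)] += 1
        freq = usage / len(plans)
        assert np.all(np.abs(freq - 0.5) < 0.05)


def _make_observer(store, beta=15.0, lapse=0.02, **kw):
    return ps.ObserverParams(
        template=ps.template_from_bank(store.bank("human_face")),
        beta=beta, lapse=lapse, **kw,
    )


@pytest.fixture(scope="module")
def store():
    return ps.StimulusStore(master_seed=0, geometry=TINY)


class TestSimulateChoice:
    def test_uniform_choice_at_beta_zero(self, store):
        obs = _make_observer(store, beta=0.0, lapse=0.0)
        rng = np.random.default_rng(0)
        counts = np.zeros(3)
        plans, store2 = ps.build_experiment("human_face", 1, seed=0, geometry=TINY)
        plan = next(p for p in plans if p.trial_type == "test")
        planes = [store2.resolve(s) for s in plan.stimulus_ids]
        for _ in range(10_000):
            rec = ps.simulate_choice(planes, plan, obs, rng, TINY)
            counts[plan.stimulus_ids.index(rec.chosen_stimulus_id)] += 1
        stat, p = sps.chisquare(counts)
        assert p > 0.01

    def test_high_beta_solves_easy_baseline(self, store):
        obs = _make_observer(store, beta=50.0, lapse=0.0)
        plans, store2 = ps.build_experiment("human_face", 4, seed=1, geometry=TINY)
        rng = np.random.default_rng(1)
        easy = [p for p in plans if p.trial_type == "baseline_easy"]
        correct = 0
        for plan in easy:
            planes = [store2.resolve(s) for s in plan.stimulus_ids]
            rec = ps.simulate_choice(planes, plan, obs, rng, TINY)
            correct += rec.correct
        assert correct / len(easy) > 0.99

    def test_rt_slower_on_test_than_easy_baseline(self, fx_tiny):
        log = fx_tiny.log
        active = log[~log["is_correction"]]
        rt_test = active.loc[active["trial_type"] == "test", "rt_ms"].mean()
        rt_easy = active.loc[active["trial_type"] == "baseline_easy", "rt_ms"].mean()
        assert rt_test > rt_easy

    def test_degenerate_template_rejected(self, store):
        with pytest.raises(ValueError, match="template"):
            ps.ObserverParams(template=np.full(TINY.target_shape, 100.0))


class TestRunExperiment:
    def test_perfect_observer_has_no_corrections(self):
        plans, store = ps.build_experiment("human_face", 2, seed=4, geometry=TINY)
        obs = _make_observer(store, beta=200.0, lapse=0.0)
        log = ps.run_experiment(plans, obs, store, seed=4)
        # beta=200 makes baseline errors vanishingly rare
        if (log["correct"] == False).sum() == 0:  # noqa: E712
            assert log["is_correction"].sum() == 0

    def test_log_rows_equal_plans_plus_baseline_errors(self, fx_tiny):
        log = fx_tiny.log
        n_planned = len(fx_tiny.config.participants) * fx_tiny.config.n_sessions * 48
        main = log[~log["is_correction"]]
        errors = (main["correct"] == False).sum()  # noqa: E712
        assert len(main) == n_planned
        assert log["is_correction"].sum() == errors

    def test_correction_follows_each_error_with_previous_target(self, fx_tiny):
        log = fx_tiny.log.reset_index(drop=True)
        for i, row in log[log["is_correction"]].iterrows():
            prev = log.iloc[i - 1]
            assert prev["correct"] == False  # noqa: E712
            assert row["stim_id_1"] == prev["stim_id_1"]
            assert row["rewarded"] == True  # noqa: E712

    def test_test_trial_reward_rate_near_half(self):
        store = ps.StimulusStore(master_seed=0, geometry=TINY)
        obs = _make_observer(store)
        log = ps.simulate_test_trials(10_000, obs, seed=9, geometry=TINY)
        rate = log["rewarded"].mean()
        assert abs(rate - 0.5) < 0.013  # 99% binomial CI at n=10,000

    def test_reward_independent_of_choice_policy(self):
        # a heavily position-biased observer still earns ~50% on test trials
        store = ps.StimulusStore(master_seed=1, geometry=TINY)
        obs = ps.ObserverParams(
            template=ps.template_from_bank(store.bank("human_face")),
            beta=0.0, position_bias=np.array([5.0, 0, 0, 0, 0, -5.0]), lapse=0.0,
        )
        log = ps.simulate_test_trials(4_000, obs, seed=10, geometry=TINY)
        assert abs(log["rewarded"].mean() - 0.5) < 0.021
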