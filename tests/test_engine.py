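import numpy as np
import pytest

import meliosim.engine as engine_mod
from meliosim.engine import (
    PairTrajectory,
    checkpoint_schedule,
    play_pair,
    run_batch,
)
from meliosim.games import GameConfigError, NormalFormGame, build_fixture
from meliosim.learners import MeliorationState, RothErevState


def _mel(n, eps=0.1):
    return MeliorationState(n_actions=n, epsilon=eps)


class TestPlayPair:
    def test_single_round(self, pd_game, rng):
        traj = play_pair(pd_game, _mel(2), _mel(2), rounds=1, rng=rng)
        assert traj.rounds == 1
        assert traj.actions_x.shape == (1,)

    def test_counts_sum_to_rounds(self, pd_game, rng):
        lx, ly = _mel(2), _mel(2)
        play_pair(pd_game, lx, ly, rounds=57, rng=rng)
        assert lx.counts.sum() == 57
        assert ly.counts.sum() == 57

    def test_action_count_mismatch(self, pd_game, rng):
        with pytest.raises(GameConfigError, match="actions"):
            play_pair(pd_game, _mel(3), _mel(2), rounds=5, rng=rng)
        with pytest.raises(GameConfigError, match="actions"):
            play_pair(pd_game, _mel(2), _mel(4), rounds=5, rng=rng)

    def test_greedy_absorption_zero_noise(self, rng):
        # all-zero payoffs except one cell paying 10 to both, no noise,
        # no exploration: once both hit the good cell they never leave
        u = np.zeros((2, 2))
        u[0, 0] = 10.0
        game = NormalFormGame("absorb", ("A", "B"), ("A", "B"), u, u, noise_sd=0.0)
        traj = play_pair(game, _mel(2, 0.0), _mel(2, 0.0), rounds=300, rng=rng)
        joint = list(zip(traj.actions_x, traj.actions_y))
        assert (0, 0) in joint
        first = joint.index((0, 0))
        assert all(j == (0, 0) for j in joint[first:])

    def test_q_values_match_trajectory_log(self, pd_game, rng):
        # melioration mean-oracle equivalence over a simulated history
        lx, ly = _mel(2), _mel(2)
        traj = play_pair(pd_game, lx, ly, rounds=400, rng=rng)
        for learner, actions, rewards in (
            (lx, traj.actions_x, traj.rewards_x),
            (ly, traj.actions_y, traj.rewards_y),
        ):
            for e in range(2):
                got = rewards[actions == e]
                expected = got.mean() if len(got) else 0.0
                assert learner.q_values[e] == pytest.approx(expected, abs=1e-9)
                assert learner.counts[e] == len(got)

    def test_roth_erev_pair(self, pd_game, rng):
        lx = RothErevState(n_actions=2, epsilon=0.1)
        ly = RothErevState(n_actions=2, epsilon=0.1)
        traj = play_pair(pd_game, lx, ly, rounds=100, rng=rng)
        assert lx.t == 100
        assert lx.cumulative_reward == pytest.approx(traj.rewards_x.sum())

    def test_information_hiding(self, pd_game, rng, monkeypatch):
        # each learner's update sees only its own action and reward
        calls = []
        real_update = engine_mod.update

        def spy(state, chosen, reward):
            calls.append((id(state), chosen, reward))
            return real_update(state, chosen, reward)

        monkeypatch.setattr(engine_mod, "update", spy)
        lx, ly = _mel(2), _mel(2)
        traj = play_pair(pd_game, lx, ly, rounds=50, rng=rng)
        x_calls = [c for c in calls if c[0] == id(lx)]
        y_calls = [c for c in calls if c[0] == id(ly)]
        assert [c[1] for c in x_calls] == list(traj.actions_x)
        assert [c[2] for c in x_calls] == list(traj.rewards_x)
        assert [c[1] for c in y_calls] == list(traj.actions_y)
        assert [c[2] for c in y_calls] == list(traj.rewards_y)

    def test_trajectory_length_invariant(self):
        with pytest.raises(ValueError, match="length"):
            PairTrajectory(
                actions_x=np.zeros(3, int),
                actions_y=np.zeros(2, int),
                rewards_x=np.zeros(3),
                rewards_y=np.zeros(3),
            )


class TestCheckpointSchedule:
    def test_log_spaced_unique(self):
        cps = checkpoint_schedule(20000, 50)
        assert cps[0] == 1 and cps[-1] == 20000
        assert (np.diff(cps) > 0).all()

    def test_short_run(self):
        cps = checkpoint_schedule(5, 50)
        assert cps[-1] == 5 and len(cps) <= 5


class TestRunBatch:
    @pytest.mark.parametrize("rule", ["melioration", "roth_erev"])
    def test_determinism(self, pd_game, rule):
        spec = {"rule": rule, "epsilon": 0.1}
        a = run_batch(pd_game, spec, 40, 100, master_seed=5, checkpoints=[50, 100])
        b = run_batch(pd_game, spec, 40, 100, master_seed=5, checkpoints=[50, 100])
        assert np.array_equal(a.final_x, b.final_x)
        assert np.array_equal(a.relfreq_x, b.relfreq_x)
        assert np.array_equal(a.checkpoint_counts_y, b.checkpoint_counts_y)

    @pytest.mark.parametrize("rule", ["melioration", "roth_erev"])
    def test_pair_results_independent_of_batch_size(self, pd_game, rule):
        # pair i depends only on (master_seed, i)
        spec = {"rule": rule, "epsilon": 0.1}
        small = run_batch(pd_game, spec, 10, 200, master_seed=5)
        large = run_batch(pd_game, spec, 30, 200, master_seed=5)
        assert np.array_equal(small.final_x, large.final_x[:10])
        assert np.array_equal(small.relfreq_y, large.relfreq_y[:10])

    def test_pair_results_independent_of_chunking(self, pd_game):
        spec = {"rule": "melioration", "epsilon": 0.1}
        a = run_batch(pd_game, spec, 25, 150, master_seed=8, chunk_pairs=7)
        b = run_batch(pd_game, spec, 25, 150, master_seed=8, chunk_pairs=2000)
        assert np.array_equal(a.final_x, b.final_x)
        assert np.array_equal(a.relfreq_x, b.relfreq_x)

    def test_relfreqs_sum_to_one(self, catalogue_game):
        batch = run_batch(
            catalogue_game, {"rule": "melioration", "epsilon": 0.1}, 20, 50, 3
        )
        assert np.allclose(batch.relfreq_x.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(batch.relfreq_y.sum(axis=1), 1.0, atol=1e-12)
        assert batch.outcome_counts().sum() == 20

    def test_pd_final_outcome_fraction(self, pd_game):
        # once both agents have learned B, independent eps-greedy choices
        # put the pair at (B,B) with probability (1 - eps/2)^2 = 0.9025
        batch = run_batch(pd_game, {"rule": "melioration", "epsilon": 0.1}, 500, 1000, 17)
        frac_bb = batch.outcome_counts()[1, 1] / 500
        assert frac_bb == pytest.approx(0.9025, abs=0.04)

    def test_play_pair_and_batch_kernel_agree(self, pd_game):
        # the reference loop and the vectorised kernel are distinct code
        # paths; their outcome statistics must agree
        n, rounds = 150, 400
        finals = []
        for i in range(n):
            rng = np.random.default_rng(1000 + i)
            traj = play_pair(pd_game, _mel(2), _mel(2), rounds, rng)
            finals.append((traj.actions_x[-1], traj.actions_y[-1]))
        loop_bb = sum(f == (1, 1) for f in finals) / n
        batch = run_batch(pd_game, {"rule": "melioration", "epsilon": 0.1}, n, rounds, 2)
        kernel_bb = batch.outcome_counts()[1, 1] / n
        # binomial SD at p=0.9, n=150 is ~0.025; allow 4 SD on the difference
        assert abs(loop_bb - kernel_bb) < 0.1

    def test_roth_erev_kernel_matches_reference_loop(self, pd_game):
        n, rounds = 150, 300
        freqs = []
        for i in range(n):
            rng = np.random.default_rng(2000 + i)
            lx = RothErevState(n_actions=2, epsilon=0.1)
            ly = RothErevState(n_actions=2, epsilon=0.1)
            traj = play_pair(pd_game, lx, ly, rounds, rng)
            freqs.append((traj.actions_x == 1).mean())
        batch = run_batch(pd_game, {"rule": "roth_erev", "epsilon": 0.1}, n, rounds, 3)
        assert abs(np.mean(freqs) - batch.relfreq_x[:, 1].mean()) < 0.05

    def test_checkpoint_counts_consistent(self, pd_game):
        cps = [10, 100, 250]
        batch = run_batch(
            pd_game, {"rule": "melioration", "epsilon": 0.1}, 30, 250, 4, checkpoints=cps
        )
        assert np.array_equal(
            batch.checkpoint_counts_x[-1] / 250.0, batch.relfreq_x
        )
        assert (batch.checkpoint_counts_x.sum(axis=2) == np.array(cps)[:, None]).all()

    def test_bad_checkpoints_rejected(self, pd_game):
        spec = {"rule": "melioration", "epsilon": 0.1}
        with pytest.raises(ValueError, match="checkpoints"):
            run_batch(pd_game, spec, 5, 100, 1, checkpoints=[50, 20])
        with pytest.raises(ValueError, match="checkpoints"):
            run_batch(pd_game, spec, 5, 100, 1, checkpoints=[50, 200])

    def test_modal_outcome_classification(self, pd_game):
        batch = run_batch(
            pd_game, {"rule": "melioration", "epsilon": 0.1}, 100, 400, 9,
            last_window=51,
        )
        modal = batch.outcome_counts("modal")
        final = batch.outcome_counts("final")
        assert modal.sum() == final.sum() == 100
        # modal classification removes one-sided exploration scatter
        assert modal[1, 1] >= final[1, 1]

    def test_modal_without_log_raises(self, pd_game):
        batch = run_batch(pd_game, {"rule": "melioration", "epsilon": 0.1}, 5, 50, 1)
        with pytest.raises(ValueError, match="window"):
            batch.outcome_counts("modal")

    def test_invalid_rule_spec(self, pd_game):
        with pytest.raises(ValueError):
            run_batch(pd_game, {"rule": "bogus", "epsilon": 0.1}, 5, 10, 1)
        with pytest.raises(ValueError):
            run_batch(pd_game, {"rule": "melioration", "epsilon": 2.0}, 5, 10, 1)
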