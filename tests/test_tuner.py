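"""Scheduler behaviour, verified against rigged deterministic trainables.

The rigged trainable's validation MAE is a known function of the
configuration and the epoch (rank-stable and decreasing in the epoch), so
each scheduler's selection and budget accounting can be checked by
enumeration.
"""

import math
from dataclasses import replace

import numpy as np
import pytest

from gastwin.trainer import SurrogateConfig, TrialRecord
from gastwin.tuner import (
    SchedulerPolicy,
    SearchSpace,
    budget_report,
    hyperband_schedule,
    run_asha,
    run_fifo,
    run_hyperband,
    run_pbt,
    sample_config,
)


class RiggedTrial:
    """Deterministic trainable: val MAE = base(config) + 0.5 / epoch.

    ``base`` is the configuration's dropout rate, so the ranking of
    configurations is known in advance and stable across epochs.
    """

    def __init__(self, config: SurrogateConfig):
        self.config = config
        self.record = TrialRecord(config=config)

    def _mae(self, epoch: int) -> float:
        return self.config.dropout_rate + 0.5 / epoch

    def train_epochs(self, k: int) -> TrialRecord:
        for _ in range(k):
            e = self.record.epochs_consumed + 1
            self.record.train_mae.append(self._mae(e))
            self.record.val_mae.append(self._mae(e))
            self.record.epochs_consumed = e
        return self.record

    @property
    def learning_rate(self) -> float:
        return self.config.learning_rate

    @learning_rate.setter
    def learning_rate(self, lr: float) -> None:
        self.config = replace(self.config, learning_rate=lr)
        self.record.config = self.config

    def get_checkpoint(self) -> dict:
        return {"config": self.config.to_dict(),
                "epochs_consumed": self.record.epochs_consumed,
                "train_mae": list(self.record.train_mae),
                "val_mae": list(self.record.val_mae)}

    def load_checkpoint(self, ckpt: dict) -> None:
        self.config = SurrogateConfig.from_dict(ckpt["config"])
        self.record.config = self.config
        self.record.epochs_consumed = ckpt["epochs_consumed"]
        self.record.train_mae = list(ckpt["train_mae"])
        self.record.val_mae = list(ckpt["val_mae"])


SPACE = SearchSpace()


def _expected_best(space, n_trials, seed):
    """Enumerate FIFO's sampled stream and return the argmin-base config."""
    rng = np.random.Generator(np.random.PCG64(seed))
    configs = [sample_config(space, rng) for _ in range(n_trials)]
    return min(configs, key=lambda c: c.dropout_rate), configs


class TestSampleConfig:
    def test_bounds_respected_over_many_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            c = sample_config(SPACE, rng)
            assert 1e-5 <= c.learning_rate <= 1e-3
            assert c.batch_size in (64, 128, 256)
            assert 0.3 <= c.dropout_rate <= 0.6
            assert c.loss_id in ("MAE", "MSE")
            assert isinstance(c.has_fc_layer, bool)

    def test_published_best_configuration_inside_space(self):
        # the best configuration the successive-halving search reported:
        # lr 8e-5, MAE loss, dropout 0.52, batch 64, extra FC layer
        lo, hi = SPACE.learning_rate_bounds
        assert lo <= 8e-5 <= hi
        assert 64 in SPACE.batch_sizes
        assert SPACE.dropout_bounds[0] <= 0.52 <= SPACE.dropout_bounds[1]
        assert "MAE" in SPACE.losses and True in SPACE.fc_options

    def test_seeded_determinism(self):
        a = sample_config(SPACE, np.random.default_rng(5))
        b = sample_config(SPACE, np.random.default_rng(5))
        assert a == b


class TestFifo:
    def test_full_budget_bookkeeping(self):
        policy = SchedulerPolicy(id="FIFO", n_trials=64, max_t=50)
        res = run_fifo(RiggedTrial, SPACE, policy, seed=1)
        assert len(res.trials) == 64
        assert all(t.epochs_consumed == 50 for t in res.trials)
        assert res.total_epochs_consumed == 3200

    def test_single_trial(self):
        policy = SchedulerPolicy(id="FIFO", n_trials=1, max_t=10)
        res = run_fifo(RiggedTrial, SPACE, policy, seed=2)
        assert res.best_config == res.trials[0].config

    def test_argmin_of_known_maes_returned(self):
        policy = SchedulerPolicy(id="FIFO", n_trials=16, max_t=20)
        expected, _ = _expected_best(SPACE, 16, seed=3)
        res = run_fifo(RiggedTrial, SPACE, policy, seed=3)
        assert res.best_config == expected
        assert res.best_val_mae == pytest.approx(
            expected.dropout_rate + 0.5 / 20)


class TestHyperbandSchedule:
    def test_reference_bracket_plan(self):
        plan = hyperband_schedule(27, 3)
        assert [(b["s"], b["n"], b["rungs"][0]) for b in plan] == \
            [(3, 27, 1), (2, 12, 3), (1, 6, 9), (0, 4, 27)]
        assert plan[0]["rungs"] == [1, 3, 9, 27]

    def test_small_budget_plan_matches_formula(self):
        plan = hyperband_schedule(3, 3)
        s_max = int(math.floor(math.log(3, 3)))
        for b in plan:
            s = b["s"]
            assert b["n"] == math.ceil((s_max + 1) / (s + 1) * 3 ** s)
        assert plan[-1]["rungs"][-1] == 3

    def test_final_rung_reaches_full_budget(self):
        for max_t, eta in [(50, 3), (81, 3), (16, 4), (9, 3)]:
            for b in hyperband_schedule(max_t, eta):
                assert b["rungs"][-1] == max_t
                assert all(r2 > r1 for r1, r2 in zip(b["rungs"], b["rungs"][1:]))


class TestHyperbandAndAsha:
    def test_hyperband_matches_fifo_best_with_fewer_epochs(self):
        expected, _ = _expected_best(SPACE, 9, seed=7)
        fifo = run_fifo(RiggedTrial, SPACE,
                        SchedulerPolicy(id="FIFO", n_trials=9, max_t=9), 7)
        hb = run_hyperband(RiggedTrial, SPACE,
                           SchedulerPolicy(id="HYPERBAND", n_trials=9,
                                           max_t=9), 7)
        assert fifo.best_config == expected
        assert hb.best_config == expected
        assert hb.total_epochs_consumed < fifo.total_epochs_consumed

    def test_asha_promotes_only_top_fraction(self):
        # three configurations with first-rung MAEs ~ {0.5, 0.4, 0.3}:
        # with eta=3, only the best may ever be promoted past a rung
        space = SearchSpace(dropout_bounds=(0.3, 0.5999))
        policy = SchedulerPolicy(id="ASHA", n_trials=3, max_t=50,
                                 grace_period=5)
        res = run_asha(RiggedTrial, space, policy, seed=11)
        promoted = [t for t in res.trials if t.epochs_consumed > 5]
        assert len(promoted) == 1
        assert promoted[0].config.dropout_rate == min(
            t.config.dropout_rate for t in res.trials)
        # rungs at 5, 15, 45 epochs: with 3 trials only the first rung ever
        # holds enough results to promote, so the winner pauses at 15
        assert promoted[0].epochs_consumed == 15

    def test_asha_single_trial_never_promoted(self):
        # floor(1/eta) = 0: a lone result is not in the promotable top third
        policy = SchedulerPolicy(id="ASHA", n_trials=1, max_t=50,
                                 grace_period=5)
        res = run_asha(RiggedTrial, SPACE, policy, seed=0)
        assert res.trials[0].epochs_consumed == 5
        assert res.trials[0].status == "stopped"

    def test_early_stopping_saves_budget(self):
        for runner, sid in [(run_hyperband, "HYPERBAND"), (run_asha, "ASHA")]:
            policy = SchedulerPolicy(id=sid, n_trials=16, max_t=50)
            res = runner(RiggedTrial, SPACE, policy, seed=13)
            assert res.total_epochs_consumed < 16 * 50


class TestPbt:
    def test_population_of_one_equals_plain_training(self):
        policy = SchedulerPolicy(id="PBT", n_trials=1, max_t=20,
                                 perturb_interval=5)
        pbt = run_pbt(RiggedTrial, SPACE, policy, seed=4)
        fifo = run_fifo(RiggedTrial, SPACE,
                        SchedulerPolicy(id="FIFO", n_trials=1, max_t=20), 4)
        assert pbt.best_config == fifo.best_config
        assert pbt.total_epochs_consumed == fifo.total_epochs_consumed == 20

    def test_full_budget_identity(self):
        policy = SchedulerPolicy(id="PBT", n_trials=8, max_t=20,
                                 perturb_interval=5)
        res = run_pbt(RiggedTrial, SPACE, policy, seed=5)
        assert res.total_epochs_consumed == 8 * 20
        assert all(t.epochs_consumed == 20 for t in res.trials)

    def test_exploit_copies_config_and_perturbs_learning_rate(self):
        policy = SchedulerPolicy(id="PBT", n_trials=8, max_t=20,
                                 perturb_interval=5)
        _, sampled = _expected_best(SPACE, 8, seed=5)
        res = run_pbt(RiggedTrial, SPACE, policy, seed=5)
        exploits = [e for e in res.events if e["event"] == "exploit"]
        perturbs = [e for e in res.events if e["event"] == "perturb"]
        assert exploits and perturbs
        assert all(p["factor"] in (0.8, 1.25) for p in perturbs)
        # every final config's non-lr fields come from the sampled population
        sampled_keys = {(c.dropout_rate, c.batch_size, c.loss_id,
                         c.has_fc_layer) for c in sampled}
        for t in res.trials:
            c = t.config
            assert (c.dropout_rate, c.batch_size, c.loss_id,
                    c.has_fc_layer) in sampled_keys


class TestCrossScheduler:
    def test_all_schedulers_find_global_best_configuration(self):
        seed, n = 21, 9
        expected, _ = _expected_best(SPACE, n, seed)
        runners = {"FIFO": run_fifo, "HYPERBAND": run_hyperband,
                   "ASHA": run_asha, "PBT": run_pbt}
        for sid, runner in runners.items():
            policy = SchedulerPolicy(id=sid, n_trials=n, max_t=20,
                                     grace_period=5, perturb_interval=5)
            res = runner(RiggedTrial, SPACE, policy, seed)
            best = res.best_config
            assert best.dropout_rate == expected.dropout_rate, sid
            assert best.batch_size == expected.batch_size, sid
            assert best.loss_id == expected.loss_id, sid

    def test_budget_ordering_matches_early_stopping_design(self):
        seed, n, max_t = 31, 16, 50
        epochs = {}
        for sid, runner in [("FIFO", run_fifo), ("HYPERBAND", run_hyperband),
                            ("ASHA", run_asha), ("PBT", run_pbt)]:
            policy = SchedulerPolicy(id=sid, n_trials=n, max_t=max_t,
                                     grace_period=5, perturb_interval=5)
            epochs[sid] = runner(RiggedTrial, SPACE, policy,
                                 seed).total_epochs_consumed
        assert epochs["HYPERBAND"] <= epochs["ASHA"] < epochs["FIFO"]
        assert epochs["FIFO"] == epochs["PBT"] == n * max_t

    def test_reproducibility_of_tune_results(self):
        for runner, sid in [(run_fifo, "FIFO"), (run_hyperband, "HYPERBAND"),
                            (run_asha, "ASHA"), (run_pbt, "PBT")]:
            policy = SchedulerPolicy(id=sid, n_trials=6, max_t=10,
                                     grace_period=2, perturb_interval=5)
            a = runner(RiggedTrial, SPACE, policy, seed=9)
            b = runner(RiggedTrial, SPACE, policy, seed=9)
            assert a.best_config == b.best_config
            assert a.total_epochs_consumed == b.total_epochs_consumed
            assert [t.val_mae for t in a.trials] == [t.val_mae for t in b.trials]


class TestBudgetReport:
    def test_one_row_per_scheduler_with_expected_columns(self):
        policy = SchedulerPolicy(id="FIFO", n_trials=4, max_t=10)
        fifo = run_fifo(RiggedTrial, SPACE, policy, seed=2)
        hb = run_hyperband(RiggedTrial, SPACE,
                           SchedulerPolicy(id="HYPERBAND", n_trials=4,
                                           max_t=10), 2)
        table = budget_report({"FIFO": fifo, "HYPERBAND": hb})
        assert len(table) == 2
        for col in ("Learning Rate", "Loss Function", "Dropout Rate",
                    "Batch Size", "Additional Fully Connected Layer"):
            assert col in table.columns
        fifo_row = table[table["Scheduler"] == "FIFO"].iloc[0]
        hb_row = table[table["Scheduler"] == "HYPERBAND"].iloc[0]
        assert fifo_row["Total Epochs Consumed"] >= hb_row["Total Epochs Consumed"]

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            budget_report({})
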