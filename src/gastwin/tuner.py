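"""Hyperparameter-search schedulers over a checkpointable training contract.

Four strategies are implemented against the same trainable interface
(``train_epochs`` / ``get_checkpoint`` / ``load_checkpoint`` / mutable
``learning_rate``), so they can drive either the real surrogate trial or a
rigged deterministic trainable in tests:

* **FIFO** — every trial runs its full epoch budget in submission order
  (the control strategy).
* **HyperBand** — synchronous successive-halving brackets: each bracket
  starts many configurations on a small epoch budget and repeatedly keeps
  the top ``1/eta`` while multiplying the budget by ``eta``.
* **ASHA** (asynchronous successive halving) — trials pause at rungs
  (``grace_period * eta^k`` epochs) and are resumed whenever they rank in
  the top ``1/eta`` of the results banked at their rung.
* **PBT** (population-based training) — the whole population trains in
  lock-step; every ``perturb_interval`` epochs the bottom quantile of
  trials clones the weights and configuration of a uniformly chosen top
  trial and multiplies its learning rate by a perturbation factor.

The objective everywhere is the final **validation** MAE.  Execution is
process-local and order-preserving, so a given ``(seed, space, policy)`` is
reproducible; with a single worker all four schedulers are exactly
deterministic.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .trainer import DivergenceError, SurrogateConfig, TrialRecord

__all__ = [
    "SearchSpace", "SchedulerPolicy", "TuneResult", "sample_config",
    "hyperband_schedule", "run_fifo", "run_hyperband", "run_asha", "run_pbt",
    "run_scheduler", "budget_report", "write_trial_log",
]

#: Trainable factory: config -> live trial object (SurrogateTrial-compatible).
TrainableFactory = Callable[[SurrogateConfig], object]


@dataclass(frozen=True)
class SearchSpace:
    """Bounds and choices for the five tuned hyperparameters."""

    learning_rate_bounds: tuple[float, float] = (1e-5, 1e-3)   # log-uniform
    batch_sizes: tuple[int, ...] = (64, 128, 256)
    dropout_bounds: tuple[float, float] = (0.3, 0.6)
    losses: tuple[str, ...] = ("MAE", "MSE")
    fc_options: tuple[bool, ...] = (True, False)

    def __post_init__(self):
        lo, hi = self.learning_rate_bounds
        if not 0 < lo < hi:
            raise ValueError("learning-rate bounds must satisfy 0 < lo < hi")
        lo, hi = self.dropout_bounds
        if not 0 <= lo <= hi < 1:
            raise ValueError("dropout bounds must lie in [0, 1), ordered")
        if not (self.batch_sizes and self.losses and self.fc_options):
            raise ValueError("choice sets must be non-empty")


@dataclass(frozen=True)
class SchedulerPolicy:
    """Scheduler identity and resource-allocation knobs."""

    id: str = "FIFO"                 # FIFO | HYPERBAND | ASHA | PBT
    eta: int = 3
    max_t: int = 50
    grace_period: int = 5
    perturb_interval: int = 5
    exploit_quantile: float = 0.25
    perturb_factors: tuple[float, float] = (0.8, 1.25)
    n_trials: int = 64
    workers: int = 1

    def __post_init__(self):
        if self.id not in ("FIFO", "HYPERBAND", "ASHA", "PBT"):
            raise ValueError(f"unknown scheduler id {self.id!r}")
        if self.eta < 2:
            raise ValueError("eta must be >= 2")
        if not 0 < self.grace_period <= self.max_t:
            raise ValueError("grace_period must be in (0, max_t]")
        if not 0.0 < self.exploit_quantile <= 0.5:
            raise ValueError("exploit_quantile must be in (0, 0.5]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class TuneResult:
    """Outcome of one scheduler run."""

    scheduler: str
    trials: list[TrialRecord]
    best_config: SurrogateConfig | None
    best_val_mae: float
    total_epochs_consumed: int
    events: list[dict] = field(default_factory=list)


def config_hash(config: SurrogateConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def sample_config(space: SearchSpace, rng: np.random.Generator,
                  base: SurrogateConfig | None = None) -> SurrogateConfig:
    """Draw one configuration uniformly from the search space (seeded)."""
    if base is None:
        base = SurrogateConfig()
    lo, hi = space.learning_rate_bounds
    lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    batch = int(rng.choice(np.asarray(space.batch_sizes)))
    drop = float(rng.uniform(*space.dropout_bounds))
    loss = str(rng.choice(np.asarray(space.losses)))
    fc = bool(rng.choice(np.asarray(space.fc_options)))
    seed = int(rng.integers(2 ** 31))
    return replace(base, learning_rate=lr, batch_size=batch, dropout_rate=drop,
                   loss_id=loss, has_fc_layer=fc, seed=seed)


def _sample_n(space: SearchSpace, n: int, seed: int,
              base: SurrogateConfig | None) -> list[SurrogateConfig]:
    rng = np.random.Generator(np.random.PCG64(seed))
    return [sample_config(space, rng, base) for _ in range(n)]


def _finish(scheduler: str, trials: list[TrialRecord],
            events: list[dict]) -> TuneResult:
    done = [t for t in trials if t.status != "failed" and t.val_mae]
    if done:
        best = min(done, key=lambda t: t.final_val_mae)
        best_config, best_mae = best.config, best.final_val_mae
    else:
        best_config, best_mae = None, float("inf")
    total = sum(t.epochs_consumed for t in trials)
    return TuneResult(scheduler, trials, best_config, best_mae, total, events)


def _train(trial, k: int, events: list[dict], tid: int, event: str) -> bool:
    """Advance a trial ``k`` epochs; returns False on divergence."""
    events.append({"trial": tid, "epoch": trial.record.epochs_consumed,
                   "event": event, "config": config_hash(trial.config)})
    try:
        trial.train_epochs(k)
    except DivergenceError:
        trial.record.status = "failed"
        return False
    r = trial.record
    events.append({"trial": tid, "epoch": r.epochs_consumed,
                   "event": "report", "train_mae": r.train_mae[-1],
                   "val_mae": r.val_mae[-1], "config": config_hash(trial.config)})
    return True


# ----------------------------------------------------------------------
# FIFO
# ----------------------------------------------------------------------

def run_fifo(factory: TrainableFactory, space: SearchSpace,
             policy: SchedulerPolicy, seed: int,
             base: SurrogateConfig | None = None) -> TuneResult:
    """Run every trial for the full ``max_t`` epochs, in submission order."""
    configs = _sample_n(space, policy.n_trials, seed, base)
    events: list[dict] = []
    trials: list[TrialRecord] = []
    for tid, cfg in enumerate(configs):
        trial = factory(cfg)
        ok = _train(trial, policy.max_t, events, tid, "start")
        trial.record.status = "complete" if ok else "failed"
        trial.record.checkpoint_ref = trial.get_checkpoint()
        trials.append(trial.record)
    return _finish("FIFO", trials, events)


# ----------------------------------------------------------------------
# HyperBand
# ----------------------------------------------------------------------

def hyperband_schedule(max_t: int, eta: int) -> list[dict]:
    """Classic HyperBand bracket plan.

    ``s_max = floor(log_eta(max_t))``; bracket ``s`` starts
    ``n = ceil((s_max+1)/(s+1) * eta^s)`` trials at initial resource
    ``r = max_t * eta^-s`` and halves ``s`` times.  Rungs carry cumulative
    epoch targets ``floor(r * eta^k)``, the final rung always at ``max_t``.
    """
    if max_t < eta:
        return [{"s": 0, "n": 1, "rungs": [max_t]}]
    s_max = int(math.floor(math.log(max_t, eta) + 1e-12))
    brackets = []
    for s in range(s_max, -1, -1):
        n = math.ceil((s_max + 1) / (s + 1) * eta ** s)
        r = max_t * eta ** (-s)
        rungs = [max(1, int(math.floor(r * eta ** k + 1e-9)))
                 for k in range(s + 1)]
        rungs[-1] = max_t
        brackets.append({"s": s, "n": n, "rungs": rungs})
    return brackets


def run_hyperband(factory: TrainableFactory, space: SearchSpace,
                  policy: SchedulerPolicy, seed: int,
                  base: SurrogateConfig | None = None) -> TuneResult:
    """Synchronous HyperBand over ``n_trials`` sampled configurations.

    Configurations are drawn from the same stream FIFO would use, then
    allocated to brackets in plan order (cycling through the plan again if
    more configurations remain than one pass needs).
    """
    configs = _sample_n(space, policy.n_trials, seed, base)
    plan = hyperband_schedule(policy.max_t, policy.eta)
    events: list[dict] = []
    trials: list[TrialRecord] = []
    queue = list(configs)
    tid = 0
    while queue:
        for bracket in plan:
            take = min(bracket["n"], len(queue))
            if take == 0:
                continue
            cohort = [factory(queue.pop(0)) for _ in range(take)]
            ids = list(range(tid, tid + take))
            tid += take
            rungs = bracket["rungs"]
            prev = 0
            survivors = list(zip(ids, cohort))
            for k, target in enumerate(rungs):
                alive = []
                for i, trial in survivors:
                    ok = _train(trial, target - prev,
                                events, i, "start" if prev == 0 else "promote")
                    if ok:
                        alive.append((i, trial))
                    else:
                        trials.append(trial.record)
                survivors = alive
                prev = target
                if not survivors:
                    break
                if k < len(rungs) - 1:
                    keep = max(1, len(survivors) // policy.eta)
                    survivors.sort(key=lambda it: it[1].record.final_val_mae)
                    for i, trial in survivors[keep:]:
                        trial.record.status = "stopped"
                        trial.record.checkpoint_ref = trial.get_checkpoint()
                        events.append({"trial": i, "epoch":
                                       trial.record.epochs_consumed,
                                       "event": "stop",
                                       "config": config_hash(trial.config)})
                        trials.append(trial.record)
                    survivors = survivors[:keep]
                    survivors.sort(key=lambda it: it[0])
            for i, trial in survivors:
                trial.record.status = "complete"
                trial.record.checkpoint_ref = trial.get_checkpoint()
                trials.append(trial.record)
    trials.sort(key=lambda r: r.epochs_consumed)
    return _finish("HYPERBAND", trials, events)


# ----------------------------------------------------------------------
# ASHA
# ----------------------------------------------------------------------

def run_asha(factory: TrainableFactory, space: SearchSpace,
             policy: SchedulerPolicy, seed: int,
             base: SurrogateConfig | None = None) -> TuneResult:
    """Asynchronous successive halving (deterministic pause/resume loop).

    Rungs sit at ``grace_period * eta^k`` cumulative epochs.  Every trial
    first runs to the bottom rung and pauses; a paused trial is resumed
    whenever its validation MAE ranks within the top ``floor(n_k / eta)``
    of the results banked at its rung.  Trials promoted past the top rung
    run to ``max_t`` and complete.
    """
    configs = _sample_n(space, policy.n_trials, seed, base)
    rungs: list[int] = []
    r = policy.grace_period
    while r < policy.max_t:
        rungs.append(r)
        r *= policy.eta
    # rung index len(rungs) means "ran to max_t"
    events: list[dict] = []
    live: list[tuple[int, object]] = []
    failed: list[TrialRecord] = []
    rung_results: list[list[tuple[float, int]]] = [[] for _ in rungs]
    at_rung: dict[int, int] = {}
    promoted: set[tuple[int, int]] = set()

    for tid, cfg in enumerate(configs):
        trial = factory(cfg)
        target = rungs[0] if rungs else policy.max_t
        ok = _train(trial, target, events, tid, "start")
        if not ok:
            failed.append(trial.record)
            continue
        live.append((tid, trial))
        if rungs:
            at_rung[tid] = 0
            rung_results[0].append((trial.record.final_val_mae, tid))
        else:
            trial.record.status = "complete"

    by_id = dict(live)
    progressed = True
    while progressed and rungs:
        progressed = False
        for k in range(len(rungs) - 1, -1, -1):
            results = sorted(rung_results[k])
            keep = len(results) // policy.eta
            for rank, (mae, tid) in enumerate(results):
                if rank >= keep:
                    break
                if (tid, k) in promoted or at_rung.get(tid) != k:
                    continue
                promoted.add((tid, k))
                trial = by_id[tid]
                target = rungs[k + 1] if k + 1 < len(rungs) else policy.max_t
                ok = _train(trial, target - rungs[k], events, tid, "promote")
                if not ok:
                    failed.append(trial.record)
                    del by_id[tid], at_rung[tid]
                    live = [(i, t) for i, t in live if i != tid]
                    continue
                if k + 1 < len(rungs):
                    at_rung[tid] = k + 1
                    rung_results[k + 1].append(
                        (trial.record.final_val_mae, tid))
                else:
                    at_rung[tid] = len(rungs)
                    trial.record.status = "complete"
                progressed = True

    trials = []
    for tid, trial in live:
        if trial.record.status == "running":
            trial.record.status = "stopped"
        trial.record.checkpoint_ref = trial.get_checkpoint()
        trials.append(trial.record)
    trials.extend(failed)
    return _finish("ASHA", trials, events)


# ----------------------------------------------------------------------
# PBT
# ----------------------------------------------------------------------

def run_pbt(factory: TrainableFactory, space: SearchSpace,
            policy: SchedulerPolicy, seed: int,
            base: SurrogateConfig | None = None) -> TuneResult:
    """Population-based training; every trial consumes the full budget.

    At each ``perturb_interval`` boundary the bottom ``exploit_quantile``
    of the population clones the checkpoint (weights + configuration) of a
    uniformly chosen top-quantile trial and multiplies its learning rate by
    a factor drawn from ``perturb_factors``.
    """
    if policy.max_t % policy.perturb_interval != 0:
        raise ValueError("perturb_interval must divide max_t")
    configs = _sample_n(space, policy.n_trials, seed, base)
    mut_rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(seed).spawn(1)[0]))
    events: list[dict] = []
    pop = [(tid, factory(cfg)) for tid, cfg in enumerate(configs)]
    n_intervals = policy.max_t // policy.perturb_interval
    alive = list(pop)
    failed: list[TrialRecord] = []
    for interval in range(n_intervals):
        still = []
        for tid, trial in alive:
            ok = _train(trial, policy.perturb_interval, events, tid,
                        "start" if interval == 0 else "continue")
            (still if ok else failed).append(
                (tid, trial) if ok else trial.record)
        alive = still
        last = interval == n_intervals - 1
        if last or len(alive) < 2:
            continue
        ranked = sorted(alive, key=lambda it: it[1].record.final_val_mae)
        nq = max(1, int(len(ranked) * policy.exploit_quantile))
        top, bottom = ranked[:nq], ranked[-nq:]
        for tid, trial in bottom:
            src_tid, src = top[int(mut_rng.integers(len(top)))]
            trial.load_checkpoint(src.get_checkpoint())
            events.append({"trial": tid, "epoch": trial.record.epochs_consumed,
                           "event": "exploit", "source": src_tid,
                           "config": config_hash(trial.config)})
            factor = float(mut_rng.choice(np.asarray(policy.perturb_factors)))
            trial.learning_rate = trial.learning_rate * factor
            events.append({"trial": tid, "epoch": trial.record.epochs_consumed,
                           "event": "perturb", "factor": factor,
                           "config": config_hash(trial.config)})
    trials = []
    for tid, trial in alive:
        trial.record.status = "complete"
        trial.record.checkpoint_ref = trial.get_checkpoint()
        trials.append(trial.record)
    trials.extend(failed)
    return _finish("PBT", trials, events)


_RUNNERS = {"FIFO": run_fifo, "HYPERBAND": run_hyperband,
            "ASHA": run_asha, "PBT": run_pbt}


def run_scheduler(factory: TrainableFactory, space: SearchSpace,
                  policy: SchedulerPolicy, seed: int,
                  base: SurrogateConfig | None = None) -> TuneResult:
    """Dispatch on ``policy.id``."""
    return _RUNNERS[policy.id](factory, space, policy, seed, base)


# ----------------------------------------------------------------------
# Reporting
# ----------------------------------------------------------------------

def budget_report(results: dict[str, TuneResult]) -> pd.DataFrame:
    """Best-configuration comparison table, one row per scheduler run."""
    if not results:
        raise ValueError("need at least one scheduler result")
    rows = []
    for name, res in results.items():
        cfg = res.best_config
        rows.append({
            "Scheduler": name,
            "Learning Rate": None if cfg is None else cfg.learning_rate,
            "Loss Function": None if cfg is None else cfg.loss_id,
            "Dropout Rate": None if cfg is None else cfg.dropout_rate,
            "Batch Size": None if cfg is None else cfg.batch_size,
            "Additional Fully Connected Layer":
                None if cfg is None else cfg.has_fc_layer,
            "Best Val MAE": res.best_val_mae,
            "Total Epochs Consumed": res.total_epochs_consumed,
        })
    return pd.DataFrame(rows)


def write_trial_log(result: TuneResult, path) -> None:
    """Line-delimited JSON event log (start/stop/promote/exploit/perturb)."""
    with open(path, "w", encoding="utf-8") as fh:
        for ev in result.events:
            fh.write(json.dumps(ev) + "\n")
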