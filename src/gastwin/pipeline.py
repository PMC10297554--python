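"""End-to-end experiment orchestration.

Stages: generate -> simulate -> split -> tune -> train -> evaluate, driven
by one :class:`ExperimentConfig`.  Every stage writes its artifacts into the
run directory and records their content hashes in ``manifest.json``; a
completed stage whose inputs and outputs are unchanged is skipped on re-run,
and all stage seeds derive deterministically from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .cohort import generate_cohort, read_cohort, split_cohort, write_cohort
from .distributions import default_distributions, load_distributions
from .evaluate import final_report, learning_curves_export
from .oracle import OracleConstants, simulate_batch
from .trainer import (SurrogateConfig, SurrogateTrial, fit_standardizer,
                      save_model_bundle, train_surrogate)
from .tuner import (SchedulerPolicy, SearchSpace, budget_report,
                    run_scheduler, write_trial_log)

__all__ = ["ExperimentConfig", "run_experiment", "stage_seed", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "simulate", "split", "tune", "train", "evaluate")


@dataclass
class ExperimentConfig:
    """Configuration of one full surrogate-development run.

    The default mirrors the full-scale study (a 1,000,000-state cohort,
    64 trials, 50 epochs); :meth:`desk_scale` returns the small
    configuration used for desk-top runs and tests.
    """

    cohort_n: int = 1_000_000
    master_seed: int = 42
    distribution_spec: str | None = None      # YAML path; None = shipped
    oracle_overrides: dict = field(default_factory=dict)
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    search_space: dict = field(default_factory=dict)
    schedulers: tuple[str, ...] = ("FIFO", "HYPERBAND", "ASHA", "PBT")
    policy: dict = field(default_factory=dict)  # shared policy knobs
    surrogate: dict = field(default_factory=dict)  # SurrogateConfig overrides
    out_dir: str = "runs/experiment"
    workers: int = 1

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.cohort_n < 100:
            raise ValueError("cohort_n must be >= 100 for a training run")

    @classmethod
    def desk_scale(cls, **kw) -> "ExperimentConfig":
        base = dict(cohort_n=30_000, policy={"n_trials": 16, "max_t": 50})
        base.update(kw)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        if "schedulers" in raw:
            raw["schedulers"] = tuple(raw["schedulers"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(self.fractions)
        d["schedulers"] = list(self.schedulers)
        return d


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict[str, Any] = {"stages": {}}
        if path.exists():
            with open(path) as fh:
                self.data = json.load(fh)

    def stage_fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec or rec.get("key") != key or rec.get("status") != "complete":
            return False
        for f, digest in rec.get("outputs", {}).items():
            p = self.path.parent / f
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, key: str, outputs: list[Path],
               status: str = "complete", **extra) -> None:
        self.data["stages"][stage] = {
            "key": key, "status": status,
            "outputs": {str(p.relative_to(self.path.parent)): _sha256(p)
                        for p in outputs if p.exists()},
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **extra,
        }
        self.save()

    def save(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2)


def _key(*parts: Any) -> str:
    return hashlib.sha256(json.dumps(parts, sort_keys=True,
                                     default=str).encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig,
                   stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the pipeline; returns the manifest dict.

    A stage whose inputs (config key) and recorded outputs are unchanged is
    skipped; a stage failure is recorded and downstream stages do not run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    manifest.data["config"] = config.to_dict()

    spec = (load_distributions(config.distribution_spec)
            if config.distribution_spec else default_distributions())
    constants = OracleConstants(**config.oracle_overrides)
    surro_defaults = SurrogateConfig(**config.surrogate)
    space = SearchSpace(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in config.search_space.items()})

    paths = {
        "cohort": out / "cohort.csv", "labelled": out / "labelled.csv",
        "train": out / "train.csv", "val": out / "val.csv",
        "test": out / "test.csv",
    }

    def stage_guard(stage, key, outputs, fn, **extra):
        if stage not in stages:
            return
        if manifest.stage_fresh(stage, key, outputs):
            logger.info("stage %s: up to date, skipped", stage)
            return
        logger.info("stage %s: running", stage)
        t0 = time.time()
        try:
            info = fn() or {}
        except Exception:
            manifest.record(stage, key, outputs, status="failed")
            raise
        manifest.record(stage, key, outputs,
                        duration_s=round(time.time() - t0, 2), **info, **extra)

    # -- generate ------------------------------------------------------
    gen_seed = stage_seed(config.master_seed, "generate")

    def do_generate():
        table = generate_cohort(config.cohort_n, gen_seed, spec)
        write_cohort(table, paths["cohort"])
        return {"rows": len(table)}

    stage_guard("generate",
                _key("generate", config.cohort_n, gen_seed,
                     [dataclasses.asdict(s) for s in spec]),
                [paths["cohort"]], do_generate)

    # -- simulate ------------------------------------------------------
    def do_simulate():
        table = read_cohort(paths["cohort"])
        labelled = simulate_batch(table, workers=config.workers,
                                  constants=constants)
        write_cohort(labelled, paths["labelled"])
        return {"rows": len(labelled), "dropped": len(table) - len(labelled)}

    stage_guard("simulate",
                _key("simulate", _maybe_hash(paths["cohort"]),
                     dataclasses.asdict(constants)),
                [paths["labelled"]], do_simulate)

    # -- split ---------------------------------------------------------
    split_seed = stage_seed(config.master_seed, "split")

    def do_split():
        labelled = read_cohort(paths["labelled"])
        tr, va, te = split_cohort(labelled, config.fractions, split_seed)
        for part, name in ((tr, "train"), (va, "val"), (te, "test")):
            write_cohort(part, paths[name])
        return {"train_rows": len(tr), "val_rows": len(va),
                "test_rows": len(te)}

    stage_guard("split",
                _key("split", _maybe_hash(paths["labelled"]),
                     config.fractions, split_seed),
                [paths["train"], paths["val"], paths["test"]], do_split)

    # -- tune ----------------------------------------------------------
    tune_seed = stage_seed(config.master_seed, "tune")
    tune_outputs = [out / "scheduler_comparison.csv"] + \
        [out / f"tune_{s.lower()}.json" for s in config.schedulers]

    best_configs: dict[str, SurrogateConfig] = {}

    def do_tune():
        train = read_cohort(paths["train"])
        val = read_cohort(paths["val"])
        stds = fit_standardizer(train)

        def factory(cfg):
            return SurrogateTrial(cfg, train, val, stds)

        results = {}
        for name in config.schedulers:
            policy = SchedulerPolicy(id=name, workers=config.workers,
                                     **config.policy)
            res = run_scheduler(factory, space, policy, tune_seed,
                                base=surro_defaults)
            results[name] = res
            with open(out / f"tune_{name.lower()}.json", "w") as fh:
                json.dump({
                    "best_config": None if res.best_config is None
                    else res.best_config.to_dict(),
                    "best_val_mae": res.best_val_mae,
                    "total_epochs_consumed": res.total_epochs_consumed,
                    "n_trials": len(res.trials),
                }, fh, indent=2)
            write_trial_log(res, out / f"tune_{name.lower()}_events.jsonl")
            if res.best_config is not None:
                best_configs[name] = res.best_config
        budget_report(results).to_csv(out / "scheduler_comparison.csv",
                                      index=False)

    stage_guard("tune",
                _key("tune", _maybe_hash(paths["train"]),
                     _maybe_hash(paths["val"]), tune_seed,
                     dataclasses.asdict(space), config.policy,
                     list(config.schedulers), surro_defaults.to_dict()),
                tune_outputs, do_tune)

    # -- train ---------------------------------------------------------
    if "train" in stages or "evaluate" in stages:
        if not best_configs:
            for name in config.schedulers:
                f = out / f"tune_{name.lower()}.json"
                if f.exists():
                    with open(f) as fh:
                        d = json.load(fh)
                    if d.get("best_config"):
                        best_configs[name] = SurrogateConfig.from_dict(
                            d["best_config"])
        if not best_configs:
            best_configs = {"DEFAULT": surro_defaults}

    trained: dict[str, tuple] = {}

    def do_train():
        train = read_cohort(paths["train"])
        val = read_cohort(paths["val"])
        stds = fit_standardizer(train)
        records = {}
        for name, cfg in best_configs.items():
            record, trial = train_surrogate(None, train, val, cfg,
                                            standardizers=stds)
            save_model_bundle(out / f"model_{name.lower()}", trial)
            trained[name] = (trial, record)
            records[name] = record
        learning_curves_export(records, out / "curves")

    train_outputs = [out / f"model_{n.lower()}" / "weights.npz"
                     for n in best_configs]
    stage_guard("train",
                _key("train", _maybe_hash(paths["train"]),
                     _maybe_hash(paths["val"]),
                     {n: c.to_dict() for n, c in best_configs.items()}),
                train_outputs, do_train)

    # -- evaluate ------------------------------------------------------
    def do_evaluate():
        test = read_cohort(paths["test"])
        train = read_cohort(paths["train"])
        if not trained:   # rebuild from bundles
            from .trainer import load_model_bundle
            for name in best_configs:
                bundle = out / f"model_{name.lower()}"
                model, stds, cfg, hist = load_model_bundle(bundle)
                trial = _BundleTrial(model, stds)
                rec = _record_from_history(cfg, hist)
                trained[name] = (trial, rec)
        reports = final_report(trained, test, train=train, out_dir=out)
        stamp = "PASS" if all(r.passed for r in reports.values()) else "FAIL"
        return {"stamp": stamp,
                "r2": {k: r.r2 for k, r in reports.items()}}

    stage_guard("evaluate",
                _key("evaluate", _maybe_hash(paths["test"]),
                     {n: c.to_dict() for n, c in best_configs.items()}),
                [out / "evaluation.json"], do_evaluate)

    return manifest.data


def _maybe_hash(path: Path) -> str:
    return _sha256(path) if path.exists() else "absent"


class _BundleTrial:
    """Prediction shim around a loaded model bundle."""

    def __init__(self, model, standardizers):
        self.model = model
        self.standardizers = standardizers

    def predict(self, table):
        from .trainer import predict
        return predict(self.model, table, self.standardizers)


def _record_from_history(cfg, hist):
    from .trainer import TrialRecord
    return TrialRecord(config=cfg, train_mae=list(hist["train_mae"]),
                       val_mae=list(hist["val_mae"]),
                       epochs_consumed=len(hist), status="complete")
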