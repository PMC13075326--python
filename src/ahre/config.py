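"""Run configuration (YAML) and the end-to-end pipeline driver.

One root seed fans out into named substreams (simulate / folds / bootstrap /
saliency) so stages can be rerun independently. ``run_all`` executes
simulate -> crossval (pretrain, transfer, train, fold-level test) ->
external prediction -> ensemble triage -> patient bootstrap -> saliency
samples, persisting every artifact under the run directory; stages whose
outputs already exist are skipped, which makes runs resumable and report
regeneration cheap.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import yaml

from . import protocol, saliency, triage
from .augment import AugmentationPolicy
from .episodes import Label, load_cohort, save_cohort
from .resnet1d import ModelSpec, TrainConfig, load_checkpoint, save_checkpoint
from .simulate import CenterSpec, SimulationConfig, save_event_logs, simulate_cohort

logger = logging.getLogger("ahre")


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    model: ModelSpec = dataclasses.field(default_factory=ModelSpec)
    training: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    pretraining: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    augmentation: AugmentationPolicy = dataclasses.field(default_factory=AugmentationPolicy)
    external_center: str = "EXT"
    thresholds: tuple[float, ...] = (0.90, 0.95)
    bootstrap_iterations: int = 1000
    n_saliency_samples: int = 3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["augmentation"]["techniques"] = list(self.augmentation.techniques)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            sim = dict(d["simulation"])
            sim["centers"] = [CenterSpec(**c) for c in sim.get("centers", [])]
            d["simulation"] = SimulationConfig(**sim)
        if "model" in d:
            d["model"] = ModelSpec(**d["model"])
        for key in ("training", "pretraining"):
            if key in d:
                sub = dict(d[key])
                if sub.get("alpha") is not None:
                    sub["alpha"] = tuple(sub["alpha"])
                d[key] = TrainConfig(**sub)
        if "augmentation" in d:
            sub = dict(d["augmentation"])
            sub["techniques"] = tuple(sub.get("techniques", ()))
            d["augmentation"] = AugmentationPolicy(**sub)
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def setup_logging(rundir: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if rundir is not None:
        rundir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(rundir / "log.txt"))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    root = logging.getLogger("ahre")
    root.setLevel(logging.INFO)
    root.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


class _Stage:
    """Log a stage's wall time and halt with its name on failure."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.time()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            logger.error("stage %s: FAILED after %.1fs (%s)", self.name, time.time() - self.t0, exc)
            return False
        logger.info("stage %s: done in %.1fs", self.name, time.time() - self.t0)
        return False


def run_all(config: RunConfig, rundir: str | Path) -> Path:
    """Execute the full pipeline into ``rundir``; idempotent per stage."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    setup_logging(rundir)
    config.save(rundir / "config.yaml")

    cohort_path = rundir / "cohort.h5"
    with _Stage("simulate"):
        if not cohort_path.exists():
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cohort, events = simulate_cohort(sim)
            save_cohort(cohort, cohort_path)
            save_event_logs(events, rundir / "events.csv")
        cohort = load_cohort(cohort_path)

    with _Stage("fold_plan"):
        plan_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
        )
        plan = protocol.build_fold_plan(cohort, plan_rng, external_center=config.external_center)

    fold_results: list[protocol.FoldResult | None] = []
    models = []
    with _Stage("crossval"):
        for i in range(len(plan.folds)):
            fdir = rundir / f"fold_{i}"
            pred_path = fdir / "predictions.csv"
            ckpt_path = fdir / "checkpoint.npz"
            if pred_path.exists() and ckpt_path.exists():
                logger.info("fold %d: cached", i)
                models.append(load_checkpoint(ckpt_path))
                fold_results.append(None)
                continue
            res = protocol.run_fold(
                cohort,
                plan,
                i,
                config.model,
                config.training,
                config.pretraining,
                config.augmentation,
                config.seed,
            )
            fdir.mkdir(parents=True, exist_ok=True)
            res.predictions.save_csv(pred_path)
            save_checkpoint(res.model, ckpt_path, seed=config.seed)
            res.train_history.history.to_csv(fdir / "log.csv", index=False)
            res.pretrain_history.history.to_csv(fdir / "pretrain_log.csv", index=False)
            models.append(res.model)
            fold_results.append(res)

    external_eps = [
        e
        for e in cohort.episodes
        if e.center_id == config.external_center and e.label != Label.SINUS
    ]
    with _Stage("external_predict"):
        training_patients = set().union(*(g.patient_ids for g in plan.groups))
        sets = protocol.predict_external(models, external_eps, training_patients)
        for i, s in enumerate(sets):
            s.save_csv(rundir / f"fold_{i}" / "external_predictions.csv")

    report_dir = rundir / "report"
    with _Stage("ensemble_triage"):
        ensemble = triage.soft_vote(sets)
        ensemble.save_csv(report_dir / "ensemble_predictions.csv")
        reports = triage.evaluate_at_thresholds(ensemble, config.thresholds)
        table = triage.workload_report(reports)
        report_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(report_dir / "workload.csv", index=False)
        (report_dir / "workload.txt").write_text(table.to_string(index=False) + "\n")
        for r in reports:
            tag = "none" if r.threshold is None else f"{r.threshold:.2f}"
            np.savetxt(report_dir / f"confusion_{tag}.csv", r.confusion, fmt="%d", delimiter=",")

    with _Stage("bootstrap"):
        boot_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(2,))
        )
        boot = triage.patient_bootstrap(
            ensemble, n_iterations=config.bootstrap_iterations, rng=boot_rng
        )
        payload = {
            "n_iterations": boot.n_iterations,
            "recall": boot.recall.to_dict(orient="records"),
            "specificity": boot.specificity.to_dict(orient="records"),
            "plug_in_recall": boot.plug_in_recall,
        }
        (report_dir / "bootstrap.json").write_text(json.dumps(payload, indent=2))

    with _Stage("saliency"):
        maps_dir = rundir / "maps"
        sal_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(3,))
        )
        picks = sal_rng.choice(
            len(external_eps), size=min(config.n_saliency_samples, len(external_eps)), replace=False
        )
        all_maps = []
        for k in picks:
            ep = external_eps[int(k)]
            cls = int(ensemble.probs[int(k)].argmax())
            member_maps = [saliency.grad_cam_pp(m, ep, cls) for m in models]
            emap = saliency.ensemble_map(member_maps)
            all_maps.append(emap)
            saliency.render(
                ep,
                emap,
                maps_dir / f"{ep.episode_id}.png",
                title=f"{ep.episode_id}: pred {triage.CLASS_NAMES[cls]} "
                f"p={ensemble.probs[int(k)].max():.2f}",
            )
        if all_maps:
            saliency.maps_to_frame(all_maps).to_csv(maps_dir / "maps.csv", index=False)

    logger.info("run complete: %s", rundir)
    return rundir
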