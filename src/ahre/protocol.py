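"""Center-level fourfold cross-validation and patient-level splitting.

Folds are defined by hospital of origin so every model is tested on data
from centers it never saw. Mirroring the published configuration, the fold
plan splits the largest center into two patient-stratified halves and
merges the two smallest centers; with more than four centers the smallest
groups keep merging until exactly four remain. Within each fold the pooled
training centers are split 80/20 at the patient level with class
stratification, the model is pretrained on sinus-vs-AT/AF, transferred, and
fine-tuned on the augmented three-class pool, then tested on the held-out
center group. Patient leakage between any training pool (including
pretraining and augmentation sources) and the fold's validation/test sets
is a hard error.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from collections import defaultdict
from typing import Sequence

import numpy as np

from . import augment as aug
from .episodes import (
    TRIAGE_CLASSES,
    CohortManifest,
    EpisodeRecord,
    Label,
    labels_to_int,
    stack_signals,
)
from .resnet1d import (
    ModelSpec,
    ResNet1D,
    TrainConfig,
    TrainResult,
    build_model,
    check_pretraining_pool,
    pretrain_then_transfer,
    train,
)
from .triage import PredictionSet

logger = logging.getLogger("ahre")


class LeakageError(RuntimeError):
    """Patient overlap between a training pool and validation/test data."""


@dataclasses.dataclass
class CenterGroup:
    group_id: str
    patient_ids: frozenset[str]


@dataclasses.dataclass
class FoldPlan:
    """Four center groups, each held out as the test set exactly once."""

    groups: list[CenterGroup]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if seen & g.patient_ids:
                raise LeakageError("a patient appears in more than one center group")
            seen |= g.patient_ids

    @property
    def folds(self) -> list[tuple[list[str], str]]:
        ids = [g.group_id for g in self.groups]
        return [([i for i in ids if i != test], test) for test in ids]

    def patients_of(self, group_id: str) -> frozenset[str]:
        for g in self.groups:
            if g.group_id == group_id:
                return g.patient_ids
        raise KeyError(group_id)


def _patient_class_counts(episodes: Sequence[EpisodeRecord]) -> dict[str, np.ndarray]:
    idx = {c: i for i, c in enumerate(TRIAGE_CLASSES)}
    out: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(len(TRIAGE_CLASSES), dtype=float))
    for e in episodes:
        if e.label in idx:
            out[e.patient_id][idx[e.label]] += 1
    return dict(out)


def _greedy_bipartition(
    counts: dict[str, np.ndarray],
    target_frac: float,
    rng: np.random.Generator,
) -> tuple[set[str], set[str]]:
    """Assign whole patients so per-class episode counts approach the target.

    Patients are visited in decreasing episode-count order (ties shuffled by
    the seeded rng) and each goes to whichever side is currently furthest
    below its per-class target for the classes the patient carries.
    """
    patients = list(counts)
    rng.shuffle(patients)
    patients.sort(key=lambda p: -counts[p].sum())
    totals = np.sum([counts[p] for p in patients], axis=0)
    target_a = target_frac * totals
    fill_a = np.zeros_like(totals)
    fill_b = np.zeros_like(totals)
    side_a: set[str] = set()
    side_b: set[str] = set()
    for p in patients:
        c = counts[p]
        weight = c / max(c.sum(), 1.0)
        deficit_a = float((np.maximum(target_a - fill_a, 0) * weight).sum())
        deficit_b = float((np.maximum((totals - target_a) - fill_b, 0) * weight).sum())
        if deficit_a >= deficit_b:
            side_a.add(p)
            fill_a += c
        else:
            side_b.add(p)
            fill_b += c
    if not side_b and len(side_a) > 1:
        mover = min(side_a, key=lambda p: counts[p].sum())
        side_a.remove(mover)
        side_b.add(mover)
    return side_a, side_b


def split_center(
    cohort: CohortManifest, center_id: str, rng: np.random.Generator
) -> tuple[set[str], set[str]]:
    """Split one center's patients into two class-stratified halves."""
    episodes = [e for e in cohort.by_center(center_id) if e.label != Label.SINUS]
    if not episodes:
        raise KeyError(f"center {center_id} absent or has no AHREs")
    counts = _patient_class_counts(episodes)
    if len(counts) < 2:
        raise ValueError(f"center {center_id} has fewer than two patients")
    return _greedy_bipartition(counts, 0.5, rng)


def build_fold_plan(
    cohort: CohortManifest,
    rng: np.random.Generator,
    external_center: str | None = None,
) -> FoldPlan:
    """Data-driven four-group plan over the non-external centers.

    The largest center (by AHRE count) is split into two patient-stratified
    halves and the two smallest centers are merged; any surplus groups keep
    merging smallest-first until exactly four remain.
    """
    centers = [c for c in cohort.centers if c != external_center]
    ahre = [e for e in cohort.episodes if e.label != Label.SINUS and e.center_id != external_center]
    if len(centers) < 4:
        raise ValueError("need at least four non-external centers for the fourfold plan")
    sizes = {c: sum(1 for e in ahre if e.center_id == c) for c in centers}
    ordered = sorted(centers, key=lambda c: -sizes[c])
    largest, smallest_two = ordered[0], ordered[-2:]
    half_a, half_b = split_center(cohort, largest, rng)
    groups: list[CenterGroup] = [
        CenterGroup(f"{largest}a", frozenset(half_a)),
        CenterGroup(f"{largest}b", frozenset(half_b)),
        CenterGroup(
            "+".join(sorted(smallest_two)),
            frozenset(
                e.patient_id for e in ahre if e.center_id in smallest_two
            ),
        ),
    ]
    for c in ordered[1:-2]:
        groups.append(
            CenterGroup(c, frozenset(e.patient_id for e in ahre if e.center_id == c))
        )
    groups.sort(key=lambda g: g.group_id)
    while len(groups) > 4:
        groups.sort(key=lambda g: len(g.patient_ids))
        a, b = groups[0], groups[1]
        groups = groups[2:] + [CenterGroup(f"{a.group_id}+{b.group_id}", a.patient_ids | b.patient_ids)]
    return FoldPlan(sorted(groups, key=lambda g: g.group_id))


def trainval_split(
    episodes: Sequence[EpisodeRecord],
    rng: np.random.Generator,
    train_frac: float = 0.8,
) -> tuple[list[EpisodeRecord], list[EpisodeRecord]]:
    """Patient-disjoint ~80/20 split with class stratification.

    Patients are atomic, so the realized fractions are best-effort. A class
    carried by a single patient cannot appear on both sides; it is placed in
    the training split with a warning.
    """
    episodes = list(episodes)
    counts = _patient_class_counts(episodes)
    carriers = defaultdict(set)
    for e in episodes:
        carriers[e.label].add(e.patient_id)
    singletons = {next(iter(pids)) for lab, pids in carriers.items() if len(pids) == 1}
    if singletons:
        warnings.warn(
            "classes carried by a single patient are pinned to the training split",
            stacklevel=2,
        )
    free = {p: c for p, c in counts.items() if p not in singletons}
    train_p, val_p = _greedy_bipartition(free, train_frac, rng) if free else (set(), set())
    train_p |= singletons
    train_eps = [e for e in episodes if e.patient_id in train_p]
    val_eps = [e for e in episodes if e.patient_id in val_p]
    return train_eps, val_eps


def _assert_no_leakage(train_pool: Sequence[EpisodeRecord], *held_out: Sequence[EpisodeRecord]) -> None:
    train_patients = {e.patient_id for e in train_pool}
    for pool in held_out:
        overlap = train_patients & {e.patient_id for e in pool}
        if overlap:
            raise LeakageError(f"patient leakage into a held-out set: {sorted(overlap)[:5]}")


def _episode_arrays(episodes: Sequence[EpisodeRecord], classes) -> tuple[np.ndarray, np.ndarray]:
    return stack_signals(episodes), labels_to_int(episodes, classes)


@dataclasses.dataclass
class FoldResult:
    fold: int
    test_group: str
    model: ResNet1D
    predictions: PredictionSet
    pretrain_history: TrainResult
    train_history: TrainResult


@dataclasses.dataclass
class CrossvalResult:
    plan: FoldPlan
    folds: list[FoldResult]

    @property
    def models(self) -> list[ResNet1D]:
        return [f.model for f in self.folds]


def _predict_episodes(model: ResNet1D, episodes: Sequence[EpisodeRecord], provenance: str) -> PredictionSet:
    x, y = _episode_arrays(episodes, TRIAGE_CLASSES)
    return PredictionSet(
        episode_ids=[e.episode_id for e in episodes],
        probs=model.predict_proba(x),
        true_labels=y,
        patient_ids=[e.patient_id for e in episodes],
        provenance=provenance,
    )


def run_fold(
    cohort: CohortManifest,
    plan: FoldPlan,
    fold_index: int,
    model_spec: ModelSpec,
    train_config: TrainConfig,
    pretrain_config: TrainConfig | None,
    policy: aug.AugmentationPolicy,
    seed: int,
) -> FoldResult:
    """Pretrain -> transfer -> fine-tune -> predict for one fold."""
    trainval_ids, test_id = plan.folds[fold_index]
    test_patients = plan.patients_of(test_id)
    ahre = [e for e in cohort.episodes if e.label != Label.SINUS]
    grouped = set().union(*(plan.patients_of(g) for g in trainval_ids))
    trainval_eps = [e for e in ahre if e.patient_id in grouped]
    test_eps = [e for e in ahre if e.patient_id in test_patients]
    if not test_eps or not trainval_eps:
        raise ValueError(f"fold {fold_index}: empty train/val or test pool")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(fold_index,)))
    train_eps, val_eps = trainval_split(trainval_eps, rng)
    _assert_no_leakage(train_eps, val_eps, test_eps)

    held_out_patients = {e.patient_id for e in val_eps} | set(test_patients)
    sinus = [
        e
        for e in cohort.episodes
        if e.label == Label.SINUS and e.patient_id not in held_out_patients
    ]
    pretrain_pool = sinus + [e for e in train_eps if e.label == Label.ATAF]
    check_pretraining_pool([e.label for e in pretrain_pool])
    _assert_no_leakage(pretrain_pool, val_eps, test_eps)

    fold_seed = int(rng.integers(0, 2**31 - 1))
    pre_cfg = pretrain_config or train_config
    pre_cfg = dataclasses.replace(pre_cfg, seed=fold_seed)

    # pretraining: sinus (0) vs AT/AF (1), no augmentation
    pre_train, pre_val = trainval_split(pretrain_pool, rng)
    classes2 = (Label.SINUS, Label.ATAF)
    x_tr, y_tr = _episode_arrays(pre_train, classes2)
    x_va, y_va = _episode_arrays(pre_val, classes2)
    model2 = build_model(dataclasses.replace(model_spec, n_classes=2), seed=fold_seed)
    logger.info("fold %d: pretraining on %d episodes", fold_index, len(pre_train))
    pre_hist = train(model2, x_tr, y_tr, x_va, y_va, pre_cfg)

    model3 = pretrain_then_transfer(model2, n_classes=3, seed=fold_seed + 1)

    aug_train = aug.apply_policy(train_eps, policy, rng)
    _assert_no_leakage(aug_train, val_eps, test_eps)
    x_tr, y_tr = _episode_arrays(aug_train, TRIAGE_CLASSES)
    x_va, y_va = _episode_arrays(val_eps, TRIAGE_CLASSES)
    cfg = dataclasses.replace(train_config, seed=fold_seed + 2)
    logger.info(
        "fold %d: training on %d episodes (%d augmented)",
        fold_index,
        len(aug_train),
        len(aug_train) - len(train_eps),
    )
    hist = train(model3, x_tr, y_tr, x_va, y_va, cfg)

    predictions = _predict_episodes(model3, test_eps, provenance=f"fold{fold_index}")
    return FoldResult(fold_index, test_id, model3, predictions, pre_hist, hist)


def run_crossval(
    cohort: CohortManifest,
    plan: FoldPlan,
    model_spec: ModelSpec,
    train_config: TrainConfig,
    seed: int,
    pretrain_config: TrainConfig | None = None,
    policy: aug.AugmentationPolicy | None = None,
) -> CrossvalResult:
    """Train and test one model per fold of the center-level plan."""
    policy = policy or aug.AugmentationPolicy()
    results = [
        run_fold(
            cohort, plan, i, model_spec, train_config, pretrain_config, policy, seed
        )
        for i in range(len(plan.folds))
    ]
    return CrossvalResult(plan, results)


def predict_external(
    models: Sequence[ResNet1D],
    external_eps: Sequence[EpisodeRecord],
    training_patients: set[str] | None = None,
) -> list[PredictionSet]:
    """Per-model predictions on the external center, aligned by episode id."""
    if training_patients is not None:
        overlap = training_patients & {e.patient_id for e in external_eps}
        if overlap:
            raise LeakageError(f"external cohort shares patients with training: {sorted(overlap)[:5]}")
    sets = [
        _predict_episodes(m, external_eps, provenance=f"fold{i}")
        for i, m in enumerate(models)
    ]
    ids = sets[0].episode_ids
    if any(s.episode_ids != ids for s in sets):
        raise ValueError("episode id mismatch across models")
    return sets
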