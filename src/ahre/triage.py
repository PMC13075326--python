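"""Soft-voting ensemble, probability-threshold triage, and evaluation.

The four cross-validation models are combined by averaging their class
probabilities; the ensemble prediction is the argmax. Predictions whose top
probability clears a threshold (0.90 / 0.95 by default) are "retained" —
auto-handled without human review — and coverage is the retained fraction.
Metrics are standard one-vs-rest precision, recall, specificity, and
F2 = 5PR/(4P+R), reported in percent. Patient-level uncertainty comes from
a bootstrap that resamples patients with replacement and draws one episode
per class each patient possesses.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .episodes import TRIAGE_CLASSES, Label

CLASS_NAMES = tuple(c.value for c in TRIAGE_CLASSES)  # ("ATAF", "NOISE", "FFO")
PROB_COLUMNS = ("p_ataf", "p_noise", "p_ffo")


@dataclasses.dataclass
class PredictionSet:
    """Per-episode class-probability rows for one model (or the ensemble)."""

    episode_ids: list[str]
    probs: np.ndarray                    # (n, 3) rows on the simplex
    true_labels: np.ndarray | None = None  # int codes into TRIAGE_CLASSES
    patient_ids: list[str] | None = None
    provenance: str = "model"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] != len(self.episode_ids):
            raise ValueError("probs must be (n_episodes, n_classes)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"episode_id": self.episode_ids})
        if self.true_labels is not None:
            df["true_label"] = [CLASS_NAMES[i] for i in self.true_labels]
        for j, col in enumerate(PROB_COLUMNS):
            df[col] = self.probs[:, j]
        return df

    def save_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "model") -> "PredictionSet":
        df = pd.read_csv(path)
        true = None
        if "true_label" in df.columns:
            true = np.array([CLASS_NAMES.index(s) for s in df["true_label"]], dtype=np.int64)
        return cls(
            episode_ids=df["episode_id"].astype(str).tolist(),
            probs=df[list(PROB_COLUMNS)].to_numpy(),
            true_labels=true,
            provenance=provenance,
        )


def soft_vote(sets: Sequence[PredictionSet]) -> PredictionSet:
    """Element-wise mean of probability rows across models."""
    if not sets:
        raise ValueError("need at least one prediction set")
    ref = sets[0]
    for s in sets[1:]:
        if s.episode_ids != ref.episode_ids:
            raise ValueError("prediction sets disagree on episode ids")
    mean = np.mean([s.probs for s in sets], axis=0)
    return PredictionSet(
        episode_ids=list(ref.episode_ids),
        probs=mean,
        true_labels=None if ref.true_labels is None else ref.true_labels.copy(),
        patient_ids=list(ref.patient_ids) if ref.patient_ids is not None else None,
        provenance="ensemble",
    )


def triage_classify(
    pset: PredictionSet, tau: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class per episode plus the retained mask.

    The prediction is the argmax row class; exact ties resolve in class
    order AT/AF, noise, FFO (np.argmax keeps the first maximum, and the
    columns are laid out in that priority order). An episode is retained
    iff its top probability is at least tau; tau=None retains everything.
    """
    pred = pset.probs.argmax(axis=1)
    if tau is None:
        retained = np.ones(len(pred), dtype=bool)
    else:
        if not 0.0 <= tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        retained = pset.probs.max(axis=1) >= tau
    return pred, retained


@dataclasses.dataclass
class TriageReport:
    """Per-class metrics over the retained episodes at one threshold."""

    threshold: float | None
    total: int
    retained: int
    incorrect: int
    confusion: np.ndarray                      # (3, 3) true x predicted, retained only
    per_class: pd.DataFrame                    # class, precision, recall, specificity, f2 (%)

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.retained / self.total if self.total else float("nan")

    @property
    def error_rate_pct(self) -> float:
        return 100.0 * self.incorrect / self.retained if self.retained else float("nan")


def per_class_metrics(
    y_pred: np.ndarray,
    y_true: np.ndarray,
    retained: np.ndarray | None = None,
    threshold: float | None = None,
) -> TriageReport:
    """One-vs-rest precision/recall/specificity/F2 in percent.

    Undefined ratios (empty denominators, e.g. a class absent from the
    retained subset) are reported as NaN, never silently as zero.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    total = len(y_true)
    if retained is None:
        retained = np.ones(total, dtype=bool)
    yp, yt = y_pred[retained], y_true[retained]
    k = len(CLASS_NAMES)
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(yt, yp):
        conf[t, p] += 1
    rows = []
    for c in range(k):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        tn = conf.sum() - tp - fp - fn
        precision = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
        recall = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        specificity = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
        if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
            f2 = float("nan")
        else:
            f2 = 5 * precision * recall / (4 * precision + recall)
        rows.append(
            {
                "class": CLASS_NAMES[c],
                "precision_pct": precision,
                "recall_pct": recall,
                "specificity_pct": specificity,
                "f2_pct": f2,
            }
        )
    return TriageReport(
        threshold=threshold,
        total=total,
        retained=int(retained.sum()),
        incorrect=int((yp != yt).sum()),
        confusion=conf,
        per_class=pd.DataFrame(rows),
    )


def evaluate_at_thresholds(
    pset: PredictionSet,
    thresholds: Sequence[float] = (0.90, 0.95),
) -> list[TriageReport]:
    """Reports for no threshold plus each requested threshold."""
    if pset.true_labels is None:
        raise ValueError("prediction set carries no ground-truth labels")
    reports = []
    for tau in (None, *thresholds):
        pred, retained = triage_classify(pset, tau)
        reports.append(per_class_metrics(pred, pset.true_labels, retained, threshold=tau))
    return reports


def workload_report(reports: Sequence[TriageReport]) -> pd.DataFrame:
    """Flat summary table across thresholds, mirroring the triage columns."""
    if not reports:
        raise ValueError("no reports to summarize")
    rows = []
    for r in reports:
        row = {
            "threshold": "-" if r.threshold is None else f"{r.threshold:.2f}",
            "retained": r.retained,
            "total": r.total,
            "coverage_pct": r.coverage_pct,
            "incorrect": r.incorrect,
            "error_rate_pct": r.error_rate_pct,
        }
        for _, rec in r.per_class.iterrows():
            prefix = rec["class"].lower()
            row[f"{prefix}_precision_pct"] = rec["precision_pct"]
            row[f"{prefix}_recall_pct"] = rec["recall_pct"]
            row[f"{prefix}_specificity_pct"] = rec["specificity_pct"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Patient-level bootstrap
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BootstrapResult:
    """Point estimates (mean over iterations) and 95% percentile CIs."""

    n_iterations: int
    recall: pd.DataFrame         # class, point_pct, ci_lo_pct, ci_hi_pct
    specificity: pd.DataFrame
    plug_in_recall: dict[str, float]


def patient_bootstrap(
    pset: PredictionSet,
    patient_ids: Sequence[str] | None = None,
    n_iterations: int = 1000,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Patient-level bootstrap of per-class recall and specificity.

    Each iteration resamples patients with replacement and, for every drawn
    patient, randomly selects one episode of each class that patient
    possesses. This keeps heavy-burden patients from dominating the
    estimate and preserves class balance across iterations.
    """
    if n_iterations < 1:
        raise ValueError("need at least one bootstrap iteration")
    if rng is None:
        rng = np.random.default_rng(0)
    if patient_ids is None:
        patient_ids = pset.patient_ids
    if patient_ids is None:
        raise ValueError("patient ids required for the patient-level bootstrap")
    if pset.true_labels is None:
        raise ValueError("prediction set carries no ground-truth labels")

    y_true = pset.true_labels
    y_pred = pset.probs.argmax(axis=1)
    patients = sorted(set(patient_ids))
    pid_arr = np.asarray(patient_ids)
    # patient -> class -> episode indices
    per_patient: dict[str, dict[int, np.ndarray]] = {}
    for p in patients:
        mask = pid_arr == p
        per_patient[p] = {
            c: np.flatnonzero(mask & (y_true == c)) for c in range(len(CLASS_NAMES))
        }
        per_patient[p] = {c: idx for c, idx in per_patient[p].items() if len(idx)}

    k = len(CLASS_NAMES)
    recalls = np.full((n_iterations, k), np.nan)
    specs = np.full((n_iterations, k), np.nan)
    n_pat = len(patients)
    for b in range(n_iterations):
        drawn = rng.integers(0, n_pat, size=n_pat)
        sel: list[int] = []
        for pi in drawn:
            for c, idx in per_patient[patients[pi]].items():
                sel.append(int(idx[rng.integers(0, len(idx))]))
        yt, yp = y_true[sel], y_pred[sel]
        for c in range(k):
            tp = int(((yt == c) & (yp == c)).sum())
            fn = int(((yt == c) & (yp != c)).sum())
            fp = int(((yt != c) & (yp == c)).sum())
            tn = int(((yt != c) & (yp != c)).sum())
            if tp + fn:
                recalls[b, c] = 100.0 * tp / (tp + fn)
            if tn + fp:
                specs[b, c] = 100.0 * tn / (tn + fp)

    def summarize(mat: np.ndarray) -> pd.DataFrame:
        rows = []
        for c in range(k):
            col = mat[:, c]
            col = col[~np.isnan(col)]
            if len(col) == 0:
                rows.append({"class": CLASS_NAMES[c], "point_pct": np.nan,
                             "ci_lo_pct": np.nan, "ci_hi_pct": np.nan})
                continue
            rows.append(
                {
                    "class": CLASS_NAMES[c],
                    "point_pct": float(col.mean()),
                    "ci_lo_pct": float(np.percentile(col, 2.5)),
                    "ci_hi_pct": float(np.percentile(col, 97.5)),
                }
            )
        return pd.DataFrame(rows)

    plug_in = {}
    for c in range(k):
        denom = int((y_true == c).sum())
        plug_in[CLASS_NAMES[c]] = (
            100.0 * int(((y_true == c) & (y_pred == c)).sum()) / denom if denom else float("nan")
        )
    return BootstrapResult(n_iterations, summarize(recalls), summarize(specs), plug_in)
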