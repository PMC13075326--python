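"""Episode data model, preprocessing, and HDF5/CSV persistence.

An atrial high-rate episode (AHRE) is represented by the last ten seconds of
the device recording sampled at 128 Hz: a 1280-sample atrial electrogram
(EGM), a 1280-sample ventricular EGM (all zeros when the device transmitted
no ventricular channel), and a binarized marker train with a one at each
sample where the device placed a sense/pace annotation.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

FS = 128
"""Sampling frequency of device EGM exports, Hz."""

EPISODE_SECONDS = 10.0
N_SAMPLES = 1280
"""Samples per channel: 10 s x 128 Hz."""


class Label(str, enum.Enum):
    """Episode classes.

    ATAF, NOISE and FFO are the three AHRE triage classes; SINUS episodes
    (periodic EGM recordings) are used only for pretraining.
    """

    ATAF = "ATAF"
    NOISE = "NOISE"
    FFO = "FFO"
    SINUS = "SINUS"


#: The three classes the classifier distinguishes, in fixed output order.
TRIAGE_CLASSES = (Label.ATAF, Label.NOISE, Label.FFO)


class MarkerType(str, enum.Enum):
    AS = "AS"   # atrial sense
    TA = "TA"   # atrial tachycardia marker
    VS = "Vs"   # ventricular sense
    VP = "Vp"   # ventricular pace


class InvalidEpisodeError(ValueError):
    """Raised when raw input cannot form a valid episode."""


class CohortIOError(RuntimeError):
    """Raised on malformed or inconsistent on-disk cohorts."""


@dataclasses.dataclass
class EpisodeRecord:
    """One preprocessed AHRE.

    Signals are max-abs normalized per channel; ``markers`` is a binary
    vector aligned to the same 1280-sample grid. ``marker_types`` optionally
    keeps the device annotation kind at each marker sample. ``provenance``
    carries augmentation bookkeeping (source episode and technique) and is
    ``None`` for original episodes.
    """

    episode_id: str
    patient_id: str
    center_id: str
    label: Label
    atrial: np.ndarray
    ventricular: np.ndarray
    has_ventricular: bool
    markers: np.ndarray
    marker_types: list[tuple[int, MarkerType]] | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.label = Label(self.label)
        self.atrial = np.asarray(self.atrial, dtype=np.float32)
        self.ventricular = np.asarray(self.ventricular, dtype=np.float32)
        self.markers = np.asarray(self.markers, dtype=np.uint8)

    def validate(self) -> None:
        for name, x in (("atrial", self.atrial), ("ventricular", self.ventricular)):
            if x.shape != (N_SAMPLES,):
                raise InvalidEpisodeError(
                    f"{self.episode_id}: {name} has {x.shape}, expected ({N_SAMPLES},)"
                )
            if not np.all(np.isfinite(x)):
                raise InvalidEpisodeError(f"{self.episode_id}: non-finite {name} samples")
            if np.max(np.abs(x)) > 1.0 + 1e-6:
                raise InvalidEpisodeError(f"{self.episode_id}: {name} not normalized")
        if self.markers.shape != (N_SAMPLES,):
            raise InvalidEpisodeError(f"{self.episode_id}: bad marker length")
        if not self.has_ventricular and np.any(self.ventricular != 0):
            raise InvalidEpisodeError(
                f"{self.episode_id}: has_ventricular=False but ventricular is nonzero"
            )
        if self.marker_types is not None:
            idx = sorted(i for i, _ in self.marker_types)
            marked = sorted(np.flatnonzero(self.markers).tolist())
            if idx != marked:
                raise InvalidEpisodeError(
                    f"{self.episode_id}: marker_types indices disagree with marker train"
                )

    def signal_matrix(self) -> np.ndarray:
        """(1280, 2) float32 input tensor, channel order (atrial, ventricular)."""
        return np.stack([self.atrial, self.ventricular], axis=1)


@dataclasses.dataclass
class CohortManifest:
    """A set of episodes plus the patient-to-center mapping."""

    episodes: list[EpisodeRecord]
    patient_to_center: dict[str, str]

    @property
    def class_counts(self) -> dict[Label, int]:
        return dict(Counter(e.label for e in self.episodes))

    def validate(self) -> None:
        for e in self.episodes:
            if e.patient_id not in self.patient_to_center:
                raise CohortIOError(f"{e.episode_id}: patient {e.patient_id} not in roster")

    def subset(self, episodes: Iterable[EpisodeRecord]) -> "CohortManifest":
        eps = list(episodes)
        return CohortManifest(eps, dict(self.patient_to_center))

    def by_center(self, center_id: str) -> list[EpisodeRecord]:
        return [e for e in self.episodes if e.center_id == center_id]

    @property
    def centers(self) -> list[str]:
        return sorted({e.center_id for e in self.episodes})

    def patients(self) -> set[str]:
        return {e.patient_id for e in self.episodes}


def normalize_channel(x: np.ndarray) -> np.ndarray:
    """Scale a channel by its max absolute value into [-1, 1].

    All-zero channels pass through unchanged, so the operation is
    idempotent and safe for absent ventricular channels.
    """
    x = np.asarray(x, dtype=np.float32)
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    if peak == 0.0:
        return x.copy()
    return x / peak


def _fit_window(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Retain the last 1280 samples; prefix-pad with zeros when shorter.

    Returns the fitted signal and the offset mapping raw sample index i to
    grid index i + offset.
    """
    n = raw.shape[0]
    if n >= N_SAMPLES:
        return raw[n - N_SAMPLES:].copy(), N_SAMPLES - n
    out = np.zeros(N_SAMPLES, dtype=np.float32)
    out[N_SAMPLES - n:] = raw
    return out, N_SAMPLES - n


def binarize_markers(
    marker_times_s: Sequence[float],
    offset: int,
    marker_kinds: Sequence[MarkerType | str] | None = None,
) -> tuple[np.ndarray, list[tuple[int, MarkerType]] | None]:
    """Place markers on the 1280-sample grid.

    Sample index is round(t * 128) shifted by the window offset; times that
    fall before the retained window are dropped, and the t = 10 s edge is
    clipped onto the final sample.
    """
    markers = np.zeros(N_SAMPLES, dtype=np.uint8)
    typed: list[tuple[int, MarkerType]] = []
    for j, t in enumerate(marker_times_s):
        idx = int(round(float(t) * FS)) + offset
        if idx == N_SAMPLES:  # exact end-of-window edge
            idx = N_SAMPLES - 1
        if 0 <= idx < N_SAMPLES:
            markers[idx] = 1
            if marker_kinds is not None:
                typed.append((idx, MarkerType(marker_kinds[j])))
    if marker_kinds is None:
        return markers, None
    # one type per sample: keep the first annotation at a collided sample
    seen: dict[int, MarkerType] = {}
    for idx, kind in typed:
        seen.setdefault(idx, kind)
    return markers, sorted(seen.items())


def preprocess(
    raw_atrial: np.ndarray,
    raw_ventricular: np.ndarray | None,
    raw_marker_times: Sequence[float] = (),
    fs: int = FS,
    marker_kinds: Sequence[MarkerType | str] | None = None,
) -> dict:
    """Standardize raw device signals into the fixed episode payload.

    Keeps the last ten seconds (prefix zero-padding shorter recordings),
    substitutes a zero vector for an absent ventricular channel, binarizes
    marker times onto the sample grid, and max-abs normalizes each channel.
    Returns the payload fields of :class:`EpisodeRecord`.
    """
    if fs != FS:
        raise InvalidEpisodeError(f"unsupported sample rate {fs}, expected {FS}")
    raw_atrial = np.asarray(raw_atrial, dtype=np.float32)
    if raw_atrial.size == 0:
        raise InvalidEpisodeError("empty atrial signal")
    if not np.all(np.isfinite(raw_atrial)):
        raise InvalidEpisodeError("non-finite atrial samples")

    atrial, offset = _fit_window(raw_atrial)
    has_ventricular = raw_ventricular is not None and np.asarray(raw_ventricular).size > 0
    if has_ventricular:
        raw_ventricular = np.asarray(raw_ventricular, dtype=np.float32)
        if not np.all(np.isfinite(raw_ventricular)):
            raise InvalidEpisodeError("non-finite ventricular samples")
        ventricular, _ = _fit_window(raw_ventricular)
    else:
        ventricular = np.zeros(N_SAMPLES, dtype=np.float32)

    markers, marker_types = binarize_markers(raw_marker_times, offset, marker_kinds)
    return {
        "atrial": normalize_channel(atrial),
        "ventricular": normalize_channel(ventricular),
        "has_ventricular": bool(has_ventricular),
        "markers": markers,
        "marker_types": marker_types,
    }


# ---------------------------------------------------------------------------
# Persistence: one HDF5 file for arrays + a CSV manifest alongside it.
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["episode_id", "patient_id", "center_id", "label", "has_ventricular"]
PROVENANCE_COLUMNS = ["source_episode_id", "technique"]


def manifest_path_for(h5_path: str | Path) -> Path:
    p = Path(h5_path)
    return p.with_suffix(".manifest.csv")


def save_cohort(manifest: CohortManifest, h5_path: str | Path) -> None:
    """Write signals/markers to HDF5 and the episode table to CSV."""
    manifest.validate()
    h5_path = Path(h5_path)
    h5_path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    with h5py.File(h5_path, "w") as f:
        f.attrs["patient_to_center"] = json.dumps(manifest.patient_to_center, sort_keys=True)
        grp = f.create_group("episodes")
        for e in manifest.episodes:
            g = grp.create_group(e.episode_id)
            g.create_dataset("atrial", data=e.atrial)
            g.create_dataset("ventricular", data=e.ventricular)
            g.create_dataset("markers", data=e.markers)
            if e.marker_types is not None:
                g.create_dataset(
                    "marker_index", data=np.array([i for i, _ in e.marker_types], dtype=np.int32)
                )
                g.create_dataset(
                    "marker_kind",
                    data=np.array([k.value for _, k in e.marker_types], dtype="S4"),
                )
            row = {
                "episode_id": e.episode_id,
                "patient_id": e.patient_id,
                "center_id": e.center_id,
                "label": e.label.value,
                "has_ventricular": e.has_ventricular,
            }
            if e.provenance:
                row.update({c: e.provenance.get(c, "") for c in PROVENANCE_COLUMNS})
            rows.append(row)
    df = pd.DataFrame(rows)
    cols = MANIFEST_COLUMNS + [c for c in PROVENANCE_COLUMNS if c in df.columns]
    df.to_csv(manifest_path_for(h5_path), index=False, columns=cols)


def load_cohort(h5_path: str | Path) -> CohortManifest:
    """Load a cohort saved by :func:`save_cohort`; round trip is lossless."""
    h5_path = Path(h5_path)
    csv_path = manifest_path_for(h5_path)
    if not h5_path.exists():
        raise CohortIOError(f"missing cohort file {h5_path}")
    if not csv_path.exists():
        raise CohortIOError(f"missing manifest {csv_path}")
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise CohortIOError(f"manifest missing columns {missing}")
    episodes: list[EpisodeRecord] = []
    with h5py.File(h5_path, "r") as f:
        p2c = json.loads(f.attrs["patient_to_center"])
        grp = f["episodes"]
        for row in df.itertuples(index=False):
            eid = row.episode_id
            if eid not in grp:
                raise CohortIOError(f"manifest references missing signal arrays: {eid}")
            g = grp[eid]
            atrial = g["atrial"][()]
            ventricular = g["ventricular"][()]
            markers = g["markers"][()]
            if atrial.shape != (N_SAMPLES,) or ventricular.shape != (N_SAMPLES,):
                raise CohortIOError(f"signal length mismatch for episode {eid}")
            marker_types = None
            if "marker_index" in g:
                marker_types = [
                    (int(i), MarkerType(k.decode()))
                    for i, k in zip(g["marker_index"][()], g["marker_kind"][()])
                ]
            provenance = None
            if "technique" in df.columns and getattr(row, "technique", ""):
                provenance = {
                    "source_episode_id": row.source_episode_id,
                    "technique": row.technique,
                }
            episodes.append(
                EpisodeRecord(
                    episode_id=eid,
                    patient_id=row.patient_id,
                    center_id=row.center_id,
                    label=Label(row.label),
                    atrial=atrial,
                    ventricular=ventricular,
                    has_ventricular=row.has_ventricular in ("True", "true", "1"),
                    markers=markers,
                    marker_types=marker_types,
                    provenance=provenance,
                )
            )
    m = CohortManifest(episodes, p2c)
    m.validate()
    return m


def labels_to_int(episodes: Sequence[EpisodeRecord], classes: Sequence[Label]) -> np.ndarray:
    index: Mapping[Label, int] = {c: i for i, c in enumerate(classes)}
    return np.array([index[e.label] for e in episodes], dtype=np.int64)


def stack_signals(episodes: Sequence[EpisodeRecord]) -> np.ndarray:
    """(n, 1280, 2) float32 batch tensor."""
    return np.stack([e.signal_matrix() for e in episodes], axis=0)
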