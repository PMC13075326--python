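"""Training-time augmentation operators and their application policy.

Five channel-coherent transforms enlarge the training pool: blanking a
random 2 s window, per-channel amplitude scaling by 0.4-1.2, amplitude
inversion, temporal shifting by 0.4-1.5 s with zero fill, and exchanging the
two temporal halves. Every noise and FFO episode receives one augmented copy
per technique; disjoint random 4% slices of the AT/AF episodes receive one
copy each (20% of AT/AF in total). Augmented copies supplement their
originals and are never used for pretraining, validation, or testing.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .episodes import FS, N_SAMPLES, EpisodeRecord, Label

BLANK_SAMPLES = 2 * FS          # 2 s window
SHIFT_RANGE_S = (0.4, 1.5)
SCALE_RANGE = (0.4, 1.2)

TECHNIQUES = ("BLANK", "SCALE", "INVERT", "SHIFT", "SWAP_HALVES")


@dataclasses.dataclass
class AugmentationPolicy:
    techniques: tuple[str, ...] = TECHNIQUES
    ataf_fraction_per_technique: float = 0.04

    @property
    def ataf_fraction_total(self) -> float:
        return self.ataf_fraction_per_technique * len(self.techniques)


def _copy(e: EpisodeRecord, technique: str, atrial, ventricular, extra=None) -> EpisodeRecord:
    prov = {"source_episode_id": e.episode_id, "technique": technique}
    if extra:
        prov.update(extra)
    return EpisodeRecord(
        episode_id=f"{e.episode_id}__{technique.lower()}",
        patient_id=e.patient_id,
        center_id=e.center_id,
        label=e.label,
        atrial=np.asarray(atrial, dtype=np.float32),
        ventricular=np.asarray(ventricular, dtype=np.float32),
        has_ventricular=e.has_ventricular,
        markers=e.markers.copy(),       # markers are not a model input; kept as-is
        marker_types=list(e.marker_types) if e.marker_types is not None else None,
        provenance=prov,
    )


def blank(e: EpisodeRecord, rng: np.random.Generator) -> EpisodeRecord:
    """Zero one random contiguous 2 s window, same window on both channels."""
    start = int(rng.integers(0, N_SAMPLES - BLANK_SAMPLES + 1))
    a = e.atrial.copy()
    v = e.ventricular.copy()
    a[start : start + BLANK_SAMPLES] = 0.0
    v[start : start + BLANK_SAMPLES] = 0.0
    return _copy(e, "BLANK", a, v, {"start": start})


def scale(e: EpisodeRecord, rng: np.random.Generator) -> EpisodeRecord:
    """Scale each channel by an independent factor drawn from [0.4, 1.2]."""
    fa = float(rng.uniform(*SCALE_RANGE))
    fv = float(rng.uniform(*SCALE_RANGE))
    out = _copy(e, "SCALE", e.atrial * fa, e.ventricular * fv, {"factors": (fa, fv)})
    return out


def invert(e: EpisodeRecord) -> EpisodeRecord:
    """Multiply both channels by -1 (an involution)."""
    return _copy(e, "INVERT", -e.atrial, -e.ventricular)


def shift(e: EpisodeRecord, rng: np.random.Generator) -> EpisodeRecord:
    """Shift both channels by 0.4-1.5 s in a random direction, zero-filling."""
    delta_s = float(rng.uniform(*SHIFT_RANGE_S))
    delta = int(round(delta_s * FS)) * (1 if rng.random() < 0.5 else -1)
    a = np.zeros_like(e.atrial)
    v = np.zeros_like(e.ventricular)
    if delta > 0:
        a[delta:] = e.atrial[:-delta]
        v[delta:] = e.ventricular[:-delta]
    else:
        a[:delta] = e.atrial[-delta:]
        v[:delta] = e.ventricular[-delta:]
    return _copy(e, "SHIFT", a, v, {"delta_samples": delta})


def swap_halves(e: EpisodeRecord) -> EpisodeRecord:
    """Exchange the first and second 5 s halves on both channels."""
    h = N_SAMPLES // 2
    a = np.concatenate([e.atrial[h:], e.atrial[:h]])
    v = np.concatenate([e.ventricular[h:], e.ventricular[:h]])
    return _copy(e, "SWAP_HALVES", a, v)


def _apply(technique: str, e: EpisodeRecord, rng: np.random.Generator) -> EpisodeRecord:
    if technique == "BLANK":
        return blank(e, rng)
    if technique == "SCALE":
        return scale(e, rng)
    if technique == "INVERT":
        return invert(e)
    if technique == "SHIFT":
        return shift(e, rng)
    if technique == "SWAP_HALVES":
        return swap_halves(e)
    raise ValueError(f"unknown augmentation technique {technique}")


def apply_policy(
    episodes: Sequence[EpisodeRecord],
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> list[EpisodeRecord]:
    """Return originals plus augmented copies per the training policy.

    Noise and FFO episodes each contribute one copy per technique. A
    disjoint random floor(4%) slice of AT/AF episodes per technique
    contributes one copy each. SINUS episodes are never augmented (they
    belong to the pretraining pool, which uses no augmentation).
    """
    episodes = list(episodes)
    out = list(episodes)
    minority = [e for e in episodes if e.label in (Label.NOISE, Label.FFO)]
    for e in minority:
        for tech in policy.techniques:
            out.append(_apply(tech, e, rng))

    ataf = [e for e in episodes if e.label == Label.ATAF]
    per_tech = math.floor(policy.ataf_fraction_per_technique * len(ataf))
    if per_tech > 0:
        chosen = rng.choice(len(ataf), size=per_tech * len(policy.techniques), replace=False)
        for ti, tech in enumerate(policy.techniques):
            for idx in chosen[ti * per_tech : (ti + 1) * per_tech]:
                out.append(_apply(tech, ataf[int(idx)], rng))
    return out
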