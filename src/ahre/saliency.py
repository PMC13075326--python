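"""Grad-CAM++ attribution for the 1D residual network.

Importance weights are computed from gradients of the (exponentiated) class
score with respect to the final convolutional feature maps of the second
residual stage. Because the network is piecewise linear between that
activation and the logits, the second- and third-order terms of Grad-CAM++
reduce to powers of the first-order gradient, so only one backward pass is
needed. The ReLU-rectified weighted channel sum is linearly upsampled to
the 1280-sample input grid; one temporal map is shared by both channels.
Ensemble maps are the element-wise mean of min-max-normalized member maps.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .episodes import N_SAMPLES, EpisodeRecord
from .resnet1d import ResNet1D

TARGET_UNIT = "block2b"
_EPS = 1e-12


@dataclasses.dataclass
class SaliencyMap:
    episode_id: str
    target_class: int
    values: np.ndarray           # (1280,) nonnegative
    provenance: str = "model"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_SAMPLES,):
            raise ValueError(f"saliency map must have {N_SAMPLES} samples")
        if np.any(self.values < -_EPS):
            raise ValueError("saliency values must be nonnegative")

    def min_max_normalized(self) -> "SaliencyMap":
        """Rescale to [0, 1]; a constant map maps to all zeros."""
        lo, hi = self.values.min(), self.values.max()
        vals = np.zeros_like(self.values) if hi - lo < _EPS else (self.values - lo) / (hi - lo)
        return dataclasses.replace(self, values=vals, normalized=True)


def grad_cam_pp(
    model: ResNet1D,
    episode: EpisodeRecord,
    class_index: int,
    target_unit: str = TARGET_UNIT,
) -> SaliencyMap:
    """Grad-CAM++ temporal saliency for one episode and class."""
    x = episode.signal_matrix()[None, ...]
    acts, grads = model.grad_wrt_unit(x, class_index, target_unit)
    A = acts[0].astype(np.float64)       # (L_feat, C_feat)
    g = grads[0].astype(np.float64)

    # exp-score trick: with Y = exp(s), d^nY/dA^n = exp(s) g^n for a
    # piecewise-linear s(A); exp(s) cancels inside alpha.
    g2 = g**2
    g3 = g2 * g
    denom = 2.0 * g2 + np.sum(A * g3, axis=0, keepdims=True)
    alpha = np.where(np.abs(denom) > _EPS, g2 / np.where(np.abs(denom) > _EPS, denom, 1.0), 0.0)
    weights = np.sum(alpha * np.maximum(g, 0.0), axis=0)   # (C_feat,)
    cam = np.maximum(A @ weights, 0.0)                      # (L_feat,)

    xp = np.linspace(0.0, 1.0, num=len(cam))
    xq = np.linspace(0.0, 1.0, num=N_SAMPLES)
    upsampled = np.interp(xq, xp, cam)
    return SaliencyMap(
        episode_id=episode.episode_id,
        target_class=class_index,
        values=upsampled,
        provenance="model",
    )


def ensemble_map(maps: Sequence[SaliencyMap]) -> SaliencyMap:
    """Min-max normalize each member map, then average element-wise."""
    if not maps:
        raise ValueError("need at least one saliency map")
    ref = maps[0]
    for m in maps[1:]:
        if m.values.shape != ref.values.shape:
            raise ValueError("saliency map length mismatch")
        if m.episode_id != ref.episode_id or m.target_class != ref.target_class:
            raise ValueError("saliency maps must share episode and target class")
    stacked = np.stack([m.min_max_normalized().values for m in maps])
    return SaliencyMap(
        episode_id=ref.episode_id,
        target_class=ref.target_class,
        values=stacked.mean(axis=0),
        provenance="ensemble",
        normalized=True,
    )


def render(
    episode: EpisodeRecord,
    smap: SaliencyMap,
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Two stacked EGM traces with saliency as background shading (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(N_SAMPLES) / 128.0
    vals = smap.min_max_normalized().values
    fig, axes = plt.subplots(2, 1, figsize=(10, 4), sharex=True)
    for ax, sig, name in zip(axes, (episode.atrial, episode.ventricular), ("A-EGM", "V-EGM")):
        ax.imshow(
            vals[None, :],
            aspect="auto",
            extent=(0, 10, -1.1, 1.1),
            cmap="Greys",
            vmin=0,
            vmax=1,
            alpha=0.6,
            interpolation="nearest",
        )
        ax.plot(t, sig, lw=0.7, color="tab:blue")
        ax.set_ylabel(name)
        ax.set_ylim(-1.1, 1.1)
    axes[1].set_xlabel("time (s)")
    fig.suptitle(title or f"{episode.episode_id} — class {smap.target_class}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def maps_to_frame(maps: Sequence[SaliencyMap]):
    """CSV-ready long table: episode_id, sample_index, value."""
    import pandas as pd

    rows = []
    for m in maps:
        rows.append(
            pd.DataFrame(
                {
                    "episode_id": m.episode_id,
                    "sample_index": np.arange(N_SAMPLES),
                    "value": m.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
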