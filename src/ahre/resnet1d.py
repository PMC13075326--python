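"""The 1D-ResNet10 classifier, focal loss, training loop, and transfer.

Architecture (defaults): a stem of conv(k=7, stride 2, 32 filters) + batch
norm + ReLU + max-pool(3, stride 2) compresses a 1280-sample two-channel
input to a 320-point feature map; two residual layers of two blocks each
(32 then 64 filters, the second layer downsampling x2 through a strided
conv with a 1x1 projection shortcut); then global average pooling and two
dense layers ending in a softmax. That is ten weight layers on the main
path (stem conv + 8 block convs + final dense), hence "ResNet10".

Training follows the published protocol: categorical focal loss, Adam at
learning rate 0.001, batch size 64, early stopping after five stagnant
epochs (50 max), and checkpoint selection by the class-weighted F2 score on
the validation set. A two-class variant is pretrained on sinus-vs-AT/AF and
every layer except the final dense layer is transferred to the three-class
model.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nnet import (
    Adam,
    BatchNorm1d,
    Conv1d,
    Dense,
    GlobalAvgPool,
    Layer,
    MaxPool1d,
    ReLU,
    softmax,
)

PROB_EPS = 1e-7


@dataclasses.dataclass
class ModelSpec:
    """Architecture hyperparameters; defaults give the 1D-ResNet10."""

    input_length: int = 1280
    input_channels: int = 2
    filters: int = 32           # F; second residual layer uses 2F
    stem_kernel: int = 7
    block_kernel: int = 3
    hidden: int = 64
    n_classes: int = 3

    def validate(self) -> None:
        # stem conv (stride 2) + max-pool (stride 2) need a multiple of 4
        if self.input_length % 4 != 0:
            raise ValueError("input_length must be divisible by the stem stride product (4)")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    gamma: float = 2.0                   # focal loss focusing parameter
    alpha: tuple[float, ...] | None = None  # per-class weights; None = uniform
    patience: int = 5
    max_epochs: int = 50
    seed: int = 0


class ResidualBlock(Layer):
    """conv-bn-relu-conv-bn plus a shortcut, ReLU after the addition."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(c_in, c_out, k, stride, rng)
        self.bn1 = BatchNorm1d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(c_out, c_out, k, 1, rng)
        self.bn2 = BatchNorm1d(c_out)
        self.relu_out = ReLU()
        if stride != 1 or c_in != c_out:
            self.proj = Conv1d(c_in, c_out, 1, stride, rng)
            self.proj_bn = BatchNorm1d(c_out)
        else:
            self.proj = None
            self.proj_bn = None

    @property
    def sublayers(self) -> list[Layer]:
        layers = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out]
        if self.proj is not None:
            layers += [self.proj, self.proj_bn]
        return layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(h + sc, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gy)
        gh = self.bn2.backward(g)
        gh = self.conv2.backward(gh)
        gh = self.relu1.backward(gh)
        gh = self.bn1.backward(gh)
        gx = self.conv1.backward(gh)
        if self.proj is not None:
            gx = gx + self.proj.backward(self.proj_bn.backward(g))
        else:
            gx = gx + g
        return gx


class ResNet1D:
    """Sequential unit list; unit boundaries double as saliency tap points."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        F = spec.filters
        self.units: list[tuple[str, Layer]] = [
            ("stem_conv", Conv1d(spec.input_channels, F, spec.stem_kernel, 2, rng)),
            ("stem_bn", BatchNorm1d(F)),
            ("stem_relu", ReLU()),
            ("stem_pool", MaxPool1d(3, 2, 1)),
            ("block1a", ResidualBlock(F, F, spec.block_kernel, 1, rng)),
            ("block1b", ResidualBlock(F, F, spec.block_kernel, 1, rng)),
            ("block2a", ResidualBlock(F, 2 * F, spec.block_kernel, 2, rng)),
            ("block2b", ResidualBlock(2 * F, 2 * F, spec.block_kernel, 1, rng)),
            ("gap", GlobalAvgPool()),
            ("fc1", Dense(2 * F, spec.hidden, rng)),
            ("fc1_relu", ReLU()),
            ("fc_out", Dense(spec.hidden, spec.n_classes, rng, he=False)),
        ]
        self.unit_names = [n for n, _ in self.units]

    # -- plumbing ----------------------------------------------------------
    def _flat_layers(self) -> list[Layer]:
        flat: list[Layer] = []
        for _, u in self.units:
            flat.extend(u.sublayers if isinstance(u, ResidualBlock) else [u])
        return flat

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, unit in self.units:
            subs = unit.sublayers if isinstance(unit, ResidualBlock) else [unit]
            for i, lay in enumerate(subs):
                for pname, p in lay.params.items():
                    state[f"{name}.{i}.{pname}"] = p.copy()
                if isinstance(lay, BatchNorm1d):
                    state[f"{name}.{i}.running_mean"] = lay.running_mean.copy()
                    state[f"{name}.{i}.running_var"] = lay.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], skip: Sequence[str] = ()) -> None:
        for name, unit in self.units:
            if name in skip:
                continue
            subs = unit.sublayers if isinstance(unit, ResidualBlock) else [unit]
            for i, lay in enumerate(subs):
                for pname in lay.params:
                    lay.params[pname] = state[f"{name}.{i}.{pname}"].copy()
                if isinstance(lay, BatchNorm1d):
                    lay.running_mean = state[f"{name}.{i}.running_mean"].copy()
                    lay.running_var = state[f"{name}.{i}.running_var"].copy()

    def n_parameters(self) -> int:
        return sum(p.size for lay in self._flat_layers() for p in lay.params.values())

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (n, length, 2) batch; caches per-unit activations."""
        self._activations = [x]
        h = x.astype(np.float32)
        for _, unit in self.units:
            h = unit.forward(h, train)
            self._activations.append(h)
        return h

    def activation(self, unit_name: str) -> np.ndarray:
        """Cached output of a named unit from the latest forward pass."""
        return self._activations[self.unit_names.index(unit_name) + 1]

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        """Backpropagate from the logits through every unit."""
        g = glogits
        for i in range(len(self.units) - 1, -1, -1):
            g = self.units[i][1].backward(g)
        return g

    def grad_wrt_unit(self, x: np.ndarray, class_index: int, unit_name: str) -> tuple[np.ndarray, np.ndarray]:
        """(activation, d logit_c / d activation) at a unit, eval mode."""
        logits = self.forward(x, train=False)
        if not 0 <= class_index < logits.shape[1]:
            raise IndexError(f"class index {class_index} out of range")
        gl = np.zeros_like(logits)
        gl[:, class_index] = 1.0
        idx = self.unit_names.index(unit_name)
        g = gl
        for i in range(len(self.units) - 1, idx, -1):
            g = self.units[i][1].backward(g)
        return self._activations[idx + 1], g

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)


def build_model(spec: ModelSpec, seed: int = 0) -> ResNet1D:
    return ResNet1D(spec, np.random.default_rng(seed))


def stem_output_length(model: ResNet1D) -> int:
    """Measured temporal length after the stem max-pool (320 by default)."""
    x = np.zeros((1, model.spec.input_length, model.spec.input_channels), dtype=np.float32)
    model.forward(x, train=False)
    return model.activation("stem_pool").shape[1]


# ---------------------------------------------------------------------------
# Losses and selection metric
# ---------------------------------------------------------------------------

def focal_loss(
    probs: np.ndarray,
    onehot: np.ndarray,
    gamma: float = 2.0,
    alpha: Sequence[float] | None = None,
) -> float:
    """Mean categorical focal loss, FL = -sum_c alpha_c (1-p_c)^gamma y_c log p_c.

    At gamma = 0 with uniform alpha this is exactly categorical
    cross-entropy. Probabilities are clipped away from zero at 1e-7.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.clip(probs, PROB_EPS, 1.0)
    a = np.ones(p.shape[1]) if alpha is None else np.asarray(alpha, dtype=np.float64)
    per = -(a * (1 - p) ** gamma * onehot * np.log(p)).sum(axis=1)
    return float(per.mean())


def focal_loss_grad(
    probs: np.ndarray,
    onehot: np.ndarray,
    gamma: float,
    alpha: Sequence[float] | None = None,
) -> np.ndarray:
    """d(mean focal loss)/d logits, chained through the softmax."""
    n, c = probs.shape
    a = np.ones(c) if alpha is None else np.asarray(alpha, dtype=np.float64)
    p = np.clip(probs, PROB_EPS, 1.0 - PROB_EPS)
    # dL/dp is nonzero only at the true class; the gamma factor kills the
    # second term exactly at gamma = 0 (plain cross-entropy)
    dLdp = -a * onehot * ((1 - p) ** gamma / p - gamma * (1 - p) ** (gamma - 1) * np.log(p))
    dot = (dLdp * probs).sum(axis=1, keepdims=True)
    return (probs * (dLdp - dot) / n).astype(np.float32)


def fbeta(precision: float, recall: float, beta: float = 2.0) -> float:
    """F-beta = (1+b^2) P R / (b^2 P + R); 5PR/(4P+R) at beta=2."""
    denom = beta**2 * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * recall / denom


def weighted_f2(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    """Support-weighted mean of per-class F2 scores (one-vs-rest)."""
    scores, weights = [], []
    for c in range(n_classes):
        support = int((y_true == c).sum())
        if support == 0:
            continue
        tp = int(((y_pred == c) & (y_true == c)).sum())
        fp = int(((y_pred == c) & (y_true != c)).sum())
        fn = support - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn)
        scores.append(fbeta(p, r, 2.0))
        weights.append(support)
    if not weights:
        return 0.0
    w = np.asarray(weights, dtype=float)
    return float((np.asarray(scores) * w).sum() / w.sum())


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainResult:
    history: pd.DataFrame          # epoch, train_loss, val_loss, val_weighted_f2
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_f2: float


def train(
    model: ResNet1D,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> TrainResult:
    """Mini-batch training with early stopping and F2-based selection.

    Returns the history and the checkpoint with the highest validation
    class-weighted F2; the model is left loaded with that checkpoint.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty train or validation split")
    rng = np.random.default_rng(config.seed)
    n_classes = model.spec.n_classes
    eye = np.eye(n_classes, dtype=np.float32)
    opt = Adam(lr=config.learning_rate)
    layers = model._flat_layers()

    best_f2, best_state, best_epoch = -1.0, model.state_dict(), 0
    stagnant = 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(x_train[idx], train=True)
            probs = softmax(logits)
            oh = eye[y_train[idx]]
            losses.append(focal_loss(probs, oh, config.gamma, config.alpha))
            model.backward(focal_loss_grad(probs, oh, config.gamma, config.alpha))
            opt.step(layers)

        val_probs = model.predict_proba(x_val)
        val_loss = focal_loss(val_probs, eye[y_val], config.gamma, config.alpha)
        val_f2 = weighted_f2(y_val, val_probs.argmax(axis=1), n_classes)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_weighted_f2": val_f2,
            }
        )
        if val_f2 > best_f2:
            best_f2, best_state, best_epoch = val_f2, model.state_dict(), epoch
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= config.patience:
                break

    model.load_state_dict(best_state)
    return TrainResult(pd.DataFrame(rows), best_state, best_epoch, best_f2)


def pretrain_then_transfer(
    pretrained: ResNet1D,
    n_classes: int = 3,
    seed: int = 0,
) -> ResNet1D:
    """Initialize an n-class model from a pretrained one.

    All layers except the final dense layer are copied; the final layer is
    freshly initialized at the new width.
    """
    spec = dataclasses.replace(pretrained.spec, n_classes=n_classes)
    target = build_model(spec, seed)
    target.load_state_dict(pretrained.state_dict(), skip=("fc_out",))
    return target


def check_pretraining_pool(labels: Sequence) -> None:
    """Pretraining distinguishes sinus from AT/AF only."""
    from .episodes import Label

    bad = {Label(l) for l in labels} - {Label.SINUS, Label.ATAF}
    if bad:
        raise ValueError(f"pretraining pool contains forbidden classes: {sorted(x.value for x in bad)}")


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ResNet1D, path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"spec": model.spec.to_dict(), "seed": seed}
    with open(path, "wb") as fh:
        np.savez(
            fh,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **model.state_dict(),
        )


def load_checkpoint(path: str | Path) -> ResNet1D:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = build_model(ModelSpec(**meta["spec"]), seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
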