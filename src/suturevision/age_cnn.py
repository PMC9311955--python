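"""Five-class age-range classifier over fused suture images.

The network is a residual CNN: a stem (one convolution + one max-pool)
followed by stages of residual blocks, global average pooling and a fully
connected softmax head over the five age ranges. Each residual block
computes ``x_{l+1} = ReLU(x_l + F(x_l))`` with an identity shortcut
(projection when the shape changes), so the backward pass carries an
additive identity term alongside the residual-branch gradient and deep
stacks stay trainable. The default layout is the canonical 50-layer
configuration — bottleneck blocks in stage counts (3, 4, 6, 3) — adapted to
a 1-channel 50x200 input; ``NetworkSpec.small()`` gives a narrow basic-block
variant that trains in minutes on a CPU for synthetic studies.

Training minimizes cross-entropy with SGD-momentum, L2 weight decay and an
exponentially decaying learning rate floored at ``end_learning_rate``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
    Sequential,
    cross_entropy,
    softmax,
)
from .roi import ROI_COLS, ROI_ROWS

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "AgeRangeCNN",
    "build_network",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

N_CLASSES = 5
BOTTLENECK_EXPANSION = 4


@dataclass
class NetworkSpec:
    """Architecture description of the residual classifier.

    stage_blocks : residual blocks per stage; (3, 4, 6, 3) is the canonical
        50-layer layout.
    base_width : channel width of stage 1; stage i doubles it i times.
    bottleneck : 1x1-3x3-1x1 blocks with 4x expansion (canonical) vs plain
        3x3-3x3 basic blocks.
    """

    stage_blocks: tuple[int, ...] = (3, 4, 6, 3)
    base_width: int = 64
    bottleneck: bool = True
    n_classes: int = N_CLASSES
    in_channels: int = 1
    stem_kernel: int = 7
    input_shape: tuple[int, int] = (ROI_ROWS, ROI_COLS)

    @classmethod
    def resnet50(cls) -> "NetworkSpec":
        return cls()

    @classmethod
    def small(cls, n_classes: int = N_CLASSES) -> "NetworkSpec":
        """Narrow basic-block variant for desk-scale CPU training."""
        return cls(
            stage_blocks=(1, 1, 1),
            base_width=8,
            bottleneck=False,
            n_classes=n_classes,
            stem_kernel=5,
        )


class _ResidualBlock(Layer):
    """One residual unit: out = ReLU(branch(x) + shortcut(x))."""

    def __init__(
        self,
        c_in: int,
        width: int,
        stride: int,
        bottleneck: bool,
        rng: np.random.Generator,
    ):
        c_out = width * BOTTLENECK_EXPANSION if bottleneck else width
        if bottleneck:
            branch: list[Layer] = [
                Conv2d(c_in, width, 1, bias=False, rng=rng),
                BatchNorm2d(width),
                ReLU(),
                Conv2d(width, width, 3, stride=stride, pad=1, bias=False, rng=rng),
                BatchNorm2d(width),
                ReLU(),
                Conv2d(width, c_out, 1, bias=False, rng=rng),
                BatchNorm2d(c_out),
            ]
        else:
            branch = [
                Conv2d(c_in, width, 3, stride=stride, pad=1, bias=False, rng=rng),
                BatchNorm2d(width),
                ReLU(),
                Conv2d(width, c_out, 3, pad=1, bias=False, rng=rng),
                BatchNorm2d(c_out),
            ]
        self.branch = Sequential(branch)
        if stride != 1 or c_in != c_out:
            self.shortcut: Sequential | None = Sequential(
                [Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng), BatchNorm2d(c_out)]
            )
        else:
            self.shortcut = None
        self.c_out = c_out

    def params(self) -> list[Param]:
        p = self.branch.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode
        self.branch.set_train(mode)
        if self.shortcut is not None:
            self.shortcut.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.branch.forward(x)
        s = self.shortcut.forward(x) if self.shortcut is not None else x
        y = f + s
        self._mask = y > 0
        return np.where(self._mask, y, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        dx = self.branch.backward(dy)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(dy)
        else:
            dx = dx + dy  # the identity term of the shortcut
        return dx


class AgeRangeCNN:
    """Residual age-range classifier with an inspectable feature layer.

    ``forward`` returns pre-softmax scores (logits); the output of the last
    residual stage — the Grad-CAM target layer — is cached per call, and
    ``backward`` can stop there to expose the score gradient w.r.t. it.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.base_width
        self.stem = Sequential(
            [
                Conv2d(
                    spec.in_channels,
                    w,
                    spec.stem_kernel,
                    stride=2,
                    pad=spec.stem_kernel // 2,
                    bias=False,
                    rng=rng,
                ),
                BatchNorm2d(w),
                ReLU(),
                MaxPool2d(3, 2, 1),
            ]
        )
        self.stages: list[Sequential] = []
        c_in = w
        for s_idx, n_blocks in enumerate(spec.stage_blocks):
            width = w * (2**s_idx)
            blocks: list[Layer] = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and s_idx > 0) else 1
                blk = _ResidualBlock(c_in, width, stride, spec.bottleneck, rng)
                blocks.append(blk)
                c_in = blk.c_out
            self.stages.append(Sequential(blocks))
        self.gap = GlobalAvgPool()
        self.fc = Linear(c_in, spec.n_classes, rng=rng)
        self.feature_channels = c_in
        self._feature: np.ndarray | None = None

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out = self.stem.params()
        for st in self.stages:
            out += st.params()
        out += self.fc.params()
        return out

    def batchnorms(self) -> list[BatchNorm2d]:
        def walk(layer) -> list[BatchNorm2d]:
            if isinstance(layer, BatchNorm2d):
                return [layer]
            if isinstance(layer, Sequential):
                return [b for l in layer.layers for b in walk(l)]
            if isinstance(layer, _ResidualBlock):
                got = walk(layer.branch)
                if layer.shortcut is not None:
                    got += walk(layer.shortcut)
                return got
            return []

        out = walk(self.stem)
        for st in self.stages:
            out += walk(st)
        return out

    def set_train(self, mode: bool) -> None:
        self.stem.set_train(mode)
        for st in self.stages:
            st.set_train(mode)
        self.fc.set_train(mode)
        self.gap.set_train(mode)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0.0

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def prepare(images: np.ndarray) -> np.ndarray:
        """8-bit images (n, H, W) or (H, W) -> normalized (n, 1, H, W)."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise ValueError(f"expected (n, H, W) images, got shape {x.shape}")
        return (x / 255.0 - 0.5)[:, None, :, :]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Normalized input (n, 1, H, W) -> logits (n, n_classes)."""
        h = self.stem.forward(x)
        for st in self.stages:
            h = st.forward(h)
        self._feature = h  # Grad-CAM target: last convolutional stage output
        pooled = self.gap.forward(h)
        return self.fc.forward(pooled)

    def backward(self, dlogits: np.ndarray, to_feature_only: bool = False) -> np.ndarray:
        """Backpropagate from the logits; returns d/d(feature) or d/d(input)."""
        dy = self.fc.backward(dlogits)
        dfeat = self.gap.backward(dy)
        if to_feature_only:
            return dfeat
        dy = dfeat
        for st in reversed(self.stages):
            dy = st.backward(dy)
        return self.stem.backward(dy)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        self.set_train(False)
        return softmax(self.forward(self.prepare(images)))

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def n_weight_layers(self) -> int:
        """Count of convolution + fully connected layers (the '50' of ResNet50)."""

        def count(layer) -> int:
            if isinstance(layer, (Conv2d, Linear)):
                return 1
            if isinstance(layer, Sequential):
                return sum(count(l) for l in layer.layers)
            if isinstance(layer, _ResidualBlock):
                return count(layer.branch)  # projection shortcuts excluded, per convention
            return 0

        return count(self.stem) + sum(count(st) for st in self.stages) + 1


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> AgeRangeCNN:
    """Construct the residual classifier for 1-channel 50x200 inputs."""
    return AgeRangeCNN(spec or NetworkSpec(), seed=seed)


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the study configuration)."""

    learning_rate: float = 0.0001
    decay_rate: float = 0.9
    decay_steps: int = 4000
    end_learning_rate: float = 0.0
    weight_decay: float = 0.0001
    batch_size: int = 50
    max_steps: int = 2000
    checkpoint_every: int = 100
    momentum: float = 0.9
    seed: int = 0
    schedule: str = "exponential"  # or "polynomial"

    def lr_at(self, step: int) -> float:
        if self.schedule == "polynomial":
            t = min(step / max(self.max_steps, 1), 1.0)
            return self.end_learning_rate + (self.learning_rate - self.end_learning_rate) * (
                1.0 - t
            )
        lr = self.learning_rate * self.decay_rate ** (step / self.decay_steps)
        return max(lr, self.end_learning_rate)


def _accuracy(model: AgeRangeCNN, images: np.ndarray, labels: np.ndarray, batch: int = 100) -> float:
    correct = 0
    for i in range(0, len(images), batch):
        p = model.predict_proba(images[i : i + batch])
        correct += int((p.argmax(axis=1) == labels[i : i + batch]).sum())
    return correct / len(images)


def train(
    model: AgeRangeCNN,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None,
    config: TrainConfig,
    test_set: tuple[np.ndarray, np.ndarray] | None = None,
    checkpoint_dir: str | Path | None = None,
) -> list[dict]:
    """SGD-momentum training with weight decay and LR decay.

    Returns the per-checkpoint history: step, lr, loss and the accuracy on
    each provided set. Aborts with diagnostics if the loss diverges.
    """
    x_tr, y_tr = np.asarray(train_set[0]), np.asarray(train_set[1])
    if len(x_tr) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    velocity = [np.zeros_like(p.value) for p in model.params()]
    history: list[dict] = []
    n = len(x_tr)

    for step in range(1, config.max_steps + 1):
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        xb = AgeRangeCNN.prepare(x_tr[idx])
        yb = y_tr[idx]
        model.set_train(True)
        model.zero_grad()
        logits = model.forward(xb)
        loss, dlogits = cross_entropy(logits, yb)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at step {step}: loss={loss}, "
                f"lr={config.lr_at(step):.3g}, batch={sorted(idx.tolist())[:10]}..."
            )
        model.backward(dlogits)
        lr = config.lr_at(step)
        for p, v in zip(model.params(), velocity):
            g = p.grad + (config.weight_decay * p.value if p.decay else 0.0)
            v *= config.momentum
            v -= lr * g
            p.value += v

        if step % config.checkpoint_every == 0 or step == config.max_steps:
            rec = {"step": step, "lr": lr, "loss": loss}
            rec["train_acc"] = _accuracy(model, x_tr, y_tr)
            if val_set is not None and len(val_set[0]):
                rec["val_acc"] = _accuracy(model, np.asarray(val_set[0]), np.asarray(val_set[1]))
            if test_set is not None and len(test_set[0]):
                rec["test_acc"] = _accuracy(model, np.asarray(test_set[0]), np.asarray(test_set[1]))
            history.append(rec)
            if checkpoint_dir is not None:
                save_checkpoint(model, config, Path(checkpoint_dir) / f"step{step:06d}.npz")
    return history


def predict(model: AgeRangeCNN, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Softmax probabilities and argmax labels (ties break to the lowest label)."""
    x = np.asarray(images)
    if x.ndim == 2:
        x = x[None]
    if x.shape[-2:] != tuple(model.spec.input_shape):
        raise ValueError(
            f"expected {model.spec.input_shape} images, got {x.shape[-2:]}"
        )
    probs = model.predict_proba(x)
    return probs, probs.argmax(axis=1)


def save_checkpoint(model: AgeRangeCNN, config: TrainConfig, path: str | Path) -> Path:
    """Parameters + batch-norm running stats + config/spec in one .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i:04d}": p.value for i, p in enumerate(model.params())}
    for i, bn in enumerate(model.batchnorms()):
        arrays[f"bn_mean_{i:04d}"] = bn.running_mean
        arrays[f"bn_var_{i:04d}"] = bn.running_var
    meta = json.dumps({"spec": asdict(model.spec), "config": asdict(config)})
    np.savez_compressed(path, meta=np.str_(meta), **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[AgeRangeCNN, TrainConfig]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        spec_d = dict(meta["spec"])
        spec_d["stage_blocks"] = tuple(spec_d["stage_blocks"])
        spec_d["input_shape"] = tuple(spec_d["input_shape"])
        spec = NetworkSpec(**spec_d)
        model = AgeRangeCNN(spec)
        for i, p in enumerate(model.params()):
            p.value[:] = z[f"param_{i:04d}"]
        for i, bn in enumerate(model.batchnorms()):
            bn.running_mean[:] = z[f"bn_mean_{i:04d}"]
            bn.running_var[:] = z[f"bn_var_{i:04d}"]
        config = TrainConfig(**meta["config"])
    return model, config
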