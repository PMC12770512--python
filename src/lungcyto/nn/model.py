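"""The hybrid two-branch classifier.

Architecture: a residual branch of bottleneck blocks (1x1 reduce,
3x3, 1x1 expand, batch-normalized, ReLU, additive shortcut) extracts
global features; an encoder/decoder branch whose skip connections
pass through additive attention gates extracts spatial features.
Both end in global average pooling; the two feature vectors are
concatenated into a dense head (512 ReLU units with L2 weight decay,
batch normalization, dropout, softmax over the three subtypes).

The attention gate is the standard additive formulation: with skip
features x and gating signal g (upsampled to x's resolution),

    alpha = sigmoid(psi(ReLU(Wx * x + Wg * g + b))),  out = alpha * x

with Wx, Wg and psi as 1x1 convolutions.

The full-scale stage plan (3, 4, 6, 3) reproduces the canonical
50-layer residual network (49 convolutions plus the classifier);
the desk-scale default uses one block per stage, reduced widths and
64x64 inputs so that training runs in minutes on one CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..errors import ConfigurationError, DataError, InputError
from .layers import (Adam, BatchNorm, Conv2D, Dense, Dropout, GlobalAvgPool,
                     Layer, MaxPool2, ReLU, Upsample2, softmax,
                     softmax_cross_entropy)


@dataclass(frozen=True)
class ModelConfig:
    """Hybrid model hyperparameters.

    ``resnet_plan`` is the number of bottleneck blocks per stage;
    stage i uses internal width ``base_filters * 2**i`` and output
    width four times that.  ``unet_depth`` is the number of
    encoder/pooling levels in the attention branch.  The published
    full-scale settings are the defaults (224x224 input, plan
    (3, 4, 6, 3), Adam at 1e-4, 25 epochs); :func:`desk_config`
    returns the small configuration used for CPU-scale runs.
    """

    input_size: tuple[int, int] = (224, 224)
    resnet_plan: tuple[int, ...] = (3, 4, 6, 3)
    unet_depth: int = 4
    base_filters: int = 8
    branch_dropout: float = 0.3
    head_units: int = 512
    head_l2: float = 1e-4
    head_dropout: float = 0.25
    num_classes: int = 3
    learning_rate: float = 1e-4
    epochs: int = 25
    batch_size: int = 32
    seed: int = 0
    pretrained: bool = False
    unet_readout: str = "decoder"

    def __post_init__(self):
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if not (0 <= self.branch_dropout < 1 and 0 <= self.head_dropout < 1):
            raise ConfigurationError("dropout rates must be in [0, 1)")
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.unet_readout not in ("decoder", "bottleneck"):
            raise ConfigurationError("unet_readout must be 'decoder' or "
                                     "'bottleneck'")
        h, w = self.input_size
        res_factor = 2 ** len(self.resnet_plan)
        unet_factor = 2 ** self.unet_depth
        for factor, who in ((res_factor, "residual branch"),
                            (unet_factor, "attention branch")):
            if h % factor or w % factor or h < factor or w < factor:
                raise ConfigurationError(
                    f"input {h}x{w} not divisible by the {who} "
                    f"downsampling factor {factor}")


def desk_config(seed: int = 0, epochs: int = 50) -> ModelConfig:
    """Desk-scale configuration: 64x64 input, one block per stage,
    reduced widths, larger learning rate suited to training a small
    network from scratch on tiny datasets.
    """
    return ModelConfig(input_size=(64, 64), resnet_plan=(1, 1, 1, 1),
                       unet_depth=2, base_filters=8, learning_rate=1e-3,
                       epochs=epochs, batch_size=6, seed=seed)


def conv_layer_count(plan: Sequence[int], include_classifier: bool = True) -> int:
    """Trainable-layer count of the residual branch: one stem
    convolution, three convolutions per bottleneck block, plus the
    classifier when used standalone.  The canonical plan (3, 4, 6, 3)
    gives 50."""
    return 1 + 3 * sum(plan) + (1 if include_classifier else 0)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def _conv_bn_relu(cin: int, cout: int, rng, k: int = 3,
                  stride: int = 1) -> Sequential:
    return Sequential([Conv2D(cin, cout, k=k, stride=stride, rng=rng),
                       BatchNorm(cout), ReLU()])


class Bottleneck(Layer):
    """Residual bottleneck block: 1x1 reduce, 3x3, 1x1 expand, with a
    projection shortcut when the shape changes and an identity
    shortcut otherwise."""

    def __init__(self, cin: int, width: int, cout: int, stride: int, rng):
        self.main = Sequential([
            Conv2D(cin, width, k=1, rng=rng), BatchNorm(width), ReLU(),
            Conv2D(width, width, k=3, stride=stride, rng=rng),
            BatchNorm(width), ReLU(),
            Conv2D(width, cout, k=1, rng=rng), BatchNorm(cout),
        ])
        if cin != cout or stride != 1:
            self.shortcut = Sequential([
                Conv2D(cin, cout, k=1, stride=stride, rng=rng),
                BatchNorm(cout)])
        else:
            self.shortcut = None
        self.relu = ReLU()

    def parameters(self):
        params = self.main.parameters()
        if self.shortcut is not None:
            params += self.shortcut.parameters()
        return params

    def forward(self, x, train: bool = True):
        y = self.main.forward(x, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu.forward(y + s, train)

    def backward(self, dy):
        dz = self.relu.backward(dy)
        dx = self.main.backward(dz)
        if self.shortcut is None:
            return dx + dz
        return dx + self.shortcut.backward(dz)


class ResidualBranch(Layer):
    """Stem, staged bottleneck blocks, global average pooling and
    feature dropout."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator):
        base = cfg.base_filters
        self.stem = _conv_bn_relu(1, base, rng)
        self.pool = MaxPool2()
        self.stages: list[Bottleneck] = []
        cin = base
        for i, n_blocks in enumerate(cfg.resnet_plan):
            width = base * 2 ** i
            cout = 4 * width
            for b in range(n_blocks):
                stride = 2 if (i > 0 and b == 0) else 1
                self.stages.append(Bottleneck(cin, width, cout, stride, rng))
                cin = cout
        self.gap = GlobalAvgPool()
        self.dropout = Dropout(cfg.branch_dropout, drop_rng)
        self.feature_len = cin

    def parameters(self):
        params = self.stem.parameters()
        for s in self.stages:
            params += s.parameters()
        return params

    def forward(self, x, train: bool = True):
        x = self.stem.forward(x, train)
        x = self.pool.forward(x, train)
        for s in self.stages:
            x = s.forward(x, train)
        x = self.gap.forward(x, train)
        return self.dropout.forward(x, train)

    def backward(self, dy):
        dy = self.dropout.backward(dy)
        dy = self.gap.backward(dy)
        for s in reversed(self.stages):
            dy = s.backward(dy)
        dy = self.pool.backward(dy)
        return self.stem.backward(dy)


class AttentionGate(Layer):
    """Additive attention gate on a skip connection.

    ``forward(x, g)`` expects the gating signal g already at x's
    spatial resolution; returns ``alpha * x`` with per-position
    coefficients alpha in (0, 1).
    """

    def __init__(self, cx: int, cg: int, cint: int, rng):
        self.theta = Conv2D(cx, cint, k=1, rng=rng)
        self.phi = Conv2D(cg, cint, k=1, rng=rng)
        self.psi = Conv2D(cint, 1, k=1, rng=rng)

    def parameters(self):
        return (self.theta.parameters() + self.phi.parameters()
                + self.psi.parameters())

    def forward(self, x, g, train: bool = True):
        tx = self.theta.forward(x, train)
        pg = self.phi.forward(g, train)
        s = tx + pg
        r = s * (s > 0)
        q = self.psi.forward(r, train)
        alpha = 1.0 / (1.0 + np.exp(-q))
        self._cache = (x, s, alpha)
        self.last_alpha = alpha
        return alpha * x

    def backward(self, dy):
        x, s, alpha = self._cache
        dx = dy * alpha
        dalpha = (dy * x).sum(axis=1, keepdims=True)
        dq = dalpha * alpha * (1 - alpha)
        dr = self.psi.backward(dq)
        ds = dr * (s > 0)
        dx += self.theta.backward(ds)
        dg = self.phi.backward(ds)
        return dx, dg


class AttentionBranch(Layer):
    """Encoder/decoder feature extractor with attention-gated skips.

    Encoder level l produces ``base * 2**l`` channels (with dropout,
    then 2x pooling); the decoder upsamples, gates the matching skip,
    concatenates and convolves back down.  The read-out is a global
    average pool of the final decoder map (or of the bottleneck, per
    config)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator):
        base = cfg.base_filters
        d = cfg.unet_depth
        self.depth = d
        self.readout = cfg.unet_readout
        self.enc = []
        cin = 1
        for level in range(d):
            cout = base * 2 ** level
            self.enc.append({"conv": _conv_bn_relu(cin, cout, rng),
                             "drop": Dropout(cfg.branch_dropout, drop_rng),
                             "pool": MaxPool2()})
            cin = cout
        self.bottleneck = _conv_bn_relu(cin, base * 2 ** d, rng)
        self.dec = []
        cg = base * 2 ** d
        for level in reversed(range(d)):
            cx = base * 2 ** level
            self.dec.append({"up": Upsample2(),
                             "gate": AttentionGate(cx, cg, max(cx // 2, 1), rng),
                             "conv": _conv_bn_relu(cg + cx, cx, rng)})
            cg = cx
        self.gap = GlobalAvgPool()
        self.feature_len = (base if self.readout == "decoder"
                            else base * 2 ** d)
        self.n_gates = d

    def parameters(self):
        params = []
        for e in self.enc:
            params += e["conv"].parameters()
        params += self.bottleneck.parameters()
        for dlevel in self.dec:
            params += dlevel["gate"].parameters()
            params += dlevel["conv"].parameters()
        return params

    def forward(self, x, train: bool = True):
        skips = []
        for e in self.enc:
            x = e["conv"].forward(x, train)
            x = e["drop"].forward(x, train)
            skips.append(x)
            x = e["pool"].forward(x, train)
        x = self.bottleneck.forward(x, train)
        bottleneck_out = x
        self._skip_channels = [s.shape[1] for s in skips]
        for dlevel, skip in zip(self.dec, reversed(skips)):
            g = dlevel["up"].forward(x, train)
            gated = dlevel["gate"].forward(skip, g, train)
            x = dlevel["conv"].forward(
                np.concatenate([g, gated], axis=1), train)
        if self.readout == "bottleneck":
            return self.gap.forward(bottleneck_out, train)
        return self.gap.forward(x, train)

    def backward(self, dy):
        if self.readout == "bottleneck":
            raise ConfigurationError(
                "backward through the bottleneck read-out is not supported; "
                "use the decoder read-out for training")
        dy = self.gap.backward(dy)
        dskips = []
        for dlevel in reversed(self.dec):
            dcat = dlevel["conv"].backward(dy)
            cg = dcat.shape[1] - dlevel["gate"].theta.cin
            dg_direct = dcat[:, :cg]
            dgated = dcat[:, cg:]
            dskip, dg_gate = dlevel["gate"].backward(dgated)
            dskips.append(dskip)
            dy = dlevel["up"].backward(dg_direct + dg_gate)
        dy = self.bottleneck.backward(dy)
        # dskips were collected shallow-to-deep; encoder unwinds deep-to-shallow
        for e, dskip in zip(reversed(self.enc), reversed(dskips)):
            dy = e["pool"].backward(dy)
            dy = e["drop"].backward(dy + dskip)
            dy = e["conv"].backward(dy)
        return dy


class HybridModel(Layer):
    """Two branches fused by concatenation into the dense head."""

    def __init__(self, cfg: ModelConfig,
                 class_names: Sequence[str] = ("adenocarcinoma",
                                               "neuroendocrine", "squamous")):
        if len(class_names) != cfg.num_classes:
            raise ConfigurationError("class_names length must equal "
                                     "num_classes")
        self.cfg = cfg
        self.class_names = tuple(class_names)
        init_rng = np.random.default_rng(cfg.seed)
        self.drop_rng = np.random.default_rng(cfg.seed + 1)
        self.residual = ResidualBranch(cfg, init_rng, self.drop_rng)
        self.attention = AttentionBranch(cfg, init_rng, self.drop_rng)
        self.fused_len = self.residual.feature_len + self.attention.feature_len
        self.head_dense = Dense(self.fused_len, cfg.head_units, rng=init_rng,
                                l2=cfg.head_l2)
        self.head_relu = ReLU()
        self.head_bn = BatchNorm(cfg.head_units)
        self.head_drop = Dropout(cfg.head_dropout, self.drop_rng)
        self.head_out = Dense(cfg.head_units, cfg.num_classes, rng=init_rng)

    def parameters(self):
        return (self.residual.parameters() + self.attention.parameters()
                + self.head_dense.parameters() + self.head_bn.parameters()
                + self.head_out.parameters())

    def forward(self, x, train: bool = True):
        f1 = self.residual.forward(x, train)
        f2 = self.attention.forward(x, train)
        fused = np.concatenate([f1, f2], axis=1)
        h = self.head_dense.forward(fused, train)
        h = self.head_relu.forward(h, train)
        h = self.head_bn.forward(h, train)
        h = self.head_drop.forward(h, train)
        return self.head_out.forward(h, train)

    def backward(self, dlogits):
        dh = self.head_out.backward(dlogits)
        dh = self.head_drop.backward(dh)
        dh = self.head_bn.backward(dh)
        dh = self.head_relu.backward(dh)
        dfused = self.head_dense.backward(dh)
        d1 = dfused[:, :self.residual.feature_len]
        d2 = dfused[:, self.residual.feature_len:]
        dx1 = self.residual.backward(d1)
        dx2 = self.attention.backward(d2)
        return dx1 + dx2

    def get_weights(self) -> list[np.ndarray]:
        return [p["value"].copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p["value"][...] = w


def build_residual_branch(cfg: ModelConfig) -> ResidualBranch:
    rng = np.random.default_rng(cfg.seed)
    return ResidualBranch(cfg, rng, np.random.default_rng(cfg.seed + 1))


def build_attention_branch(cfg: ModelConfig) -> AttentionBranch:
    rng = np.random.default_rng(cfg.seed)
    return AttentionBranch(cfg, rng, np.random.default_rng(cfg.seed + 1))


def build_hybrid(cfg: ModelConfig, class_names: Sequence[str] = (
        "adenocarcinoma", "neuroendocrine", "squamous")) -> HybridModel:
    return HybridModel(cfg, class_names)


def head_param_count(model: HybridModel) -> int:
    """Trainable parameter count of the fusion head: dense-512 weights
    and bias, batch-norm scale and shift, output weights and bias."""
    return sum(p["value"].size for p in
               (model.head_dense.parameters() + model.head_bn.parameters()
                + model.head_out.parameters()))


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        })


def images_to_input(images: Sequence[np.ndarray]) -> np.ndarray:
    """Stack uint8 grayscale images into a rescaled (N, 1, H, W) batch."""
    arr = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    return arr[:, None, :, :] / 255.0


def _evaluate(model: HybridModel, x: np.ndarray,
              y: np.ndarray, batch: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits = model.forward(x[i:i + batch], train=False)
        loss, _ = softmax_cross_entropy(logits, y[i:i + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_model(model: HybridModel, images: Sequence[np.ndarray],
                labels: Sequence[str], cfg: ModelConfig | None = None,
                augment_cfg=None, val_images: Sequence[np.ndarray] | None = None,
                val_labels: Sequence[str] | None = None,
                restore_best: bool = True) -> TrainingHistory:
    """Seeded mini-batch training with optional on-the-fly augmentation.

    Augmentation (when given) is applied to training images only.
    Validation metrics are computed on ``val_images`` when provided,
    otherwise on the (un-augmented) training set.  The best-validation
    weights are checkpointed and restored at the end.
    """
    from ..augment import augment_image

    cfg = cfg or model.cfg
    if len(images) == 0:
        raise DataError("empty training set")
    if len(images) != len(labels):
        raise DataError("images and labels differ in length")
    index = {c: i for i, c in enumerate(model.class_names)}
    try:
        y = np.array([index[l] for l in labels])
    except KeyError as exc:
        raise DataError(f"unknown label {exc.args[0]!r}") from exc

    images = [np.asarray(im) for im in images]
    if any(im.shape != tuple(cfg.input_size) for im in images):
        raise InputError(f"images must match input_size {cfg.input_size}")
    x_plain = images_to_input(images)
    if val_images is not None:
        yv = np.array([index[l] for l in val_labels])
        xv = images_to_input(val_images)
    else:
        yv = xv = None  # mirror training metrics instead of a second pass

    rng = np.random.default_rng(cfg.seed + 2)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainingHistory()
    best = (-np.inf, None)
    n = len(images)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses, epoch_correct = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            if augment_cfg is not None:
                batch_imgs = [augment_image(images[j], augment_cfg, rng)
                              for j in idx]
                xb = images_to_input(batch_imgs)
            else:
                xb = x_plain[idx]
            yb = y[idx]
            model.zero_grad()
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss * len(idx))
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
        history.train_loss.append(float(np.sum(epoch_losses) / n))
        history.train_accuracy.append(epoch_correct / n)
        if xv is not None:
            vloss, vacc = _evaluate(model, xv, yv, cfg.batch_size)
        else:
            vloss, vacc = history.train_loss[-1], history.train_accuracy[-1]
        history.val_loss.append(vloss)
        history.val_accuracy.append(vacc)
        if vacc > best[0]:
            best = (vacc, model.get_weights())
    if restore_best and best[1] is not None:
        model.set_weights(best[1])
    return history


def predict(model: HybridModel, images: Sequence[np.ndarray],
            batch: int = 32):
    """Class probabilities and argmax labels (lowest index on ties)."""
    images = [np.asarray(im) for im in images]
    if any(im.shape != tuple(model.cfg.input_size) for im in images):
        raise InputError(f"images must match input_size "
                         f"{model.cfg.input_size}")
    x = images_to_input(images)
    probs = []
    for i in range(0, len(x), batch):
        logits = model.forward(x[i:i + batch], train=False)
        probs.append(softmax(logits))
    probs = np.concatenate(probs, axis=0)
    idx = probs.argmax(axis=1)
    return probs, [model.class_names[i] for i in idx]
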