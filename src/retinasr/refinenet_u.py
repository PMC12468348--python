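"""Five-grade retinopathy classifier: a U-Net style encoder/bridge/decoder
whose decoder output is flattened into a dropout/dense/softmax grading head,
plus a deliberately plain CNN baseline.

The encoder halves the spatial side four times (448 -> 224 -> 112 -> 56 ->
28 at the reference input size) while the decoder restores it symmetrically
through transposed convolutions and skip concatenations.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._layers import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Dropout,
                      Linear, Module, maxpool2d)
from ._layers import Dropout as _Dropout
from ._tensor import Tensor, no_grad

__all__ = [
    "UNetConfig", "TrainClfConfig", "ClassifierOutput",
    "RefineNetU", "BaselineCNN", "relu", "leaky_relu", "cross_entropy",
    "predict", "train_classifier", "predict_batch", "build_classifier",
    "baseline_cnn_forward", "classify_head",
]


def relu(x):
    """max(0, x) elementwise (scalar or array)."""
    return np.maximum(x, 0)


def leaky_relu(x, a: float = 0.01):
    """x for x >= 0, a * x otherwise; a must lie in (0, 1)."""
    if not 0.0 < a < 1.0:
        raise ValueError(f"leaky slope must be in (0, 1), got {a}")
    x = np.asarray(x)
    out = np.where(x >= 0, x, a * x)
    return out.item() if out.ndim == 0 else out


@dataclasses.dataclass
class UNetConfig:
    encoder_filters: tuple[int, ...] = (64, 128, 256, 512)
    kernel_size: int = 3
    pool_size: int = 2
    encoder_dropout: float = 0.5
    head_dropout: float = 0.3
    dense_units: tuple[int, int] = (128, 5)
    leaky_slope: float = 0.01
    input_side: int = 448
    head: bool = True           # the dense head is huge at side 448
    batch_norm: bool = True
    dtype: str = "float32"

    @property
    def bridge_filters(self) -> int:
        return self.encoder_filters[-1] * 2

    @property
    def decoder_filters(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_filters))

    def __post_init__(self):
        if self.input_side % 16 != 0:
            raise ValueError(
                f"input side {self.input_side} must be divisible by 16 "
                "(four 2x poolings)")
        if len(self.encoder_filters) != 4:
            raise ValueError("expected four encoder stages")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclasses.dataclass
class TrainClfConfig:
    epochs: int = 3
    batch_size: int = 20
    lr: float = 5e-4
    clip_norm: float | None = 1.0   # tames the very large dense head
    lr_decay: float = 1.0           # step decay factor (1.0 = constant lr) ...
    lr_decay_from: int = 3          # ... applied from this epoch index on
    augment: bool = True            # seeded flips / right-angle rotations
    bn_refresh: bool = True         # refresh BN stats dropout-free at the end
    holdout_per_class: int = 0      # internal val split for best-epoch keep
    ema_decay: float | None = None  # Polyak weight averaging for evaluation
    dropout_free_final: int = 0     # anneal dropout off for the last k epochs
    freeze_bn_after: int | None = None  # freeze BN stats from this epoch on
    head_weight_decay: float = 0.0  # decoupled L2 on the dense head


@dataclasses.dataclass
class ClassifierOutput:
    logits: np.ndarray
    probs: np.ndarray
    predicted: int

    def __post_init__(self):
        if self.probs.shape != (5,):
            raise ValueError("expected 5-class probabilities")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be a simplex vector")


def predict(output) -> int:
    """Most probable class; ties broken toward the lowest class index."""
    probs = output.probs if isinstance(output, ClassifierOutput) else \
        np.asarray(output)
    return int(np.argmax(probs))


def cross_entropy(probs: np.ndarray, labels: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy of simplex rows against one-hot rows."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    labels = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    if probs.shape != labels.shape:
        raise ValueError(f"shape mismatch {probs.shape} vs {labels.shape}")
    onehot = np.isin(labels, (0.0, 1.0)).all() and \
        np.allclose(labels.sum(axis=1), 1.0)
    if not onehot:
        raise ValueError("labels must be one-hot rows")
    return float(-(labels * np.log(np.maximum(probs, eps))).sum(axis=1).mean())


class _ConvBNRelu(Module):
    def __init__(self, c_in, c_out, k, rng, batch_norm, dtype):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, rng, padding=k // 2, dtype=dtype)
        self.bn = BatchNorm2d(c_out, dtype=dtype) if batch_norm else None

    def forward(self, x):
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return x.relu()


class RefineNetU(Module):
    def __init__(self, config: UNetConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config = config or UNetConfig()
        rng = np.random.default_rng(seed)
        dt = config.np_dtype
        k, bn = config.kernel_size, config.batch_norm
        filters = config.encoder_filters

        self.enc = []
        c_prev = 1
        for f in filters:
            self.enc.append([_ConvBNRelu(c_prev, f, k, rng, bn, dt),
                             _ConvBNRelu(f, f, k, rng, bn, dt)])
            c_prev = f
        self.enc_dropout = Dropout(config.encoder_dropout, spatial=True)

        fb = config.bridge_filters
        self.bridge1 = _ConvBNRelu(c_prev, fb, k, rng, bn, dt)
        self.bridge2 = _ConvBNRelu(fb, fb, k, rng, bn, dt)

        self.dec = []
        c_prev = fb
        for f in config.decoder_filters:
            up = ConvTranspose2d(c_prev, f, 2, rng, stride=2, dtype=dt)
            self.dec.append([up, _ConvBNRelu(2 * f, f, k, rng, bn, dt),
                             _ConvBNRelu(f, f, k, rng, bn, dt)])
            c_prev = f

        if config.head:
            flat = filters[0] * config.input_side ** 2
            self.head_dropout = Dropout(config.head_dropout)
            self.dense1 = Linear(flat, config.dense_units[0], rng, dtype=dt)
            self.dense2 = Linear(config.dense_units[0], config.dense_units[1],
                                 rng, dtype=dt)

    # -- stages --------------------------------------------------------------
    def encoder_forward(self, x: Tensor, rng=None):
        """Returns (pooled bottleneck input, [pre-pool skip maps])."""
        side = x.data.shape[2]
        if side % 16 != 0:
            raise ValueError(f"input side {side} not divisible by 16")
        skips = []
        for block in self.enc:
            for layer in block:
                x = layer(x)
            skips.append(x)
            x = maxpool2d(x, self.config.pool_size)
        x = self.enc_dropout(x, rng)
        return x, skips

    def bridge_forward(self, x: Tensor) -> Tensor:
        return self.bridge2(self.bridge1(x))

    def decoder_forward(self, x: Tensor, skips) -> Tensor:
        for (up, conv1, conv2), skip in zip(self.dec, reversed(skips)):
            x = up(x)
            if x.data.shape[2:] != skip.data.shape[2:]:
                raise ValueError(
                    f"skip shape {skip.data.shape} does not match upsampled "
                    f"{x.data.shape}")
            x = conv2(conv1(Tensor.concat([x, skip], axis=1)))
        return x

    def head_forward(self, x: Tensor, rng=None) -> Tensor:
        B = x.data.shape[0]
        flat = x.reshape(B, -1)
        flat = self.head_dropout(flat, rng)
        hidden = self.dense1(flat).leaky_relu(self.config.leaky_slope)
        return self.dense2(hidden)   # logits; softmax applied by callers

    def forward(self, x: Tensor, rng=None) -> Tensor:
        pooled, skips = self.encoder_forward(x, rng)
        b = self.bridge_forward(pooled)
        d = self.decoder_forward(b, skips)
        return self.head_forward(d, rng)


class BaselineCNN(Module):
    """Plain conv/BN/ReLU/pool stack (16/32/64 filters) with a small dense
    head; the deliberately loose reference classifier."""

    def __init__(self, input_side: int = 448, seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        if input_side % 8 != 0:
            raise ValueError(f"input side {input_side} must be divisible by 8")
        self.input_side = input_side
        rng = np.random.default_rng(seed)
        self.stages = []
        c_prev = 1
        for f in (16, 32, 64):
            self.stages.append(_ConvBNRelu(c_prev, f, 3, rng, True, dtype))
            c_prev = f
        flat = 64 * (input_side // 8) ** 2
        self.dense1 = Linear(flat, 64, rng, dtype=dtype)
        self.dense2 = Linear(64, 5, rng, dtype=dtype)

    def forward(self, x: Tensor, rng=None) -> Tensor:
        for stage in self.stages:
            x = maxpool2d(stage(x), 2)
        B = x.data.shape[0]
        hidden = self.dense1(x.reshape(B, -1)).relu()
        return self.dense2(hidden)


def build_classifier(name: str, input_side: int,
                     filters=(64, 128, 256, 512), seed: int = 0) -> Module:
    if name == "refinenet_u":
        return RefineNetU(UNetConfig(encoder_filters=tuple(filters),
                                     input_side=input_side), seed=seed)
    if name == "cnn":
        return BaselineCNN(input_side=input_side, seed=seed)
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def classify_head(decoder_out: np.ndarray, model: RefineNetU,
                  training: bool = False, seed: int | None = None
                  ) -> ClassifierOutput:
    """Flatten -> dropout -> dense/LeakyReLU -> dense -> softmax for one map."""
    rng = np.random.default_rng(seed) if training else None
    model.train(training)
    with no_grad():
        logits = model.head_forward(Tensor(np.asarray(decoder_out)[None]
                                           .astype(model.dense1.weight.dtype)),
                                    rng)
        probs = logits.softmax(axis=-1)
    model.eval()
    lg = logits.data[0].astype(np.float64)
    pr = probs.data[0].astype(np.float64)
    pr = pr / pr.sum()
    return ClassifierOutput(logits=lg, probs=pr, predicted=int(np.argmax(pr)))


def baseline_cnn_forward(image, model: BaselineCNN) -> ClassifierOutput:
    """Grade one normalized (H, W) raster with the baseline CNN."""
    arr = np.asarray(image.pixels if hasattr(image, "pixels") else image)
    model.eval()
    with no_grad():
        logits = model(Tensor(arr[None, None]
                              .astype(model.dense1.weight.dtype)))
        probs = logits.softmax(axis=-1)
    lg = logits.data[0].astype(np.float64)
    pr = probs.data[0].astype(np.float64)
    pr = pr / pr.sum()
    return ClassifierOutput(logits=lg, probs=pr, predicted=int(np.argmax(pr)))


def predict_batch(model: Module, images, batch_size: int = 25) -> np.ndarray:
    """Class probabilities (N, 5) for a list of (H, W) arrays, eval mode."""
    dtype = model.parameters()[0].data.dtype
    model.eval()
    out = []
    for start in range(0, len(images), batch_size):
        chunk = np.stack([np.asarray(im, dtype=dtype)
                          for im in images[start:start + batch_size]])[:, None]
        with no_grad():
            logits = model(Tensor(chunk))
            out.append(logits.softmax(axis=-1).data)
    return np.concatenate(out).astype(np.float64)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def save_clf_checkpoint(model: Module, path) -> None:
    import json
    import pathlib
    path = pathlib.Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    if isinstance(model, RefineNetU):
        meta = {"model": "refinenet_u",
                "input_side": model.config.input_side,
                "encoder_filters": list(model.config.encoder_filters)}
    else:
        meta = {"model": "cnn", "input_side": model.input_side}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_clf_checkpoint(path) -> Module:
    import json
    import pathlib
    path = pathlib.Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["model"] == "refinenet_u":
        model = RefineNetU(UNetConfig(
            encoder_filters=tuple(meta["encoder_filters"]),
            input_side=meta["input_side"]))
    else:
        model = BaselineCNN(input_side=meta["input_side"])
    model.load_state_dict(dict(np.load(path.with_suffix(".npz"))))
    model.eval()
    return model


def train_classifier(model: Module, dataset, config: TrainClfConfig,
                     seed: int, eval_set=None):
    """Minimize categorical cross-entropy with Adam.

    ``dataset`` is a list of ((H, W) array, grade) pairs.  Returns a history
    dict with per-epoch train loss/accuracy (and eval accuracy when an
    ``eval_set`` is supplied).  Deterministic under seed.
    """
    labels = np.array([g for _, g in dataset], dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset must contain at least 2 classes")
    dtype = model.parameters()[0].data.dtype
    images = [np.asarray(im, dtype=dtype) for im, _ in dataset]
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    if config.holdout_per_class > 0:
        for cls in np.unique(labels):
            members = np.flatnonzero(labels == cls)
            val_idx.extend(rng.permutation(members)[:config.holdout_per_class])
    val_set = set(val_idx)
    train_idx = [i for i in range(len(images)) if i not in val_set]
    opt = Adam(model.parameters(), lr=config.lr, clip_norm=config.clip_norm)
    named = list(model.named_parameters())
    ema = ({name: p.data.copy() for name, p in named}
           if config.ema_decay else None)
    history = {"loss": [], "accuracy": [], "eval_accuracy": [],
               "val_accuracy": []}
    best = (-1.0, None)

    def _with_ema(fn):
        if ema is None:
            return fn()
        saved = {name: p.data for name, p in named}
        for name, p in named:
            p.data = ema[name].copy()
        try:
            return fn()
        finally:
            for name, p in named:
                p.data = saved[name]
    drop_modules = [m for m in model.modules() if isinstance(m, _Dropout)]
    drop_rates = [m.p for m in drop_modules]
    for _epoch in range(config.epochs):
        if _epoch >= config.lr_decay_from:
            opt.lr = config.lr * config.lr_decay ** (
                _epoch - config.lr_decay_from + 1)
        if config.dropout_free_final and \
                _epoch >= config.epochs - config.dropout_free_final:
            for m in drop_modules:
                m.p = 0.0
        if config.freeze_bn_after is not None and \
                _epoch == config.freeze_bn_after:
            _refresh_bn_stats(model, [images[i] for i in train_idx],
                              config.batch_size)
            for m in model.modules():
                if isinstance(m, BatchNorm2d):
                    m.freeze_stats = True
        model.train(True)
        order = np.asarray(train_idx)[rng.permutation(len(train_idx))]
        losses, hits, total = [], 0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [images[i] for i in idx]
            if config.augment:
                batch = [np.ascontiguousarray(_augment(im, rng))
                         for im in batch]
            x = Tensor(np.stack(batch)[:, None])
            y = labels[idx]
            onehot = np.zeros((len(idx), 5), dtype=dtype)
            onehot[np.arange(len(idx)), y] = 1.0
            logits = model(x, rng)
            logp = logits.log_softmax(axis=-1)
            loss = -(logp * Tensor(onehot)).sum() * (1.0 / len(idx))
            val = float(loss.data)
            if not np.isfinite(val):
                raise RuntimeError(f"NaN/Inf loss at epoch {_epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            if config.head_weight_decay and hasattr(model, "dense1"):
                f = 1.0 - opt.lr * config.head_weight_decay
                model.dense1.weight.data *= f
                model.dense2.weight.data *= f
            if ema is not None:
                d = config.ema_decay
                for name, p in named:
                    ema[name] *= d
                    ema[name] += (1 - d) * p.data
            losses.append(val)
            hits += int((logits.data.argmax(axis=1) == y).sum())
            total += len(idx)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(hits / total)
        if val_idx:
            def _val():
                if config.bn_refresh and not _bn_frozen(model):
                    _refresh_bn_stats(model, [images[i] for i in train_idx],
                                      config.batch_size)
                vp = predict_batch(model, [images[i] for i in val_idx])
                return (float((vp.argmax(axis=1) == labels[val_idx]).mean()),
                        model.state_dict())
            vacc, state = _with_ema(_val)
            history["val_accuracy"].append(vacc)
            if vacc > best[0]:
                best = (vacc, state)
        if eval_set is not None:
            if config.bn_refresh:
                _refresh_bn_stats(model, images, config.batch_size)
                model.train(True)
            probs = predict_batch(model, [im for im, _ in eval_set])
            acc = float((probs.argmax(axis=1) ==
                         np.array([g for _, g in eval_set])).mean())
            history["eval_accuracy"].append(acc)
    for m, rate in zip(drop_modules, drop_rates):
        m.p = rate
    if best[1] is not None:
        model.load_state_dict(best[1])
    elif ema is not None:
        for name, p in named:
            p.data = ema[name]
    if config.bn_refresh and not _bn_frozen(model):
        _refresh_bn_stats(model, images, config.batch_size)
    model.eval()
    return history


def _bn_frozen(model: Module) -> bool:
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    return bool(bns) and all(m.freeze_stats for m in bns)


def _augment(im: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # soft augmentation: half the samples stay in the canonical orientation
    if rng.random() < 0.5:
        return im
    k = int(rng.integers(0, 4))
    if k:
        im = np.rot90(im, k)
    if rng.random() < 0.5:
        im = im[:, ::-1]
    return im


def _refresh_bn_stats(model: Module, images, batch_size: int) -> None:
    """One dropout-free pass in training mode so BatchNorm running stats
    reflect the inference-time activation distribution."""
    from ._layers import Dropout
    drops = [m for m in model.modules() if isinstance(m, Dropout)]
    saved = [d.p for d in drops]
    for d in drops:
        d.p = 0.0
    model.train(True)
    with no_grad():
        for start in range(0, len(images), batch_size):
            chunk = np.stack(images[start:start + batch_size])[:, None]
            model(Tensor(chunk))
    for d, p in zip(drops, saved):
        d.p = p
    model.eval()
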