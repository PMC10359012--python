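"""Fire-module convolutional classifier in pure NumPy.

The classifier follows the SqueezeNet v1.1 design: a stem convolution,
a stack of *fire modules* (a 1x1 "squeeze" convolution feeding parallel
1x1 and 3x3 "expand" convolutions whose outputs are concatenated), a
final 1x1 class convolution, global average pooling and softmax. Two
variants are provided:

* ``v1.1`` — the full eight-fire layout (227-px input),
* ``tiny`` — a two-fire, halved-width layout on 64-px inputs used for
  desk-scale experiments and the test suite.

Training is plain mini-batch stochastic gradient descent with momentum
on the cross-entropy loss, fully seeded and single-threaded, so a seed
reproduces the final weights bit-for-bit. Backward passes are written
alongside each layer; their correctness is checked against central
finite differences in the test suite, and the same machinery supplies
the class-score gradients that Grad-CAM needs.

Data layout is NCHW float32 (float64 available for gradient checks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mousemime.errors import ConstructionError, LayerLookupError, TrainingError

# --------------------------------------------------------------------- layers


class Layer:
    """Base layer: forward caches what backward needs; params/grads are
    parallel dicts of arrays."""

    name: str = ""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution via explicit kernel-offset accumulation."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        if k not in (1, 3):
            raise ConstructionError(f"unsupported kernel size {k}")
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k))
        self.params = {"W": w.astype(dtype), "b": np.zeros(cout, dtype=dtype)}
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}

    def _cols(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        n, c = xp.shape[:2]
        k, st = self.k, self.stride
        cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i:i + st * oh:st, j:j + st * ow:st]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ConstructionError(
                f"conv expects {self.cin} channels, got {c}")
        p, k, st = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // st + 1
        ow = (w + 2 * p - k) // st + 1
        cols = self._cols(xp, oh, ow)
        self._cache = (x.shape, xp.shape, cols, oh, ow)
        W = self.params["W"].reshape(self.cout, -1)
        # (cout, CKK) @ (n, CKK, OHW) broadcasts to (n, cout, OHW)
        out = (W @ cols.reshape(n, self.cin * k * k, oh * ow)) \
            .reshape(n, self.cout, oh, ow)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, cols, oh, ow = self._cache
        n = dout.shape[0]
        k, st, p = self.k, self.stride, self.pad
        d2 = dout.transpose(1, 0, 2, 3).reshape(self.cout, -1)
        colmat = cols.reshape(n, self.cin * k * k, oh * ow) \
                     .transpose(1, 0, 2).reshape(self.cin * k * k, -1)
        self.grads["W"][:] = (d2 @ colmat.T).reshape(self.params["W"].shape)
        self.grads["b"][:] = dout.sum(axis=(0, 2, 3))
        W = self.params["W"].reshape(self.cout, -1)
        dcols = (W.T @ d2).reshape(self.cin, k, k, n, oh, ow) \
                          .transpose(3, 0, 1, 2, 4, 5)
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + st * oh:st, j:j + st * ow:st] += dcols[:, :, i, j]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2, stride-2 max pooling (floor mode: odd trailing row/col dropped)."""

    def forward(self, x):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, :, :2 * ho, :2 * wo]
        xr = xc.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5) \
               .reshape(n, c, ho, wo, 4)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._in_shape
        ho, wo = h // 2, w // 2
        flat = np.zeros((n, c, ho, wo, 4), dtype=dout.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, :2 * ho, :2 * wo] = flat.reshape(n, c, ho, wo, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * ho, 2 * wo)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W).

    Used by the from-scratch ``tiny`` variant to make the 110-iteration
    SGD budget sufficient; the ``v1.1`` layout stays norm-free like the
    original architecture. ``training`` toggles batch statistics vs
    running averages.
    """

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.params = {"gamma": np.ones(channels, dtype=dtype),
                       "beta": np.zeros(channels, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.training = True
        self.stats_buffer: list | None = None

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
            if self.stats_buffer is not None:
                self.stats_buffer.append((mean, var, x.shape[0]))
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, x.shape)
        g = self.params["gamma"][None, :, None, None]
        return g * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dout):
        xhat, std, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.grads["gamma"][:] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][:] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        if not self.training:
            return dxhat / std[None, :, None, None]
        sum_d = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dx = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (dxhat - sum_d / n_eff - xhat * sum_dx / n_eff) \
            / std[None, :, None, None]


class Fire(Layer):
    """Fire module: 1x1 squeeze -> ReLU -> parallel 1x1/3x3 expands ->
    ReLU -> channel concatenation."""

    def __init__(self, cin: int, squeeze: int, expand1: int, expand3: int,
                 rng=None, dtype=np.float32, use_bn: bool = False):
        super().__init__()
        if squeeze >= expand1 + expand3:
            raise ConstructionError(
                "fire module needs squeeze < total expand channels")
        if expand1 != expand3:
            raise ConstructionError(
                "expand channels must split evenly into 1x1 and 3x3 branches")
        rng = rng or np.random.default_rng(0)
        self.squeeze = Conv2d(cin, squeeze, 1, rng=rng, dtype=dtype)
        self.expand1 = Conv2d(squeeze, expand1, 1, rng=rng, dtype=dtype)
        self.expand3 = Conv2d(squeeze, expand3, 3, pad=1, rng=rng, dtype=dtype)
        self.relu_s, self.relu_e = ReLU(), ReLU()
        self.bn_s = BatchNorm(squeeze, dtype=dtype) if use_bn else None
        self.bn_e = BatchNorm(expand1 + expand3, dtype=dtype) if use_bn else None
        self.cout = expand1 + expand3
        self._subs = {"squeeze": self.squeeze, "expand1": self.expand1,
                      "expand3": self.expand3}
        if use_bn:
            self._subs["bn_s"] = self.bn_s
            self._subs["bn_e"] = self.bn_e
        for sub, layer in self._subs.items():
            for pname, arr in layer.params.items():
                self.params[f"{sub}.{pname}"] = arr
                self.grads[f"{sub}.{pname}"] = layer.grads[pname]

    def forward(self, x):
        s = self.squeeze.forward(x)
        if self.bn_s is not None:
            s = self.bn_s.forward(s)
        s = self.relu_s.forward(s)
        e1 = self.expand1.forward(s)
        e3 = self.expand3.forward(s)
        self._n1 = e1.shape[1]
        e = np.concatenate([e1, e3], axis=1)
        if self.bn_e is not None:
            e = self.bn_e.forward(e)
        return self.relu_e.forward(e)

    def backward(self, dout):
        d = self.relu_e.backward(dout)
        if self.bn_e is not None:
            d = self.bn_e.backward(d)
        d1, d3 = d[:, :self._n1], d[:, self._n1:]
        ds = self.expand1.backward(d1) + self.expand3.backward(d3)
        ds = self.relu_s.backward(ds)
        if self.bn_s is not None:
            ds = self.bn_s.backward(ds)
        return self.squeeze.backward(ds)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._in_shape).astype(dout.dtype)


# ---------------------------------------------------------------------- model


@dataclass
class ModelSpec:
    """Architecture description.

    ``fire_blocks`` lists (squeeze, expand1, expand3) widths; ``plan``
    interleaves stem/pool/fire/head stages in order.
    """

    variant: str = "tiny"
    in_side: int = 64
    n_classes: int = 3
    stem_channels: int = 24
    fire_blocks: tuple = ((12, 24, 24), (24, 48, 48))
    pools_after: tuple = (0, 1)  # insert a pool after stem (0) / fire i+1
    use_bn: bool = True  # tiny trains from scratch; v1.1 is norm-free

    @staticmethod
    def tiny() -> "ModelSpec":
        return ModelSpec()

    @staticmethod
    def v11(in_side: int = 227, n_classes: int = 3) -> "ModelSpec":
        return ModelSpec(
            variant="v1.1", in_side=in_side, n_classes=n_classes,
            stem_channels=64,
            fire_blocks=((16, 64, 64), (16, 64, 64),
                         (32, 128, 128), (32, 128, 128),
                         (48, 192, 192), (48, 192, 192),
                         (64, 256, 256), (64, 256, 256)),
            pools_after=(0, 2, 4), use_bn=False)


class Softmax:
    @staticmethod
    def probs(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


class Model:
    """Sequential fire-module classifier with named layers."""

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float32):
        if spec.n_classes < 2:
            raise ConstructionError("need >= 2 classes")
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        layers: list[tuple[str, Layer]] = []
        layers.append(("conv1", Conv2d(3, spec.stem_channels, 3, stride=2,
                                       pad=1, rng=rng, dtype=dtype)))
        if spec.use_bn:
            layers.append(("bn1", BatchNorm(spec.stem_channels, dtype=dtype)))
        layers.append(("relu1", ReLU()))
        cin = spec.stem_channels
        if 0 in spec.pools_after:
            layers.append(("pool1", MaxPool2x2()))
        for i, (s, e1, e3) in enumerate(spec.fire_blocks, start=2):
            layers.append((f"fire{i}", Fire(cin, s, e1, e3, rng=rng,
                                            dtype=dtype,
                                            use_bn=spec.use_bn)))
            cin = e1 + e3
            if (i - 1) in spec.pools_after:
                layers.append((f"pool{i}", MaxPool2x2()))
        layers.append(("conv_class", Conv2d(cin, spec.n_classes, 1, rng=rng,
                                            dtype=dtype)))
        layers.append(("gap", GlobalAvgPool()))
        self.layers = layers
        for name, layer in layers:
            layer.name = name

    # -- forward / backward

    def forward(self, x: np.ndarray, capture: str | None = None):
        """Logits for a NCHW batch; optionally also return the named
        layer's output activation."""
        a = x.astype(self.dtype, copy=False)
        captured = None
        for name, layer in self.layers:
            a = layer.forward(a)
            if name == capture:
                captured = a
        return (a, captured) if capture else a

    def forward_from(self, start_after: str, activation: np.ndarray) -> np.ndarray:
        """Re-run the tail of the network from a replacement activation
        of the named layer (used by the finite-difference saliency
        oracle)."""
        names = [n for n, _ in self.layers]
        if start_after not in names:
            raise LayerLookupError(f"no layer named {start_after!r}")
        i = names.index(start_after)
        a = activation.astype(self.dtype, copy=False)
        for _, layer in self.layers[i + 1:]:
            a = layer.forward(a)
        return a

    def backward(self, dlogits: np.ndarray,
                 stop_at: str | None = None) -> np.ndarray:
        """Backpropagate; returns the gradient w.r.t. the input, or —
        when ``stop_at`` names a layer — w.r.t. that layer's output."""
        if stop_at is not None and stop_at not in self.layer_names():
            raise LayerLookupError(f"no layer named {stop_at!r}")
        d = dlogits.astype(self.dtype, copy=False)
        for name, layer in reversed(self.layers):
            if name == stop_at:
                return d
            d = layer.backward(d)
        return d

    def layer_names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def last_feature_layer(self) -> str:
        """Default Grad-CAM target: the last convolutional feature layer
        before the class convolution / global pooling."""
        names = self.layer_names()
        feats = [n for n in names if n.startswith(("fire", "conv"))
                 and n != "conv_class"]
        return feats[-1]

    def parameters(self):
        for _, layer in self.layers:
            for pname in layer.params:
                yield layer.name, pname, layer.params[pname], layer.grads[pname]

    def _batchnorms(self):
        for name, layer in self.layers:
            if isinstance(layer, BatchNorm):
                yield name, layer
            elif isinstance(layer, Fire) and layer.bn_s is not None:
                yield f"{name}.bn_s", layer.bn_s
                yield f"{name}.bn_e", layer.bn_e

    def set_training(self, mode: bool) -> None:
        """Switch batch-normalization between batch statistics (train)
        and running averages (inference)."""
        for _, bn in self._batchnorms():
            bn.training = mode

    # -- inference

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        self.set_training(False)
        probs = []
        for i in range(0, len(x), batch):
            logits = self.forward(x[i:i + batch])
            probs.append(Softmax.probs(logits))
        return np.concatenate(probs, axis=0)

    # -- serialization (portable text-free tensor archive: npz + manifest)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"{lname}/{pname}": arr
                  for lname, pname, arr, _ in self.parameters()}
        for bname, bn in self._batchnorms():
            arrays[f"{bname}/running_mean"] = bn.running_mean
            arrays[f"{bname}/running_var"] = bn.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        manifest = {k: list(v.shape) for k, v in arrays.items()}
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"variant": self.spec.variant,
                       "layers": manifest}, fh, indent=1)

    def load(self, path: str | Path) -> None:
        data = np.load(Path(path).with_suffix(".npz"))
        for lname, pname, arr, _ in self.parameters():
            arr[:] = data[f"{lname}/{pname}"]
        for bname, bn in self._batchnorms():
            bn.running_mean[:] = data[f"{bname}/running_mean"]
            bn.running_var[:] = data[f"{bname}/running_var"]


def build_model(spec: ModelSpec | None = None, seed: int = 0,
                dtype=np.float32) -> Model:
    """Construct a seeded, deterministically initialized classifier."""
    return Model(spec or ModelSpec.tiny(), seed=seed, dtype=dtype)


# ------------------------------------------------------------------- training


@dataclass
class TrainConfig:
    """Training protocol. Defaults follow the reference protocol
    (SGD with momentum, batch 512, cross-entropy, lr 3e-4, 110
    iterations, validation every 10); the lr default suits fine-tuning
    from pretrained weights — from-scratch desk runs use
    :func:`tiny_train_config`."""

    batch_size: int = 512
    learning_rate: float = 3e-4
    momentum: float = 0.9
    iterations: int = 110
    val_period: int = 10
    seed: int = 0
    weights_file: str | None = None  # optional pretrained init

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ConstructionError("learning rate must be >= 0")
        if self.iterations < 1 or self.batch_size < 1:
            raise ConstructionError("iterations and batch size must be >= 1")


def tiny_train_config(seed: int = 0) -> TrainConfig:
    """Desk-scale protocol: a large stable mini-batch and a from-scratch
    learning rate, same 110-iteration SGD-with-momentum budget."""
    return TrainConfig(batch_size=256, learning_rate=0.3, seed=seed)


@dataclass
class TrainingHistory:
    """Per-iteration training metrics plus periodic validation."""

    iterations: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_iterations: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"iteration": self.iterations,
                             "train_loss": self.train_loss,
                             "train_acc": self.train_acc})


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = len(y)
    p = Softmax.probs(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


def evaluate_loss(model: Model, x: np.ndarray, y: np.ndarray,
                  batch: int = 256) -> tuple[float, float]:
    model.set_training(False)
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits = model.forward(x[i:i + batch])
        loss, _ = cross_entropy(logits, y[i:i + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(model: Model, train_x: np.ndarray, train_y: np.ndarray,
          val_x: np.ndarray | None = None, val_y: np.ndarray | None = None,
          cfg: TrainConfig | None = None,
          augment_fn=None) -> TrainingHistory:
    """Mini-batch SGD with momentum on cross-entropy.

    ``augment_fn(batch_images_uint8_nhwc, rng) -> nhwc`` is applied to
    each training mini-batch only (online augmentation). Batches are
    drawn by epoch-wise reshuffling; the batch size shrinks to the
    training-set size when larger. Raises :class:`TrainingError` with
    the iteration index if the loss becomes non-finite.
    """
    cfg = cfg or TrainConfig()
    if cfg.weights_file:
        model.load(cfg.weights_file)
    rng = np.random.default_rng(cfg.seed)
    n = len(train_x)
    bs = min(cfg.batch_size, n)
    history = TrainingHistory()
    velocity = {(l, p): np.zeros_like(arr)
                for l, p, arr, _ in model.parameters()}
    order = rng.permutation(n)
    cursor = 0
    for it in range(1, cfg.iterations + 1):
        if cursor + bs > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor:cursor + bs]
        cursor += bs
        xb, yb = train_x[idx], train_y[idx]
        if augment_fn is not None:
            xb = augment_fn(xb, rng)
        model.set_training(True)
        logits = model.forward(xb)
        loss, dlogits = cross_entropy(logits, yb)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at iteration {it}", it)
        acc = float((logits.argmax(axis=1) == yb).mean())
        model.backward(dlogits)
        if cfg.learning_rate > 0:
            for key, (_, _, arr, grad) in zip(velocity,
                                              model.parameters()):
                v = velocity[key]
                v *= cfg.momentum
                v -= cfg.learning_rate * grad
                arr += v
        history.iterations.append(it)
        history.train_loss.append(loss)
        history.train_acc.append(acc)
        if val_x is not None and (it % cfg.val_period == 0
                                  or it == cfg.iterations):
            vloss, vacc = evaluate_loss(model, val_x, val_y)
            history.val_iterations.append(it)
            history.val_loss.append(vloss)
            history.val_acc.append(vacc)
    model.set_training(False)
    return history


def recalibrate_batchnorm(model: Model, x: np.ndarray,
                          batch: int = 256) -> None:
    """Replace BN running statistics with exact activation moments over
    a reference set (normally the un-augmented training images).

    The exponential running averages collected during a short training
    run lag behind the final weights; recomputing them removes that lag
    before inference.
    """
    bns = [bn for _, bn in model._batchnorms()]
    if not bns:
        return
    for bn in bns:
        bn.training = True
        bn.stats_buffer = []
    for i in range(0, len(x), batch):
        model.forward(x[i:i + batch])
    for bn in bns:
        total = sum(n for _, _, n in bn.stats_buffer)
        mean = sum(m * n for m, _, n in bn.stats_buffer) / total
        second = sum((v + m**2) * n for m, v, n in bn.stats_buffer) / total
        bn.running_mean = mean.astype(bn.running_mean.dtype)
        bn.running_var = np.maximum(second - mean**2, 0).astype(
            bn.running_var.dtype)
        bn.stats_buffer = None
        bn.training = False


def images_to_batch(images, dtype=np.float32) -> np.ndarray:
    """uint8 NHWC (or list of HWC) -> normalized float NCHW in [-0.5, 0.5]."""
    arr = np.stack([im.image if hasattr(im, "image") else im for im in images]) \
        if not isinstance(images, np.ndarray) else images
    x = arr.astype(dtype) / 255.0 - 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))
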