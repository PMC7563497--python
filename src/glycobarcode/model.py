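"""Barcode CNN: architecture specification, builder, and sklearn-style classifier.

Two architectures ship:

* ``table1`` — the classical 25-layer AlexNet stack (227x227x3 input,
  five convolutions with grouped variants, cross-channel normalization,
  overlapping max pooling, two 4096-unit fully connected layers with 50%
  dropout) ending in an ``n_classes`` softmax. In ``transfer`` mode the
  early layers are loaded from user-supplied pretrained weights and frozen;
  only the final fully connected / softmax / classification stage is trained.
* ``reduced`` — a desk-scale twin (64x64x3 input, two conv blocks, one
  64-unit fully connected layer) exposing the identical training and
  prediction interface, used wherever full-scale training would be wasteful.

Training follows the study configuration: batch size 5, 30 epochs, initial
learning rate 1e-4, optimizer SGD-with-momentum (0.9) or Adam. Inputs are
zero-centered with per-channel means computed on the training split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn

ARCHS = ("table1", "reduced")
MODES = ("fresh", "transfer")


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor: name, kind and its geometry parameters."""

    name: str
    kind: str
    params: dict = field(default_factory=dict)


@dataclass
class NetworkSpec:
    """Ordered layer stack plus mode and the set of frozen layer names."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int]  # (H, W, C)
    mode: str = "fresh"
    frozen: frozenset = frozenset()
    arch: str = "table1"

    def shape_trace(self) -> list[tuple]:
        """Output shape (C, H, W) or (units,) after each layer."""
        h, w, c = self.input_shape
        shape: tuple = (c, h, w)
        trace = []
        for layer in self.layers:
            p = layer.params
            if layer.kind == "conv":
                cc, hh, ww = shape
                oh = (hh + 2 * p["pad"] - p["kernel"]) // p["stride"] + 1
                ow = (ww + 2 * p["pad"] - p["kernel"]) // p["stride"] + 1
                shape = (p["filters"], oh, ow)
            elif layer.kind == "pool":
                cc, hh, ww = shape
                oh = (hh - p["kernel"]) // p["stride"] + 1
                ow = (ww - p["kernel"]) // p["stride"] + 1
                shape = (cc, oh, ow)
            elif layer.kind == "fc":
                shape = (p["units"],)
            # input/relu/norm/dropout/softmax/output keep their shape
            trace.append(shape)
        return trace

    def layer_param_count(self, name: str) -> int:
        """Weight + bias count of a conv or fc layer, from geometry alone."""
        shapes = dict(zip([l.name for l in self.layers], self.shape_trace()))
        names = [l.name for l in self.layers]
        for i, layer in enumerate(self.layers):
            if layer.name != name:
                continue
            p = layer.params
            prev = shapes[names[i - 1]]
            if layer.kind == "conv":
                cin = prev[0] // p.get("groups", 1)
                return p["filters"] * (p["kernel"] ** 2 * cin) + p["filters"]
            if layer.kind == "fc":
                fan_in = int(np.prod(prev))
                return fan_in * p["units"] + p["units"]
            return 0
        raise KeyError(name)

    def trainable_layers(self) -> list[str]:
        return [
            l.name
            for l in self.layers
            if l.kind in ("conv", "fc") and l.name not in self.frozen
        ]


def _table1_layers(n_classes: int) -> tuple[LayerSpec, ...]:
    return (
        LayerSpec("data", "input", {"shape": (227, 227, 3), "normalization": "zerocenter"}),
        LayerSpec("conv1", "conv", {"filters": 96, "kernel": 11, "stride": 4, "pad": 0, "groups": 1}),
        LayerSpec("relu1", "relu"),
        LayerSpec("norm1", "norm", {"window": 5}),
        LayerSpec("pool1", "pool", {"kernel": 3, "stride": 2}),
        LayerSpec("conv2", "conv", {"filters": 256, "kernel": 5, "stride": 1, "pad": 2, "groups": 2}),
        LayerSpec("relu2", "relu"),
        LayerSpec("norm2", "norm", {"window": 5}),
        LayerSpec("pool2", "pool", {"kernel": 3, "stride": 2}),
        LayerSpec("conv3", "conv", {"filters": 384, "kernel": 3, "stride": 1, "pad": 1, "groups": 1}),
        LayerSpec("relu3", "relu"),
        LayerSpec("conv4", "conv", {"filters": 384, "kernel": 3, "stride": 1, "pad": 1, "groups": 2}),
        LayerSpec("relu4", "relu"),
        LayerSpec("conv5", "conv", {"filters": 256, "kernel": 3, "stride": 1, "pad": 1, "groups": 2}),
        LayerSpec("relu5", "relu"),
        LayerSpec("pool5", "pool", {"kernel": 3, "stride": 2}),
        LayerSpec("fc6", "fc", {"units": 4096}),
        LayerSpec("relu6", "relu"),
        LayerSpec("drop6", "dropout", {"p": 0.5}),
        LayerSpec("fc7", "fc", {"units": 4096}),
        LayerSpec("relu7", "relu"),
        LayerSpec("drop7", "dropout", {"p": 0.5}),
        LayerSpec("fc8", "fc", {"units": n_classes}),
        LayerSpec("prob", "softmax"),
        LayerSpec("output", "classification"),
    )


def _reduced_layers(n_classes: int) -> tuple[LayerSpec, ...]:
    return (
        LayerSpec("data", "input", {"shape": (64, 64, 3), "normalization": "zerocenter"}),
        LayerSpec("conv1", "conv", {"filters": 8, "kernel": 5, "stride": 2, "pad": 0, "groups": 1}),
        LayerSpec("relu1", "relu"),
        LayerSpec("pool1", "pool", {"kernel": 3, "stride": 2}),
        LayerSpec("conv2", "conv", {"filters": 16, "kernel": 3, "stride": 1, "pad": 1, "groups": 1}),
        LayerSpec("relu2", "relu"),
        LayerSpec("pool2", "pool", {"kernel": 3, "stride": 2}),
        LayerSpec("fc1", "fc", {"units": 64}),
        LayerSpec("relu3", "relu"),
        LayerSpec("drop1", "dropout", {"p": 0.5}),
        LayerSpec("fc2", "fc", {"units": n_classes}),
        LayerSpec("prob", "softmax"),
        LayerSpec("output", "classification"),
    )


def build_network(
    mode: str = "fresh",
    n_classes: int = 2,
    arch: str = "table1",
    pretrained_weights: dict[str, np.ndarray] | str | Path | None = None,
) -> NetworkSpec:
    """Assemble a NetworkSpec in fresh or transfer mode.

    Transfer mode replaces the final fully connected / softmax /
    classification stage with fresh layers and freezes everything earlier
    (pretrained parameters are not changed during training); it therefore
    requires a weight source for the early layers. Pretrained weights are a
    user-supplied plug-in — nothing is downloaded.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if arch not in ARCHS:
        raise ValueError(f"arch must be one of {ARCHS}")
    if mode == "transfer" and pretrained_weights is None:
        raise ValueError(
            "transfer mode requires pretrained weights for the early layers; "
            "use mode='fresh' to train from scratch"
        )
    layers = _table1_layers(n_classes) if arch == "table1" else _reduced_layers(n_classes)
    frozen: frozenset = frozenset()
    if mode == "transfer":
        final_fc = [l.name for l in layers if l.kind == "fc"][-1]
        frozen = frozenset(
            l.name for l in layers if l.kind in ("conv", "fc") and l.name != final_fc
        )
    h, w, c = layers[0].params["shape"]
    return NetworkSpec(layers=layers, input_shape=(h, w, c), mode=mode, frozen=frozen, arch=arch)


def instantiate(spec: NetworkSpec, rng: np.random.Generator) -> _nn.Network:
    """Materialize a NetworkSpec into a runnable network with initialized weights."""
    shapes = spec.shape_trace()
    names = [l.name for l in spec.layers]
    built: list[_nn.Layer] = []
    prev_shape: tuple = (spec.input_shape[2], spec.input_shape[0], spec.input_shape[1])
    flattened = False
    name_of: dict[int, str] = {}
    for i, layer in enumerate(spec.layers):
        p = layer.params
        obj: _nn.Layer | None = None
        if layer.kind == "conv":
            obj = _nn.Conv2D(
                prev_shape[0], p["filters"], p["kernel"], p["stride"], p["pad"], p.get("groups", 1)
            )
            obj.init(rng)
        elif layer.kind == "relu":
            obj = _nn.ReLU()
        elif layer.kind == "norm":
            obj = _nn.CrossChannelNorm(n=p["window"])
        elif layer.kind == "pool":
            obj = _nn.MaxPool(p["kernel"], p["stride"])
        elif layer.kind == "fc":
            if not flattened:
                built.append(_nn.Flatten())
                flattened = True
            obj = _nn.Dense(int(np.prod(prev_shape)), p["units"])
            obj.init(rng)
        elif layer.kind == "dropout":
            obj = _nn.Dropout(p["p"], rng=rng)
        # input/softmax/classification are not compute layers here
        if obj is not None:
            if layer.name in spec.frozen:
                obj.trainable = False
            name_of[len(built)] = layer.name
            built.append(obj)
        prev_shape = shapes[i]
    net = _nn.Network(built)
    net.layer_names = name_of  # index in built stack -> spec layer name
    return net


class CNNClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional classifier over barcode rasters, sklearn estimator API.

    Parameters follow the study's training configuration; ``arch='reduced'``
    selects the desk-scale network (64x64 inputs), ``arch='table1'`` the full
    stack (227x227 inputs). ``mode='transfer'`` freezes user-supplied
    pretrained early layers and trains only the final classification stage.

    Fitted attributes: ``classes_``, ``network_``, ``spec_``,
    ``channel_mean_`` (training-split per-channel means used for zero
    centering), ``history_`` (per-epoch loss and accuracy).
    """

    def __init__(
        self,
        arch: str = "reduced",
        mode: str = "fresh",
        optimizer: str = "sgdm",
        learning_rate: float = 1e-4,
        max_epochs: int = 30,
        batch_size: int = 5,
        momentum: float = 0.9,
        random_state: int = 0,
        pretrained_weights: dict | None = None,
    ):
        self.arch = arch
        self.mode = mode
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.momentum = momentum
        self.random_state = random_state
        self.pretrained_weights = pretrained_weights

    # -- helpers ---------------------------------------------------------

    def _check_images(self, X: np.ndarray, fitted_shape: tuple | None = None) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("expected images of shape (n, side, side, 3)")
        expect = fitted_shape or (
            self.spec_.input_shape if hasattr(self, "spec_") else None
        )
        if expect is not None and X.shape[1:] != tuple(expect):
            raise ValueError(f"image shape {X.shape[1:]} does not match network input {expect}")
        return X.astype(np.float32)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        x = (X - self.channel_mean_[None, None, None, :]).astype(np.float32)
        return np.transpose(x, (0, 3, 1, 2))  # NHWC -> NCHW

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if self.optimizer not in ("sgdm", "adam"):
            raise ValueError("optimizer must be 'sgdm' or 'adam'")
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set must contain both classes")
        self.classes_ = classes
        yi = np.searchsorted(classes, y)

        self.spec_ = build_network(
            mode=self.mode,
            n_classes=len(classes),
            arch=self.arch,
            pretrained_weights=self.pretrained_weights,
        )
        X = self._check_images(X, self.spec_.input_shape)
        rng = np.random.default_rng(self.random_state)
        self.network_ = instantiate(self.spec_, rng)
        if self.mode == "transfer":
            self._load_pretrained()

        self.channel_mean_ = X.mean(axis=(0, 1, 2))
        xs = self._prepare(X)

        opt = (
            _nn.SGDM(self.learning_rate, self.momentum)
            if self.optimizer == "sgdm"
            else _nn.Adam(self.learning_rate)
        )
        n = xs.shape[0]
        self.history_ = {"loss": [], "accuracy": []}
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.network_.forward(xs[idx], training=True)
                loss, dlogits = _nn.cross_entropy_grad(logits, yi[idx])
                if not np.isfinite(loss):
                    self.history_["loss"].append(float(loss))
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch + 1} (non-finite loss)"
                    )
                self.network_.backward(dlogits)
                opt.step(self.network_.layers)
                losses.append(loss * len(idx))
                correct += int((logits.argmax(axis=1) == yi[idx]).sum())
            self.history_["loss"].append(float(np.sum(losses) / n))
            self.history_["accuracy"].append(correct / n)
        return self

    def _load_pretrained(self) -> None:
        weights = self.pretrained_weights
        if isinstance(weights, (str, Path)):
            with np.load(weights) as z:
                weights = {k: z[k] for k in z.files}
        loaded = set()
        for li, layer in enumerate(self.network_.layers):
            name = self.network_.layer_names.get(li)
            if name is None or name not in self.spec_.frozen:
                continue
            for k, v in layer.params().items():
                key = f"{name}.{k}"
                if key not in weights:
                    raise ValueError(f"pretrained weights missing {key}")
                if weights[key].shape != v.shape:
                    raise ValueError(f"pretrained weight {key} has wrong shape")
                v[...] = weights[key]
                loaded.add(key)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._check_images(X, self.spec_.input_shape)
        logits = self.network_.forward(self._prepare(X), training=False)
        return _nn.softmax(logits)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def decision_scores(self, X, positive_label="EOC") -> np.ndarray:
        """Probability of the positive class for each sample."""
        proba = self.predict_proba(X)
        col = int(np.where(self.classes_ == positive_label)[0][0])
        return proba[:, col]

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint with the architecture spec and class order."""
        check_is_fitted(self, "network_")
        meta = {
            "arch": self.arch,
            "mode": self.mode,
            "classes": [str(c) for c in self.classes_],
            "params": {
                k: v
                for k, v in self.get_params().items()
                if k != "pretrained_weights" and np.isscalar(v)
            },
        }
        state = self.network_.state()
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            __channel_mean__=self.channel_mean_,
            **state,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {k: z[k] for k in z.files if not k.startswith("__")}
            mean = z["__channel_mean__"]
        clf = cls(**{k: v for k, v in meta["params"].items()})
        clf.classes_ = np.array(meta["classes"])
        clf.spec_ = build_network(
            mode="fresh", n_classes=len(clf.classes_), arch=meta["arch"]
        )
        clf.network_ = instantiate(clf.spec_, np.random.default_rng(0))
        clf.network_.load_state(state)
        clf.channel_mean_ = mean
        return clf
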