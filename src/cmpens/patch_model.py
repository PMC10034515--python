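"""Patch-based pixel classifier with L1-norm filter pruning.

The classifier maps a 51 x 51 x 3 window to the class membership probability
(CMP) of its *center* pixel being foreground ("cell").  The canonical
architecture is a small VGG-style stack:

    input 51x51x3
    conv 25 @ 4x4 (ReLU, dropout 0.10) -> maxpool 2x2   -> 24x24x25
    conv 50 @ 5x5 (ReLU, dropout 0.20) -> maxpool 2x2   -> 10x10x50
    conv 80 @ 6x6 (ReLU, dropout 0.25) -> maxpool 2x2   ->  3x 3x80
    dense 1024 (ReLU, dropout 0.5)
    dense 1024 (ReLU, dropout 0.5)
    dense 2, softmax

All convolutions are valid-mode; the last pooling uses ceil semantics
(5 -> 3).  Everything — forward pass, backpropagation, Adam, dropout — is
implemented here on numpy, which keeps the weight tensors directly
addressable for structured pruning: pruning a fraction f of a convolutional
layer deletes its round(f * N) smallest-L1-norm filters together with the
matching input channels of the successor layer (and the matching block of
dense-layer inputs after the last convolution, using channel-major
flattening).

A compact variant (:func:`compact_config`) with the same topology but fewer
filters is provided for desk-scale ensemble experiments on synthetic scenes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .aggregation import ProbabilityMap, BinaryMask
from .synthetic_data import PatchDataset, valid_center_bounds, _window

__all__ = [
    "ArchitectureConfig",
    "TrainConfig",
    "PatchModel",
    "build_network",
    "compact_config",
    "extract_patches",
    "train",
    "predict_cmp",
    "grid_truth",
    "l1_filter_norms",
    "prune_l1",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    patch_size: int = 51
    in_channels: int = 3
    conv_filters: tuple[int, ...] = (25, 50, 80)
    conv_kernels: tuple[int, ...] = (4, 5, 6)
    fc_sizes: tuple[int, ...] = (1024, 1024)
    conv_dropout: tuple[float, ...] = (0.1, 0.2, 0.25)
    fc_dropout: tuple[float, ...] = (0.5, 0.5)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != len(self.conv_kernels) != len(self.conv_dropout):
            raise ValueError("conv_filters, conv_kernels, conv_dropout must align")
        if len(self.fc_sizes) != len(self.fc_dropout):
            raise ValueError("fc_sizes and fc_dropout must align")


def compact_config() -> ArchitectureConfig:
    """Reduced-width variant for desk-scale synthetic experiments."""
    return ArchitectureConfig(
        conv_filters=(8, 12, 16), fc_sizes=(64, 64), conv_dropout=(0.1, 0.2, 0.25),
        fc_dropout=(0.5, 0.5),
    )


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: seeded 70:30 train/validation split, cross-entropy
    loss, Adam, early stopping on validation loss."""

    seed: int = 0
    epochs: int = 30
    patience: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 64
    val_fraction: float = 0.3
    pretrain_epochs: int = 3  # used when training a shared pretraining checkpoint

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


# --------------------------------------------------------------------------
# layers


class _Conv2D:
    """Valid-mode convolution; weights (N, C, K, K), NHWC activations."""

    is_conv = True

    def __init__(self, weight: np.ndarray, bias: np.ndarray):
        self.W = np.asarray(weight, dtype=np.float32)
        self.b = np.asarray(bias, dtype=np.float32)

    @property
    def n_filters(self) -> int:
        return self.W.shape[0]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, k, _ = self.W.shape
        windows = sliding_window_view(x, (k, k), axis=(1, 2))  # (B, Ho, Wo, C, K, K)
        b_, ho, wo = windows.shape[:3]
        cols = windows.reshape(b_, ho, wo, c * k * k)
        wmat = self.W.transpose(1, 2, 3, 0).reshape(c * k * k, n)
        out = cols @ wmat + self.b
        if train:
            self._cols, self._x_shape = cols, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, k, _ = self.W.shape
        b_, ho, wo, _ = dout.shape
        cols2 = self._cols.reshape(-1, c * k * k)
        d2 = dout.reshape(-1, n)
        self.dW = (cols2.T @ d2).reshape(c, k, k, n).transpose(3, 0, 1, 2)
        self.db = d2.sum(axis=0)
        wmat = self.W.transpose(1, 2, 3, 0).reshape(c * k * k, n)
        dcols = (d2 @ wmat.T).reshape(b_, ho, wo, c, k, k)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dx[:, ki : ki + ho, kj : kj + wo, :] += dcols[:, :, :, :, ki, kj]
        self._cols = None
        return dx

    def params(self):
        return [("W", self.W), ("b", self.b)]


class _MaxPool2x2:
    """2x2/stride-2 max pooling with ceil semantics (odd edges padded)."""

    is_conv = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b_, h, w, c = x.shape
        ph, pw = (-h) % 2, (-w) % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=-np.inf)
        ho, wo = x.shape[1] // 2, x.shape[2] // 2
        xp = x.reshape(b_, ho, 2, wo, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(b_, ho, wo, c, 4)
        idx = xp.argmax(axis=-1)
        out = np.take_along_axis(xp, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._in_shape, self._pad = idx, (b_, h, w, c), (ph, pw)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b_, h, w, c = self._in_shape
        ph, pw = self._pad
        ho, wo = dout.shape[1], dout.shape[2]
        dxp = np.zeros((b_, ho, wo, c, 4), dtype=np.float32)
        np.put_along_axis(dxp, self._idx[..., None], dout[..., None], axis=-1)
        dx = dxp.reshape(b_, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
            b_, 2 * ho, 2 * wo, c
        )
        return dx[:, : h, : w, :]

    def params(self):
        return []


class _ReLU:
    is_conv = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class _Dropout:
    is_conv = False

    def __init__(self, rate: float):
        self.rate = float(rate)

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class _Flatten:
    """Channel-major flatten: NHWC -> (B, C*H*W) with feature = ch*H*W + pos."""

    is_conv = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        b_ = x.shape[0]
        return x.transpose(0, 3, 1, 2).reshape(b_, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b_, h, w, c = self._shape
        return dout.reshape(b_, c, h, w).transpose(0, 2, 3, 1)

    def params(self):
        return []


class _Dense:
    is_conv = False

    def __init__(self, weight: np.ndarray, bias: np.ndarray):
        self.W = np.asarray(weight, dtype=np.float32)  # (in, out)
        self.b = np.asarray(bias, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T

    def params(self):
        return [("W", self.W), ("b", self.b)]


# --------------------------------------------------------------------------
# model


class PatchModel:
    """The patch classifier: an explicit layer stack over numpy arrays."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.pruned_fraction: tuple[float, ...] | None = None
        self.history: dict[str, list[float]] = {}
        rng = np.random.default_rng(seed)

        def glorot(shape, fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape).astype(np.float32)

        layers: list = []
        size = config.patch_size
        c_in = config.in_channels
        for n_f, k, dr in zip(config.conv_filters, config.conv_kernels, config.conv_dropout):
            w = glorot((n_f, c_in, k, k), c_in * k * k, n_f)
            layers += [_Conv2D(w, np.zeros(n_f)), _ReLU(), _Dropout(dr), _MaxPool2x2()]
            size = -(-(size - k + 1) // 2)  # valid conv then ceil-mode 2x2 pool
            c_in = n_f
        layers.append(_Flatten())
        self.feature_map_hw = (size, size)
        feat = size * size * c_in
        for n_out, dr in zip(config.fc_sizes, config.fc_dropout):
            layers += [_Dense(glorot((feat, n_out), feat, n_out), np.zeros(n_out)),
                       _ReLU(), _Dropout(dr)]
            feat = n_out
        layers.append(_Dense(glorot((feat, config.n_classes), feat, config.n_classes),
                             np.zeros(config.n_classes)))
        self.layers = layers

    # -- introspection ------------------------------------------------------

    @property
    def conv_layers(self) -> list[_Conv2D]:
        return [l for l in self.layers if getattr(l, "is_conv", False)]

    @property
    def dense_layers(self) -> list[_Dense]:
        return [l for l in self.layers if isinstance(l, _Dense)]

    def n_parameters(self) -> int:
        return int(sum(p.size for layer in self.layers for _, p in layer.params()))

    def copy(self) -> "PatchModel":
        return copy.deepcopy(self)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for _, p in layer.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for name, p in layer.params():
                setattr(layer, name, weights[i].astype(np.float32).copy())
                i += 1

    # -- inference ----------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                out = layer.forward(out, train=train, rng=rng)
            else:
                out = layer.forward(out, train=train)
        return out

    def predict_logits(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        outs = [self._forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax probabilities, columns (background, foreground)."""
        return _softmax(self.predict_logits(patches, batch_size))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_network(config: ArchitectureConfig | None = None, seed: int = 0) -> PatchModel:
    """Instantiate the patch classifier (canonical widths by default)."""
    return PatchModel(config or ArchitectureConfig(), seed=seed)


# --------------------------------------------------------------------------
# data


def extract_patches(image: np.ndarray, positions, mask: np.ndarray | None = None,
                    patch_size: int = 51) -> PatchDataset:
    """Cut valid-mode patches centered at (row, col) positions.

    Every position must admit a full window; labels come from the mask's
    center-pixel value when a mask is supplied (else -1).
    """
    img = np.asarray(image)
    r0, r1, c0, c1 = valid_center_bounds(img.shape[:2], patch_size)
    patches, labels, pos_arr = [], [], []
    for (r, c) in positions:
        if not (r0 <= r <= r1 and c0 <= c <= c1):
            raise ValueError(
                f"position ({r}, {c}) too close to the border for a "
                f"{patch_size}x{patch_size} patch (valid rows {r0}..{r1}, cols {c0}..{c1})"
            )
        patches.append(_window(img, r, c, patch_size))
        labels.append(int(mask[r, c]) if mask is not None else -1)
        pos_arr.append((r, c))
    return PatchDataset(
        patches=np.stack(patches).astype(np.float32),
        labels=np.asarray(labels, dtype=np.int64),
        positions=np.asarray(pos_arr),
        source_image=np.zeros(len(patches), dtype=np.int64),
    )


# --------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, model: PatchModel, lr: float):
        self.lr, self.beta1, self.beta2, self.eps = lr, 0.9, 0.999, 1e-8
        self.t = 0
        self.state = {}
        for li, layer in enumerate(model.layers):
            for name, p in layer.params():
                self.state[(li, name)] = (np.zeros_like(p), np.zeros_like(p))

    def step(self, model: PatchModel) -> None:
        self.t += 1
        for li, layer in enumerate(model.layers):
            for name, p in layer.params():
                g = getattr(layer, "d" + name)
                m, v = self.state[(li, name)]
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                self.state[(li, name)] = (m, v)
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())


def train(model: PatchModel, data: PatchDataset, cfg: TrainConfig | None = None) -> PatchModel:
    """Train in place with a seeded 70:30 split and early stopping.

    Deterministic given (model seed, data, cfg.seed).  Raises if the training
    split does not contain both classes.  The weights of the best-validation
    epoch are restored on exit; per-epoch losses land in ``model.history``.
    """
    cfg = cfg or TrainConfig()
    if len(data) == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(cfg.seed)
    n = len(data)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    y = data.labels
    if np.unique(y[tr_idx]).size < 2:
        raise ValueError("training split contains a single class; need both classes")
    x_tr = np.asarray(data.patches[tr_idx], dtype=np.float32)
    y_tr = y[tr_idx]
    x_val = np.asarray(data.patches[val_idx], dtype=np.float32)
    y_val = y[val_idx]

    opt = _Adam(model, cfg.learning_rate)
    best_val, best_weights, since_best = np.inf, None, 0
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            bi = order[start : start + cfg.batch_size]
            xb, yb = x_tr[bi], y_tr[bi]
            logits = model._forward(xb, train=True, rng=rng)
            probs = _softmax(logits)
            losses.append(_cross_entropy(probs, yb))
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits = (dlogits / len(yb)).astype(np.float32)
            grad = dlogits
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            opt.step(model)
        history["train_loss"].append(float(np.mean(losses)))
        if len(x_val):
            val_loss = _cross_entropy(model.predict_proba(x_val), y_val)
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val, best_weights, since_best = val_loss, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_weights is not None:
        model.set_weights(best_weights)
    model.history = history
    return model


# --------------------------------------------------------------------------
# dense prediction


def predict_cmp(model: PatchModel, image: np.ndarray, stride: int = 1,
                batch_size: int = 512, full_grid: bool = False) -> ProbabilityMap:
    """Foreground CMP on the stride-subsampled grid of valid patch centers.

    With ``full_grid=True`` the image is reflection-padded by half a patch so
    that every stride-th pixel gets a prediction (an S x S image yields a
    ceil(S/stride) grid, e.g. 250 x 250 = 62 500 pixels for a 1000 x 1000
    image at stride 4); the default predicts only fully valid windows.
    The returned map's ``grid`` attribute records origin, stride and source
    image shape so predictions can be aligned with ground truth.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    img = np.asarray(image, dtype=np.float32)
    ps = model.config.patch_size
    orig_shape = tuple(img.shape[:2])
    if full_grid:
        half = ps // 2
        if min(orig_shape) <= half:  # reflect padding needs dim > pad width
            raise ValueError(f"image {orig_shape} too small to pad for patch size {ps}")
        img = np.pad(img, ((half, half), (half, half), (0, 0)), mode="reflect")
    r0, r1, c0, c1 = valid_center_bounds(img.shape[:2], ps)
    rows = np.arange(r0, r1 + 1, stride)
    cols = np.arange(c0, c1 + 1, stride)
    windows = sliding_window_view(img, (ps, ps), axis=(0, 1))  # (H', W', C, ps, ps)
    out = np.empty((len(rows), len(cols)), dtype=np.float64)
    centers = [(r, c) for r in rows for c in cols]
    for start in range(0, len(centers), batch_size):
        chunk = centers[start : start + batch_size]
        batch = np.stack(
            [windows[r - r0, c - c0].transpose(1, 2, 0) for r, c in chunk]
        )
        probs = model.predict_proba(batch)[:, 1]
        for (r, c), p in zip(chunk, probs):
            out[(r - r0) // stride, (c - c0) // stride] = p
    pm = ProbabilityMap(values=np.clip(out, 0.0, 1.0), method="member")
    origin = (0, 0) if full_grid else (int(r0), int(c0))
    pm.grid = {"origin": origin, "stride": int(stride), "image_shape": orig_shape,
               "patch_size": int(ps), "full_grid": bool(full_grid)}
    return pm


def grid_truth(mask: np.ndarray, patch_size: int = 51, stride: int = 1) -> BinaryMask:
    """Ground truth sampled on the same center grid as :func:`predict_cmp`."""
    m = np.asarray(mask)
    r0, r1, c0, c1 = valid_center_bounds(m.shape[:2], patch_size)
    sub = m[r0 : r1 + 1 : stride, c0 : c1 + 1 : stride]
    return BinaryMask(values=(sub > 0).astype(np.uint8))


# --------------------------------------------------------------------------
# checkpoints


def save_model(model: PatchModel, path) -> None:
    """Write weights as an .npz checkpoint with a JSON sidecar.

    The sidecar (same stem, .json) records the architecture (and its hash),
    seed, pruning fractions and parameter count — enough to audit provenance
    without loading the arrays.
    """
    import hashlib
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    arrays = {}
    for li, layer in enumerate(model.layers):
        for name, p in layer.params():
            arrays[f"layer{li:02d}_{name}"] = p
    np.savez(path, **arrays)
    arch = asdict(model.config)
    sidecar = {
        "architecture": arch,
        "architecture_hash": hashlib.sha256(
            json.dumps(arch, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": model.seed,
        "pruned_fraction": model.pruned_fraction,
        "n_parameters": model.n_parameters(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> PatchModel:
    """Rebuild a model from an .npz checkpoint and its JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arch = sidecar["architecture"]
    for key in ("conv_filters", "conv_kernels", "fc_sizes", "conv_dropout", "fc_dropout"):
        arch[key] = tuple(arch[key])
    model = PatchModel(ArchitectureConfig(**arch), seed=sidecar.get("seed", 0))
    with np.load(path) as data:
        for li, layer in enumerate(model.layers):
            for name, p in layer.params():
                arr = data[f"layer{li:02d}_{name}"]
                setattr(layer, name, arr.astype(np.float32))
    pf = sidecar.get("pruned_fraction")
    if pf is not None:
        # restore pruned shapes by slicing a fresh build is unnecessary: the
        # loaded arrays already carry the pruned geometry
        model.pruned_fraction = tuple(pf)
    return model


# --------------------------------------------------------------------------
# pruning


def l1_filter_norms(layer) -> np.ndarray:
    """Per-filter L1 norms (sum of absolute kernel weights) of a conv layer."""
    if not getattr(layer, "is_conv", False):
        raise ValueError("l1_filter_norms expects a convolutional layer")
    return np.abs(layer.W).sum(axis=(1, 2, 3))


def _n_to_remove(fraction: float, n_filters: int) -> int:
    n = int(np.floor(fraction * n_filters + 0.5))  # round half-up
    return min(n, n_filters - 1)  # always retain at least one filter


def prune_l1(model: PatchModel, fraction) -> PatchModel:
    """Structured L1 pruning of all convolutional layers.

    ``fraction`` is a single value or one value per conv layer, each in
    [0, 1).  For each layer the round(f*N) filters with the smallest L1
    norms are removed (ties: lower index removed first), together with the
    successor layer's matching input channels; after the last conv layer the
    matching channel-major block of dense-input features is removed.
    Returns a new model; f = 0 yields a bit-exact copy.
    """
    fractions = np.broadcast_to(np.asarray(fraction, dtype=float),
                                (len(model.conv_layers),))
    if (fractions < 0).any() or (fractions >= 1).any():
        raise ValueError("pruning fractions must satisfy 0 <= f < 1")
    pruned = model.copy()
    convs = pruned.conv_layers
    first_dense = pruned.dense_layers[0]
    h, w = pruned.feature_map_hw
    for i, (layer, f) in enumerate(zip(convs, fractions)):
        norms = l1_filter_norms(layer)
        n_rm = _n_to_remove(f, layer.n_filters)
        if n_rm == 0:
            continue
        order = np.argsort(norms, kind="stable")  # stable: ties by lower index
        keep = np.sort(order[n_rm:])
        layer.W = layer.W[keep]
        layer.b = layer.b[keep]
        if i + 1 < len(convs):
            convs[i + 1].W = convs[i + 1].W[:, keep]
        else:
            # channel-major flatten: features of channel ch are the block
            # [ch*h*w, (ch+1)*h*w)
            feat_keep = (keep[:, None] * (h * w) + np.arange(h * w)[None, :]).ravel()
            first_dense.W = first_dense.W[feat_keep]
    pruned.pruned_fraction = tuple(float(f) for f in fractions)
    return pruned
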