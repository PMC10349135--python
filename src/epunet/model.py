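"""GAM-structured interpretable CNN ensembles.

The model follows the generalized-additive template

    g(E[Y | I]) = beta + sum_i C_i(I_i; eta_i)

where each sub-network ``C_i = C2_i(C1_i(.))`` consumes exactly one
perceptual feature map ``I_i`` of the input image: ``C1_i`` is a conventional
CNN feature extractor and ``C2_i`` a single affine unit with a tanh
activation, so every sub-network contributes a univariate Relative
Similarity Score (RSS) in [-1, 1]. For binary classification the link g is
the logit, so the prediction is ``sigmoid(beta + sum_i RSS_i)``; the
pre-link score therefore lies in [beta - N, beta + N]. For multiclass the
heads emit one score per class and the link is a softmax. All sub-networks
and the intercept ``beta`` are trained jointly by backpropagating a single
consensus cross-entropy loss.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .nn import (
    SGD,
    BatchNorm2D,
    Conv2D,
    Dense,
    Flatten,
    Inception,
    MaxPool2x2,
    ReLU,
    Sequential,
    Tanh,
)
from .pfm import DEFAULT_PFM_NAMES, PFMStack

__all__ = [
    "SubNetwork",
    "EPUModel",
    "TrainConfig",
    "TrainingError",
    "build_base_I",
    "build_base_II",
    "build_epu",
    "train",
    "save_model",
    "load_model",
]

_HIDDEN_WIDTH = 512  # width of the single hidden FC layer of C1
_HEAD_SCALE = 0.1  # near-zero head init: the ensemble starts at chance


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


class SubNetwork:
    """One ensemble member: feature extractor C1 + univariate tanh head C2.

    ``conv_registry`` lists named capture points for every convolutional
    layer (the activation after its rectifier) in depth order; PRM
    construction reads mid-layer feature maps through it.
    """

    def __init__(self, net: Sequential, conv_registry: list[tuple[str, int]],
                 arch_id: str, input_size: tuple[int, int], out_dim: int):
        self.net = net
        self.conv_registry = conv_registry
        self.arch_id = arch_id
        self.input_size = input_size
        self.out_dim = out_dim

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_registry)

    def forward(self, x: np.ndarray, train: bool = False,
                capture_layers: list[int] | None = None):
        """x: (B, 1, H, W) float32 -> (B, out_dim) in [-1, 1].

        ``capture_layers`` are 1-based indices into the conv registry; when
        given, returns (output, {registry_index: feature_maps}).
        """
        if capture_layers:
            at = {self.conv_registry[i - 1][1] for i in capture_layers}
            cap = {"at": at, "out": {}}
            out = self.net.forward(x, train=train, capture=cap)
            feats = {
                i: cap["out"][self.conv_registry[i - 1][1]] for i in capture_layers
            }
            return out, feats
        return self.net.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)


def _conv_block(layers, registry, in_ch, widths, kernel, rng):
    """Append convs (+ReLU each) then maxpool + batchnorm; register each conv
    (capture point = its rectified activation)."""
    ch = in_ch
    for w in widths:
        layers.append(Conv2D(ch, w, kernel, rng))
        layers.append(ReLU())
        n_conv = sum(1 for name, _ in registry if name.startswith("conv")) + 1
        registry.append((f"conv{n_conv}", len(layers) - 1))
        ch = w
    layers.append(MaxPool2x2())
    layers.append(BatchNorm2D(ch))
    return ch


def _fc_head(layers, flat_dim, out_dim, rng):
    layers.append(Flatten())
    layers.append(Dense(flat_dim, _HIDDEN_WIDTH, rng))
    layers.append(ReLU())
    layers.append(Dense(_HIDDEN_WIDTH, out_dim, rng,
                        weight_scale=_HEAD_SCALE / np.sqrt(_HIDDEN_WIDTH)))
    layers.append(Tanh())


def build_base_I(input_size: tuple[int, int], rng: np.random.Generator | None = None,
                 in_ch: int = 1, out_dim: int = 1) -> SubNetwork:
    """Reference architecture I: three convolutional blocks, then an FC head.

    Blocks: [2 x conv64, maxpool, batchnorm], [2 x conv128, maxpool,
    batchnorm], [3 x conv256, maxpool, batchnorm]; all kernels 3 x 3. The
    head is one 512-unit rectified layer (C1 output) followed by the
    univariate tanh unit (C2).
    """
    h, w = input_size
    if h % 8 or w % 8:
        raise ValueError(f"input size {input_size} must be divisible by 8")
    rng = rng or np.random.default_rng(0)
    layers, registry = [], []
    ch = _conv_block(layers, registry, in_ch, [64, 64], 3, rng)
    ch = _conv_block(layers, registry, ch, [128, 128], 3, rng)
    ch = _conv_block(layers, registry, ch, [256, 256, 256], 3, rng)
    _fc_head(layers, (h // 8) * (w // 8) * ch, out_dim, rng)
    return SubNetwork(Sequential(layers), registry, "base_i", input_size, out_dim)


def build_base_II(input_size: tuple[int, int], rng: np.random.Generator | None = None,
                  in_ch: int = 1, out_dim: int = 1,
                  inception_widths: tuple[int, int, int, int] = (16, 32, 8, 8)) -> SubNetwork:
    """Reference architecture II: Base_I with one extra leading block built
    around an inception module (parallel 1x1/3x3/5x5/pool branches)."""
    h, w = input_size
    if h % 16 or w % 16:
        raise ValueError(f"input size {input_size} must be divisible by 16")
    rng = rng or np.random.default_rng(0)
    layers, registry = [], []
    inc = Inception(in_ch, rng, inception_widths)
    layers.append(inc)
    registry.append(("inception", 0))
    layers.append(MaxPool2x2())
    layers.append(BatchNorm2D(inc.out_ch))
    ch = _conv_block(layers, registry, inc.out_ch, [64, 64], 3, rng)
    ch = _conv_block(layers, registry, ch, [128, 128], 3, rng)
    ch = _conv_block(layers, registry, ch, [256, 256, 256], 3, rng)
    _fc_head(layers, (h // 16) * (w // 16) * ch, out_dim, rng)
    return SubNetwork(Sequential(layers), registry, "base_ii", input_size, out_dim)


_BUILDERS = {"base_i": build_base_I, "base_ii": build_base_II}


class EPUModel:
    """The additive ensemble: N independent sub-networks plus a trainable
    intercept, combined through a logit (binary) or softmax (multiclass)
    link."""

    def __init__(self, subnetworks: list[SubNetwork], pfm_names, n_classes: int = 2):
        if len(subnetworks) != len(pfm_names):
            raise ValueError("one sub-network per PFM name required")
        self.subnetworks = subnetworks
        self.pfm_names = tuple(pfm_names)
        self.n_classes = n_classes
        self.out_dim = 1 if n_classes == 2 else n_classes
        self.link = "sigmoid" if n_classes == 2 else "softmax"
        # GAM intercept; float64 so the additivity contract is exact
        self.bias = np.zeros(self.out_dim, dtype=np.float64)
        self._bias_grad = np.zeros_like(self.bias)
        self.trained = False

    @property
    def n(self) -> int:
        return len(self.subnetworks)

    # -- forward ---------------------------------------------------------
    def _check_stack(self, stacks) -> np.ndarray:
        if isinstance(stacks, PFMStack):
            if stacks.names != self.pfm_names:
                raise ValueError(
                    f"PFM names {stacks.names} do not match model {self.pfm_names}"
                )
            stacks = stacks.maps[None]
        stacks = np.asarray(stacks, dtype=np.float32)
        if stacks.ndim == 3:
            stacks = stacks[None]
        if stacks.ndim != 4 or stacks.shape[1] != self.n:
            raise ValueError(
                f"expected (B, {self.n}, H, W) stack, got shape {stacks.shape}"
            )
        return stacks

    def forward(self, stacks, train: bool = False):
        """Run the ensemble.

        Returns ``(prediction, rss)``: for binary models prediction is a
        (B,) probability of class 1 and rss a (B, N) array in [-1, 1]; for
        multiclass, prediction is (B, n_classes) summing to 1 and rss is
        (B, N, n_classes). The sub-network scores are summed in sorted
        order, so permuting sub-networks together with their PFMs leaves
        the prediction bit-identical.
        """
        stacks = self._check_stack(stacks)
        outs = [
            sn.forward(stacks[:, i : i + 1], train=train).astype(np.float64)
            for i, sn in enumerate(self.subnetworks)
        ]
        rss = np.stack(outs, axis=1)  # (B, N, out_dim)
        score = self.bias + np.sort(rss, axis=1).sum(axis=1)  # (B, out_dim)
        if self.link == "sigmoid":
            p = 1.0 / (1.0 + np.exp(-score[:, 0]))
            return p, rss[:, :, 0]
        score = score - score.max(axis=1, keepdims=True)
        e = np.exp(score)
        return e / e.sum(axis=1, keepdims=True), rss

    def predict_proba(self, stacks) -> np.ndarray:
        return self.forward(stacks)[0]

    def decision_scores(self, stacks):
        """Pre-link additive score beta + sum_i RSS_i."""
        p, rss = self.forward(stacks)
        if self.link == "sigmoid":
            return self.bias[0] + rss.sum(axis=1)
        return self.bias + rss.sum(axis=1)

    # -- training --------------------------------------------------------
    def _loss_and_grad(self, stacks: np.ndarray, y: np.ndarray):
        """Consensus cross-entropy; returns (loss, dscore (B, out_dim))."""
        b = stacks.shape[0]
        outs = [
            sn.forward(stacks[:, i : i + 1], train=True).astype(np.float64)
            for i, sn in enumerate(self.subnetworks)
        ]
        rss = np.stack(outs, axis=1)
        score = self.bias + np.sort(rss, axis=1).sum(axis=1)
        if self.link == "sigmoid":
            z = score[:, 0]
            # stable BCE: softplus(z) - y*z
            loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
            p = 1.0 / (1.0 + np.exp(-z))
            dscore = ((p - y) / b)[:, None]
        else:
            s = score - score.max(axis=1, keepdims=True)
            logp = s - np.log(np.exp(s).sum(axis=1, keepdims=True))
            loss = float(-np.mean(logp[np.arange(b), y.astype(int)]))
            probs = np.exp(logp)
            onehot = np.zeros_like(probs)
            onehot[np.arange(b), y.astype(int)] = 1.0
            dscore = (probs - onehot) / b
        return loss, dscore

    def backward_from_score(self, dscore: np.ndarray) -> None:
        """Backpropagate d(loss)/d(score) jointly into every sub-network and
        the intercept — Eq-style joint update of the whole ensemble."""
        self._bias_grad = dscore.sum(axis=0)
        d32 = dscore.astype(np.float32)
        for sn in self.subnetworks:
            sn.backward(d32)

    def named_params(self):
        for i, sn in enumerate(self.subnetworks):
            for path, layer, key in sn.net.named_params():
                yield f"sn{i}_{path}", layer, key

    def state_arrays(self) -> dict:
        out = {"bias": self.bias}
        for i, sn in enumerate(self.subnetworks):
            for k, v in sn.net.state_arrays().items():
                out[f"sn{i}_{k}"] = v
        return out

    def load_state_arrays(self, arrays: dict) -> None:
        self.bias = arrays["bias"].astype(np.float64).copy()
        for i, sn in enumerate(self.subnetworks):
            sn.net.load_state_arrays(arrays, prefix=f"sn{i}_")


class _BiasHolder:
    """Adapter so the intercept rides the same optimizer as the layers."""

    def __init__(self, model: EPUModel):
        self.model = model

    @property
    def params(self):
        return {"bias": self.model.bias}

    @property
    def grads(self):
        return {"bias": self.model._bias_grad}


def build_epu(base, pfm_names=DEFAULT_PFM_NAMES, n_classes: int = 2,
              input_size: tuple[int, int] = (128, 128), seed: int = 0) -> EPUModel:
    """Construct an ensemble with one independent sub-network per PFM.

    ``base`` is an architecture id ('base_i' | 'base_ii') or a factory
    ``f(input_size, rng, in_ch, out_dim) -> SubNetwork``. No weights are
    shared between sub-networks; two builds with the same seed are
    parameter-identical.
    """
    pfm_names = tuple(pfm_names)
    if not pfm_names:
        raise ValueError("pfm_names must be nonempty")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    factory = _BUILDERS[base] if isinstance(base, str) else base
    rng = np.random.default_rng(seed)
    out_dim = 1 if n_classes == 2 else n_classes
    subnets = [
        factory(input_size, rng=rng, in_ch=1, out_dim=out_dim) for _ in pfm_names
    ]
    return EPUModel(subnets, pfm_names, n_classes)


@dataclass
class TrainConfig:
    """Optimization settings; the seed fully determines initialization-free
    stochasticity (shuffling, augmentation draws)."""

    batch_size: int = 64
    lr: float = 1e-2
    momentum: float = 0.9
    epochs: int = 30
    augment: bool = True
    seed: int = 0
    early_stopping_patience: int | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _augment_batch(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Orientation-only augmentation: flips and 90-degree rotations applied
    to the PFM stacks (right-angle rotations only when maps are square)."""
    xb = xb.copy()
    square = xb.shape[-1] == xb.shape[-2]
    for j in range(xb.shape[0]):
        if rng.random() < 0.5:
            xb[j] = xb[j, :, :, ::-1]
        if rng.random() < 0.5:
            xb[j] = xb[j, :, ::-1, :]
        if square:
            k = int(rng.integers(4))
            if k:
                xb[j] = np.rot90(xb[j], k, axes=(-2, -1))
    return xb


def train(model: EPUModel, stacks: np.ndarray, y: np.ndarray,
          config: TrainConfig | None = None,
          val_stacks: np.ndarray | None = None, val_y: np.ndarray | None = None,
          verbose: bool = False) -> dict:
    """Jointly optimize all sub-networks and the intercept with SGD.

    One consensus loss is backpropagated through the whole ensemble at every
    step. Returns a history dict with per-epoch training loss and, when a
    validation split is given, validation AUC (binary) or accuracy
    (multiclass).
    """
    from sklearn.metrics import roc_auc_score

    config = config or TrainConfig()
    stacks = np.asarray(stacks, dtype=np.float32)
    y = np.asarray(y)
    if stacks.shape[0] == 0:
        raise ValueError("dataset is empty")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")

    opt = SGD(lr=config.lr, momentum=config.momentum)
    opt.register(model.named_params())
    opt.register([("bias", _BiasHolder(model), "bias")])

    rng = np.random.default_rng(config.seed)
    n = stacks.shape[0]
    history = {"loss": [], "val_metric": []}
    best_metric, patience_left = -np.inf, config.early_stopping_patience

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = stacks[idx]
            if config.augment:
                xb = _augment_batch(xb, rng)
            loss, dscore = model._loss_and_grad(xb, y[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}: "
                    f"loss={loss}, lr={config.lr}"
                )
            model.backward_from_score(dscore)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))

        metric = np.nan
        if val_stacks is not None:
            p = model.predict_proba(val_stacks)
            if model.link == "sigmoid":
                metric = float(roc_auc_score(val_y, p))
            else:
                metric = float(np.mean(p.argmax(axis=1) == val_y))
        history["val_metric"].append(metric)
        if verbose:
            print(f"epoch {epoch + 1:3d}  loss {history['loss'][-1]:.4f}"
                  f"  val {metric:.4f}")

        if config.early_stopping_patience is not None and np.isfinite(metric):
            if metric > best_metric + 1e-6:
                best_metric, patience_left = metric, config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    model.trained = True
    return history


def save_model(model: EPUModel, path, meta: dict | None = None) -> None:
    """Checkpoint: .npz of all arrays + JSON sidecar with the metadata needed
    to rebuild (pfm names, architecture id, input size, class count)."""
    path = str(path)
    np.savez_compressed(path if path.endswith(".npz") else path + ".npz",
                        **model.state_arrays())
    sidecar = {
        "pfm_names": list(model.pfm_names),
        "arch_id": model.subnetworks[0].arch_id,
        "input_size": list(model.subnetworks[0].input_size),
        "n_classes": model.n_classes,
        "trained": model.trained,
        "meta": meta or {},
    }
    jpath = (path[:-4] if path.endswith(".npz") else path) + ".json"
    with open(jpath, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path) -> EPUModel:
    path = str(path)
    npz_path = path if path.endswith(".npz") else path + ".npz"
    jpath = npz_path[:-4] + ".json"
    with open(jpath) as fh:
        sidecar = json.load(fh)
    model = build_epu(
        sidecar["arch_id"], sidecar["pfm_names"], sidecar["n_classes"],
        tuple(sidecar["input_size"]), seed=0,
    )
    with np.load(npz_path) as arrays:
        model.load_state_arrays(dict(arrays))
    model.trained = bool(sidecar.get("trained", False))
    return model
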