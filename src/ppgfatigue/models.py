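"""Classifier families: 1-D ResNet, 1-D Xception, BiLSTM, and the two hybrids.

An extractor (residual or depthwise-separable convolution stack) turns a
fixed-length PPG window into a (channels, steps) feature map; a BiLSTM reads
the feature sequence; a dense layer plus beta-scaled softmax produces the
fatigue / non-fatigue probabilities.  Training is SGD with momentum and
decoupled weight decay on the summed cross-entropy (see :mod:`.nnops`).

Layer counting convention: ``layers`` counts weighted main-path layers —
the entry convolution, two convolutions per residual block (shortcut
projections excluded), depthwise and pointwise convolutions separately, and
any final 1x1 channel projection.  Under this convention the 36-layer
residual extractor and the 37-layer separable extractor both reduce a
1056-sample window by a total temporal stride of 8 to the contracted
feature-map shapes (15, 132) and (64, 132).

The model-facing surface follows the fitted-model idiom: build a
:class:`FatigueClassifier` from a config, call :meth:`~FatigueClassifier.fit`
on windows, and get a :class:`FitResult` carrying the training history,
diagnostics and prediction methods.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .nnops import (
    AvgPoolTime,
    BiLSTM,
    ChannelNorm,
    Conv1d,
    Dense,
    LayerNorm,
    MeanOverTime,
    Module,
    ReLU,
    ResidualBlock,
    SeparableConv,
    Sequential,
    SoftmaxCrossEntropy,
    Transpose,
    sgd_step,
    softmax,
)

FAMILIES = ("resnet", "xception", "lstm", "resnet_bilstm", "xception_bilstm")

CANONICAL_WINDOW = 1056  # samples; stride 8 gives the contracted 132 steps


@dataclass(frozen=True)
class ModelConfig:
    """Architecture family plus optimiser hyperparameters.

    ``kernels`` is the internal feature-map (channel) count, ``kernel_size``
    the convolution length, ``out_channels`` the extractor's output channel
    count (defaults: 15 for residual families, 64 for separable ones), and
    ``total_stride`` the overall temporal downsampling factor.  The defaults
    are desk-scale — small enough to cross-validate a cohort on one CPU in
    minutes; :meth:`reference_resnet`, :meth:`reference_xception` and
    :meth:`published_scale` give the published-scale settings.
    """

    family: str = "resnet_bilstm"
    layers: int = 8
    kernels: int = 8
    kernel_size: int = 9
    bilstm_hidden: int = 16
    learning_rate: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 20
    batch_size: int = 64
    beta: float = 1.0
    seed: int = 0
    in_channels: int = 1
    out_channels: int | None = None
    total_stride: int = 32
    grad_clip: float = 1.0  # global grad-norm ceiling per batch; 0 disables

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        for name in ("layers", "kernels", "kernel_size", "epochs", "batch_size", "in_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if not (0 <= self.momentum < 1):
            raise ValueError(f"momentum must be in [0, 1), got {self.momentum}")
        if self.weight_decay < 0:
            raise ValueError(f"weight_decay must be nonnegative, got {self.weight_decay}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        ts = self.total_stride
        if ts < 2 or (ts & (ts - 1)) != 0:
            raise ValueError(f"total_stride must be a power of two >= 2, got {ts}")

    @property
    def resolved_out_channels(self) -> int:
        if self.out_channels is not None:
            return self.out_channels
        return 64 if self.family.startswith("xception") else 15

    @classmethod
    def reference_resnet(cls, **overrides) -> "ModelConfig":
        """The 36-layer residual extractor: (15, 132) on a 1056-sample window."""
        base = dict(
            family="resnet_bilstm", layers=36, kernels=32, kernel_size=15,
            out_channels=15, total_stride=8,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def reference_xception(cls, **overrides) -> "ModelConfig":
        """The 37-layer separable extractor: (64, 132) on a 1056-sample window."""
        base = dict(
            family="xception_bilstm", layers=37, kernels=32, kernel_size=36,
            out_channels=64, total_stride=8,
        )
        base.update(overrides)
        return cls(**base)

    def published_scale(self, epochs: int = 500) -> "ModelConfig":
        """Published-scale optimiser settings: lr 0.001, 500-2000 epochs."""
        if not (500 <= epochs <= 2000):
            raise ValueError(f"published-scale epochs lie in [500, 2000], got {epochs}")
        return replace(self, learning_rate=0.001, epochs=epochs)


def _stride_plan(total_stride: int, n_units: int) -> tuple[int, list[int]]:
    """Distribute a power-of-two stride over the entry conv and the first units."""
    n_halvings = int(np.log2(total_stride))
    n_strided = min(n_units, n_halvings - 1)
    entry = total_stride >> n_strided
    strides = [2] * n_strided + [1] * (n_units - n_strided)
    return entry, strides


def build_extractor(family: str, config: ModelConfig) -> Sequential:
    """Build the convolutional feature extractor for ``family``.

    Output on a (B, in_channels, T) batch is (B, out_channels,
    ceil(T / total_stride)).
    """
    if family not in ("resnet", "xception"):
        raise ValueError(f"extractor family must be 'resnet' or 'xception', got {family!r}")
    rng = np.random.default_rng([config.seed, 0xFEA7])
    ch = config.kernels
    out_ch = config.resolved_out_channels
    k = config.kernel_size
    layers: list[Module] = []
    if family == "resnet":
        n_blocks, extra = divmod(config.layers - 2, 2)
        if n_blocks < 1:
            raise ValueError(f"resnet needs layers >= 4, got {config.layers}")
        entry, strides = _stride_plan(config.total_stride, n_blocks)
        layers.append(Conv1d(config.in_channels, ch, k, entry, "same", "identity", rng, "entry"))
        layers.append(ChannelNorm(ch, "entry_norm"))
        layers.append(ReLU())
        for i, s in enumerate(strides):
            layers.append(ResidualBlock(ch, ch, k, s, rng, f"res{i}"))
        if extra:
            layers.append(Conv1d(ch, ch, k, 1, "same", "relu", rng, "extra"))
        layers.append(Conv1d(ch, out_ch, 1, 1, "same", "relu", rng, "proj"))
    else:
        n_sep, extra = divmod(config.layers - 1, 2)
        if n_sep < 1:
            raise ValueError(f"xception needs layers >= 3, got {config.layers}")
        entry, strides = _stride_plan(config.total_stride, n_sep)
        layers.append(Conv1d(config.in_channels, ch, k, entry, "same", "identity", rng, "entry"))
        layers.append(ChannelNorm(ch, "entry_norm"))
        layers.append(ReLU())
        for i, s in enumerate(strides):
            last = i == n_sep - 1 and not extra
            layers.append(SeparableConv(ch, out_ch if last else ch, k, s, rng, f"sep{i}"))
        if extra:
            layers.append(Conv1d(ch, out_ch, 1, 1, "same", "relu", rng, "proj"))
    net = Sequential(layers)
    net.n_weighted_layers = _count_weighted(net)
    if net.n_weighted_layers != config.layers:
        raise ValueError(
            f"builder produced {net.n_weighted_layers} weighted layers, "
            f"config demands {config.layers}"
        )
    return net


def _count_weighted(net: Sequential) -> int:
    n = 0
    for layer in net.layers:
        if isinstance(layer, (ResidualBlock, SeparableConv)):
            n += layer.n_weighted_layers
        elif isinstance(layer, Conv1d):
            n += 1
    return n


def extractor_output_shape(family: str, config: ModelConfig, window_len: int) -> tuple[int, int]:
    """(channels, steps) the extractor emits for a window of ``window_len`` samples."""
    net = build_extractor(family, config)
    y = net.forward(np.zeros((1, config.in_channels, window_len)))
    return (y.shape[1], y.shape[2])


def _build_network(config: ModelConfig) -> Sequential:
    rng = np.random.default_rng([config.seed, 0x7EAD])
    fam = config.family
    h = config.bilstm_hidden
    if fam in ("resnet", "xception"):
        extractor = build_extractor(fam, config)
        head_in = config.resolved_out_channels
        tail: list[Module] = [
            Transpose(),
            LayerNorm(head_in),
            MeanOverTime(),
            Dense(head_in, 2, rng, "head"),
        ]
        return Sequential([extractor, *tail])
    if fam == "lstm":
        return Sequential(
            [
                AvgPoolTime(config.total_stride),
                Transpose(),
                BiLSTM(config.in_channels, h, rng),
                MeanOverTime(),
                Dense(2 * h, 2, rng, "head"),
            ]
        )
    extractor = build_extractor(fam.split("_")[0], config)
    return Sequential(
        [
            extractor,
            Transpose(),
            LayerNorm(config.resolved_out_channels),
            BiLSTM(config.resolved_out_channels, h, rng),
            MeanOverTime(),
            Dense(2 * h, 2, rng, "head"),
        ]
    )


def _fit_norm(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel standardisation constants over the whole training set.

    Training-set-level (not per-window) so that window-mean differences
    between classes survive normalisation.
    """
    mu = X.mean(axis=(0, 2), keepdims=True)
    sd = np.maximum(X.std(axis=(0, 2), keepdims=True), 1e-8)
    return mu, sd


@dataclass
class FitResult:
    """Outcome of one training run: history, diagnostics, and prediction."""

    model: "FatigueClassifier"
    history: pd.DataFrame = field(repr=False)  # epoch, loss, rmse
    train_accuracy: float = float("nan")
    n_train: int = 0

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def summary(self) -> str:
        cfg = self.config
        buf = io.StringIO()
        buf.write("Fatigue classifier fit\n")
        buf.write("=" * 54 + "\n")
        buf.write(f"{'family':<22}{cfg.family:>32}\n")
        buf.write(f"{'weighted layers':<22}{cfg.layers:>32}\n")
        buf.write(f"{'kernels / size':<22}{f'{cfg.kernels} / {cfg.kernel_size}':>32}\n")
        buf.write(f"{'bilstm hidden':<22}{cfg.bilstm_hidden:>32}\n")
        buf.write(f"{'optimiser':<22}{'SGD(momentum)':>32}\n")
        buf.write(f"{'lr / momentum / wd':<22}{f'{cfg.learning_rate} / {cfg.momentum} / {cfg.weight_decay}':>32}\n")
        buf.write(f"{'epochs x batch':<22}{f'{cfg.epochs} x {cfg.batch_size}':>32}\n")
        buf.write(f"{'training windows':<22}{self.n_train:>32}\n")
        buf.write(f"{'final train loss':<22}{self.history.loss.iloc[-1]:>32.4f}\n")
        buf.write(f"{'final train RMSE':<22}{self.history.rmse.iloc[-1]:>32.4f}\n")
        buf.write(f"{'train accuracy':<22}{self.train_accuracy:>32.4f}\n")
        return buf.getvalue()

    def plot_history(self, ax=None):
        """Per-epoch training loss and RMSE curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history.epoch, self.history.loss, label="cross-entropy loss")
        ax.plot(self.history.epoch, self.history.rmse, label="RMSE")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax


class FatigueClassifier:
    """Windowed-PPG fatigue classifier; ``fit`` returns a :class:`FitResult`.

    Deterministic given the config seed: weight initialisation, batch
    shuffling and every update are driven by seeded generators.
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.network: Sequential | None = None
        self.norm_mu = np.zeros((1, 1, 1))
        self.norm_sd = np.ones((1, 1, 1))

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> FitResult:
        """Train on windows X (N, C, T) with binary labels y (1 = fatigue)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3:
            raise ValueError(f"X must be (N, C, T), got shape {X.shape}")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        cfg = self.config
        self.norm_mu, self.norm_sd = _fit_norm(X)
        Xn = (X - self.norm_mu) / self.norm_sd
        self.network = _build_network(cfg)
        head = SoftmaxCrossEntropy(cfg.beta)
        rng = np.random.default_rng([cfg.seed, 0x5417])
        params = self.network.parameters()
        velocity = [np.zeros_like(p.value) for p in params]
        n = len(Xn)
        hist = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            ep_sq = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = Xn[idx], y[idx]
                self.network.zero_grad()
                logits = self.network.forward(xb)
                loss, probs = head.forward(logits, yb)
                self.network.backward(head.backward())
                if cfg.grad_clip > 0:
                    # clip the global norm of the per-sample-mean gradient;
                    # one oversized step can permanently kill the ReLU stack
                    gnorm = np.sqrt(
                        sum(float(np.sum((p.grad / len(idx)) ** 2)) for p in params)
                    )
                    if gnorm > cfg.grad_clip:
                        scale = cfg.grad_clip / gnorm
                        for p in params:
                            p.grad *= scale
                for p, vel in zip(params, velocity):
                    p.value[...], vel[...] = sgd_step(
                        p.value,
                        p.grad,
                        vel,
                        learning_rate=cfg.learning_rate,
                        momentum=cfg.momentum,
                        weight_decay=cfg.weight_decay,
                        r=n,
                        batch_size=len(idx),
                        is_bias=p.is_bias,
                    )
                ep_loss += loss
                ep_sq += float(np.sum((probs[:, 1] - yb) ** 2))
            hist.append((epoch, ep_loss / n, np.sqrt(ep_sq / n)))
        history = pd.DataFrame(hist, columns=["epoch", "loss", "rmse"])
        acc = float(np.mean(self.predict(X) == y))
        return FitResult(model=self, history=history, train_accuracy=acc, n_train=n)

    # -- inference ----------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.network is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 2
        if squeeze:
            X = X[None]
        if X.shape[1] != self.config.in_channels:
            raise ValueError(
                f"window has {X.shape[1]} channels, model expects {self.config.in_channels}"
            )
        logits = self.network.forward((X - self.norm_mu) / self.norm_sd)
        probs = softmax(logits, self.config.beta)
        return probs[0] if squeeze else probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=-1)


def train_model(windows, config: ModelConfig | None = None) -> FitResult:
    """Train a classifier on a list of :class:`~ppgfatigue.dataset.Window`."""
    from .dataset import windows_to_arrays

    X, y, _ = windows_to_arrays(windows)
    return FatigueClassifier(config).fit(X, y)


def predict(model, window) -> np.ndarray:
    """Class-probability pair (non-fatigue, fatigue) for one window."""
    clf = model.model if isinstance(model, FitResult) else model
    samples = getattr(window, "samples", window)
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return clf.predict_proba(arr)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(result: FitResult | FatigueClassifier, path) -> None:
    """Single-archive checkpoint: weights plus the ModelConfig."""
    clf = result.model if isinstance(result, FitResult) else result
    if clf.network is None:
        raise RuntimeError("cannot checkpoint an unfitted classifier")
    arrays = {f"param_{i}": p.value for i, p in enumerate(clf.network.parameters())}
    arrays["norm_mu"] = clf.norm_mu
    arrays["norm_sd"] = clf.norm_sd
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(clf.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> FatigueClassifier:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["config_json"].tobytes()).decode()))
        clf = FatigueClassifier(cfg)
        clf.network = _build_network(cfg)
        clf.norm_mu = data["norm_mu"]
        clf.norm_sd = data["norm_sd"]
        for i, p in enumerate(clf.network.parameters()):
            p.value[...] = data[f"param_{i}"]
    return clf
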