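"""The shallow spiral-core localization network.

A six-stage convolutional network maps a 5-frame, 86 x 86 voltage-movie
window to an 86 x 86 per-pixel spiral-core probability map in [0, 1]:

    gradient stem (per-frame spatial gradients appended as channels)
    -> 3x3x3 space-time convolution (valid in time: 5 -> 3)   [16 channels]
    -> 3x3x3 max pooling, stride 1x2x2 (time 3 -> 1, 86 -> 43)
    -> 1x3x3 convolution                                       [32 channels]
    -> 1x3x3 max pooling, stride 2 (43 -> 21)
    -> two stride-2 transposed convolutions (21 -> 42 -> 84)
    -> bilinear interpolation to 86 x 86, sigmoid.

The loss is a mean-absolute-error against a Gaussian core-probability target
plus an anti-collapse hinge that penalizes predictions whose global peak
falls below a floor (preventing the trivial all-zero solution).  Internal
pooled sizes follow same-padding arithmetic 86 -> 43 -> 21; the final resize
restores the input raster.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn
from .errors import ConfigError

INPUT_SIDE = 86
INPUT_FRAMES = 5


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture knobs.  Kernel shapes and strides are part of the design
    contract and are validated, not configurable."""

    conv1_channels: int = 16
    conv2_channels: int = 32
    deconv1_channels: int = 16
    input_side: int = INPUT_SIDE
    input_frames: int = INPUT_FRAMES
    seed: int = 0

    def __post_init__(self):
        if self.input_side != INPUT_SIDE or self.input_frames != INPUT_FRAMES:
            raise ConfigError(
                f"network input is fixed at {INPUT_FRAMES} x {INPUT_SIDE} x {INPUT_SIDE}"
            )
        for w in (self.conv1_channels, self.conv2_channels, self.deconv1_channels):
            if w < 1:
                raise ConfigError("channel widths must be >= 1")


@dataclass(frozen=True)
class LossConfig:
    """lambda_collapse * max(0, peak_floor - max(pred)) is added to the MAE."""

    lambda_collapse: float = 5.0
    peak_floor: float = 0.8

    def __post_init__(self):
        if self.lambda_collapse < 0:
            raise ConfigError("lambda_collapse must be >= 0")
        if not 0.0 < self.peak_floor < 1.0:
            raise ConfigError("peak_floor must be in (0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0
    lr_schedule: str = "constant"  # or 'cosine' decay over the run

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ConfigError("lr_schedule must be 'cosine' or 'constant'")


def gradient_stem(windows: np.ndarray) -> np.ndarray:
    """(B, 5, 86, 86) -> (B, 3, 5, 86, 86): value + per-frame central-difference
    spatial gradients (edges replicated by numpy.gradient)."""
    w = np.asarray(windows, dtype=np.float32)
    gy, gx = np.gradient(w, axis=(2, 3))
    return np.stack([w, gy, gx], axis=1).astype(np.float32)


class CoreCNN:
    """The network plus its fixed gradient stem.

    ``forward`` consumes a batch of raw windows (B, 5, 86, 86); ``predict``
    consumes one window (5, 86, 86) and returns the (86, 86) probability map.
    """

    def __init__(self, config: NetworkConfig | None = None):
        self.config = config or NetworkConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        side = c.input_side
        self.layers = [
            _nn.Conv3d(rng, 3, c.conv1_channels, (3, 3, 3)),      # (B,16,3,86,86)
            _nn.ReLU(),
            _nn.TemporalMax(),                                     # (B,16,86,86)
            _nn.MaxPool2d(k=3, stride=2, pad=1),                   # 86 -> 43
            _nn.Conv2d(rng, c.conv1_channels, c.conv2_channels),   # (B,32,43,43)
            _nn.ReLU(),
            _nn.MaxPool2d(k=3, stride=2, pad=0),                   # 43 -> 21
            _nn.ConvTranspose2d(rng, c.conv2_channels, c.deconv1_channels),  # 21 -> 42
            _nn.ReLU(),
            _nn.ConvTranspose2d(rng, c.deconv1_channels, 1),       # 42 -> 84
            _nn.BilinearResize(side, 84),                          # 84 -> 86
            _nn.Sigmoid(),
        ]
        # start the output at the sparse-target background prior so the
        # sigmoid never saturates wholesale under the L1 pull (with a zero
        # bias the first epochs drag every pre-activation far negative and
        # the vanishing sigmoid slope kills the core-pixel signal)
        self.layers[9].b[:] = -4.5

    # -- plumbing ---------------------------------------------------------

    @property
    def input_side(self) -> int:
        return self.config.input_side

    def parameters(self):
        return [(p, g) for layer in self.layers for (_, p, g) in layer.params]

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def shape_report(self) -> list[tuple]:
        """Layer-by-layer output shapes for a single zero window."""
        x = gradient_stem(np.zeros((1, INPUT_FRAMES, self.input_side, self.input_side)))
        report = [("gradient_stem", x.shape[1:])]
        for layer in self.layers:
            x = layer.forward(x)
            report.append((type(layer).__name__, x.shape[1:]))
        return report

    def footprint_bytes(self) -> int:
        return sum(p.nbytes for p, _ in self.parameters())

    # -- forward / backward ----------------------------------------------

    def forward(self, windows: np.ndarray, train: bool = False) -> np.ndarray:
        x = gradient_stem(windows)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x[:, 0]  # single output channel

    def backward(self, g: np.ndarray):
        x = g[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            x = layer.backward(x)

    def predict(self, window: np.ndarray) -> np.ndarray:
        window = np.asarray(window)
        expected = (INPUT_FRAMES, self.input_side, self.input_side)
        if window.shape != expected:
            raise ConfigError(f"predict expects a window of shape {expected}, got {window.shape}")
        if not np.isfinite(window).all():
            raise ConfigError("window contains non-finite values")
        return self.forward(window[None])[0]

    # -- persistence ------------------------------------------------------

    def _config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self.config), sort_keys=True).encode()).hexdigest()[:16]

    def save(self, path: str):
        arrays = {}
        for i, layer in enumerate(self.layers):
            for name, p, _ in layer.params:
                arrays[f"layer{i}_{name}"] = p
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps({"config": asdict(self.config), "hash": self._config_hash()}).encode(),
                dtype=np.uint8,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str) -> "CoreCNN":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__config__"]).decode())
            model = cls(NetworkConfig(**meta["config"]))
            if model._config_hash() != meta["hash"]:
                raise ConfigError("checkpoint config hash mismatch")
            for i, layer in enumerate(model.layers):
                for name, p, _ in layer.params:
                    p[...] = z[f"layer{i}_{name}"]
        return model


def build_network(config: NetworkConfig | None = None, verbose: bool = True) -> CoreCNN:
    """Build the network, print the layer-by-layer shape report and the
    parameter footprint (flagged if above 1 MB: the model is meant to stay
    small enough for embedded deployment)."""
    model = CoreCNN(config)
    if verbose:
        for name, shape in model.shape_report():
            print(f"  {name:18s} {shape}")
        kb = model.footprint_bytes() / 1024
        flag = "  [WARNING: exceeds 1 MB]" if kb > 1024 else ""
        print(f"  parameters: {model.n_parameters()} ({kb:.1f} KiB){flag}")
    return model


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def loss(pred: np.ndarray, target: np.ndarray, cfg: LossConfig | None = None):
    """Mean absolute error plus the anti-collapse hinge.

    Returns (value, gradient wrt pred).  The hinge max(0, floor - max(pred))
    puts a subgradient of -lambda on the batch's peak prediction pixels when
    they sit below the floor.
    """
    cfg = cfg or LossConfig()
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ConfigError(f"pred shape {pred.shape} != target shape {target.shape}")
    n = pred.size
    diff = pred - target
    value = np.abs(diff).mean()
    grad = np.sign(diff) / n
    # hinge per sample (batch leading axis if 3D, else single map)
    maps = pred[None] if pred.ndim == 2 else pred
    gmaps = grad[None] if pred.ndim == 2 else grad
    n_maps = maps.shape[0]
    for i in range(n_maps):
        peak = maps[i].max()
        if peak < cfg.peak_floor:
            value += cfg.lambda_collapse * (cfg.peak_floor - peak) / n_maps
            idx = np.unravel_index(maps[i].argmax(), maps[i].shape)
            gmaps[i][idx] -= cfg.lambda_collapse / n_maps
    return float(value), grad.astype(np.float32)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def localization_errors(model: CoreCNN, windows: np.ndarray, cores: np.ndarray,
                        batch: int = 32) -> np.ndarray:
    """Distance (px) between predicted argmax and true core per window."""
    errs = []
    for i in range(0, len(windows), batch):
        pred = model.forward(windows[i : i + batch])
        for p, c in zip(pred, cores[i : i + batch]):
            iy, ix = np.unravel_index(p.argmax(), p.shape)
            errs.append(float(np.hypot(iy - c[0], ix - c[1])))
    return np.asarray(errs)


def train(
    corpus,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    checkpoint_path: str | None = None,
    verbose: bool = False,
):
    """Train on a corpus with train/val split; returns (model, history).

    ``corpus`` provides float32 arrays ``train_x`` (N, 5, 86, 86), ``train_y``
    (N, 86, 86) and the corresponding ``val_x``, ``val_y``.  History holds
    per-epoch mean train and validation loss; the best-validation parameters
    are restored at the end (and saved when a path is given).
    """
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    net_cfg = net_cfg or NetworkConfig(seed=train_cfg.seed)
    tx, ty = np.asarray(corpus.train_x, np.float32), np.asarray(corpus.train_y, np.float32)
    vx, vy = np.asarray(corpus.val_x, np.float32), np.asarray(corpus.val_y, np.float32)
    if len(tx) == 0 or len(vx) == 0:
        raise ConfigError("empty train or validation split")
    model = CoreCNN(net_cfg)
    opt = _nn.Adam(model.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    bs = train_cfg.batch_size
    for epoch in range(train_cfg.epochs):
        if train_cfg.lr_schedule == "cosine":
            opt.lr = train_cfg.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / train_cfg.epochs)
            )
        order = rng.permutation(len(tx))
        tot = 0.0
        for i in range(0, len(order), bs):
            idx = order[i : i + bs]
            pred = model.forward(tx[idx], train=True)
            val, grad = loss(pred, ty[idx], loss_cfg)
            model.backward(grad)
            opt.step()
            tot += val * len(idx)
        history["train_loss"].append(tot / len(tx))
        vtot = 0.0
        for i in range(0, len(vx), bs):
            pred = model.forward(vx[i : i + bs])
            val, _ = loss(pred, vy[i : i + bs], loss_cfg)
            vtot += val * len(pred)
        vloss = vtot / len(vx)
        history["val_loss"].append(vloss)
        if vloss < best[0]:
            best = (vloss, [p.copy() for p, _ in model.parameters()])
        if verbose:
            print(f"epoch {epoch + 1}/{train_cfg.epochs}: train {history['train_loss'][-1]:.4f} val {vloss:.4f}")
    if best[1] is not None:
        for (p, _), saved in zip(model.parameters(), best[1]):
            p[...] = saved
    if checkpoint_path:
        model.save(checkpoint_path)
    return model, history


__all__ = [
    "NetworkConfig", "LossConfig", "TrainConfig", "CoreCNN",
    "build_network", "gradient_stem", "loss", "train", "localization_errors",
    "INPUT_SIDE", "INPUT_FRAMES",
]
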