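"""Depthwise-separable fully-convolutional wound segmenter.

The backbone is the 13 depthwise-separable convolution stages of MobileNet
(a depthwise + pointwise pair counts as one stage) behind a 3x3 stride-2 stem,
with every channel width scaled by a depth multiplier DM in {0.25, 0.5, 1.0}.
The fully connected classifier of MobileNet is replaced by interpolation:
two-class 1x1 score convolutions are applied to the last stage (stride 32)
and, after upsampling the deep scores 2x, fused by elementwise addition with
the scores of the last stride-16 stage (the stage before the final
downsampling), FCN-16s style.  The fused map is bilinearly upsampled 16x so
the output resolution equals the input resolution; softmax over the two
channels gives the per-pixel wound probability.

Training follows a stepwise-halved learning-rate schedule
``lr = base_lr * 0.5 ** max(0, floor(step / 5000) - 2)`` with Adam, decoupled
weight decay and batch normalization, minibatches of 5.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn
from .evaluation import confusion, iou
from .preprocess import AugmentConfig, augment as augment_pairs, standardize

__all__ = [
    "NetConfig",
    "TrainConfig",
    "MobileFCN",
    "build_network",
    "lr_at",
    "epochs",
    "train",
    "segment",
    "save_checkpoint",
    "load_checkpoint",
]

# (output channels at DM=1, stride) for the 13 depthwise-separable stages
_DS_STAGES = [
    (64, 1), (128, 2), (128, 1), (256, 2), (256, 1),
    (512, 2), (512, 1), (512, 1), (512, 1), (512, 1), (512, 1),
    (1024, 2), (1024, 1),
]
_STEM_CHANNELS = 32
_SKIP_STAGE = 10  # index of the last stride-16 stage (0-based)


@dataclass(frozen=True)
class NetConfig:
    depth_multiplier: float = 0.25
    input_size: int = 512
    fuse_layers: int = 1
    upsample_factor: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_multiplier not in (0.25, 0.5, 1.0):
            raise ValueError("depth_multiplier must be one of 0.25, 0.5, 1.0")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be a multiple of 32")
        if self.fuse_layers not in (0, 1):
            raise ValueError("only zero or one fused layer is supported")


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 0.01
    lr_halving_interval: int = 5000
    lr_delay: int = 2
    batch_size: int = 5
    total_steps: int = 50000
    weight_decay: float = 4e-5
    seed: int = 0
    eval_interval: int = 200

    def __post_init__(self) -> None:
        for name in ("base_lr", "lr_halving_interval", "lr_delay", "batch_size",
                     "total_steps", "eval_interval"):
            if getattr(self, name) < 0 or (name not in ("lr_delay",) and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")


class MobileFCN:
    """The network object: owns layers, parameters and both passes."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dm = config.depth_multiplier

        def ch(base: int) -> int:
            return max(1, round(base * dm))

        self.stem = [
            _nn.Conv2d(3, ch(_STEM_CHANNELS), k=3, stride=2, rng=rng),
            _nn.BatchNorm2d(ch(_STEM_CHANNELS)),
            _nn.ReLU(),
        ]
        self.stages: list[list] = []
        cin = ch(_STEM_CHANNELS)
        for base, stride in _DS_STAGES:
            cout = ch(base)
            self.stages.append([
                _nn.DepthwiseConv2d(cin, stride=stride, rng=rng),
                _nn.BatchNorm2d(cin),
                _nn.ReLU(),
                _nn.Conv2d(cin, cout, k=1, stride=1, rng=rng),
                _nn.BatchNorm2d(cout),
                _nn.ReLU(),
            ])
            cin = cout
        self.score_deep = _nn.Conv2d(ch(_DS_STAGES[-1][0]), 2, k=1, stride=1, rng=rng, bias=True)
        self.up2 = _nn.BilinearUpsample(2)
        if config.fuse_layers:
            self.score_skip = _nn.Conv2d(ch(_DS_STAGES[_SKIP_STAGE][0]), 2, k=1,
                                         stride=1, rng=rng, bias=True)
        else:
            self.score_skip = None
        self.up16 = _nn.BilinearUpsample(config.upsample_factor)

    # -- parameters ---------------------------------------------------------

    @property
    def params(self) -> list[_nn.Param]:
        layers = self.stem + [l for stage in self.stages for l in stage]
        layers += [self.score_deep]
        if self.score_skip is not None:
            layers.append(self.score_skip)
        return [p for layer in layers for p in layer.params]

    def parameter_count(self) -> int:
        """Total number of trainable scalars (conv weights, biases and
        batch-norm scale/shift)."""
        return int(sum(p.value.size for p in self.params))

    # -- passes -------------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for layer in self.stem:
            h = layer.forward(h, training)
        skip = None
        for i, stage in enumerate(self.stages):
            for layer in stage:
                h = layer.forward(h, training)
            if i == _SKIP_STAGE:
                skip = h
        deep = self.score_deep.forward(h, training)
        fused = self.up2.forward(deep, training)
        if self.score_skip is not None:
            fused = fused + self.score_skip.forward(skip, training)
        return self.up16.forward(fused, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.up16.backward(dlogits)
        dskip = self.score_skip.backward(dfused) if self.score_skip is not None else None
        dh = self.score_deep.backward(self.up2.backward(dfused))
        for i in range(len(self.stages) - 1, -1, -1):
            if i == _SKIP_STAGE and dskip is not None:
                dh = dh + dskip
            for layer in reversed(self.stages[i]):
                dh = layer.backward(dh)
        for layer in reversed(self.stem):
            dh = layer.backward(dh)

    # -- batch-norm running statistics (needed for checkpoints) -------------

    def _bn_layers(self) -> list[_nn.BatchNorm2d]:
        layers = self.stem + [l for stage in self.stages for l in stage]
        return [l for l in layers if isinstance(l, _nn.BatchNorm2d)]

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params)}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn_mean_{i}"] = bn.running_mean
            state[f"bn_var_{i}"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p.value = state[f"param_{i}"].astype(np.float32)
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = state[f"bn_mean_{i}"].astype(np.float32)
            bn.running_var = state[f"bn_var_{i}"].astype(np.float32)


def build_network(config: NetConfig | None = None) -> MobileFCN:
    """Construct the segmentation network for the given configuration."""
    return MobileFCN(config or NetConfig())


def lr_at(step: int, config: TrainConfig) -> float:
    """Stepwise-halved learning rate,
    ``base_lr * 0.5 ** max(0, floor(step / interval) - delay)``."""
    if step < 0:
        raise ValueError("step must be non-negative")
    exponent = max(0, step // config.lr_halving_interval - config.lr_delay)
    return config.base_lr * 0.5**exponent


def epochs(total_steps: int, n_train: int, batch: int) -> int:
    """Number of epochs implied by a step budget: round(total_steps / (n_train / batch))."""
    if n_train <= 0 or batch <= 0:
        raise ValueError("n_train and batch must be positive")
    if total_steps < 0:
        raise ValueError("total_steps must be non-negative")
    return round(total_steps / (n_train / batch))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_pair(item) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(item, "image") and hasattr(item, "wound_mask"):
        return np.asarray(item.image), np.asarray(item.wound_mask)
    image, mask = item
    return np.asarray(image), np.asarray(mask).astype(bool)


def _to_batch(pairs: list[tuple[np.ndarray, np.ndarray]]):
    x = np.stack([standardize(img).transpose(2, 0, 1) for img, _ in pairs]).astype(np.float32)
    y = np.stack([mask for _, mask in pairs]).astype(np.int64)
    return x, y


def _pooled_test_iou(network: MobileFCN, test_pairs) -> float:
    counts = None
    for img, mask in test_pairs:
        prob = segment(network, img)
        c = confusion(prob >= 0.5, mask)
        counts = c if counts is None else tuple(a + b for a, b in zip(counts, c))
    value = iou(counts)
    return float("nan") if value is None else value


def train(
    network: MobileFCN,
    group,
    config: TrainConfig,
    augment_training_data: bool = True,
):
    """Train the network on a dataset group.

    Training images are expanded by the deformation/cropping augmentation
    (cropped at the network input size), standardized per image and fed to
    Adam under the halving learning-rate schedule with decoupled weight decay.
    Pooled test IoU is logged every ``config.eval_interval`` steps.

    Returns ``(network, log)`` where ``log`` has the per-step loss trajectory
    and the test-IoU series.
    """
    train_pairs = [_as_pair(item) for item in group.train]
    test_pairs = [_as_pair(item) for item in group.test]
    if not train_pairs:
        raise ValueError("empty training set")
    size = network.config.input_size
    if augment_training_data:
        expanded: list[tuple[np.ndarray, np.ndarray]] = []
        for i, (img, mask) in enumerate(train_pairs):
            cfg = AugmentConfig(crop_size=size, seed=config.seed * 100003 + i)
            expanded.extend(augment_pairs(img, mask, cfg))
        train_pairs = expanded
    rng = np.random.default_rng(config.seed)
    optimizer = _nn.Adam(network.params, lr=config.base_lr,
                         weight_decay=config.weight_decay)
    log = {"steps": [], "loss": [], "eval_steps": [], "test_iou": []}
    for step in range(config.total_steps):
        idx = rng.integers(0, len(train_pairs), size=config.batch_size)
        x, y = _to_batch([train_pairs[i] for i in idx])
        logits = network.forward(x, training=True)
        loss, dlogits = _nn.softmax_cross_entropy(logits, y)
        optimizer.zero_grad()
        network.backward(dlogits)
        optimizer.lr = lr_at(step, config)
        optimizer.step()
        log["steps"].append(step)
        log["loss"].append(loss)
        if test_pairs and ((step + 1) % config.eval_interval == 0
                           or step == config.total_steps - 1):
            log["eval_steps"].append(step + 1)
            log["test_iou"].append(_pooled_test_iou(network, test_pairs))
    return network, log


def segment(network: MobileFCN, image: np.ndarray) -> np.ndarray:
    """Per-pixel wound probability for one RGB image.

    The image is standardized internally and reflect-padded to a multiple of
    32 if needed; the returned probability map matches the input resolution.
    """
    img = np.asarray(image)
    x = standardize(img).transpose(2, 0, 1)[None].astype(np.float32)
    h, w = x.shape[2], x.shape[3]
    ph = (-h) % 32
    pw = (-w) % 32
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    logits = network.forward(x, training=False)
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    prob = ez[:, 1] / ez.sum(axis=1)
    return prob[0, :h, :w].astype(np.float64)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(network: MobileFCN, path: str) -> None:
    """Serialize weights + running statistics + config to an .npz file."""
    state = network.state_arrays()
    state["config_json"] = np.frombuffer(
        json.dumps(asdict(network.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path: str) -> MobileFCN:
    data = np.load(path)
    config = NetConfig(**json.loads(bytes(data["config_json"]).decode()))
    network = MobileFCN(config)
    network.load_state_arrays({k: data[k] for k in data.files if k != "config_json"})
    return network
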