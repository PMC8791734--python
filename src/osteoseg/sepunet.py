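"""Depthwise-separable U-Net (SepUNet), rotation ensembling, and its trainer.

The segmentation model is a U-shaped fully convolutional network.  Each of the
four encoder levels is a DoubleConv (two 3x3 conv + batch-norm + ReLU) followed
by a SeparableBlock (depthwise 3x3 convolution then pointwise 1x1 convolution,
with batch-norm + ReLU); 3x3/stride-2 max pooling sits between levels.  The
four decoder levels upsample by bilinear x2 interpolation, concatenate the
same-level encoder features (skip connection) and apply a DoubleConv; a final
1x1 convolution with a sigmoid yields a per-pixel tumor probability map.
Depthwise-separable convolutions spend C*k*k + C*C' weights where a plain
convolution spends C*C'*k*k, buying depth at fixed parameter cost.

At inference the slice is additionally presented rotated by 90/180/270
degrees; the four probability maps are rotated back and combined as a weighted
average with weights (a0, a1, a2, a3), sum 1, default (0.4, 0.2, 0.2, 0.2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .metrics import LossConfig, total_loss_t

__all__ = [
    "SepUNetConfig",
    "SepUNet",
    "EnsembleWeights",
    "ProbabilityMap",
    "TrainSchedule",
    "build_model",
    "predict",
    "rotation_ensemble",
    "train_segmentation",
    "save_model",
    "load_model",
]


@dataclass
class SepUNetConfig:
    base_channels: int = 16  # doubled at each of the 4 encoder levels
    depth: int = 4

    def validate(self) -> None:
        if self.depth != 4:
            raise ValueError("this U-Net is fixed at 4 encoder/decoder levels")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")


@dataclass
class EnsembleWeights:
    a0: float = 0.4
    a1: float = 0.2
    a2: float = 0.2
    a3: float = 0.2

    def validate(self) -> None:
        w = (self.a0, self.a1, self.a2, self.a3)
        if any(x < 0 for x in w):
            raise ValueError("ensemble weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("ensemble weights must sum to 1")

    def as_tuple(self) -> tuple:
        return (self.a0, self.a1, self.a2, self.a3)


@dataclass
class ProbabilityMap:
    values: np.ndarray  # (H, W) in [0, 1]
    spacing: float = 1.0  # mm per pixel


@dataclass
class TrainSchedule:
    """Adam schedule: constant initial lr, a hard drop at a fixed epoch
    fraction, then cosine annealing over the tail (the full-scale recipe drops
    0.001 -> 0.0001 at epoch 200 of 300)."""

    epochs: int = 300
    lr_initial: float = 1e-3
    lr_after_drop: float = 1e-4
    drop_fraction: float = 200.0 / 300.0
    batch_size: int = 8

    def lr_at(self, epoch: int) -> float:
        drop = int(round(self.drop_fraction * self.epochs))
        if epoch < drop or self.epochs <= drop:
            return self.lr_initial
        tail = self.epochs - drop
        t = (epoch - drop) / max(tail - 1, 1)
        return self.lr_after_drop * 0.5 * (1.0 + np.cos(np.pi * t))


class _DoubleConv(nn.Module):
    def __init__(self, cin: int, cout: int, rng):
        self.c1 = nn.Conv2d(cin, cout, 3, rng)
        self.b1 = nn.BatchNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, 3, rng)
        self.b2 = nn.BatchNorm2d(cout)

    def __call__(self, x):
        return self.b2(self.c2(self.b1(self.c1(x)).relu())).relu()


class _SeparableBlock(nn.Module):
    def __init__(self, ch: int, rng):
        self.dw = nn.DepthwiseConv2d(ch, 3, rng)
        self.pw = nn.Conv2d(ch, ch, 1, rng)
        self.bn = nn.BatchNorm2d(ch)

    def __call__(self, x):
        return self.bn(self.pw(self.dw(x))).relu()


class SepUNet(nn.Module):
    def __init__(self, config: SepUNetConfig, seed: int):
        config.validate()
        rng = np.random.default_rng(seed)
        self.config = config
        c = config.base_channels
        enc_ch = [c, 2 * c, 4 * c, 8 * c]
        self.enc = []
        cin = 1
        for co in enc_ch:
            self.enc.append(_DoubleConv(cin, co, rng))
            self.enc.append(_SeparableBlock(co, rng))
            cin = co
        self.bottleneck = _DoubleConv(enc_ch[-1], 16 * c, rng)
        self.dec = []
        cprev = 16 * c
        for co in reversed(enc_ch):
            self.dec.append(_DoubleConv(cprev + co, co, rng))
            cprev = co
        self.head = nn.Conv2d(enc_ch[0], 1, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) with H, W divisible by 16 -> (N, 1, H, W) in (0, 1)."""
        skips = []
        h = x
        for i in range(4):
            h = self.enc[2 * i](h)
            h = self.enc[2 * i + 1](h)
            skips.append(h)
            h = nn.maxpool2d_3s2(h)
        h = self.bottleneck(h)
        for i, dc in enumerate(self.dec):
            h = nn.upsample_bilinear2x(h)
            h = nn.concat([skips[3 - i], h], axis=1)
            h = dc(h)
        return self.head(h).sigmoid()


def build_model(config: SepUNetConfig | None = None, seed: int = 0) -> SepUNet:
    """Deterministically initialized SepUNet for the given seed."""
    return SepUNet(config or SepUNetConfig(), seed)


def _prep_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float) / 255.0
    return (img - img.mean()) / (img.std() + 1e-8)


def _pad_to_16(img: np.ndarray) -> tuple:
    H, W = img.shape
    ph, pw = (-H) % 16, (-W) % 16
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img, (H, W)


def predict(model: SepUNet, image: np.ndarray, spacing: float = 1.0) -> ProbabilityMap:
    """Forward pass in inference mode; pads to a multiple of 16 and un-pads."""
    img, (H, W) = _pad_to_16(_prep_image(image))
    model.set_training(False)
    out = model(Tensor(img[None, None]))
    return ProbabilityMap(values=out.data[0, 0, :H, :W], spacing=spacing)


def rotation_ensemble(
    model,
    image: np.ndarray,
    weights: EnsembleWeights | None = None,
    spacing: float = 1.0,
    predict_fn=None,
) -> ProbabilityMap:
    """Weighted average of predictions under the four 90-degree rotations.

    The slice is rotated by 90k degrees counter-clockwise, predicted, and the
    probability map rotated back before pixelwise averaging, so the output
    grid always matches the input grid (non-square slices included).
    ``predict_fn(image) -> (H', W') array`` may replace the model forward pass.
    """
    weights = weights or EnsembleWeights()
    weights.validate()
    fn = predict_fn if predict_fn is not None else (
        lambda im: predict(model, im, spacing).values
    )
    acc = np.zeros(np.asarray(image).shape, dtype=float)
    for k, a in enumerate(weights.as_tuple()):
        if a == 0.0:
            continue
        pk = fn(np.ascontiguousarray(np.rot90(image, k)))
        acc += a * np.rot90(pk, -k)
    return ProbabilityMap(values=acc, spacing=spacing)


def train_segmentation(
    model: SepUNet,
    train_set,
    loss_cfg: LossConfig | None = None,
    schedule: TrainSchedule | None = None,
    seed: int = 0,
    curation_order=None,
    us_count: int | None = None,
) -> SepUNet:
    """Minimize the compound BCE+Dice loss with Adam under the drop+cosine
    schedule.  ``train_set`` is a list of objects with ``.image`` and ``.mask``
    (phantom samples qualify).  When ``curation_order`` (US-first slice indices)
    is given, the first half of the epochs trains on the US prefix only, then
    the full set joins — simple samples first.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    loss_cfg = loss_cfg or LossConfig()
    loss_cfg.validate()
    schedule = schedule or TrainSchedule()
    if schedule.epochs == 0:
        return model
    rng = np.random.default_rng(seed)

    imgs = np.stack([_pad_to_16(_prep_image(s.image))[0] for s in train_set])[:, None]
    msks = np.stack([_pad_to_16(np.asarray(s.mask, dtype=float))[0] for s in train_set])[
        :, None
    ]

    opt = nn.Adam(model.parameters(), lr=schedule.lr_initial)
    history = []
    for epoch in range(schedule.epochs):
        opt.lr = schedule.lr_at(epoch)
        if curation_order is not None and epoch < schedule.epochs // 2:
            n_easy = us_count if us_count else max(1, len(curation_order) // 2)
            pool = np.asarray(curation_order)[: max(1, n_easy)]
        else:
            pool = np.arange(len(train_set))
        perm = rng.permutation(pool)
        epoch_loss, nb = 0.0, 0
        model.set_training(True)
        for b in range(0, len(perm), schedule.batch_size):
            idx = perm[b : b + schedule.batch_size]
            prob = model(Tensor(imgs[idx]))
            loss = total_loss_t(prob, msks[idx], loss_cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            nb += 1
        history.append(epoch_loss / max(nb, 1))
    model.loss_history = history
    return model


def save_model(model: SepUNet, path) -> None:
    """Single-file checkpoint: config JSON + flat parameter arrays."""
    arrays = model.state_arrays()
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(asdict(model.config)).encode(), dtype=np.uint8
        ),
        **{f"a{i}": a for i, a in enumerate(arrays)},
    )


def load_model(path) -> SepUNet:
    with np.load(path) as z:
        cfg = SepUNetConfig(**json.loads(bytes(z["__config__"].tobytes()).decode()))
        model = SepUNet(cfg, seed=0)
        n = len(model.state_arrays())
        model.load_state_arrays([z[f"a{i}"] for i in range(n)])
    return model
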