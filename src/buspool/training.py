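"""Dataset assembly, augmentation and seeded training of the frame classifier.

The training recipe mirrors the study conditions: Adam with beta1 = 0.5,
beta2 = 0.99, starting learning rate 1e-4, batch size 2, cross-entropy
loss.  Augmentation is applied offline, the way the study expanded its
training set: the original frames are kept and ``augment_copies``
stochastically augmented copies of each are appended before training.
The stack applies horizontal flipping (p = 0.5), 90 degree rotation,
isotropic rescaling by +/-20% with crop/pad restore, median blurring, and
contrast-limited adaptive histogram equalization (clip limit 4.0, 8x8
tiles).

Splits are always made per sequence, never per frame: frames within one
scan are near-duplicates and a frame-level split would leak between train
and test.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import exposure

from .convnext import CLASS_NAMES, ConvNeXt, softmax
from .frame_io import Frame, resize_bilinear
from .nn.optim import Adam


@dataclass(frozen=True)
class AugmentConfig:
    hflip_prob: float = 0.5
    rot90_prob: float = 0.5
    scale_fraction: float = 0.2
    median_kernel: int = 3
    clahe_clip: float = 4.0
    clahe_tiles: Tuple[int, int] = (8, 8)
    per_op_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.99
    batch_size: int = 2
    epochs: int = 40
    input_size: int = 224
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    augment_enabled: bool = True
    augment_copies: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.beta1 < 1.0 or not 0.0 < self.beta2 < 1.0:
            raise ValueError("beta1 and beta2 must lie strictly in (0, 1)")


@dataclass
class LabelledFrames:
    """A flat collection of frames with 0/1 labels (benign = 0, malignant = 1)."""

    pixels: np.ndarray  # (n, S, S), 0-255 scale
    labels: np.ndarray  # (n,), int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.pixels.shape[0] != self.labels.shape[0]:
            raise ValueError("pixels and labels disagree in length")

    def __len__(self) -> int:
        return int(self.labels.shape[0])


def frames_from_sequences(sequences) -> LabelledFrames:
    """Flatten labelled BUS sequences into a frame-level training collection."""
    stacks, labels = [], []
    for seq in sequences:
        if seq.label not in CLASS_NAMES:
            raise ValueError(f"sequence {seq.sequence_id!r} has no benign/malignant label")
        y = CLASS_NAMES.index(seq.label)
        for frame in seq:
            stacks.append(frame.pixels)
            labels.append(y)
    if not stacks:
        raise ValueError("no frames found in the given sequences")
    return LabelledFrames(np.stack(stacks), np.array(labels))


def expand_with_augmented(data: LabelledFrames, config: AugmentConfig,
                          copies: int, rng: np.random.Generator) -> LabelledFrames:
    """Offline dataset expansion: originals plus `copies` augmented copies each."""
    if copies < 1:
        return data
    stacks = [data.pixels]
    labels = [data.labels]
    for _ in range(copies):
        stacks.append(np.stack([augment(im, config, rng) for im in data.pixels]))
        labels.append(data.labels)
    return LabelledFrames(np.concatenate(stacks), np.concatenate(labels))


def cross_entropy(gt: Sequence[float], p: Sequence[float], eps: float = 1e-12) -> float:
    """Cross-entropy -sum(gt_i * log(p_i)), natural log, p clipped to [eps, 1]."""
    gt = np.asarray(gt, dtype=float)
    p = np.asarray(p, dtype=float)
    if gt.shape != p.shape:
        raise ValueError(f"gt and p dimension mismatch: {gt.shape} vs {p.shape}")
    return float(-(gt * np.log(np.clip(p, eps, 1.0))).sum())


# -- augmentation ------------------------------------------------------------

def _rescale_crop_pad(pixels: np.ndarray, factor: float) -> np.ndarray:
    """Isotropic rescale then center-crop (or zero-pad) back to original size."""
    h, w = pixels.shape
    nh = max(8, int(round(h * factor)))
    scaled = resize_bilinear(pixels, nh)
    if nh == h:
        return scaled
    if nh > h:
        off = (nh - h) // 2
        return scaled[off : off + h, off : off + w]
    out = np.zeros_like(pixels)
    off = (h - nh) // 2
    out[off : off + nh, off : off + nh] = scaled
    return out


def _clahe(pixels: np.ndarray, clip: float, tiles: Tuple[int, int]) -> np.ndarray:
    """CLAHE on the 0-255 scale; clip limit uses the 256-bin convention
    (a clip of 4.0 maps to skimage's normalized clip_limit 4/256)."""
    h, w = pixels.shape
    kernel = (max(1, h // tiles[0]), max(1, w // tiles[1]))
    eq = exposure.equalize_adapthist(
        np.clip(pixels, 0, 255).astype(np.uint8),
        kernel_size=kernel,
        clip_limit=clip / 256.0,
    )
    return eq * 255.0


def augment(pixels, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply the stochastic augmentation stack to one frame.

    Output has the input's dimensions and stays on the [0, 255] scale.
    Fully deterministic given the random generator state.
    """
    out = np.asarray(pixels.pixels if isinstance(pixels, Frame) else pixels, dtype=float)
    if rng.random() < config.hflip_prob:
        out = out[:, ::-1]
    if rng.random() < config.rot90_prob:
        out = np.rot90(out)
    if rng.random() < config.per_op_prob and config.scale_fraction > 0:
        factor = rng.uniform(1.0 - config.scale_fraction, 1.0 + config.scale_fraction)
        out = _rescale_crop_pad(np.ascontiguousarray(out), factor)
    if rng.random() < config.per_op_prob:
        out = ndimage.median_filter(out, size=config.median_kernel, mode="reflect")
    if rng.random() < config.per_op_prob:
        out = _clahe(out, config.clahe_clip, config.clahe_tiles)
    return np.clip(np.ascontiguousarray(out), 0.0, 255.0)


# -- training loop -----------------------------------------------------------

@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_accuracy: float


def evaluate_accuracy(model: ConvNeXt, data: LabelledFrames, batch_size: int = 16) -> float:
    x = data.pixels[:, :, :, None] / 255.0
    correct = 0
    for i in range(0, len(data), batch_size):
        logits = model.forward(x[i : i + batch_size])
        correct += int((logits.argmax(axis=1) == data.labels[i : i + batch_size]).sum())
    return correct / len(data)


def train(
    model: ConvNeXt,
    train_set: LabelledFrames,
    val_set: LabelledFrames,
    config: TrainConfig,
) -> Tuple[ConvNeXt, List[EpochRecord]]:
    """Adam cross-entropy training; returns the best-validation model and history.

    Deterministic given ``config.seed``: minibatch order and augmentation
    draws come from one seeded generator.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation splits must both be non-empty")
    rng = np.random.default_rng(config.seed)
    if config.augment_enabled:
        train_set = expand_with_augmented(train_set, config.augment, config.augment_copies, rng)
    opt = Adam(model.params(), lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2)

    history: List[EpochRecord] = []
    best_state = model.state_dict()
    best_acc = -1.0
    n = len(train_set)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = train_set.pixels[idx][:, :, :, None] / 255.0
            y = train_set.labels[idx]
            logits = model.forward(x)
            p = softmax(logits)
            onehot = np.eye(model.config.num_classes)[y]
            loss = float(np.mean([cross_entropy(onehot[i], p[i]) for i in range(len(y))]))
            losses.append(loss)
            opt.zero_grad()
            model.backward((p - onehot) / len(y))
            opt.step()
        val_acc = evaluate_accuracy(model, val_set)
        history.append(EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)), val_accuracy=val_acc))
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = copy.deepcopy(model.state_dict())
    model.load_state_dict(best_state)
    return model, history
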