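"""From-scratch ConvNeXt image classifier for benign/malignant frame scoring.

The network follows the modernized-ResNet design: a *patchify* stem (4x4
convolution with stride 4, then LayerNorm), four stages of residual blocks
(depthwise 7x7 -> LayerNorm -> 1x1 expand -> GELU -> 1x1 project) with a
stage-compute-ratio of (3, 4, 6, 3), separate downsampling layers between
stages (LayerNorm then 2x2 stride-2 convolution), and a head of global
average pooling -> LayerNorm -> linear classifier.  For a 224x224 input the
stage feature maps are 56, 28, 14 and 7 pixels square.

Everything runs on numpy arrays; see :mod:`buspool.nn` for the layer
implementations and the finite-difference tests validating their gradients.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .frame_io import Frame
from .nn.layers import (
    ConvNeXtBlock,
    GlobalAvgPool,
    LayerNorm,
    Linear,
    PatchConv,
)

CHECKPOINT_VERSION = 1

#: class index convention used throughout: benign = 0, malignant = 1
CLASS_NAMES = ("benign", "malignant")


@dataclass(frozen=True)
class ConvNeXtConfig:
    stage_depths: Tuple[int, int, int, int] = (3, 4, 6, 3)
    stage_widths: Tuple[int, int, int, int] = (96, 192, 384, 768)
    patch_size: int = 4
    patch_stride: int = 4
    dw_kernel: int = 7
    expansion_ratio: int = 4
    num_classes: int = 2
    norm_epsilon: float = 1e-6
    gelu_mode: str = "exact"
    input_size: int = 224

    def __post_init__(self) -> None:
        if self.dw_kernel % 2 == 0:
            raise ValueError("dw_kernel must be odd")
        if self.patch_size != self.patch_stride:
            raise ValueError("patchify layer is non-overlapping: patch_size must equal patch_stride")
        if self.input_size % (self.patch_stride * 8) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by "
                f"patch_stride * 8 = {self.patch_stride * 8} (three stride-2 downsamplings)"
            )
        if self.gelu_mode not in ("exact", "tanh"):
            raise ValueError(f"unknown gelu_mode {self.gelu_mode!r}")
        if len(self.stage_depths) != 4 or len(self.stage_widths) != 4:
            raise ValueError("stage_depths and stage_widths must each have 4 entries")

    @property
    def stage_sizes(self) -> Tuple[int, int, int, int]:
        s = self.input_size // self.patch_stride
        return (s, s // 2, s // 4, s // 8)


#: desk-scale preset for tests and the synthetic end-to-end experiment
TINY_WIDTHS = (16, 32, 64, 128)


def tiny_config(input_size: int = 64, **overrides) -> ConvNeXtConfig:
    """The tiny test preset: full (3,4,6,3) depth at widths (16,32,64,128)."""
    kwargs = dict(stage_widths=TINY_WIDTHS, input_size=input_size)
    kwargs.update(overrides)
    return ConvNeXtConfig(**kwargs)


class ConvNeXt:
    """ConvNeXt classifier with manual forward/backward passes.

    ``forward`` returns logits (benign, malignant).  ``backward`` propagates
    a logit gradient through the whole network, accumulating parameter
    gradients; it can optionally capture the gradient at the stage-4 output
    (the hook point for Grad-CAM).
    """

    def __init__(self, config: ConvNeXtConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        eps = c.norm_epsilon

        self.stem = [
            PatchConv(1, c.stage_widths[0], c.patch_size, rng, name="stem.conv"),
            LayerNorm(c.stage_widths[0], eps, name="stem.ln"),
        ]
        self.stages = []
        self.downsamples = []
        for s in range(4):
            blocks = [
                ConvNeXtBlock(
                    c.stage_widths[s],
                    rng,
                    dw_kernel=c.dw_kernel,
                    expansion_ratio=c.expansion_ratio,
                    epsilon=eps,
                    gelu_mode=c.gelu_mode,
                    name=f"stage{s + 1}.block{b}",
                )
                for b in range(c.stage_depths[s])
            ]
            self.stages.append(blocks)
            if s < 3:
                self.downsamples.append(
                    [
                        LayerNorm(c.stage_widths[s], eps, name=f"down{s + 1}.ln"),
                        PatchConv(c.stage_widths[s], c.stage_widths[s + 1], 2, rng, name=f"down{s + 1}.conv"),
                    ]
                )
        self.head = [
            GlobalAvgPool(),
            LayerNorm(c.stage_widths[3], eps, name="head.ln"),
            Linear(c.stage_widths[3], c.num_classes, rng, name="head.fc"),
        ]
        # flat forward-order layer list, with the index just past stage 4
        self._layers = list(self.stem)
        for s in range(4):
            self._layers.extend(self.stages[s])
            if s < 3:
                self._layers.extend(self.downsamples[s])
        self._stage4_end = len(self._layers)
        self._layers.extend(self.head)
        self.stage4_output: Optional[np.ndarray] = None
        #: identifier of the Grad-CAM hook point (last conv output of stage 4)
        self.gradcam_layer_id = f"stage4.block{c.stage_depths[3] - 1}.pw2+residual"

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        return [p for layer in self._layers for p in layer.params()]

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def state_dict(self) -> dict:
        return {p.name: p.data.copy() for p in self.params()}

    def load_state_dict(self, state: dict) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"checkpoint is missing parameter {p.name}")
            if state[p.name].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {p.name}: checkpoint {state[p.name].shape} vs model {p.data.shape}"
                )
            p.data = np.asarray(state[p.name], dtype=float).copy()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, S, S, 1) scaled to [0, 1] -> logits (batch, num_classes)."""
        if x.ndim != 4 or x.shape[1] != self.config.input_size or x.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected input of shape (n, {self.config.input_size}, {self.config.input_size}, 1), got {x.shape}"
            )
        h = x
        for i, layer in enumerate(self._layers):
            h = layer.forward(h)
            if i == self._stage4_end - 1:
                self.stage4_output = h
        return h

    def backward(self, dlogits: np.ndarray, capture_stage4: bool = False):
        """Backpropagate a logit gradient; returns the captured stage-4
        activation gradient when requested (else the input gradient)."""
        g = dlogits
        for i in reversed(range(len(self._layers))):
            g = self._layers[i].backward(g)
            if capture_stage4 and i == self._stage4_end:
                return g
        return g

    # -- inference ----------------------------------------------------------
    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def frame_to_input(frame) -> np.ndarray:
    """Frame (or 2-D array, 0-255) -> network input batch (1, S, S, 1) in [0, 1]."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    return pixels[None, :, :, None] / 255.0


def predict_frame(model: ConvNeXt, frame) -> float:
    """Softmax probability of the malignant class for one frame."""
    x = frame_to_input(frame)
    s = model.config.input_size
    if x.shape[1] != s or x.shape[2] != s:
        raise ValueError(f"frame size {x.shape[1:3]} does not match model input size {s}")
    return float(model.predict_proba(x)[0, 1])


def batch_predict(model: ConvNeXt, pixel_stack: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Malignant-class probabilities for a stack of frames (n, S, S) in 0-255."""
    x = np.asarray(pixel_stack, dtype=float)[:, :, :, None] / 255.0
    out = []
    for i in range(0, x.shape[0], batch_size):
        out.append(model.predict_proba(x[i : i + batch_size])[:, 1])
    return np.concatenate(out) if out else np.empty(0)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: ConvNeXt, path) -> None:
    """Single-file .npz checkpoint: weights + embedded config + version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.config)}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ConvNeXt:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg_dict = meta["config"]
        cfg_dict["stage_depths"] = tuple(cfg_dict["stage_depths"])
        cfg_dict["stage_widths"] = tuple(cfg_dict["stage_widths"])
        config = ConvNeXtConfig(**cfg_dict)
        model = ConvNeXt(config, seed=0)
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model
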