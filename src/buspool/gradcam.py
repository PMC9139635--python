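"""Grad-CAM visual explanations for the frame classifier.

For a target class c with pre-softmax score y_c and feature-map
activations A^k at the hooked convolutional layer, the neuron importance
weights are the global-average-pooled gradients

    beta_k = (1/Z) * sum_ij  d y_c / d A^k_ij

and the localization map is the ReLU of their weighted combination

    M = ReLU( sum_k beta_k * A^k ).

The map lives at the hooked layer's spatial resolution (stage 4: input/32)
and is bilinearly upsampled onto the input frame for overlay rendering.
Gradients are taken from the pre-softmax logit, not the probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .convnext import CLASS_NAMES, ConvNeXt, frame_to_input
from .frame_io import Frame, resize_bilinear


@dataclass
class GradCamMap:
    """Non-negative localization map at the hooked layer's resolution."""

    values: np.ndarray
    target_class: str
    layer_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grad-CAM map must be 2-D")
        if (self.values < 0).any():
            raise ValueError("Grad-CAM map values must be non-negative")

    def upsampled(self, size: int) -> np.ndarray:
        """Bilinear upsampling of the raw map to size x size."""
        v = self.values
        lo, hi = v.min(), v.max()
        scale = hi - lo if hi > lo else 1.0
        up = resize_bilinear((v - lo) / scale * 255.0, size) / 255.0
        return up * scale + lo


def neuron_importance(gradients: np.ndarray) -> np.ndarray:
    """Per-channel global average pooling of the gradients: beta_k."""
    g = np.asarray(gradients, dtype=float)
    if g.ndim != 3 or g.size == 0:
        raise ValueError(f"expected non-empty (channels, i, j) gradients, got shape {g.shape}")
    return g.mean(axis=(1, 2))


def gradcam_map(activations: np.ndarray, weights: np.ndarray, target_class: str = "malignant",
                layer_id: str = "") -> GradCamMap:
    """ReLU of the beta-weighted combination of activation maps."""
    a = np.asarray(activations, dtype=float)
    w = np.asarray(weights, dtype=float)
    if a.ndim != 3:
        raise ValueError(f"expected (channels, u, v) activations, got shape {a.shape}")
    if a.shape[0] != w.shape[0]:
        raise ValueError(f"channel mismatch: {a.shape[0]} activations vs {w.shape[0]} weights")
    combined = np.einsum("k,kuv->uv", w, a)
    return GradCamMap(values=np.maximum(combined, 0.0), target_class=target_class, layer_id=layer_id)


def model_activations_and_gradients(model: ConvNeXt, frame, target_class: str):
    """Stage-4 activations A^k and gradients d y_c / d A^k for one frame."""
    if target_class not in CLASS_NAMES:
        raise ValueError(f"unknown class {target_class!r}; expected one of {CLASS_NAMES}")
    x = frame_to_input(frame)
    logits = model.forward(x)
    dlogits = np.zeros_like(logits)
    dlogits[0, CLASS_NAMES.index(target_class)] = 1.0
    grad = model.backward(dlogits, capture_stage4=True)
    # stage-4 activations are stored channels-last; Grad-CAM uses (k, u, v)
    return model.stage4_output[0].transpose(2, 0, 1), grad[0].transpose(2, 0, 1)


def explain_frame(model, frame, target_class: str = "malignant") -> GradCamMap:
    """Grad-CAM map for one frame.

    ``model`` is either a :class:`ConvNeXt` or any object exposing
    ``activations_and_gradients(frame, target_class) -> (A, dA)`` with
    channels-first 3-D arrays (used for contrived scorers in validation).
    """
    if isinstance(model, ConvNeXt):
        acts, grads = model_activations_and_gradients(model, frame, target_class)
        layer_id = model.gradcam_layer_id
    else:
        acts, grads = model.activations_and_gradients(frame, target_class)
        layer_id = getattr(model, "layer_id", "custom")
    beta = neuron_importance(grads)
    return gradcam_map(acts, beta, target_class=target_class, layer_id=layer_id)


def render_overlay(frame, cam: GradCamMap, out_path, malignancy_score=None,
                   colormap: str = "jet", alpha: float = 0.4) -> None:
    """Save a heat overlay PNG: red = high contribution, blue = low.

    The map is min-max normalized per image for display only; raw values
    stay available on the GradCamMap.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    up = cam.upsampled(pixels.shape[0])
    lo, hi = up.min(), up.max()
    display = (up - lo) / (hi - lo) if hi > lo else np.zeros_like(up)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(pixels, cmap="gray", vmin=0, vmax=255)
    ax.imshow(display, cmap=colormap, alpha=alpha, vmin=0, vmax=1)
    if malignancy_score is not None:
        ax.text(
            0.02, 0.98, f"S_M = {malignancy_score:.3f}",
            transform=ax.transAxes, va="top", color="white", fontsize=11,
            bbox=dict(facecolor="black", alpha=0.6, pad=2),
        )
    ax.set_axis_off()
    fig.savefig(out_path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def save_map_matrix(cam: GradCamMap, out_path) -> None:
    """Write the raw (non-upsampled) map as a plain-text matrix."""
    header = f"target_class={cam.target_class} layer={cam.layer_id} shape={cam.values.shape}"
    np.savetxt(out_path, cam.values, header=header)
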