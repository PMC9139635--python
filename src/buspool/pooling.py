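"""Quality-gated pooling of per-frame malignancy scores.

The sequence-level malignancy score is the mean of the per-frame scores
over the frames that pass the quality gate:

    S_M = (1 / N_q) * sum_i w_i * s_i

where ``s_i`` is frame i's malignancy score, ``w_i`` in {0, 1} is its
quality gate and ``N_q = sum_i w_i``.  A sequence is called malignant when
``S_M >= threshold`` (default 0.5).

When every frame fails the gate (N_q = 0) the formula is undefined; the
pooled score falls back to the unweighted mean over all frames and the
result is flagged ``low_confidence``.  Results whose pooled score lies
within a small margin of the decision threshold are likewise flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .frame_io import BUSSequence
from .quality import QualityThresholds, assess_frame

#: |S_M - threshold| below this margin flags the decision as low-confidence.
DEFAULT_CONFIDENCE_MARGIN = 0.05


@dataclass
class MalignancyResult:
    """Per-frame scores, gates and the pooled sequence-level decision."""

    frame_scores: list
    gates: list
    pooled_score: float
    threshold: float
    predicted_label: str
    low_confidence: bool
    sequence_id: str = ""
    brightness: Optional[list] = None
    blurriness: Optional[list] = None
    settings: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frame_scores)

    @property
    def n_quality(self) -> int:
        return int(sum(self.gates))


def pool_malignancy(frame_scores: Sequence[float], gates: Sequence[int]) -> float:
    """Pooled malignancy score S_M = (1/N_q) * sum(w_i * s_i).

    With N_q = 0 the gated mean is undefined; the unweighted mean of all
    frame scores is returned instead (callers should flag low confidence,
    see :func:`score_sequence`).
    """
    scores = np.asarray(frame_scores, dtype=float)
    w = np.asarray(gates, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot pool an empty score list")
    if scores.shape != w.shape:
        raise ValueError(f"scores and gates length mismatch: {scores.shape} vs {w.shape}")
    n_q = w.sum()
    if n_q == 0:
        return float(scores.mean())
    return float((w * scores).sum() / n_q)


def classify(pooled_score: float, threshold: float = 0.5) -> str:
    """Malignant iff pooled_score >= threshold (ties go to malignant)."""
    if not (0.0 <= pooled_score <= 1.0 and 0.0 <= threshold <= 1.0):
        raise ValueError("pooled_score and threshold must lie in [0, 1]")
    return "malignant" if pooled_score >= threshold else "benign"


def score_sequence(
    sequence: BUSSequence,
    scorer: Callable,
    thresholds: QualityThresholds = QualityThresholds(),
    threshold: float = 0.5,
    sigma: float = 1.0,
    quality_on_resized: bool = False,
    confidence_margin: float = DEFAULT_CONFIDENCE_MARGIN,
) -> MalignancyResult:
    """Run the full per-frame scoring + quality gating + pooling pipeline.

    ``scorer`` maps a Frame to a malignancy probability in [0, 1] (e.g.
    ``lambda f: predict_frame(model, f)``).
    """
    scores, gates, brightness, blurriness = [], [], [], []
    for frame in sequence:
        s = float(scorer(frame))
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"scorer returned {s} for frame {frame.index}; expected a value in [0, 1]")
        quality = assess_frame(frame, thresholds, sigma=sigma, on_resized=quality_on_resized)
        scores.append(s)
        gates.append(quality.gate)
        brightness.append(quality.brightness)
        blurriness.append(quality.blurriness)

    pooled = pool_malignancy(scores, gates)
    n_q = int(sum(gates))
    label = classify(pooled, threshold)
    low_confidence = (n_q == 0) or (abs(pooled - threshold) < confidence_margin)
    return MalignancyResult(
        frame_scores=scores,
        gates=gates,
        pooled_score=pooled,
        threshold=threshold,
        predicted_label=label,
        low_confidence=low_confidence,
        sequence_id=sequence.sequence_id,
        brightness=brightness,
        blurriness=blurriness,
        settings={
            "sigma": sigma,
            "quality_on_resized": quality_on_resized,
            "brightness_min": thresholds.brightness_min,
            "brightness_max": thresholds.brightness_max,
            "blur_min": thresholds.blur_min,
            "blur_max": thresholds.blur_max,
            "confidence_margin": confidence_margin,
        },
    )
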