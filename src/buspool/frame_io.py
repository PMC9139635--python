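"""Reading and writing breast-ultrasound (BUS) frame sequences and results.

A *sequence* is a directory of single-channel image files (PNG/TIFF/JPEG),
one file per frame, ordered by filename.  Frames are converted to grayscale
and resized to the classifier's working geometry (default 224x224); the
native-resolution pixels are retained on each :class:`Frame` because the
image-quality metrics are, by default, computed before resizing.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np
from PIL import Image

if TYPE_CHECKING:  # pragma: no cover
    from .pooling import MalignancyResult

VALID_LABELS = ("benign", "malignant")
IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

#: ITU-R BT.601 luminance weights used to collapse RGB-encoded frames.
LUMINANCE_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class Frame:
    """A single 2-D grayscale ultrasound frame.

    ``pixels`` holds the working-geometry image (float, 0-255 scale);
    ``original`` holds the native-resolution grayscale image when it differs
    from ``pixels`` (quality metrics default to the native frame).
    """

    pixels: np.ndarray
    index: int = 0
    source: Optional[str] = None
    original: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"frame pixels must be 2-D, got shape {self.pixels.shape}")
        if self.height < 8 or self.width < 8:
            raise ValueError(f"frame too small: {self.pixels.shape} (minimum 8x8)")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("frame intensities must lie in [0, 255]")
        if self.index < 0:
            raise ValueError("frame index must be non-negative")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def quality_pixels(self, on_resized: bool = False) -> np.ndarray:
        """Pixels on which the quality metrics should be evaluated."""
        if on_resized or self.original is None:
            return self.pixels
        return self.original


@dataclass
class BUSSequence:
    """An ordered series of same-sized frames for one patient/lesion."""

    frames: list
    sequence_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a BUS sequence needs at least one frame")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {VALID_LABELS}")
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have inconsistent shapes after loading: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class ManifestRow:
    sequence_directory: str
    label: str
    split: str


@dataclass
class Manifest:
    rows: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def subset(self, split: str) -> "Manifest":
        return Manifest([r for r in self.rows if r.split == split])


_NUM_RE = re.compile(r"(\d+)")


def natural_key(name: str):
    """Lexicographic sort key treating digit runs numerically (frame_2 < frame_10)."""
    return tuple(int(tok) if tok.isdigit() else tok for tok in _NUM_RE.split(name))


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[:, :, :3].astype(float) @ LUMINANCE_WEIGHTS
    raise ValueError(f"unsupported image shape {arr.shape}")


def resize_bilinear(pixels: np.ndarray, target_size: int) -> np.ndarray:
    """Resize a 2-D image to target_size x target_size by bilinear interpolation."""
    if pixels.shape == (target_size, target_size):
        return pixels.astype(float)
    img = Image.fromarray(pixels.astype(np.float32), mode="F")
    resized = img.resize((target_size, target_size), resample=Image.BILINEAR)
    return np.clip(np.asarray(resized, dtype=float), 0.0, 255.0)


def load_frame(path: Path, index: int, target_size: Optional[int]) -> Frame:
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except Exception as exc:
        raise ValueError(f"could not read frame file {path}: {exc}") from exc
    gray = np.clip(_to_grayscale(arr), 0.0, 255.0)
    if target_size is None or gray.shape == (target_size, target_size):
        return Frame(pixels=gray, index=index, source=str(path))
    resized = resize_bilinear(gray, target_size)
    return Frame(pixels=resized, index=index, source=str(path), original=gray)


def load_sequence(
    directory,
    target_size: Optional[int] = 224,
    sequence_id: Optional[str] = None,
    label: Optional[str] = None,
) -> BUSSequence:
    """Load every image file in *directory* as one BUS sequence.

    Frames are ordered by filename (natural sort), converted to grayscale by
    fixed luminance weights and resized to ``target_size`` square with
    bilinear interpolation.  Pass ``target_size=None`` to keep native
    resolution.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"sequence directory not found: {directory}")
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS),
        key=lambda p: natural_key(p.name),
    )
    if not files:
        raise ValueError(f"no frames: directory {directory} contains no readable image files")
    frames = [load_frame(p, i, target_size) for i, p in enumerate(files)]
    return BUSSequence(frames=frames, sequence_id=sequence_id or directory.name, label=label)


def load_manifest(csv_path) -> Manifest:
    """Read a sequence manifest CSV with columns sequence_directory,label,split."""
    import pandas as pd

    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    required = {"sequence_directory", "label", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {csv_path} is missing columns: {sorted(missing)}")
    rows = []
    for _, rec in df.iterrows():
        label = str(rec["label"]).strip().lower()
        if label not in VALID_LABELS:
            raise ValueError(f"unknown label {rec['label']!r} in manifest {csv_path}")
        split = str(rec["split"]).strip().lower()
        if split not in ("train", "val", "test"):
            raise ValueError(f"unknown split {rec['split']!r} in manifest {csv_path}")
        seq_dir = Path(str(rec["sequence_directory"]))
        if not seq_dir.is_absolute():
            seq_dir = csv_path.parent / seq_dir
        rows.append(ManifestRow(str(seq_dir), label, split))
    return Manifest(rows)


def result_to_dict(result: "MalignancyResult") -> dict:
    frames = []
    for i in range(result.n_frames):
        rec = {
            "index": i,
            "score": result.frame_scores[i],
            "gate": int(result.gates[i]),
        }
        if result.brightness is not None:
            rec["brightness"] = result.brightness[i]
        if result.blurriness is not None:
            rec["blurriness"] = result.blurriness[i]
        frames.append(rec)
    return {
        "sequence_id": result.sequence_id,
        "frames": frames,
        "summary": {
            "pooled_score": result.pooled_score,
            "n_frames": result.n_frames,
            "n_quality": result.n_quality,
            "threshold": result.threshold,
            "predicted_label": result.predicted_label,
            "low_confidence": bool(result.low_confidence),
        },
        "settings": dict(result.settings or {}),
    }


def write_result(result: "MalignancyResult", out_path) -> None:
    """Serialize a MalignancyResult as JSON (full floating-point precision)."""
    doc = result_to_dict(result)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_result(path) -> "MalignancyResult":
    """Inverse of :func:`write_result`; round-trips all scores bit-exactly."""
    from .pooling import MalignancyResult

    with open(path) as fh:
        doc = json.load(fh)
    frames = doc["frames"]
    summary = doc["summary"]
    return MalignancyResult(
        frame_scores=[f["score"] for f in frames],
        gates=[int(f["gate"]) for f in frames],
        pooled_score=summary["pooled_score"],
        threshold=summary["threshold"],
        predicted_label=summary["predicted_label"],
        low_confidence=bool(summary["low_confidence"]),
        sequence_id=doc.get("sequence_id", ""),
        brightness=[f.get("brightness") for f in frames] if frames and "brightness" in frames[0] else None,
        blurriness=[f.get("blurriness") for f in frames] if frames and "blurriness" in frames[0] else None,
        settings=doc.get("settings") or {},
    )
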