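"""Synthetic ultrasound-like phantom sequences for benign/malignant lesions.

The generator emulates the phenomenology of B-mode breast ultrasound that
the pipeline keys on, without claiming acoustic realism:

* a speckled background (multiplicative gamma noise, unit mean) overlaid
  with sparse bright point scatterers ("glints"): the glints carry the
  high-frequency content that puts the Laplacian-variance blurriness score
  of a sharp frame into its operating band while adding little to the mean
  brightness,
* a hypoechoic (darker) star-convex lesion: benign lesions are smooth,
  round-to-oval and mildly hypoechoic; malignant ones are irregular/
  spiculated, taller than wide (elongated), markedly hypoechoic and carry
  punctate echogenic foci (microcalcification-like bright dots) and a
  heterogeneous internal echotexture — the standard sonographic
  malignancy cues,
* quality-degrading artifacts: acoustic-shadow bands, motion blur and
  gain (over/under-amplification) errors.

Degradations scheduled by :func:`generate_sequence` are calibrated to
violate a default quality threshold (blur pushes the blurriness score
below its minimum; gain and deep shadow push brightness out of its band),
so the quality gate can be exercised end to end.  All calibration
constants live on :class:`PhantomConfig`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from .frame_io import BUSSequence, Frame, Manifest, ManifestRow
from .quality import QualityThresholds, assess_frame

DEGRADATIONS = ("blur", "gain", "shadow")


@dataclass(frozen=True)
class PhantomConfig:
    frame_size: int = 64
    background_mean: float = 18.0
    speckle_shape: float = 4.0
    glint_density: float = 0.040
    malignant_glint_density: float = 0.030
    glint_value: float = 255.0
    lesion_radius_range: Tuple[float, float] = (0.15, 0.3)
    lesion_contrast: float = -8.0
    malignant_contrast: float = -14.0
    foci_count_range: Tuple[int, int] = (8, 10)
    foci_radius: float = 2.0
    foci_value: float = 180.0
    heterogeneity_amplitude: float = 20.0
    heterogeneity_scale: float = 3.0
    spiculation_amplitude: float = 0.4
    benign_spiculation: float = 0.05
    n_spicules: int = 8
    benign_eccentricity_range: Tuple[float, float] = (0.8, 1.0)
    malignant_eccentricity_range: Tuple[float, float] = (0.4, 0.6)
    shadow_prob: float = 0.0
    blur_prob: float = 0.0
    gain_prob: float = 0.0
    blur_sigma: float = 3.0
    gain_range: Tuple[float, float] = (0.3, 2.5)
    # corruption calibration: draws guaranteed to break a default threshold
    corrupt_gain_low: Tuple[float, float] = (0.28, 0.35)
    corrupt_gain_high: Tuple[float, float] = (2.2, 2.5)
    shadow_attenuation: float = 0.05
    shadow_fraction: float = 0.7
    jitter_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_radius_range
        if not (0.0 < lo < hi < 0.5):
            raise ValueError("lesion_radius_range must satisfy 0 < lo < hi < 0.5")
        for p in (self.shadow_prob, self.blur_prob, self.gain_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("artifact probabilities must lie in [0, 1]")
        if not 0.0 <= self.background_mean <= 255.0:
            raise ValueError("background_mean must lie in [0, 255]")


@dataclass
class LesionGeometry:
    """Persistent per-sequence lesion anatomy (speckle is redrawn per frame)."""

    center: Tuple[float, float]
    radius: float  # pixels
    eccentricity: float
    angle: float
    spic_amplitude: float
    n_spicules: int
    spic_phase: float
    contrast: float
    foci: Tuple[Tuple[float, float], ...] = ()  # (r_frac, theta) inside the lesion


def sample_lesion_geometry(config: PhantomConfig, label: str, rng: np.random.Generator) -> LesionGeometry:
    if label not in ("benign", "malignant"):
        raise ValueError(f"unknown label {label!r}")
    s = config.frame_size
    lo, hi = config.lesion_radius_range
    radius = rng.uniform(lo, hi) * s
    margin = radius * (1.0 + config.spiculation_amplitude) + 2
    center = (
        rng.uniform(margin, s - margin) if s - 2 * margin > 0 else s / 2,
        rng.uniform(margin, s - margin) if s - 2 * margin > 0 else s / 2,
    )
    if label == "malignant":
        amp = config.spiculation_amplitude
        ecc_range = config.malignant_eccentricity_range
        contrast = config.malignant_contrast
        n_foci = int(rng.integers(config.foci_count_range[0], config.foci_count_range[1] + 1))
        foci = tuple((rng.uniform(0.0, 0.75), rng.uniform(0, 2 * np.pi)) for _ in range(n_foci))
    else:
        amp = config.benign_spiculation
        ecc_range = config.benign_eccentricity_range
        contrast = config.lesion_contrast
        foci = ()
    return LesionGeometry(
        center=center,
        radius=radius,
        eccentricity=rng.uniform(*ecc_range),
        angle=rng.uniform(0, np.pi),
        spic_amplitude=amp,
        n_spicules=config.n_spicules,
        spic_phase=rng.uniform(0, 2 * np.pi),
        contrast=contrast,
        foci=foci,
    )


def lesion_mask(geometry: LesionGeometry, size: int, offset: Tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Boolean mask of the star-convex lesion region."""
    rows, cols = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float), indexing="ij")
    dy = rows - (geometry.center[0] + offset[0])
    dx = cols - (geometry.center[1] + offset[1])
    # rotate into the lesion frame and squash one axis (elliptical base shape)
    ca, sa = np.cos(geometry.angle), np.sin(geometry.angle)
    u = ca * dx + sa * dy
    v = (-sa * dx + ca * dy) / geometry.eccentricity
    r = np.hypot(u, v)
    theta = np.arctan2(v, u)
    boundary = geometry.radius * (
        1.0 + geometry.spic_amplitude * np.sin(geometry.n_spicules * theta + geometry.spic_phase)
    )
    return r <= boundary


def _speckle(shape, gamma_shape: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative gamma speckle."""
    return rng.gamma(gamma_shape, 1.0 / gamma_shape, size=shape)


def _foci_pixel_centers(geometry: LesionGeometry, offset: Tuple[float, float]):
    """Echogenic-foci centers in pixel coordinates (foci ride the lesion frame)."""
    ca, sa = np.cos(geometry.angle), np.sin(geometry.angle)
    for r_frac, theta in geometry.foci:
        boundary = geometry.radius * (
            1.0 + geometry.spic_amplitude * np.sin(geometry.n_spicules * theta + geometry.spic_phase)
        )
        u = r_frac * boundary * np.cos(theta)
        v = r_frac * boundary * np.sin(theta) * geometry.eccentricity
        dx = ca * u - sa * v
        dy = sa * u + ca * v
        yield geometry.center[0] + offset[0] + dy, geometry.center[1] + offset[1] + dx


def apply_degradation(pixels: np.ndarray, kind: str, config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply one named degradation, calibrated to break a quality threshold."""
    out = np.asarray(pixels, dtype=float)
    if kind == "blur":
        return np.clip(ndimage.gaussian_filter(out, config.blur_sigma, mode="reflect"), 0, 255)
    if kind == "gain":
        band = config.corrupt_gain_low if rng.random() < 0.5 else config.corrupt_gain_high
        return np.clip(out * rng.uniform(*band), 0, 255)
    if kind == "shadow":
        edge = int(round(out.shape[0] * (1.0 - config.shadow_fraction)))
        shadowed = out.copy()
        shadowed[edge:, :] *= config.shadow_attenuation
        return np.clip(shadowed, 0, 255)
    raise ValueError(f"unknown degradation {kind!r}")


def render_frame(
    config: PhantomConfig,
    geometry: LesionGeometry,
    rng: np.random.Generator,
    index: int = 0,
    offset: Tuple[float, float] = (0.0, 0.0),
    degradation: Optional[str] = None,
) -> Tuple[Frame, np.ndarray]:
    """One speckle realization of the lesion scene, optionally degraded."""
    s = config.frame_size
    mask = lesion_mask(geometry, s, offset)
    mean_map = np.full((s, s), config.background_mean)
    mean_map[mask] = max(config.background_mean + geometry.contrast, 1.0)
    if geometry.foci and config.heterogeneity_amplitude > 0:
        # malignant interiors are heterogeneous: a smooth random blotch
        # field raises patches of the lesion back toward background level
        field = ndimage.gaussian_filter(rng.standard_normal((s, s)), config.heterogeneity_scale)
        field = (field - field.min()) / max(field.max() - field.min(), 1e-9)
        mean_map = np.where(mask, mean_map + config.heterogeneity_amplitude * field, mean_map)
    pixels = mean_map * _speckle((s, s), config.speckle_shape, rng)
    if geometry.foci:
        rows, cols = np.meshgrid(np.arange(s, dtype=float), np.arange(s, dtype=float), indexing="ij")
        for fy, fx in _foci_pixel_centers(geometry, offset):
            disc = (rows - fy) ** 2 + (cols - fx) ** 2 <= config.foci_radius**2
            pixels[disc] = config.foci_value
    # glints ride the echogenic background; the hypoechoic lesion interior
    # has few scatterers, so the lesion area stays glint-free.  Density is
    # rescaled by the background fraction to keep the expected glint count
    # (hence the sharpness statistics) independent of lesion size.
    density = config.malignant_glint_density if geometry.foci else config.glint_density
    background_frac = max(1.0 - float(mask.mean()), 0.5)
    glints = (rng.random((s, s)) < density / background_frac) & ~mask
    pixels = np.clip(np.where(glints, config.glint_value, pixels), 0, 255)

    if degradation is not None:
        pixels = apply_degradation(pixels, degradation, config, rng)
    else:
        if rng.random() < config.shadow_prob:
            pixels = apply_degradation(pixels, "shadow", config, rng)
        if rng.random() < config.blur_prob:
            pixels = apply_degradation(pixels, "blur", config, rng)
        if rng.random() < config.gain_prob:
            factor = rng.uniform(*config.gain_range)
            pixels = np.clip(pixels * factor, 0, 255)

    return Frame(pixels=pixels, index=index), mask


def generate_frame(config: PhantomConfig, label: str, rng: np.random.Generator) -> Tuple[Frame, np.ndarray]:
    """A single phantom frame with its lesion mask (fresh geometry)."""
    geometry = sample_lesion_geometry(config, label, rng)
    return render_frame(config, geometry, rng)


def generate_sequence(
    config: PhantomConfig,
    label: str,
    n_frames: int,
    corrupt_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    sequence_id: str = "",
    max_resample: int = 5,
    thresholds: QualityThresholds = QualityThresholds(),
) -> Tuple[BUSSequence, np.ndarray, np.ndarray]:
    """A persistent-lesion sequence with a corrupted subset of frames.

    Returns (sequence, corruption flags, lesion mask of the uncorrupted
    geometry).  ``round(corrupt_fraction * n_frames)`` frames receive one
    degradation drawn from blur/gain/shadow, each calibrated to violate a
    default quality threshold.  Clean frames whose speckle realization
    happens to fall outside the gate bands are redrawn (up to
    ``max_resample`` times) so that corruption flags match gate outcomes.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0.0 <= corrupt_fraction <= 1.0:
        raise ValueError("corrupt_fraction must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    geometry = sample_lesion_geometry(config, label, rng)
    n_corrupt = int(round(corrupt_fraction * n_frames))
    corrupt_idx = set(rng.choice(n_frames, size=n_corrupt, replace=False).tolist())

    frames, flags = [], np.zeros(n_frames, dtype=bool)
    for i in range(n_frames):
        offset = tuple(rng.integers(-config.jitter_px, config.jitter_px + 1, size=2).astype(float))
        if i in corrupt_idx:
            kind = DEGRADATIONS[rng.integers(len(DEGRADATIONS))]
            frame, _ = render_frame(config, geometry, rng, index=i, offset=offset, degradation=kind)
            flags[i] = True
        else:
            frame, _ = render_frame(config, geometry, rng, index=i, offset=offset)
            for _ in range(max_resample):
                if assess_frame(frame, thresholds).gate == 1:
                    break
                frame, _ = render_frame(config, geometry, rng, index=i, offset=offset)
        frames.append(frame)
    sequence = BUSSequence(frames=frames, sequence_id=sequence_id or f"phantom-{label}", label=label)
    return sequence, flags, lesion_mask(geometry, config.frame_size)


def _assign_splits(n: int, rng: np.random.Generator) -> list:
    """Deterministic 70/15/15 split; val and test each get >= 1 item when n >= 3."""
    if n >= 3:
        n_train = min(max(int(round(0.7 * n)), 1), n - 2)
        n_val = min(max(int(round(0.15 * n)), 1), n - n_train - 1)
    else:
        n_train = max(n - 1, 1)
        n_val = 0
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
    perm = rng.permutation(n)
    out = [""] * n
    for pos, item in enumerate(perm):
        out[item] = splits[pos]
    return out


def generate_dataset(
    out_dir,
    n_benign: int,
    n_malignant: int,
    frames_per_sequence: int,
    config: PhantomConfig = PhantomConfig(),
    corrupt_fraction: float = 0.0,
) -> Tuple[Manifest, dict]:
    """Write phantom sequence directories + a manifest CSV under *out_dir*.

    The train/val/test split is sequence-level, stratified per class and
    deterministic given ``config.seed``.  Returns the manifest and a dict
    of per-sequence corruption flags.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one sequence per class")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    rows, flags_by_id = [], {}
    for label, count in (("benign", n_benign), ("malignant", n_malignant)):
        splits = _assign_splits(count, rng)
        for k in range(count):
            seq_id = f"{label}_{k:03d}"
            seq_dir = out_dir / seq_id
            seq_dir.mkdir(exist_ok=True)
            seq, flags, _ = generate_sequence(
                config, label, frames_per_sequence, corrupt_fraction, rng, sequence_id=seq_id
            )
            for frame in seq:
                img = Image.fromarray(np.round(frame.pixels).astype(np.uint8))
                img.save(seq_dir / f"frame_{frame.index:04d}.png")
            flags_by_id[seq_id] = flags
            # manifest paths are relative to the dataset root for portability
            rows.append(ManifestRow(seq_id, label, splits[k]))

    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sequence_directory", "label", "split"])
        for row in rows:
            writer.writerow([row.sequence_directory, row.label, row.split])
    return Manifest(rows), flags_by_id
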