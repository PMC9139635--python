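"""Synthetic phantom generator: determinism, morphology, gate calibration."""

import dataclasses

import numpy as np
import pytest

from buspool.frame_io import load_manifest, load_sequence
from buspool.phantom import (
    PhantomConfig,
    apply_degradation,
    generate_dataset,
    generate_frame,
    generate_sequence,
    lesion_mask,
    sample_lesion_geometry,
)
from buspool.quality import assess_frame


class TestConfigValidation:
    def test_radius_range_bounds(self):
        with pytest.raises(ValueError):
            PhantomConfig(lesion_radius_range=(0.2, 0.6))
        with pytest.raises(ValueError):
            PhantomConfig(lesion_radius_range=(0.3, 0.1))

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            PhantomConfig(blur_prob=1.5)


class TestGenerateFrame:
    def test_bit_identical_under_same_seed(self, phantom_config):
        a, mask_a = generate_frame(phantom_config, "malignant", np.random.default_rng(3))
        b, mask_b = generate_frame(phantom_config, "malignant", np.random.default_rng(3))
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(mask_a, mask_b)

    def test_lesion_is_hypoechoic(self, phantom_config):
        """Mean intensity inside the lesion sits well below the background."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            frame, mask = generate_frame(phantom_config, "benign", rng)
            assert frame.pixels[mask].mean() < frame.pixels[~mask].mean() - 5.0

    def test_frame_invariants(self, phantom_config, rng):
        for label in ("benign", "malignant"):
            frame, mask = generate_frame(phantom_config, label, rng)
            assert frame.pixels.shape == (64, 64)
            assert frame.pixels.min() >= 0 and frame.pixels.max() <= 255
            assert mask.dtype == bool and 0 < mask.sum() < mask.size

    def test_unknown_label_rejected(self, phantom_config, rng):
        with pytest.raises(ValueError):
            generate_frame(phantom_config, "unknown", rng)

    def test_malignant_lesions_are_elongated_and_irregular(self, phantom_config, rng):
        benign = sample_lesion_geometry(phantom_config, "benign", rng)
        malignant = sample_lesion_geometry(phantom_config, "malignant", rng)
        assert malignant.eccentricity < benign.eccentricity
        assert malignant.spic_amplitude > benign.spic_amplitude
        assert len(malignant.foci) > 0 and len(benign.foci) == 0

    def test_low_gain_frame_fails_brightness_gate(self, phantom_config):
        """Under-amplified frames (gain ~0.3) drop below the brightness band."""
        rng = np.random.default_rng(6)
        geometry = sample_lesion_geometry(phantom_config, "benign", rng)
        from buspool.phantom import render_frame

        frame, _ = render_frame(phantom_config, geometry, rng)
        dimmed = np.clip(frame.pixels * 0.3, 0, 255)
        assert assess_frame(dimmed).brightness < 10.0


class TestDegradations:
    @pytest.mark.parametrize("kind", ["blur", "gain", "shadow"])
    def test_each_degradation_violates_a_default_threshold(self, phantom_config, kind):
        rng = np.random.default_rng(8)
        violations = 0
        trials = 25
        for _ in range(trials):
            frame, _ = generate_frame(phantom_config, "malignant", rng)
            degraded = apply_degradation(frame.pixels, kind, phantom_config, rng)
            violations += 1 - assess_frame(degraded).gate
        assert violations >= 0.9 * trials

    def test_unknown_degradation_rejected(self, phantom_config, rng):
        with pytest.raises(ValueError):
            apply_degradation(np.zeros((64, 64)), "fog", phantom_config, rng)


class TestGenerateSequence:
    def test_corruption_count_rounds(self, phantom_config, rng):
        seq, flags, _ = generate_sequence(phantom_config, "benign", 13, 0.15, rng)
        assert len(seq) == 13
        assert flags.sum() == 2  # round(13 * 0.15)

    def test_lesion_geometry_persists_across_frames(self, phantom_config):
        rng = np.random.default_rng(9)
        seq, flags, mask = generate_sequence(phantom_config, "malignant", 6, 0.0, rng)
        # every frame's lesion region stays hypoechoic (median is robust to
        # the bright echogenic foci inside malignant lesions)
        for frame in seq:
            inside = np.median(frame.pixels[mask])
            outside = np.median(frame.pixels[~mask])
            assert inside < outside

    def test_corrupted_frames_fail_gate_clean_frames_pass(self, phantom_config):
        """Gate calibration over 20 seeded sequences: >= 90% of corrupted
        frames rejected, >= 95% of clean frames accepted."""
        clean_pass = clean_total = corrupt_fail = corrupt_total = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            label = "malignant" if seed % 2 else "benign"
            seq, flags, _ = generate_sequence(phantom_config, label, 10, 0.3, rng)
            for frame, corrupted in zip(seq, flags):
                gate = assess_frame(frame).gate
                if corrupted:
                    corrupt_total += 1
                    corrupt_fail += 1 - gate
                else:
                    clean_total += 1
                    clean_pass += gate
        assert corrupt_fail / corrupt_total >= 0.90
        assert clean_pass / clean_total >= 0.95

    def test_full_corruption_leads_to_nq_zero(self, phantom_config, rng):
        from buspool.pooling import score_sequence

        seq, flags, _ = generate_sequence(phantom_config, "benign", 5, 1.0, rng)
        assert flags.all()
        result = score_sequence(seq, scorer=lambda f: 0.4)
        assert result.n_quality == 0
        assert result.low_confidence

    def test_invalid_arguments(self, phantom_config, rng):
        with pytest.raises(ValueError):
            generate_sequence(phantom_config, "benign", 0, 0.0, rng)
        with pytest.raises(ValueError):
            generate_sequence(phantom_config, "benign", 5, 1.5, rng)


class TestGenerateDataset:
    def test_dataset_layout_and_manifest(self, tmp_path, phantom_config):
        cfg = dataclasses.replace(phantom_config, seed=42)
        manifest, flags = generate_dataset(tmp_path / "d", 3, 4, 5, cfg)
        assert len(manifest) == 7
        assert len(flags) == 7
        loaded = load_manifest(tmp_path / "d" / "manifest.csv")
        assert len(loaded) == 7
        labels = [r.label for r in loaded]
        assert labels.count("benign") == 3 and labels.count("malignant") == 4
        seq = load_sequence(loaded.rows[0].sequence_directory, target_size=None)
        assert len(seq) == 5
        assert {r.split for r in loaded} <= {"train", "val", "test"}

    def test_byte_identical_datasets_under_same_seed(self, tmp_path, phantom_config):
        import hashlib

        cfg = dataclasses.replace(phantom_config, seed=11)

        def digest(root):
            h = hashlib.sha256()
            for p in sorted(root.rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        generate_dataset(tmp_path / "a", 2, 2, 3, cfg)
        generate_dataset(tmp_path / "b", 2, 2, 3, cfg)
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_zero_count_rejected(self, tmp_path, phantom_config):
        with pytest.raises(ValueError):
            generate_dataset(tmp_path / "x", 0, 2, 3, phantom_config)


class TestLesionMask:
    def test_mask_respects_radius_scale(self, phantom_config, rng):
        geometry = sample_lesion_geometry(phantom_config, "benign", rng)
        mask = lesion_mask(geometry, 64)
        area = mask.sum()
        # star-convex region area is within a factor ~2 of the base ellipse
        base = np.pi * geometry.radius**2 * geometry.eccentricity
        assert 0.4 * base < area < 2.5 * base

    def test_offset_translates_mask(self, phantom_config, rng):
        geometry = sample_lesion_geometry(phantom_config, "benign", rng)
        a = lesion_mask(geometry, 64)
        b = lesion_mask(geometry, 64, offset=(2.0, 0.0))
        assert np.array_equal(np.roll(a, 2, axis=0)[3:-3], b[3:-3])
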