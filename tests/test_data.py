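"""Phantom generator, NIfTI slice loading, preprocessing and case splits."""

import numpy as np
import pytest

from segdistill.data import (
    MODALITIES,
    DatasetSplit,
    MultimodalSample,
    PhantomConfig,
    enhance_contrast_brightness,
    generate_phantom,
    load_brats_slice,
    load_phantom_nifti,
    save_phantom_nifti,
    split_cases,
)


class TestGeneratePhantom:
    def test_shape_value_and_label_contracts(self):
        s = generate_phantom(PhantomConfig(image_size=160), rng_seed=7)
        for m in MODALITIES:
            img = s.modality(m)
            assert img.shape == (160, 160)
            assert img.min() >= 0.0 and img.max() <= 1.0
        assert set(np.unique(s.label)) <= {0, 1, 2, 4}

    def test_deterministic_for_fixed_seed(self, desk_config):
        a = generate_phantom(desk_config, rng_seed=11)
        b = generate_phantom(desk_config, rng_seed=11)
        for m in MODALITIES:
            np.testing.assert_array_equal(a.modality(m), b.modality(m))
        np.testing.assert_array_equal(a.label, b.label)

    def test_zero_radius_gives_tumor_free_slice(self):
        cfg = PhantomConfig(image_size=64, tumor_radius_range=(0.0, 0.0))
        s = generate_phantom(cfg, rng_seed=3)
        assert not s.label.any()

    def test_nested_region_hierarchy(self, desk_config):
        for seed in range(20):
            lab = generate_phantom(desk_config, rng_seed=seed).label
            et = lab == 4
            tc = np.isin(lab, (1, 4))
            wt = np.isin(lab, (1, 2, 4))
            assert np.all(~et | tc), "enhancing must lie inside the core"
            assert np.all(~tc | wt), "core must lie inside the whole tumor"

    def test_modality_contrast_roles(self, desk_config):
        """Core is salient on T1ce, edema on FLAIR, at the default noise level."""
        s = generate_phantom(desk_config, rng_seed=5)
        bg = s.label == 0
        core = np.isin(s.label, (1, 4))
        edema = s.label == 2
        assert s.t1ce[core].mean() > s.t1ce[bg].mean()
        assert s.flair[edema].mean() > s.flair[bg].mean()

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(PhantomConfig(image_size=16), rng_seed=0)
        with pytest.raises(ValueError):
            generate_phantom(PhantomConfig(tumor_radius_range=(10.0, 5.0)), rng_seed=0)
        with pytest.raises(ValueError):
            generate_phantom(PhantomConfig(core_fraction_range=(0.5, 1.5)), rng_seed=0)


class TestMultimodalSample:
    def test_shape_mismatch_rejected(self):
        z = np.zeros((8, 8), dtype=np.float32)
        with pytest.raises(ValueError):
            MultimodalSample(t1=z, t1ce=z, t2=z, flair=np.zeros((4, 4)), label=np.zeros((8, 8), int))

    def test_bad_label_values_rejected(self):
        z = np.zeros((8, 8), dtype=np.float32)
        lab = np.zeros((8, 8), dtype=int)
        lab[0, 0] = 3
        with pytest.raises(ValueError):
            MultimodalSample(t1=z, t1ce=z, t2=z, flair=z, label=lab)


class TestNiftiRoundTrip:
    def test_save_load_preserves_values(self, desk_config, tmp_path):
        s = generate_phantom(desk_config, rng_seed=2)
        save_phantom_nifti(s, tmp_path)
        loaded = load_phantom_nifti(tmp_path / s.case_id)
        for m in MODALITIES:
            np.testing.assert_allclose(loaded.modality(m), s.modality(m), atol=1e-6)
        np.testing.assert_array_equal(loaded.label, s.label)
        assert loaded.case_id == s.case_id


class TestLoadBratsSlice:
    @pytest.fixture()
    def volume_paths(self, tmp_path, rng):
        import nibabel as nib

        shape = (200, 190, 12)
        paths = {}
        vols = {}
        for m in MODALITIES:
            vol = rng.uniform(0, 1000, size=shape).astype(np.float32)
            p = tmp_path / f"{m}.nii.gz"
            nib.save(nib.Nifti1Image(vol, np.eye(4)), str(p))
            paths[m] = p
            vols[m] = vol
        lab = rng.choice([0, 1, 2, 4], size=shape).astype(np.int16)
        lp = tmp_path / "seg.nii.gz"
        nib.save(nib.Nifti1Image(lab, np.eye(4)), str(lp))
        return paths, lp, vols, lab

    def test_crop_normalize_contract(self, volume_paths):
        paths, lp, _, _ = volume_paths
        s = load_brats_slice(paths, lp, slice_index=5, crop_size=160)
        assert s.t1.shape == (160, 160)
        assert 0.0 <= s.t1.min() and s.t1.max() <= 1.0

    def test_crop_window_matches_direct_slicing(self, volume_paths):
        paths, lp, vols, lab = volume_paths
        s = load_brats_slice(paths, lp, slice_index=3, crop_size=160)
        y0 = (200 - 160) // 2
        x0 = (190 - 160) // 2
        raw = vols["t2"][y0 : y0 + 160, x0 : x0 + 160, 3].astype(np.float64)
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        np.testing.assert_allclose(s.t2, expected, atol=1e-6)
        np.testing.assert_array_equal(s.label, lab[y0 : y0 + 160, x0 : x0 + 160, 3])

    def test_constant_slice_normalizes_to_zero(self, tmp_path):
        import nibabel as nib

        shape = (170, 170, 3)
        paths = {}
        for m in MODALITIES:
            vol = np.full(shape, 7.0, dtype=np.float32)
            p = tmp_path / f"{m}.nii.gz"
            nib.save(nib.Nifti1Image(vol, np.eye(4)), str(p))
            paths[m] = p
        lp = tmp_path / "seg.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros(shape, np.int16), np.eye(4)), str(lp))
        s = load_brats_slice(paths, lp, slice_index=1)
        assert np.all(s.flair == 0.0)

    def test_out_of_range_slice_rejected(self, volume_paths):
        paths, lp, _, _ = volume_paths
        with pytest.raises(IndexError):
            load_brats_slice(paths, lp, slice_index=99)

    def test_shape_mismatch_rejected(self, volume_paths, tmp_path):
        import nibabel as nib

        paths, lp, _, _ = volume_paths
        bad = tmp_path / "bad.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((64, 64, 12), np.float32), np.eye(4)), str(bad))
        paths = dict(paths, t1=bad)
        with pytest.raises(ValueError):
            load_brats_slice(paths, lp, slice_index=0)


class TestEnhanceContrastBrightness:
    def test_identity_default(self, rng):
        img = rng.uniform(0, 1, size=(8, 8)).astype(np.float32)
        np.testing.assert_array_equal(enhance_contrast_brightness(img), img)

    def test_clipping_bound(self):
        img = np.full((4, 4), 0.5, dtype=np.float32)
        np.testing.assert_array_equal(enhance_contrast_brightness(img, gain=2.0), np.ones((4, 4)))

    def test_matches_elementwise_closed_form(self):
        img = np.linspace(0, 1, 25, dtype=np.float32).reshape(5, 5)
        out = enhance_contrast_brightness(img, gain=1.2, bias=0.05)
        np.testing.assert_allclose(out, np.clip(1.2 * img + 0.05, 0, 1), atol=1e-7)


class TestSplitCases:
    def test_published_fractions_on_100_cases(self):
        split = split_cases([f"c{i}" for i in range(100)], seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (80, 10, 10)

    def test_smallest_admissible_and_too_few(self):
        split = split_cases([f"c{i}" for i in range(10)], seed=1)
        assert (len(split.train), len(split.val), len(split.test)) == (8, 1, 1)
        with pytest.raises(ValueError):
            split_cases([f"c{i}" for i in range(9)], seed=1)

    def test_deterministic_and_disjoint(self):
        ids = [f"case-{i}" for i in range(37)]
        a = split_cases(ids, seed=5)
        b = split_cases(ids, seed=5)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)
        a.validate(ids)  # union + disjointness invariants

    def test_split_validate_catches_overlap(self):
        bad = DatasetSplit(train=["a", "b"], val=["b"], test=["c"])
        with pytest.raises(ValueError):
            bad.validate(["a", "b", "c"])
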