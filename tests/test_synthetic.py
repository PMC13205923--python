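"""Phantom generator: determinism, ground-truth consistency, splits."""

import numpy as np
import pandas as pd
import pytest

from nodulenet import manifest as mf
from nodulenet import synthetic


class TestRenderPhantom:
    def test_zero_nodules_empty_box_list(self, rng):
        params = synthetic.PhantomParams(image_side=64)
        _, boxes = synthetic.render_phantom(params, rng, 0)
        assert boxes == []

    def test_high_contrast_peak_inside_box(self):
        params = synthetic.PhantomParams(image_side=224, nodule_contrast=0.9, noise_sd=0.01)
        img, boxes = synthetic.render_phantom(params, np.random.default_rng(2), 1)
        r, c = np.unravel_index(img.argmax(), img.shape)
        assert boxes[0].contains(r, c)

    def test_same_seed_bit_identical(self):
        params = synthetic.PhantomParams(image_side=96)
        a, boxes_a = synthetic.render_phantom(params, np.random.default_rng(7), 2)
        b, boxes_b = synthetic.render_phantom(params, np.random.default_rng(7), 2)
        np.testing.assert_array_equal(a, b)
        assert boxes_a == boxes_b

    def test_boxes_inside_image_and_values_bounded(self, rng):
        params = synthetic.PhantomParams(image_side=128)
        for _ in range(10):
            img, boxes = synthetic.render_phantom(params, rng, 2)
            assert img.min() >= 0.0 and img.max() <= 1.0
            side = params.image_side
            for b in boxes:
                assert b.fits_in(side, side)


class TestManifestAndSplits:
    def test_labels_match_box_presence(self):
        df = synthetic.build_manifest(synthetic.PhantomParams(image_side=64, n_patients=40, seed=2))
        assert ((df["label"] == 1) == (df["boxes"].map(len) > 0)).all()

    def test_prevalence_near_default(self):
        params = synthetic.PhantomParams(image_side=64, n_patients=400, seed=5)
        df = synthetic.build_manifest(params)
        assert abs(df["label"].mean() - params.prevalence) < 0.03

    def test_split_invariants_over_many_seeds(self):
        """Patient disjointness and ±2-image per-class stratification, 100 seeds."""
        fractions = (0.70, 0.15, 0.15)
        for seed in range(100):
            df = synthetic.build_manifest(
                synthetic.PhantomParams(image_side=64, n_patients=60, seed=seed)
            )
            assert (df.groupby("patient_id")["split"].nunique() == 1).all()
            n_pos, n_neg = df["label"].sum(), (1 - df["label"]).sum()
            for frac, name in zip(fractions, synthetic.SPLIT_NAMES):
                sub = df[df["split"] == name]
                assert abs(sub["label"].sum() - frac * n_pos) <= 2
                assert abs((1 - sub["label"]).sum() - frac * n_neg) <= 2

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synthetic.SplitSpec(fractions=(0.5, 0.2, 0.2))

    def test_generate_dataset_round_trip(self, tmp_path):
        params = synthetic.PhantomParams(image_side=64, n_patients=12, seed=3)
        df = synthetic.generate_dataset(params, out_dir=tmp_path)
        again = mf.read_manifest(tmp_path / "manifest.csv")
        pd.testing.assert_frame_equal(df, again)
        for row in df.itertuples():
            assert (tmp_path / row.image_path).exists()

    def test_generate_dataset_deterministic(self, tmp_path):
        params = synthetic.PhantomParams(image_side=64, n_patients=6, seed=8)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        df1 = synthetic.generate_dataset(params, out_dir=d1)
        df2 = synthetic.generate_dataset(params, out_dir=d2)
        pd.testing.assert_frame_equal(df1, df2)
        for row in df1.itertuples():
            assert (d1 / row.image_path).read_bytes() == (d2 / row.image_path).read_bytes()


class TestAugmentation:
    def test_eval_guard(self, rng):
        with pytest.raises(ValueError, match="training split only"):
            synthetic.augment_training_image(np.zeros((64, 64)), rng, split="test")

    def test_fixed_seed_repeatable(self):
        img = np.random.default_rng(0).random((64, 64))
        a = synthetic.augment_training_image(img, np.random.default_rng(5))
        b = synthetic.augment_training_image(img, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_randomness_disabled_reduces_to_preprocess(self):
        img = np.random.default_rng(1).random((64, 64))
        frozen = synthetic.AugmentParams(
            hflip_prob=0.0, max_rotation_deg=0.0, max_translation_frac=0.0, max_intensity_frac=0.0
        )
        out = synthetic.augment_training_image(img, np.random.default_rng(0), params=frozen)
        np.testing.assert_allclose(out, synthetic.preprocess_image(img), atol=1e-5)

    def test_constant_image_standardizes_per_channel(self):
        out = synthetic.preprocess_image(np.full((64, 64), 0.5))
        for ch in range(3):
            assert np.allclose(out[ch], out[ch].flat[0])
        expected = (0.5 - synthetic.IMAGENET_MEAN) / synthetic.IMAGENET_STD
        np.testing.assert_allclose(out[:, 0, 0], expected, atol=1e-2)  # 8-bit resize quantization


class TestUpsampleMinority:
    def _train_df(self, n0=20, n1=6):
        rows = [(f"P{i}", f"n{i}.png", 0, "train", []) for i in range(n0)]
        rows += [(f"Q{i}", f"p{i}.png", 1, "train", [mf.BBox(0, 0, 5, 5)]) for i in range(n1)]
        return pd.DataFrame(rows, columns=["patient_id", "image_path", "label", "split", "boxes"])

    def test_factor_one_is_identity(self):
        df = self._train_df()
        out = synthetic.upsample_minority(df, factor=1.0)
        assert len(out) == len(df)

    def test_target_ratio_equalizes(self):
        out = synthetic.upsample_minority(self._train_df(), target_ratio=1.0)
        assert (out["label"] == 1).sum() == (out["label"] == 0).sum()

    def test_counts_reproduce_printed_weights(self):
        """Upsampling positives to 1034 against 2623 negatives yields the
        1.7684/0.6971 weight pair downstream."""
        from nodulenet.training import compute_class_weights

        df = self._train_df(n0=2623, n1=795)  # ~1.30x upsampling
        out = synthetic.upsample_minority(df, factor=1034 / 795)
        n1 = int((out["label"] == 1).sum())
        n0 = int((out["label"] == 0).sum())
        assert (n0, n1) == (2623, 1034)
        w = compute_class_weights(n0, n1)
        assert (round(w.w1, 4), round(w.w0, 4)) == (1.7684, 0.6971)

    def test_guards(self):
        df = self._train_df()
        with pytest.raises(ValueError, match=">= 1"):
            synthetic.upsample_minority(df, factor=0.5)
        with pytest.raises(ValueError, match="exactly one"):
            synthetic.upsample_minority(df)
        df_bad = df.assign(split="test")
        with pytest.raises(ValueError, match="training split"):
            synthetic.upsample_minority(df_bad, factor=2.0)


class TestManifestIO:
    def test_box_serialization_round_trip(self):
        boxes = [mf.BBox(1, 2, 3, 4), mf.BBox(10, 20, 30, 40)]
        assert mf.boxes_from_str(mf.boxes_to_str(boxes)) == boxes
        assert mf.boxes_from_str("") == []

    def test_label_box_consistency_enforced(self, tmp_path, tiny_manifest):
        bad = tiny_manifest.copy()
        bad.loc[1, "label"] = 1  # positive but no boxes
        path = tmp_path / "m.csv"
        mf.write_manifest(bad, path)
        with pytest.raises(ValueError, match="inconsistency"):
            mf.read_manifest(path)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mf.BBox(0, 0, 0, 5)
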