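"""Window scanning, training targets, per-voxel pipelines, output selection."""

import numpy as np
import pytest

from petseg import neural as nn
from petseg import segmenter as seg
from petseg.phantom import generate_nema, nema_default_spec
from petseg.volume_io import LabelVolume, PETVolume


class TestExtractWindows:
    def test_tiling_counts_match_slice_geometry(self, rng):
        ws = seg.extract_windows(rng.random((168, 168)), window=12, stride=12)
        assert ws.windows.shape == (196, 144)
        ws = seg.extract_windows(rng.random((84, 84)), window=12, stride=12)
        assert ws.windows.shape == (49, 144)

    def test_tiling_covers_every_voxel_once_and_origins_reconstruct(self, rng):
        x = rng.random((36, 48))
        ws = seg.extract_windows(x, window=12, stride=12)
        rebuilt = np.zeros_like(x)
        for win, (s, r, c) in zip(ws.windows, ws.origins):
            rebuilt[r: r + 12, c: c + 12] = win.reshape(12, 12)
        assert np.array_equal(rebuilt, x)

    def test_centered_scan_one_window_per_voxel(self, rng):
        x = rng.random((20, 17))
        ws = seg.extract_windows(x, window=12, centered=True, slice_index=3)
        assert ws.windows.shape == (20 * 17, 144)
        # the centre element of each window is the voxel itself
        centers = ws.windows[:, 5 * 12 + 5].reshape(20, 17)
        assert np.array_equal(centers, x)
        assert np.all(ws.origins[:, 0] == 3)

    def test_row_major_flattening(self):
        x = np.arange(144, dtype=float).reshape(12, 12)
        ws = seg.extract_windows(x, window=12, stride=12)
        assert np.array_equal(ws.windows[0], np.arange(144))

    def test_small_slices_are_padded_to_fit(self, rng):
        ws = seg.extract_windows(rng.random((8, 8)), window=12, stride=12)
        assert ws.windows.shape == (1, 144)

    def test_invalid_window_rejected(self, rng):
        with pytest.raises(ValueError):
            seg.extract_windows(rng.random((20, 20)), window=0)


class TestLabelWindows:
    def test_any_rule_examples(self):
        truth = np.zeros((24, 24))
        ws = seg.extract_windows(np.zeros((24, 24)), window=12, stride=12)
        assert seg.label_windows(ws, truth, rule="any").sum() == 0
        truth[3, 3] = 1  # single tumour voxel -> exactly one positive tile
        assert np.array_equal(seg.label_windows(ws, truth, rule="any"),
                              [1, 0, 0, 0])

    def test_any_rule_counts_match_bruteforce_on_nema_slice(self):
        spec = nema_default_spec(noise_sigma=0.0)
        _, truth = generate_nema(spec)
        mid = truth.labels[:, :, 33] > 0
        ws = seg.extract_windows(mid.astype(float), window=12, stride=12)
        targets = seg.label_windows(ws, mid.astype(float), rule="any")
        expected = sum(
            mid[r: r + 12, c: c + 12].any()
            for r in range(0, 168, 12) for c in range(0, 168, 12))
        assert targets.sum() == expected > 0

    def test_center_rule_returns_center_values(self, rng):
        truth = rng.random((15, 15))
        ws = seg.extract_windows(np.zeros((15, 15)), window=12, centered=True)
        assert np.array_equal(seg.label_windows(ws, truth, rule="center"),
                              truth.ravel())

    def test_center_rule_requires_dense_scan(self, rng):
        ws = seg.extract_windows(rng.random((24, 24)), window=12, stride=12)
        with pytest.raises(ValueError):
            seg.label_windows(ws, np.zeros((24, 24)), rule="center")

    def test_misaligned_truth_rejected(self, rng):
        ws = seg.extract_windows(rng.random((24, 24)), window=12)
        with pytest.raises(ValueError):
            seg.label_windows(ws, np.zeros((20, 20)))


class TestDownsampleTruth:
    def test_rules_on_crafted_block(self):
        t = np.zeros((4, 4))
        t[0, 0] = 1          # block (0,0): 1/4 foreground
        t[2:4, 0:2] = 1      # block (1,0): 4/4
        t[2, 2] = t[2, 3] = 1  # block (1,1): 2/4
        assert np.array_equal(seg.downsample_truth(t, 2, "any"),
                              [[1, 0], [1, 1]])
        assert np.array_equal(seg.downsample_truth(t, 2, "majority"),
                              [[0, 0], [1, 1]])
        assert seg.downsample_truth(t, 2, "fraction") == pytest.approx(
            np.array([[0.25, 0.0], [1.0, 0.5]]))

    def test_fractional_occupancy_is_averaged(self):
        occ = np.array([[0.5, 0.5], [0.0, 0.2]])
        assert seg.downsample_truth(occ, 2, "fraction") == pytest.approx(np.array([[0.3]]))


class TestPipelines:
    def zero_model(self):
        return nn.MLPModel([np.zeros((2, 144)), np.zeros((1, 2))],
                           [np.zeros(2), np.zeros(1)])

    def test_zero_volume_zero_model_all_background(self):
        vol = PETVolume(np.zeros((24, 24, 2)), (1, 1, 1))
        res = seg.segment_spatial(vol, self.zero_model())
        assert not res.labels.labels.any()
        assert res.labels.scale_factor == 1

    def test_rethresholding_scores_is_idempotent(self, rng):
        vol = PETVolume(rng.random((24, 24, 2)), (1, 1, 1))
        model = nn.init_mlp((144, 4, 1), seed=0)
        res = seg.segment_spatial(vol, model, threshold=0.5)
        again = (res.raw_scores > 0.5).astype(np.int16)
        assert np.array_equal(again, res.labels.labels)

    def test_wavelet_map_has_half_inplane_shape_and_scale(self, rng):
        vol = PETVolume(rng.random((128, 128, 2)), (1, 1, 1))
        model = nn.init_mlp((144, 4, 1), seed=0)
        res = seg.segment_wavelet(vol, model, levels=1)
        assert res.labels.shape == (64, 64, 2)
        assert res.labels.scale_factor == 2
        assert res.labels.domain_tag == "wavelet"

    def test_nan_model_rejected(self, rng):
        model = self.zero_model()
        model.weights[0][0, 0] = np.nan
        vol = PETVolume(rng.random((24, 24, 1)), (1, 1, 1))
        with pytest.raises(ValueError):
            seg.segment_spatial(vol, model)

    def test_end_to_end_blob_detection_spatial(self, rng):
        # high-contrast blob on a flat background: train densely on slice 0,
        # detect on slice 1 where the blob moved
        vox = np.full((32, 32, 2), 0.1)
        truth = np.zeros((32, 32, 2), dtype=np.int16)
        vox[8:12, 8:12, 0] = 1.0
        truth[8:12, 8:12, 0] = 1
        vox[20:24, 14:18, 1] = 1.0
        truth[20:24, 14:18, 1] = 1
        vol = PETVolume(vox, (1, 1, 1))
        labels = LabelVolume(truth)
        X, y = seg.build_training_set(vol, labels, [0], domain="spatial",
                                      target="presence",
                                      n_background_per_slice=60, seed=0)
        model = nn.init_mlp((144, 10, 1), seed=0)
        cfg = nn.TrainingConfig(algorithm="lm", max_epochs=15)
        model, _ = nn.train_lm(model, (X, y), cfg)
        res = seg.segment_spatial(vol, model)
        detected = res.labels.labels[:, :, 1] > 0
        assert detected[20:24, 14:18].sum() >= 12  # blob found on unseen slice


class TestSelectBest:
    def make_result(self, labels, tag, scale=1):
        domain = "wavelet" if scale > 1 else "spatial"
        lv = LabelVolume(labels.astype(np.int16), domain, scale)
        return seg.SegmentationResult(lv, labels.astype(float), tag)

    def test_single_result_returned(self):
        truth = LabelVolume(np.zeros((4, 4, 1), dtype=np.int16))
        res = self.make_result(np.zeros((4, 4, 1)), "spatial")
        assert seg.select_best([res], truth) is res

    def test_perfect_beats_imperfect(self):
        t = np.zeros((4, 4, 1), dtype=np.int16)
        t[1, 1, 0] = 1
        truth = LabelVolume(t)
        perfect = self.make_result(t.copy(), "threshold")
        wrong = self.make_result(np.zeros_like(t), "spatial")
        assert seg.select_best([wrong, perfect], truth) is perfect

    def test_tie_prefers_wavelet(self):
        t = np.zeros((4, 4, 1), dtype=np.int16)
        truth = LabelVolume(t)
        spatial = self.make_result(np.zeros_like(t), "spatial")
        wavelet = self.make_result(np.zeros((2, 2, 1)), "wavelet", scale=2)
        assert seg.select_best([spatial, wavelet], truth).pipeline_tag == "wavelet"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            seg.select_best([], LabelVolume(np.zeros((2, 2, 1), dtype=np.int16)))
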