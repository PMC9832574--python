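import warnings

import numpy as np
import pytest

from microglia_morph import segmentation as seg
from microglia_morph import synthetic as syn


def one_step_perona_malik_oracle(img, k, dt=0.2):
    """Hand-rolled single diffusion step, pixel by pixel."""
    out = img.astype(float).copy()
    nr, nc = img.shape
    for r in range(nr):
        for c in range(nc):
            flux = 0.0
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    d = img[rr, cc] - img[r, c]
                    flux += np.exp(-(d / k) ** 2) * d
            out[r, c] += dt * flux
    return out


class TestSmooth:
    def test_constant_image_unchanged(self):
        cfg = seg.SegmentationConfig(diffusion_iterations=5)
        img = np.full((20, 20), 7.0)
        assert np.array_equal(seg.smooth(img, cfg), img)

    def test_single_step_matches_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 50, (9, 9))
        img[4, 4] = 200.0
        cfg = seg.SegmentationConfig(diffusion_iterations=1,
                                     diffusion_conductance=15.0)
        expected = one_step_perona_malik_oracle(img, 15.0)
        assert np.allclose(seg.smooth(img, cfg), expected, atol=1e-12)

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 100, (40, 40))
        cfg = seg.SegmentationConfig(diffusion_iterations=20,
                                     diffusion_conductance=10.0)
        out = seg.smooth(img, cfg)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-3)

    def test_strong_edge_position_preserved(self):
        img = np.full((30, 60), 10.0)
        img[:, 30:] = 200.0  # contrast >> conductance scale
        cfg = seg.SegmentationConfig(diffusion_iterations=15,
                                     diffusion_conductance=5.0)
        out = seg.smooth(img, cfg)
        grad_before = np.abs(np.diff(img[15]))
        grad_after = np.abs(np.diff(out[15]))
        assert np.argmax(grad_after) == np.argmax(grad_before)

    def test_nonfinite_rejected(self):
        cfg = seg.SegmentationConfig()
        img = np.ones((5, 5))
        img[2, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            seg.smooth(img, cfg)


class TestRelativeThreshold:
    def _blob_image(self, level):
        img = np.full((50, 50), 10.0)
        img[20:30, 20:30] = level
        return img

    def test_blob_recovered_at_factor_1_5(self):
        img = self._blob_image(20.0)
        binary = seg.relative_threshold(img, 1.5)
        assert np.array_equal(binary, img == 20.0)

    def test_higher_factor_empties_foreground(self):
        img = self._blob_image(20.0)
        assert not seg.relative_threshold(img, 2.5).any()

    def test_flat_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="flat"):
            out = seg.relative_threshold(np.full((10, 10), 5.0), 1.5)
        assert not out.any()

    def test_noisy_field_foreground_matches_truth(self):
        cells = (
            (syn.archetype("round", seed=1), (60.0, 60.0)),
            (syn.archetype("fried_egg", seed=2), (60.0, 190.0)),
            (syn.archetype("round", seed=3), (190.0, 120.0)),
        )
        spec = syn.FieldSpec(image_size_px=(250, 250), cells=cells,
                             noise_sd=1.0, seed=4)
        fld = syn.render_field(spec)
        binary = seg.relative_threshold(fld.field.red, 1.5)
        truth = fld.truth_mask > 0
        jacc = (binary & truth).sum() / (binary | truth).sum()
        assert jacc >= 0.98


class TestLabelAndFilter:
    def test_two_blobs_two_labels(self):
        cfg = seg.SegmentationConfig(pixel_size_um=1.0)
        img = np.zeros((100, 100), bool)
        img[10:30, 10:30] = True   # 400 um^2
        img[60:80, 60:80] = True
        mask = seg.label_and_filter(img, cfg)
        assert sorted(np.unique(mask)) == [0, 1, 2]

    def test_labels_in_raster_order(self):
        cfg = seg.SegmentationConfig(pixel_size_um=1.0)
        img = np.zeros((100, 100), bool)
        img[50:70, 5:25] = True    # lower-left, but later in raster order
        img[5:25, 50:70] = True    # first pixel earlier
        mask = seg.label_and_filter(img, cfg)
        assert mask[5, 50] == 1 and mask[50, 5] == 2

    def test_small_component_removed(self):
        cfg = seg.SegmentationConfig(pixel_size_um=1.0)  # min size 200 um^2
        img = np.zeros((60, 60), bool)
        img[10:25, 10:20] = True   # 150 um^2 < 200
        assert seg.label_and_filter(img, cfg).max() == 0

    def test_long_skeleton_removed(self):
        # straight band 700 px long: skeleton ~ 700 px * 0.758 um/px = 530 um
        cfg = seg.SegmentationConfig()
        img = np.zeros((20, 720), bool)
        img[8:13, 5:705] = True
        assert seg.label_and_filter(img, cfg).max() == 0
        relaxed = seg.SegmentationConfig(max_skeleton_length_um=1000)
        assert seg.label_and_filter(img, relaxed).max() == 1

    def test_skeleton_length_against_straight_line_oracle(self):
        img = np.zeros((9, 400), bool)
        img[3:6, 2:398] = True
        # skeleton of a straight 3-px band is a straight 1-px line
        length = seg.skeleton_length_um(img, pixel_size_um=1.0)
        n_px = 396
        assert length == pytest.approx(n_px - 1, abs=6)

    @pytest.mark.parametrize("min_size", [100, 200, 400, 800])
    def test_size_filter_monotone(self, min_size):
        img = np.zeros((100, 100), bool)
        img[5:20, 5:20] = True       # 225 um^2 at 1 um/px
        img[40:60, 40:60] = True     # 400
        img[70:99, 70:99] = True     # 841
        cfg = seg.SegmentationConfig(pixel_size_um=1.0,
                                     min_cell_size_um2=min_size)
        n = seg.label_and_filter(img, cfg).max()
        expected = sum(a >= min_size for a in (225, 400, 841))
        assert n == expected


class TestEdits:
    @pytest.fixture
    def mask(self):
        m = np.zeros((40, 60), dtype=np.int32)
        m[5:15, 5:55] = 1
        m[25:35, 5:25] = 2
        m[25:35, 35:55] = 3
        return m

    def test_merge_reduces_label_count(self, mask):
        out = seg.apply_edits(mask, [seg.MaskEdit(kind="merge", labels={2, 3})])
        assert len(np.unique(out)) == len(np.unique(mask)) - 1
        merged = set(np.unique(out[(mask == 2) | (mask == 3)]))
        assert len(merged) == 1

    def test_split_transects_label(self, mask):
        edit = seg.MaskEdit(kind="split", label=1,
                            polyline=((0, 30), (39, 30)))
        out = seg.apply_edits(mask, [edit])
        pieces = set(np.unique(out[mask == 1])) - {0}
        assert len(pieces) == 2

    def test_split_then_merge_restores_partition(self, mask):
        split = seg.MaskEdit(kind="split", label=1, polyline=((0, 30), (39, 30)))
        once = seg.apply_edits(mask, [split])
        pieces = sorted(set(np.unique(once[mask == 1])) - {0})
        back = seg.apply_edits(once, [seg.MaskEdit(kind="merge",
                                                   labels=set(pieces))])
        # identical up to the removed polyline pixels
        survivors = (mask == 1) & (back > 0)
        assert len(set(back[survivors].tolist())) == 1
        removed = (mask == 1) & (back == 0)
        assert removed.sum() == 10  # the transect column inside label 1

    def test_nonintersecting_split_warns_noop(self, mask):
        edit = seg.MaskEdit(kind="split", label=2, polyline=((0, 58), (39, 58)))
        with pytest.warns(UserWarning, match="no-op"):
            out = seg.apply_edits(mask, [edit])
        assert np.array_equal(out > 0, mask > 0)

    def test_missing_label_rejected(self, mask):
        with pytest.raises(ValueError, match="missing"):
            seg.apply_edits(mask, [seg.MaskEdit(kind="merge", labels={2, 9})])


class TestTracking:
    def test_static_cells_keep_ids(self):
        m = np.zeros((30, 30), dtype=np.int32)
        m[5:15, 5:15] = 1
        m[20:28, 20:28] = 2
        out = seg.track([m, m, m])
        for frame in out:
            assert np.array_equal(frame, m)

    def test_moving_cell_keeps_id(self):
        frames = []
        for t in range(4):
            m = np.zeros((30, 60), dtype=np.int32)
            m[10:20, 5 + 3 * t:15 + 3 * t] = 1
            frames.append(m)
        out = seg.track(frames)
        for t, frame in enumerate(out):
            assert set(np.unique(frame)) == {0, 1}

    def test_new_cell_gets_fresh_id(self):
        a = np.zeros((30, 30), dtype=np.int32)
        a[2:10, 2:10] = 1
        a[20:28, 2:10] = 2
        b = np.zeros((30, 30), dtype=np.int32)
        b[2:10, 2:10] = 1           # cell 1 stays, cell 2 gone
        b[20:28, 20:28] = 7         # a new cell elsewhere
        out = seg.track([a, b])
        new_id = int(out[1][24, 24])
        assert new_id not in (0, 1, 2)

    def test_recovery_on_clean_field(self, clean_field):
        _, fld = clean_field
        mask = seg.segment_frame(fld.field.red, seg.SegmentationConfig())
        assert mask.max() == fld.truth_mask.max()
        for lab in range(1, mask.max() + 1):
            ours = mask == lab
            overlap = fld.truth_mask[ours]
            truth_lab = np.bincount(overlap[overlap > 0]).argmax()
            truth = fld.truth_mask == truth_lab
            jacc = (ours & truth).sum() / (ours | truth).sum()
            assert jacc >= 0.95


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(min_cell_size_um2=0), dict(intensity_threshold_factor=-1),
        dict(pixel_size_um=0), dict(skeleton_length_mode="banana"),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            seg.SegmentationConfig(**kwargs)
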