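import numpy as np
import pandas as pd
import pytest
import skimage.filters

from microglia_morph import phagocytosis as ph
from microglia_morph import segmentation as seg
from microglia_morph import synthetic as syn


@pytest.fixture(scope="module")
def two_spike_image():
    """1000 px at grey 10, 200 px at grey 100."""
    return np.array([10.0] * 1000 + [100.0] * 200).reshape(40, 30)


class TestMaxProject:
    def test_single_plane_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(ph.max_project([img]), img)

    def test_pixelwise_maximum(self):
        stack = [np.full((2, 2), v) for v in (5.0, 9.0, 3.0)]
        assert (ph.max_project(stack) == 9.0).all()

    def test_random_stack_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 100, (3, 15, 17))
        out = ph.max_project(list(stack))
        for r in range(15):
            for c in range(17):
                assert out[r, c] == max(stack[0, r, c], stack[1, r, c],
                                        stack[2, r, c])

    def test_mismatched_planes_rejected(self):
        with pytest.raises(ValueError):
            ph.max_project([np.zeros((2, 2)), np.zeros((3, 3))])


class TestAutoThreshold:
    def test_isodata_intermeans_fixed_point(self, two_spike_image):
        t = ph.isodata_threshold(two_spike_image)
        # hand iteration on the two-spike histogram: mu0=10, mu1=100 -> t=55
        assert t == pytest.approx(55.0, abs=1.0)

    def test_isodata_matches_bruteforce_criterion(self, two_spike_image):
        t = ph.isodata_threshold(two_spike_image)
        counts, edges = np.histogram(two_spike_image.ravel(), bins=256,
                                     range=(10.0, 100.0))
        centers = (edges[:-1] + edges[1:]) / 2
        best_c, best_err = None, np.inf
        for c in centers:
            below = centers <= c
            w0, w1 = counts[below].sum(), counts[~below].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (counts[below] * centers[below]).sum() / w0
            m1 = (counts[~below] * centers[~below]).sum() / w1
            err = abs(c - (m0 + m1) / 2)
            if err < best_err:
                best_err, best_c = err, c
        assert t == pytest.approx(best_c, abs=(edges[1] - edges[0]))

    def test_both_methods_recover_bright_pixels_exactly(self, two_spike_image):
        for method in ("huang", "isodata"):
            fg = ph.auto_threshold(two_spike_image, method)
            assert fg.sum() == 200
            assert (two_spike_image[fg] == 100.0).all()

    def test_huang_matches_bruteforce_minimum(self, two_spike_image):
        t = ph.huang_threshold(two_spike_image)
        counts, edges = np.histogram(two_spike_image.ravel(), bins=256,
                                     range=(10.0, 100.0))
        centers = (edges[:-1] + edges[1:]) / 2
        c_range = centers[-1] - centers[0]

        def entropy_at(i):
            below = np.arange(256) <= i
            w0, w1 = counts[below].sum(), counts[~below].sum()
            if w0 == 0 or w1 == 0:
                return np.inf
            mu0 = (counts[below] * centers[below]).sum() / w0
            mu1 = (counts[~below] * centers[~below]).sum() / w1
            total = 0.0
            for g in range(256):
                mu = mu0 if g <= i else mu1
                u = 1.0 / (1.0 + abs(centers[g] - mu) / c_range)
                if 0 < u < 1:
                    total += counts[g] * -(u * np.log(u)
                                           + (1 - u) * np.log(1 - u))
            return total

        entropies = np.array([entropy_at(i) for i in range(255)])
        assert entropy_at(int(np.argmin(np.abs(centers - t)))) \
            == pytest.approx(entropies.min(), abs=1e-9)

    def test_huang_separates_noisy_bimodal_populations(self):
        rng = np.random.default_rng(5)
        img = np.concatenate([rng.normal(30, 4, 3000),
                              rng.normal(140, 12, 800)]).reshape(38, 100)
        img = np.clip(img, 0, None)
        fg = int((img > ph.huang_threshold(img)).sum())
        assert 790 <= fg <= 830  # essentially the 800 bright pixels

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ph.auto_threshold(np.full((5, 5), 3.0), "huang")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ph.auto_threshold(np.eye(5), "otsu")

    def test_isodata_agrees_with_skimage_on_bimodal(self):
        rng = np.random.default_rng(2)
        img = np.concatenate([rng.normal(20, 3, 4000),
                              rng.normal(120, 10, 1000)]).reshape(50, 100)
        ours = ph.isodata_threshold(img)
        theirs = skimage.filters.threshold_isodata(img)
        assert ours == pytest.approx(theirs, abs=3.0)


class TestContainment:
    def _masks(self):
        cells = np.zeros((30, 30), dtype=np.int32)
        cells[5:25, 5:15] = 3
        return cells

    def test_fully_inside(self):
        cells = self._masks()
        particles = np.zeros((30, 30), bool)
        particles[10:13, 8:11] = True
        rec = ph.assign_containment(cells, particles, 1.0).iloc[0]
        assert rec["host_cell_id"] == 3
        assert rec["inside_area_um2"] == rec["area_um2"]

    def test_on_background(self):
        cells = self._masks()
        particles = np.zeros((30, 30), bool)
        particles[2:4, 20:22] = True
        rec = ph.assign_containment(cells, particles, 1.0).iloc[0]
        assert rec["host_cell_id"] == 0

    def test_straddling_majority_and_exact_half(self):
        cells = self._masks()
        # 60/40 split: 6 px inside col 13-14, 4 px outside col 15-16
        particles = np.zeros((30, 30), bool)
        particles[10:12, 12:17] = True  # 10 px: cols 12,13,14 in, 15,16 out
        rec = ph.assign_containment(cells, particles, 1.0).iloc[0]
        assert rec["host_cell_id"] == 3
        # exactly 50%: 2x2 straddling the boundary at col 15
        particles = np.zeros((30, 30), bool)
        particles[10:12, 13:17] = True  # cols 13,14 in; 15,16 out -> 4/8
        rec = ph.assign_containment(cells, particles, 1.0).iloc[0]
        assert rec["host_cell_id"] == 0

    def test_area_conservation(self, clean_field):
        _, fld = clean_field
        rec = ph.assign_containment(fld.truth_mask, fld.particle_mask,
                                    fld.field.pixel_size_um)
        px2 = fld.field.pixel_size_um ** 2
        total = float((fld.particle_mask > 0).sum()) * px2
        inside = rec["inside_area_um2"].sum()
        outside = (rec["area_um2"] - rec["inside_area_um2"]).sum()
        assert inside + outside == pytest.approx(total, abs=1e-9)


@pytest.fixture(scope="module")
def engulfment_lapse():
    """One shrinking co-moving engulfed particle + one static free particle."""
    cells = (
        (syn.archetype("fried_egg", seed=2), (90.0, 90.0)),
        (syn.archetype("round", seed=3), (90.0, 220.0)),
    )
    particles = (
        syn.ParticleSpec(radius_um=4.0, engulfed_by=1),
        syn.ParticleSpec(radius_um=3.0, position=(220.0, 150.0)),
    )
    spec = syn.FieldSpec(image_size_px=(300, 300), cells=cells,
                         particles=particles, seed=5)
    frames = syn.render_timelapse(spec, n_frames=5, motion={1: (3.0, 0.0)},
                                  shrink_rate=0.2)
    cell_masks = [f.truth_mask for f in frames]
    particle_masks = [f.particle_mask > 0 for f in frames]
    return frames, cell_masks, particle_masks


class TestConfirmEngulfment:
    def test_engulfed_confirmed_free_not(self, engulfment_lapse):
        frames, cell_masks, particle_masks = engulfment_lapse
        _, conf, _ = ph.analyse_timelapse(cell_masks, particle_masks,
                                          frames[0].field.pixel_size_um)
        confirmed = conf[conf["confirmed"]]
        assert len(confirmed) == 1
        assert confirmed.iloc[0]["host_cell_id"] == 1
        free = conf[conf["host_cell_id"] == 0]
        assert not free["confirmed"].any()

    def test_constant_area_particle_unconfirmed(self, engulfment_lapse):
        frames, cell_masks, _ = engulfment_lapse
        # same lapse without shrinkage: co-movement alone must not confirm
        spec_frames = syn.render_timelapse(
            syn.FieldSpec(
                image_size_px=(300, 300),
                cells=((syn.archetype("fried_egg", seed=2), (90.0, 90.0)),),
                particles=(syn.ParticleSpec(radius_um=4.0, engulfed_by=1),),
                seed=5),
            n_frames=5, motion={1: (3.0, 0.0)}, shrink_rate=0.0)
        masks = [f.truth_mask for f in spec_frames]
        pmasks = [f.particle_mask > 0 for f in spec_frames]
        _, conf, _ = ph.analyse_timelapse(masks, pmasks, 0.758, min_shrink=0.1)
        assert not conf["confirmed"].any()
        assert conf["co_movement_ok"].all()

    def test_short_track_flagged_insufficient(self):
        rec = pd.DataFrame([
            dict(particle_id=1, frame_index=0, area_um2=10.0, centroid_row=5.0,
                 centroid_col=5.0, host_cell_id=1, inside_area_um2=10.0,
                 needs_review=True, track_id=1),
            dict(particle_id=1, frame_index=1, area_um2=9.0, centroid_row=5.0,
                 centroid_col=5.0, host_cell_id=1, inside_area_um2=9.0,
                 needs_review=True, track_id=1),
        ])
        conf = ph.confirm_engulfment(rec, {0: {1: (5.0, 5.0)},
                                           1: {1: (5.0, 5.0)}})
        assert bool(conf.iloc[0]["insufficient_data"])
        assert not conf.iloc[0]["confirmed"]

    def test_min_shrink_gate_monotone(self, engulfment_lapse):
        frames, cell_masks, particle_masks = engulfment_lapse
        px = frames[0].field.pixel_size_um
        counts = []
        for min_shrink in (0.0, 0.3, 0.6, 0.9):
            _, conf, _ = ph.analyse_timelapse(cell_masks, particle_masks, px,
                                              min_shrink=min_shrink)
            counts.append(int(conf["confirmed"].sum()))
        assert counts == sorted(counts, reverse=True)


class TestStatistics:
    def test_phago_index_arithmetic(self):
        assert ph.phago_index(50, 200, 5) == pytest.approx(5.0)
        assert ph.phago_index(0, 200, 5) == 0.0
        assert ph.phago_index(100, 100, 1) == pytest.approx(100.0)

    def test_phago_index_errors(self):
        with pytest.raises(ValueError):
            ph.phago_index(10, 0, 5)
        with pytest.raises(ValueError):
            ph.phago_index(10, 100, 0)

    def test_phagocytosing_pct(self):
        flags = {i: i < 4 for i in range(25)}
        assert ph.phagocytosing_pct(flags) == pytest.approx(16.0)
        assert ph.phagocytosing_pct({1: False, 2: False}) == 0.0
        assert ph.phagocytosing_pct({1: True}) == 100.0

    def test_delta_sytox_signed(self):
        assert ph.delta_sytox(500, 300) == 200
        assert ph.delta_sytox(300, 300) == 0
        assert ph.delta_sytox(300, 500) == -200

    def test_truth_derived_statistics_on_synthetic_field(self, clean_field):
        _, fld = clean_field
        px2 = fld.field.pixel_size_um ** 2
        rec = ph.assign_containment(fld.truth_mask, fld.particle_mask,
                                    fld.field.pixel_size_um)
        inside = rec["inside_area_um2"].sum()
        total = rec["area_um2"].sum()
        n = int(fld.truth_mask.max())
        # truth: particle 1 engulfed by cell 2, particle 2 free
        truth_inside = fld.particles.loc[0, "area_px"] * px2
        truth_total = fld.particles["area_px"].sum() * px2
        assert inside == pytest.approx(truth_inside, abs=1e-9)
        assert total == pytest.approx(truth_total, abs=1e-9)
        expected = 100.0 * (truth_inside / truth_total) / n
        assert ph.phago_index(inside, total, n) == pytest.approx(expected)


class TestIndexProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.floats(0.0, 1.0), st.floats(1.0, 1e4), st.integers(1, 500))
    @settings(derandomize=True, max_examples=60)
    def test_phago_index_bounds(self, frac, total, n):
        """The index lies in [0, 100/n] for any inside fraction."""
        inside = frac * total
        idx = ph.phago_index(inside, total, n)
        assert 0.0 <= idx <= 100.0 / n + 1e-9
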