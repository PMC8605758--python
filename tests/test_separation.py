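"""Structure-tensor junction detection and 1-px separation cuts."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from sporemorph.morphometry import label_objects
from sporemorph.segmentation import threshold_fallback
from sporemorph.separation import (JunctionSet, SeparationParams,
                                   apply_separation, calibrate_eigen_threshold,
                                   junction_regions, link_junctions,
                                   separate_mask, structure_eigen_map)


@pytest.fixture(scope="module")
def pair_setup(disk_pair_scene):
    scene, objects, img, mask = disk_pair_scene
    d_px = 12.0 / scene.um_per_px
    params = SeparationParams(smoothing_scale=1.0,
                              integration_scale=d_px / 10,
                              max_radius_px=0.6 * d_px)
    thr = calibrate_eigen_threshold(d_px, params, noise_sd=scene.noise_sd)
    emap = structure_eigen_map(img, params.smoothing_scale,
                               params.integration_scale)
    seg_mask = threshold_fallback(img)
    return scene, objects, img, seg_mask, params, thr, emap


def _contact_px(objects, scene):
    (x0, y0), (x1, y1) = objects[0].center_um, objects[1].center_um
    return ((x0 + x1) / 2 / scene.um_per_px, (y0 + y1) / 2 / scene.um_per_px)


class TestStructureEigenMap:
    def test_uniform_image_all_zero(self):
        emap = structure_eigen_map(np.full((40, 50), 200.0), 1.0, 3.0)
        assert np.allclose(emap, 0.0)

    def test_nonnegative_and_scale_validation(self, pair_setup):
        _, _, img, _, params, _, emap = pair_setup
        assert np.all(emap >= 0)
        with pytest.raises(ValueError):
            structure_eigen_map(img, -1.0, 3.0)

    def test_global_maxima_flank_the_contact(self, pair_setup):
        scene, objects, _, _, _, _, emap = pair_setup
        cx, cy = _contact_px(objects, scene)
        # the two highest responses sit within 5 px of the junction corners
        flat = np.argsort(emap.ravel())[::-1][:40]
        ys, xs = np.unravel_index(flat, emap.shape)
        top = np.column_stack([xs[:2], ys[:2]])
        for x, y in top:
            assert abs(x - cx) <= 5
        assert any(y < cy for _, y in top) and any(y > cy for _, y in top)

    def test_isolated_disk_weaker_than_junction(self, pair_setup):
        scene, objects, _, _, _, _, emap = pair_setup
        cx, cy = _contact_px(objects, scene)
        ix, iy = (objects[2].center_um[0] / scene.um_per_px,
                  objects[2].center_um[1] / scene.um_per_px)
        junction = emap[int(cy) - 10:int(cy) + 10, int(cx) - 10:int(cx) + 10]
        iso = emap[int(iy) - 16:int(iy) + 16, int(ix) - 16:int(ix) + 16]
        assert junction.max() > 2 * iso.max()


class TestJunctionRegions:
    def test_threshold_above_max_gives_empty_set(self, pair_setup):
        *_, emap = pair_setup
        js = junction_regions(emap, float(emap.max()) * 2)
        assert js.n == 0

    def test_tangent_pair_yields_two_flanking_regions(self, pair_setup):
        scene, objects, _, seg_mask, _, thr, emap = pair_setup
        cx, cy = _contact_px(objects, scene)
        js = junction_regions(emap, thr, foreground=seg_mask)
        near = [(x, y) for x, y in js.centroids
                if abs(x - cx) < 12 and abs(y - cy) < 12]
        assert len(near) == 2
        assert any(y < cy for _, y in near) and any(y > cy for _, y in near)

    def test_isolated_disk_triggers_no_regions(self, pair_setup):
        scene, objects, _, seg_mask, _, thr, emap = pair_setup
        js = junction_regions(emap, thr, foreground=seg_mask)
        ix = objects[2].center_um[0] / scene.um_per_px
        iy = objects[2].center_um[1] / scene.um_per_px
        near_iso = [(x, y) for x, y in js.centroids
                    if abs(x - ix) < 16 and abs(y - iy) < 16]
        assert near_iso == []

    def test_nonpositive_threshold_rejected(self, pair_setup):
        *_, emap = pair_setup
        with pytest.raises(ValueError):
            junction_regions(emap, 0.0)


class TestLinkJunctions:
    def _junctions(self, centroids):
        return JunctionSet(eigen_threshold=1.0,
                           regions=np.zeros((1, 1), dtype=int),
                           centroids=centroids)

    def test_pair_within_radius_linked(self):
        lines = link_junctions(self._junctions([(10, 10), (10, 20)]), 15)
        assert lines.n == 1

    def test_pair_beyond_radius_not_linked(self):
        lines = link_junctions(self._junctions([(10, 10), (10, 30)]), 15)
        assert lines.n == 0

    def test_each_centroid_used_once_nearest_first(self):
        # three collinear points: only the closest pair links
        lines = link_junctions(self._junctions([(0, 0), (6, 0), (13, 0)]), 10)
        assert lines.n == 1
        assert lines.segments[0] == ((0, 0), (6, 0))

    def test_two_tangent_pairs_give_two_segments(self):
        pts = [(10, 10), (10, 20), (60, 10), (60, 20)]
        lines = link_junctions(self._junctions(pts), 15)
        assert lines.n == 2


class TestApplySeparation:
    def test_empty_lines_identity(self, pair_setup):
        _, _, _, seg_mask, params, thr, _ = pair_setup
        from sporemorph.separation import SeparationLines
        out = apply_separation(seg_mask, SeparationLines())
        assert np.array_equal(out, seg_mask)

    def test_cut_disconnects_tangent_pair(self, pair_setup):
        scene, objects, img, seg_mask, params, thr, _ = pair_setup
        cx, cy = _contact_px(objects, scene)
        sub = seg_mask[:, :int(cx) + 30]         # region holding only the pair
        before = ndi.label(sub, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))[1]
        out, lines, _ = separate_mask(img, seg_mask, params,
                                      eigen_threshold=thr)
        assert lines.n >= 1
        after = ndi.label(out[:, :int(cx) + 30], structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))[1]
        assert before == 1 and after == 2

    def test_never_adds_foreground_and_bounded_loss(self, pair_setup):
        scene, objects, img, seg_mask, params, thr, _ = pair_setup
        out, lines, _ = separate_mask(img, seg_mask, params,
                                      eigen_threshold=thr)
        assert not (out & ~seg_mask).any()
        lost = int(seg_mask.sum() - out.sum())
        budget = sum(
            int(np.hypot(x1 - x0, y1 - y0)) + 1
            for (x0, y0), (x1, y1) in lines.segments)
        assert lost <= budget

    def test_out_of_bounds_segment_rejected(self, pair_setup):
        _, _, _, seg_mask, *_ = pair_setup
        from sporemorph.separation import SeparationLines
        bad = SeparationLines(segments=[((0, 0), (10_000, 0))])
        with pytest.raises(ValueError, match="outside"):
            apply_separation(seg_mask, bad)


class TestEndToEndSeparation:
    def test_monolayer_pairs_split_and_isolated_untouched(self):
        """Dense monolayer with 30% contacts: >= 90% of touching pairs end
        in distinct labels, <= 2% of isolated spores are falsely split."""
        from sporemorph.fixtures import (SceneConfig, make_tile_grid,
                                         objects_from_table)
        scene = SceneConfig(tile_rows=1, tile_cols=1, tile_width_px=960,
                            tile_height_px=720, um_per_px=0.5,
                            spores_per_tile_mean=80.0, contact_fraction=0.3,
                            seed=37)
        grid, truth = make_tile_grid(scene)
        img = grid.tiles[(0, 0)]
        d_px = 12.0 / scene.um_per_px
        params = SeparationParams(smoothing_scale=1.0,
                                  integration_scale=d_px / 10,
                                  max_radius_px=0.6 * d_px)
        thr = calibrate_eigen_threshold(d_px, params, noise_sd=scene.noise_sd)
        mask = threshold_fallback(img)
        out, _, _ = separate_mask(img, mask, params, eigen_threshold=thr)
        labels = label_objects(out)

        objects = objects_from_table(truth)
        centers = np.array([o.center_um for o in objects]) / scene.um_per_px
        radii = np.array([o.radius_um for o in objects]) / scene.um_per_px
        label_at = [labels[int(round(y)), int(round(x))]
                    for x, y in centers]
        touching = set()
        pairs = []
        for i in range(len(objects)):
            for j in range(i + 1, len(objects)):
                if np.hypot(*(centers[i] - centers[j])) <= \
                        radii[i] + radii[j] + 0.1:
                    pairs.append((i, j))
                    touching.update((i, j))
        split_ok = sum(1 for i, j in pairs
                       if label_at[i] != 0 and label_at[j] != 0
                       and label_at[i] != label_at[j])
        assert pairs, "fixture must contain touching pairs"
        assert split_ok / len(pairs) >= 0.9
        # isolated spores keep exactly one label: compare object count
        isolated = [k for k in range(len(objects)) if k not in touching]
        falsely_split = 0
        for k in isolated:
            x, y = centers[k]
            r = int(radii[k] * 0.7)
            window = labels[int(y) - r:int(y) + r, int(x) - r:int(x) + r]
            inside = np.unique(window[window > 0])
            if len(inside) > 1:
                falsely_split += 1
        assert falsely_split / max(len(isolated), 1) <= 0.02
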