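"""Shared synthetic fixtures: small rendered scenes with exact ground truth."""

import numpy as np
import pytest

from sporemorph.fixtures import (SceneConfig, GroundTruthObject, render_tile,
                                 ground_truth_mask, make_tile_grid)


@pytest.fixture(scope="session")
def small_scene() -> SceneConfig:
    """One 400 x 300 px tile at 0.5 µm/px with a handful of spores."""
    return SceneConfig(tile_rows=1, tile_cols=1, tile_width_px=400,
                       tile_height_px=300, um_per_px=0.5,
                       spores_per_tile_mean=8.0, contact_fraction=0.0,
                       seed=3)


@pytest.fixture(scope="session")
def small_slide(small_scene):
    """(grid, truth) of the one-tile scene."""
    return make_tile_grid(small_scene)


@pytest.fixture(scope="session")
def disk_pair_scene():
    """One tile holding a tangent spore pair plus an isolated spore.

    The tangent pair touches with the generator's sub-pixel contact
    overlap; the isolated spore sits well clear of both.
    """
    scene = SceneConfig(tile_rows=1, tile_cols=1, tile_width_px=300,
                        tile_height_px=200, um_per_px=0.5, noise_sd=3.0,
                        seed=11)
    d = 12.0
    touch = 0.5 * scene.um_per_px
    objects = [
        GroundTruthObject(0, "spore_normal", (60.0, 50.0), d, 1.0, 0.0, (0, 0)),
        GroundTruthObject(1, "spore_normal", (60.0 + d - touch, 50.0), d,
                          1.0, 0.0, (0, 0)),
        GroundTruthObject(2, "spore_normal", (110.0, 50.0), d, 1.0, 0.3, (0, 0)),
    ]
    img = render_tile(objects, scene, (0, 0))
    mask = ground_truth_mask(objects, scene, (0, 0))
    return scene, objects, img, mask


@pytest.fixture(scope="session")
def clean_tile():
    """Noise-free tile with isolated spores and its ground-truth mask."""
    scene = SceneConfig(tile_rows=1, tile_cols=1, tile_width_px=320,
                        tile_height_px=240, um_per_px=0.5, noise_sd=0.0,
                        spores_per_tile_mean=6.0, contact_fraction=0.0,
                        seed=21)
    grid, truth = make_tile_grid(scene)
    img = grid.tiles[(0, 0)]
    from sporemorph.fixtures import objects_from_table
    mask = ground_truth_mask(objects_from_table(truth), scene, (0, 0))
    return scene, img, mask
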