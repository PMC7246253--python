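"""Feed-forward feature extraction: hue, orientation, size, salience."""

import numpy as np
import pytest

from dnf_visearch import stimuli as stim
from dnf_visearch.vision_frontend import (
    extract_color,
    extract_maps,
    extract_orientation,
    extract_size,
    salience_input,
)


def one_bar(tile=12, color="red", orientation=0.0,
            length=stim.BAR_LENGTH_PX, width=stim.BAR_WIDTH_PX):
    spec = stim.StimulusArraySpec(
        items=[stim.ArrayItem(tile, color, orientation)],
        target_index=0, condition=1, experiment=1, set_size=4, seed=0,
    )
    frame = stim.render(spec, "array")
    return frame


def cell_of(cfg, tile):
    xd, yd = cfg.vision.space_dims()
    cx, cy = stim.tile_center(tile)
    return xd.index_of(cx), yd.index_of(cy)


@pytest.mark.parametrize("color,hue", [("red", 0.0), ("green", 120.0),
                                       ("blue", 240.0)])
def test_pure_colors_map_to_their_hue(cfg, color, hue):
    frame = one_bar(color=color)
    cmap = extract_color(frame, cfg.vision)
    xi, yi = cell_of(cfg, 12)
    got = cfg.vision.hue_dim().grid()[int(cmap[xi, yi].argmax())]
    d = abs(got - hue)
    assert min(d, 360 - d) < cfg.vision.hue_dim().spacing


def test_background_gives_zero_color_response(cfg):
    spec = stim.generate_array(1, 4, seed=0)
    blank = stim.render(spec, "blank")
    assert extract_color(blank, cfg.vision).max() == 0.0


def _moment_axis(frame):
    """Oracle: principal-axis angle of the bar mask via image moments,
    in the renderer's convention (0 = vertical)."""
    from skimage.color import rgb2hsv

    sat = rgb2hsv(frame.rgb)[..., 1]
    ys, xs = np.nonzero(sat > 0.5)
    x = xs - xs.mean()
    y = ys - ys.mean()
    theta = 0.5 * np.arctan2(2 * (x * y).mean(),
                             (x ** 2).mean() - (y ** 2).mean())
    # image angle from horizontal -> renderer angle from vertical
    return (90.0 - np.rad2deg(theta)) % 180.0


@pytest.mark.parametrize("angle", [0.0, 45.0, 90.0, 135.0])
def test_orientation_argmax_matches_moment_axis(cfg, angle):
    frame = one_bar(orientation=angle)
    oracle = _moment_axis(frame)
    omap = extract_orientation(frame, cfg.vision)
    xi, yi = cell_of(cfg, 12)
    got = cfg.vision.orientation_dim().grid()[int(omap[xi, yi].argmax())]
    d = abs(got - oracle)
    assert min(d, 180 - d) <= cfg.vision.orientation_dim().spacing


def test_isotropic_blob_has_no_preferred_orientation(cfg):
    # a square patch: opponent channels cancel
    frame = one_bar()
    frame.rgb[:] = 255
    cx, cy = stim.tile_center(12)
    frame.rgb[int(cy) - 20:int(cy) + 20, int(cx) - 20:int(cx) + 20] = (255, 0, 0)
    omap = extract_orientation(frame, cfg.vision)
    xi, yi = cell_of(cfg, 12)
    assert omap[xi, yi].max() < 0.3


def test_size_dominant_level_grows_with_bar_length(cfg_full):
    levels = []
    for length in (30.0, 60.0, 120.0):
        frame = one_bar(length=length)
        smap = extract_size(frame, cfg_full.vision)
        xi, yi = cell_of(cfg_full, 12)
        local = smap[xi - 1:xi + 2, yi - 1:yi + 2, :].max(axis=(0, 1))
        levels.append(int(local.argmax()))
    assert levels == sorted(levels), f"levels must not decrease: {levels}"


def test_same_bars_same_dominant_scale(cfg_full):
    spec = stim.StimulusArraySpec(
        items=[stim.ArrayItem(10, "red", 0.0), stim.ArrayItem(14, "red", 0.0)],
        target_index=0, condition=1, experiment=1, set_size=4, seed=0,
    )
    smap = extract_size(stim.render(spec, "array"), cfg_full.vision)
    lv = []
    for tile in (10, 14):
        xi, yi = cell_of(cfg_full, tile)
        local = smap[xi - 1:xi + 2, yi - 1:yi + 2, :].max(axis=(0, 1))
        lv.append(int(local.argmax()))
    assert lv[0] == lv[1]


@pytest.mark.parametrize("k", [1, 4, 8])
def test_salience_has_one_maximum_per_item(cfg, k):
    from scipy import ndimage

    sizes = {1: 4, 4: 4, 8: 8}
    spec = stim.generate_array(2, sizes[k], seed=k)
    spec.items[:] = spec.items[:k]
    maps = extract_maps(stim.render(spec, "array"), cfg.vision)
    sal = salience_input(maps, features=cfg.features).grid
    supra = sal > 0.4
    labels, n = ndimage.label(supra)
    assert n == k


def test_empty_frame_zero_salience(cfg):
    spec = stim.generate_array(1, 4, seed=0)
    maps = extract_maps(stim.render(spec, "blank"), cfg.vision)
    assert salience_input(maps, features=cfg.features).grid.max() == 0.0


def test_deleting_item_changes_salience_only_locally(cfg):
    spec = stim.generate_array(2, 6, seed=4)
    maps_all = extract_maps(stim.render(spec, "array"), cfg.vision)
    removed = spec.items[2]
    spec2 = stim.StimulusArraySpec(
        items=[i for i in spec.items if i is not removed],
        target_index=0, condition=2, experiment=1, set_size=6, seed=4,
    )
    maps_less = extract_maps(stim.render(spec2, "array"), cfg.vision)
    a = salience_input(maps_all, features=cfg.features).grid
    b = salience_input(maps_less, features=cfg.features).grid
    diff = np.abs(a - b)
    xd, yd = cfg.vision.space_dims()
    cx, cy = stim.tile_center(removed.tile)
    xi, yi = xd.index_of(cx), yd.index_of(cy)
    far = diff.copy()
    far[max(xi - 4, 0):xi + 5, max(yi - 4, 0):yi + 5] = 0.0
    assert diff[xi, yi] > 0.5
    assert far.max() < 0.1


def test_translation_equivariance(cfg):
    """Moving an item by one tile moves its feature response by one tile."""
    m1 = extract_maps(one_bar(tile=11, orientation=45.0), cfg.vision)
    m2 = extract_maps(one_bar(tile=12, orientation=45.0), cfg.vision)
    shift = int(round(stim.TILE_PX / cfg.vision.cell_px[0]))
    rolled = np.roll(m1.orientation, shift, axis=0)
    # compare on the interior to avoid boundary effects
    assert np.allclose(rolled[shift:, :, :], m2.orientation[shift:, :, :],
                       atol=0.15)


def test_feature_independence_color_change(cfg):
    a = extract_maps(one_bar(color="red", orientation=45.0), cfg.vision)
    b = extract_maps(one_bar(color="blue", orientation=45.0), cfg.vision)
    assert np.allclose(a.orientation, b.orientation, atol=0.12)
    assert np.allclose(a.size, b.size, atol=0.12)
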