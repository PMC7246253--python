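"""Scene working memory: read-out, commitment, capacity, recall."""

import numpy as np
import pytest

from dnf_visearch import stimuli as stim
from dnf_visearch.dnf_core import RngStreams
from dnf_visearch.scene_memory import (
    commit_item,
    extract_attended_features,
    make_memory,
    memory_snapshot,
    recall_at_location,
    retained_tiles,
    spatial_peak_count,
)
from dnf_visearch.vision_frontend import extract_maps


HUE_OF = {"red": 0.0, "green": 120.0, "blue": 240.0}


def scene(items):
    spec = stim.StimulusArraySpec(
        items=[stim.ArrayItem(*i) for i in items],
        target_index=0, condition=3, experiment=1, set_size=6, seed=0,
    )
    return spec


def profile_peak(dim, profile):
    """Circular weighted mean of a feature profile (robust to saturated
    plateaus in the squashed read-out)."""
    w = np.asarray(profile, dtype=float)
    ang = np.deg2rad(dim.grid() * (360.0 / dim.length))
    z = (w * np.exp(1j * ang)).sum()
    val = np.rad2deg(np.angle(z)) * (dim.length / 360.0)
    return float(val % dim.length)


def circ_close(got, want, period, tol):
    d = abs(got - want) % period
    return min(d, period - d) <= tol


def test_attended_features_match_item(cfg):
    spec = scene([(6, "red", 45.0), (18, "green", 90.0)])
    maps = extract_maps(stim.render(spec, "array"), cfg.vision)
    memory = make_memory(cfg)
    out = extract_attended_features(maps, stim.tile_center(6), memory,
                                    dt=cfg.dt, rng=RngStreams(0))
    hue = cfg.vision.hue_dim()
    ori = cfg.vision.orientation_dim()
    assert out["color"].max() > 0.3
    assert profile_peak(hue, out["color"]) == pytest.approx(0.0, abs=31)
    assert profile_peak(ori, out["orientation"]) == pytest.approx(45.0, abs=23)
    # the other item's features do not intrude
    green_bin = hue.index_of(120.0)
    assert out["color"][green_bin] < 0.2


def test_empty_tile_yields_no_activation(cfg):
    spec = scene([(6, "red", 45.0)])
    maps = extract_maps(stim.render(spec, "array"), cfg.vision)
    memory = make_memory(cfg)
    out = extract_attended_features(maps, stim.tile_center(14), memory,
                                    dt=cfg.dt, rng=RngStreams(0))
    assert all(v.max() < 0.2 for v in out.values())


def _commit(memory, cfg, tile, color, orientation, rng):
    hue = cfg.vision.hue_dim()
    ori = cfg.vision.orientation_dim()
    from dnf_visearch.dnf_core import gaussian_bump

    slices = {
        "color": gaussian_bump((hue,), (HUE_OF[color],), hue.spacing, 1.0),
        "orientation": gaussian_bump((ori,), (orientation,), ori.spacing, 1.0),
    }
    commit_item(memory, stim.tile_center(tile), slices, dt=cfg.dt, rng=rng)


def test_three_commits_three_locations(cfg):
    memory = make_memory(cfg)
    rng = RngStreams(1)
    for tile, color, ori in ((0, "red", 45.0), (14, "green", 90.0),
                             (18, "blue", 0.0)):
        _commit(memory, cfg, tile, color, ori, rng)
    assert spatial_peak_count(memory) == 3
    assert set(retained_tiles(memory)) == {0, 14, 18}


def test_recommit_does_not_duplicate(cfg):
    memory = make_memory(cfg)
    rng = RngStreams(2)
    _commit(memory, cfg, 10, "red", 45.0, rng)
    _commit(memory, cfg, 10, "red", 45.0, rng)
    assert spatial_peak_count(memory) == 1


def test_capacity_limits_sequential_commits(cfg):
    """Committing more items than the capacity displaces older ones: the
    retained count saturates near the configured limit."""
    memory = make_memory(cfg)
    rng = RngStreams(3)
    plan = [(0, "red", 0.0), (4, "green", 45.0), (10, "blue", 90.0),
            (14, "red", 135.0), (16, "green", 0.0), (18, "blue", 45.0)]
    for tile, color, ori in plan:
        _commit(memory, cfg, tile, color, ori, rng)
    n = spatial_peak_count(memory)
    assert 3 <= n <= 5, f"capacity-limited retention, got {n}"
    assert n < 6, "at least one item must have been displaced"


def test_binding_recall_at_location(cfg):
    memory = make_memory(cfg)
    rng = RngStreams(4)
    _commit(memory, cfg, 6, "red", 45.0, rng)
    _commit(memory, cfg, 18, "blue", 90.0, rng)
    hue = cfg.vision.hue_dim()
    ori = cfg.vision.orientation_dim()
    rec = recall_at_location(memory, stim.tile_center(6), dt=cfg.dt,
                             rng=rng)
    assert circ_close(profile_peak(hue, rec["color"]), 0.0, 360, 31)
    assert circ_close(profile_peak(ori, rec["orientation"]), 45.0, 180, 23)
    rec2 = recall_at_location(memory, stim.tile_center(18), dt=cfg.dt,
                              rng=rng)
    assert circ_close(profile_peak(hue, rec2["color"]), 240.0, 360, 31)
    empty = recall_at_location(memory, stim.tile_center(2), dt=cfg.dt,
                               rng=rng)
    assert all(v.max() < 0.2 for v in empty.values())


def test_memory_snapshot_reports_stored_features(cfg):
    memory = make_memory(cfg)
    rng = RngStreams(5)
    _commit(memory, cfg, 6, "green", 90.0, rng)
    snap = memory_snapshot(memory)
    assert len(snap) == 1
    assert snap[0]["tile"] == 6
    assert circ_close(snap[0]["color"], 120.0, 360, 31)
    assert circ_close(snap[0]["orientation"], 90.0, 180, 23)


def test_memory_survives_blank_frame(cfg):
    """The scene memory maps are not reset by stimulus offset (unlike the
    spatial working memory field)."""
    from dnf_visearch import task_control as tc
    from dnf_visearch.vision_frontend import salience_input

    spec = scene([(6, "red", 45.0), (18, "green", 90.0)])
    arch = tc.Architecture(cfg, seed=6)
    arch.cue_tile_center = None
    arch.item_salience_mass = tc.reference_item_mass(cfg)
    maps = extract_maps(stim.render(spec, "array"), cfg.vision)
    sal = salience_input(maps, features=cfg.features).grid
    while arch.t_ms < 2000:
        arch.step(maps, sal)
    # a commitment interrupted mid-drive may be lost; every consolidated
    # item (strong sustained peak) must survive the blank
    consolidated = set(retained_tiles(arch.memory, min_activation=7.0))
    assert consolidated
    for _ in range(int(600 / cfg.dt)):  # blank display
        arch.step(None, None)
    tiles_after = set(retained_tiles(arch.memory, min_activation=2.0))
    assert tiles_after >= consolidated
    assert (arch.attention.swm.u > 0).sum() == 0, "SWM resets, memory stays"
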