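"""Task sequencing: exploration cycles, cue retention, guided search."""

import numpy as np
import pytest

from dnf_visearch import stimuli as stim
from dnf_visearch import task_control as tc
from dnf_visearch.vision_frontend import extract_maps, salience_input

HUE_OF = {"red": 0.0, "green": 120.0, "blue": 240.0}


def make_arch(cfg, seed, cue_tile=True, cue_features=("color", "orientation")):
    arch = tc.Architecture(cfg, seed=seed)
    arch.cue_features = cue_features
    arch.cue_tile_center = stim.tile_center(stim.CUE_TILE) if cue_tile else None
    arch.item_salience_mass = tc.reference_item_mass(cfg)
    return arch


def maps_and_salience(cfg, spec, segment):
    maps = extract_maps(stim.render(spec, segment), cfg.vision)
    return maps, salience_input(maps, features=cfg.features).grid


def test_explore_cycles_commit_distinct_items(cfg):
    """Three items, three cycles: three distinct commitments, no repeats
    before coverage."""
    spec = stim.StimulusArraySpec(
        items=[stim.ArrayItem(0, "red", 45.0), stim.ArrayItem(8, "green", 90.0),
               stim.ArrayItem(16, "blue", 0.0)],
        target_index=0, condition=3, experiment=1, set_size=6, seed=0,
    )
    arch = make_arch(cfg, seed=1, cue_tile=False)
    maps, sal = maps_and_salience(cfg, spec, "array")
    committed = []
    for _ in range(3):
        event = tc.run_explore_cycle(arch, maps, max_ms=1500.0)
        assert event is not None, "each cycle must end in a commitment"
        committed.append(event["tile"])
    assert set(committed) == {0, 8, 16}, f"visited {committed}"


def test_empty_array_never_commits(cfg):
    spec = stim.StimulusArraySpec(
        items=[], target_index=0, condition=3, experiment=1,
        set_size=6, seed=0,
    )
    arch = make_arch(cfg, seed=2, cue_tile=False)
    maps, _ = maps_and_salience(cfg, spec, "array")
    event = tc.run_explore_cycle(arch, maps, max_ms=1200.0)
    assert event is None


@pytest.mark.parametrize("k", [4, 6, 8])
def test_exploration_scan_path_avoids_revisits(cfg, k):
    """Inhibition of return makes sequential commitments visit distinct
    items: within the working-memory capacity window no item is committed
    twice (beyond it, verification retries may return to evicted items)."""
    spec = stim.generate_array(2, k if k in (4, 6, 8) else 8, seed=40 + k)
    arch = make_arch(cfg, seed=40 + k, cue_tile=False)
    maps, _ = maps_and_salience(cfg, spec, "array")
    visited = []
    for _ in range(k):
        event = tc.run_explore_cycle(arch, maps, max_ms=2500.0)
        if event is None:
            break
        visited.append(event["tile"])
    window = visited[:min(k, cfg.memory_capacity)]
    assert len(window) == len(set(window)), f"early revisit: {visited}"
    assert len(set(visited)) >= min(k, 3)


def test_retain_stores_cue_features(cfg):
    spec = stim.generate_array(3, 6, seed=5)
    arch = make_arch(cfg, seed=3)
    maps, _ = maps_and_salience(cfg, spec, "array+cue")
    event = tc.run_retain(arch, maps, max_ms=2500.0)
    assert event is not None, "retention must complete"
    want_hue = HUE_OF[spec.target.color]
    d = abs(event["cue"]["color"] - want_hue) % 360
    assert min(d, 360 - d) <= 31
    d = abs(event["cue"]["orientation"] - spec.target.orientation) % 180
    assert min(d, 180 - d) <= 23


def test_cue_persists_after_retention(cfg):
    """The search-cue fields are self-sustained: the stored peaks outlive
    the retention episode."""
    spec = stim.generate_array(3, 6, seed=5)
    arch = make_arch(cfg, seed=3)
    maps, sal = maps_and_salience(cfg, spec, "array+cue")
    event = tc.run_retain(arch, maps, max_ms=2500.0)
    assert event is not None
    for _ in range(int(800 / cfg.dt)):
        arch.step(maps, sal)
    for f in arch.cue_features:
        assert arch.task.cue_fields_I[f].u.max() > 2.0


def test_guidance_follows_n_minus_1_rule(cfg):
    """With n cued features, guidance peaks appear exactly for items
    sharing at least n-1 of them (scene pathway)."""
    items = [stim.ArrayItem(6, "red", 45.0), stim.ArrayItem(8, "red", 90.0),
             stim.ArrayItem(16, "green", 45.0), stim.ArrayItem(18, "green", 90.0)]
    spec = stim.StimulusArraySpec(items=items, target_index=0, condition=3,
                                  experiment=1, set_size=4, seed=0)
    maps = extract_maps(stim.render(spec, "array"), cfg.vision)
    xd, yd = cfg.vision.space_dims()

    def biases(cue):
        bias = tc.compute_guidance(maps, {}, cue, None, cfg)
        out = {}
        for it in items:
            cx, cy = stim.tile_center(it.tile)
            xi, yi = xd.index_of(cx), yd.index_of(cy)
            out[(it.color, it.orientation)] = float(
                bias[max(xi - 1, 0):xi + 2, max(yi - 1, 0):yi + 2].max())
        return out

    two = biases({"color": 0.0, "orientation": 45.0})
    assert two[("red", 45.0)] > 0.3      # full match
    assert two[("red", 90.0)] > 0.3      # shares color
    assert two[("green", 45.0)] > 0.3    # shares orientation
    assert two[("green", 90.0)] < 0.05   # shares nothing

    one = biases({"color": 0.0})
    assert one[("red", 45.0)] > 0.3 and one[("red", 90.0)] > 0.3
    assert one[("green", 45.0)] < 0.05 and one[("green", 90.0)] < 0.05

    none = biases({})
    assert max(none.values()) < 0.05


def test_search_finds_target(cfg):
    ok = 0
    for k in range(4):
        spec = stim.generate_array(3, 6, seed=60 + k)
        outcome, arch = tc.run_trial(spec, cfg=cfg, seed=70 + k)
        if outcome.selected_tile == spec.target.tile:
            ok += 1
            assert outcome.rt_ms is not None and outcome.rt_ms > 0
    assert ok >= 3


def test_task_nodes_mutually_exclusive(cfg):
    """At most one task node supra-threshold at a time over a full trial."""
    spec = stim.generate_array(2, 6, seed=8)
    arch = make_arch(cfg, seed=9)
    maps, sal = maps_and_salience(cfg, spec, "array+cue")
    both = 0
    for _ in range(int(3500 / cfg.dt)):
        arch.step(maps, sal)
        on = sum(node.u > 0.5 for node in (arch.task.explore_node,
                                           arch.task.retain_node,
                                           arch.task.search_node))
        both += on > 1
        if arch._outcome is not None:
            break
    # transitions may overlap for a few integration steps, nothing more
    assert both * cfg.dt <= 100.0


def test_rejections_precede_match_on_hard_arrays(cfg):
    """Conjunction search shows CoD-driven rejection cycling on arrays
    where the first selection is unlikely to be the target."""
    rejections = []
    for k in range(3):
        spec = stim.generate_array(3, 8, seed=80 + k)
        outcome, arch = tc.run_trial(spec, cfg=cfg, seed=90 + k)
        rejections.append(outcome.rejections)
    assert sum(rejections) >= 1
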