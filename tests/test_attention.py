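"""Attentional selection, IOR, transient detectors, SWM reset."""

import numpy as np
import pytest

from dnf_visearch import stimuli as stim
from dnf_visearch import task_control as tc
from dnf_visearch.attention import (
    detect_offset_and_reset_swm,
    detect_onset,
    make_attention,
    update_ior_trace,
)
from dnf_visearch.dnf_core import detect_peaks, gaussian_bump
from dnf_visearch.vision_frontend import extract_maps, salience_input


def two_item_arch(seed, tiles=(6, 13), bias_tile=None, cfg=None,
                  steps=250):
    """Drive the full selection machinery on a small display."""
    from dnf_visearch.config import experiments_config

    cfg = cfg or experiments_config()
    spec = stim.StimulusArraySpec(
        items=[stim.ArrayItem(t, "red", 0.0) for t in dict.fromkeys(tiles)],
        target_index=0, condition=1, experiment=1, set_size=4, seed=0,
    )
    arch = tc.Architecture(cfg, seed=seed)
    arch.cue_tile_center = None
    arch.item_salience_mass = tc.reference_item_mass(cfg)
    if bias_tile is not None:
        cx, cy = stim.tile_center(bias_tile)
        arch.attention.ior_trace += gaussian_bump(
            arch.space_dims, (cx, cy), 30.0, 0.9)
    maps = extract_maps(stim.render(spec, "array"), cfg.vision)
    sal = salience_input(maps, features=cfg.features).grid
    first = None
    for _ in range(steps):
        arch.step(maps, sal)
        if first is None:
            loc = arch.attended_location()
            if loc is not None:
                first = arch._tile_of(loc)
    return first, arch


def test_single_item_is_selected():
    first, _ = two_item_arch(seed=0, tiles=(6,), steps=400)
    assert first == 6


def test_two_equal_items_split_roughly_evenly():
    wins = {6: 0, 13: 0}
    for seed in range(60):
        first, _ = two_item_arch(seed=seed, steps=150)
        if first in wins:
            wins[first] += 1
    total = sum(wins.values())
    assert total >= 55
    frac = wins[6] / total
    assert 0.3 <= frac <= 0.7, f"split {wins}"


def test_ior_bias_redirects_selection():
    other = 0
    for seed in range(30):
        first, _ = two_item_arch(seed=seed, bias_tile=6, steps=150)
        if first == 13:
            other += 1
    assert other >= 26, "inhibited location must lose almost always"


def test_selection_uniqueness_across_arrays(cfg):
    """At most one consolidated selection peak at any step, across random
    arrays and seeds (hard invariant)."""
    for seed in range(25):
        spec = stim.generate_array(3, 8, seed=seed)
        arch = tc.Architecture(cfg, seed=seed)
        arch.cue_tile_center = None
        arch.item_salience_mass = tc.reference_item_mass(cfg)
        maps = extract_maps(stim.render(spec, "array"), cfg.vision)
        sal = salience_input(maps, features=cfg.features).grid
        for _ in range(120):
            arch.step(maps, sal)
            peaks = detect_peaks(arch.attention.selection, min_mass=2.0)
            strong = [p for p in peaks if p.activation > 1.0]
            assert len(strong) <= 1


def test_ior_trace_builds_and_decays(cfg):
    trace = np.zeros((10, 10))
    sel = np.zeros((10, 10))
    sel[4, 4] = 0.95
    for _ in range(100):  # 300 ms attended
        trace = update_ior_trace(trace, sel, 3.0, cfg)
    assert trace[4, 4] > 0.7
    assert trace[0, 0] == 0.0
    for _ in range(400):
        trace = update_ior_trace(trace, np.zeros((10, 10)), 3.0, cfg)
    assert 0.3 < trace[4, 4] < trace.max() + 1e-9  # slow decay


def test_onset_detector_transient_window(cfg):
    att = make_attention(cfg)
    shape = att.ior_trace.shape
    inp = np.zeros(shape)
    # constant zero input: no output
    for _ in range(100):
        out = detect_onset(att.onset, inp, 3.0)
    assert out.max() == 0.0
    inp[10, 10] = 1.0
    peak_seen = False
    for i in range(400):  # 1.2 s with the step held
        out = detect_onset(att.onset, inp, 3.0)
        if out[10, 10] > 0.3:
            peak_seen = True
    assert peak_seen
    assert out.max() < 0.05, "transient must die out under tonic input"


def test_two_simultaneous_onsets_two_transients(cfg):
    att = make_attention(cfg)
    inp = np.zeros(att.ior_trace.shape)
    inp[4, 4] = 1.0
    inp[15, 12] = 1.0
    best = np.zeros_like(inp)
    for _ in range(60):
        best = np.maximum(best, detect_onset(att.onset, inp, 3.0))
    assert best[4, 4] > 0.3 and best[15, 12] > 0.3


def test_offset_transient_resets_swm(cfg):
    att = make_attention(cfg)
    # plant two sustained working-memory peaks
    for t in (6, 13):
        cx, cy = stim.tile_center(t)
        att.swm.u += 9.0 * gaussian_bump(att.dims, (cx, cy), 20.0)
    inp = gaussian_bump(att.dims, stim.tile_center(4), 25.0, 1.0)
    for _ in range(200):  # input present: no offset, peaks persist
        detect_offset_and_reset_swm(att.offset, inp, att.swm, 3.0, cfg)
    assert (att.swm.u > 0).sum() > 0
    for _ in range(200):  # the item disappears: global deboost
        detect_offset_and_reset_swm(att.offset, np.zeros_like(inp),
                                    att.swm, 3.0, cfg)
    assert (att.swm.u > 0).sum() == 0, "all SWM peaks must be extinguished"
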