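"""Central configuration of all dynamic parameters.

Every field's resting level, time constant, sigmoid steepness, noise level,
and interaction kernel, and every projection gain of the architecture graph
lives here, keyed by field name, so that a whole model variant is one
structured-text (YAML) document.  Two stock configurations are provided:

* :func:`default_config` -- full sampling (one grid cell per 10 stimulus
  pixels, 15-degree feature bins, all three feature dimensions);
* :func:`experiments_config` -- the reduced sampling used by the experiment
  harness (one cell per 20 pixels, 30-degree hue bins, 22.5-degree
  orientation bins, color + orientation only), which preserves at least a
  two-bin separation between any two stimulus feature values at a fraction
  of the cost.

Amplitude conventions: feature maps are normalized so one stimulus item
contributes a bump of amplitude ~1; thresholded field outputs saturate
near 1; projection gains are therefore in units of "one item" / "one
peak".  Ridge, slice, and column inputs are individually sub-threshold by
construction: the target fields' resting levels are set so that only
coincident inputs cross threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import yaml

from .vision_frontend import VisionConfig

__all__ = ["ArchitectureConfig", "default_config", "experiments_config"]


@dataclass(frozen=True)
class ArchitectureConfig:
    # --- sampling -----------------------------------------------------
    vision: VisionConfig = dc_field(default_factory=VisionConfig)
    features: tuple[str, ...] = ("color", "orientation", "size")
    dt: float = 3.0  # ms, explicit Euler

    # --- salience field C (detection regime, multi-peak) --------------
    salience_gain: float = 3.5  # salience input -> C
    c_h: float = -3.0
    c_tau: float = 15.0
    c_beta: float = 4.0
    c_noise: float = 0.05
    c_exc_amp: float = 2.0
    c_exc_width_px: float = 25.0
    c_inh_amp: float = 1.0
    c_inh_width_px: float = 60.0

    # --- spatial selection field D (selection regime) ------------------
    d_h: float = -3.0
    d_tau: float = 15.0
    d_beta: float = 2.0  # shallow sigmoid: sub-threshold competition
    d_noise: float = 0.1
    d_exc_amp: float = 10.0
    d_exc_width_px: float = 40.0
    d_inh_amp: float = 2.0
    d_inh_width_px: float = 100.0
    d_global_inh: float = 2.0
    # winner-take-all via a dedicated inhibitory pool driven by activation
    # above a higher threshold: candidates compete only once one of them
    # consolidates, and a single winner suppresses all others
    d_pool_threshold: float = 0.8
    d_pool_beta: float = 10.0  # steep pool sigmoid: no sub-threshold leak
    d_pool_tau: float = 30.0  # pool lag lets a winner consolidate through
    d_pool_gain: float = 0.0  # architecture selection uses the saccade race
    d_pool_ref: float = 10.0
    d_boost_commit: float = 1.5  # homogeneous boost during explore/retain
    d_boost_search: float = 1.0  # guidance supplies the rest during search
    d_gain_salience: float = 1.5  # sigma(C) -> D
    d_gain_onset: float = 1.5  # onset transient -> D (local excitation)
    d_gain_scene_guidance: float = 0.7  # sigma(K1) -> D
    d_gain_memory_guidance: float = 2.5  # sigma(J1) -> D
    d_gain_ior: float = 0.5  # IOR trace D2 -> D during search
    d_gain_ior_explore: float = 1.6  # stronger during free exploration
    d_gain_swm: float = 0.7  # sigma(D1) -> D (inhibitory)
    d_gain_rejection: float = 2.0  # within-trial rejection trace -> D
    d_gain_instruction: float = 2.0  # instructed cue-tile boost during retain

    # --- spatial working memory D1 (sustained, capacity-limited) -------
    swm_h: float = -2.5
    swm_tau: float = 30.0
    swm_beta: float = 10.0
    swm_noise: float = 0.02
    swm_exc_amp: float = 12.0
    swm_exc_width_px: float = 20.0
    swm_inh_amp: float = 8.4
    swm_inh_width_px: float = 60.0
    swm_capacity_inh: float = 0.05  # weak per-item pool (graded competition)
    swm_gain_selection: float = 7.0  # sigma(D) -> D1 while committing
    swm_deboost: float = -20.0  # global deboost on offset transient

    # --- IOR memory trace D2 -------------------------------------------
    ior_build_tau: float = 80.0  # ms
    ior_decay_tau: float = 10000.0  # ms
    ior_reset_on_offset: bool = True  # reset with SWM at array offset
    ior_reset_tau: float = 30.0  # ms, decay during reset transient

    # --- onset / offset transient detectors D3 / D4 --------------------
    transient_fast_tau: float = 50.0
    transient_slow_tau: float = 300.0
    onset_threshold: float = 0.25
    offset_threshold: float = 0.25
    transient_out_gain: float = 3.0
    offset_event_mass: float = 1.0  # supra mass that counts as a scene change

    # --- scene space/feature selection fields E ------------------------
    e_h: float = -1.9
    e_tau: float = 15.0
    e_beta: float = 4.0
    e_noise: float = 0.0
    e_gain_scene: float = 1.2  # maps B -> E
    e_gain_column: float = 1.2  # attention column -> E
    column_width_px: float = 30.0

    # --- memory space/feature maps F (sustained, capacity-limited) -----
    f_h: float = -5.0
    f_tau: float = 30.0
    f_beta: float = 10.0
    f_noise: float = 0.02
    f_exc_amp: float = 18.0
    f_exc_width_px: float = 20.0
    f_exc_width_bins: float = 1.0  # along the feature axis, in bins
    f_inh_amp: float = 13.0
    f_inh_width_px: float = 40.0
    f_inh_width_bins: float = 3.0
    memory_capacity: int = 4  # slots in scene and spatial working memory
    f_capacity_inh: float = 0.05  # weak per-item pool (graded competition)
    f_gain_column: float = 4.5  # attention column -> F
    f_gain_slice: float = 2.5  # attended feature slice -> F (below wave threshold)
    f_consolidation_ms: float = 200.0  # commit drive persists through reset

    # --- memory space/feature selection fields G -----------------------
    g_h: float = -1.9
    g_tau: float = 15.0
    g_beta: float = 4.0
    g_gain_memory: float = 1.2  # sigma(F) -> G
    g_gain_column: float = 1.2

    # --- search cue fields I (sustained, 1-D) and retain gates I1 ------
    cue_h: float = -2.5
    cue_tau: float = 30.0
    cue_beta: float = 4.0
    cue_noise: float = 0.01
    cue_exc_amp: float = 12.0
    cue_exc_width_bins: float = 0.7
    cue_inh_amp: float = 7.0
    cue_inh_width_bins: float = 3.6
    cue_global_inh: float = 1.5
    cue_gain_gate: float = 4.0  # gated attended features -> I
    cue_readout_threshold: float = 2.0  # only a consolidated cue drives readout
    cue_consolidation_ms: float = 180.0  # gate drive persists through reset
    gate_h: float = -2.2
    gate_tau: float = 15.0
    gate_beta: float = 4.0
    gate_gain_att: float = 2.0
    gate_boost: float = 1.2  # from retain node
    gate_exc_amp: float = 2.0  # widens the gate peak over ~3 feature bins
    gate_exc_width_bins: float = 1.2

    # --- match/mismatch network H --------------------------------------
    match_h: float = -3.0
    mismatch_h: float = -2.0
    match_tau: float = 15.0
    match_beta: float = 4.0
    match_input_gain: float = 6.0  # 1-D profiles -> attended/expected fields
    match_gain_attended: float = 2.0
    match_gain_expected: float = 4.0  # broad inhibitory overlap
    match_gain_presence: float = 2.0  # expected-present gate
    match_overlap_bins: float = 1.2  # smoothing of the expected inverse
    match_overlap_bins_size: float = 0.6  # the 3-level size axis is tighter
    peak_detector_h: float = -1.5
    peak_detector_tau: float = 15.0
    peak_detector_gain: float = 6.0  # per unit of normalized peak mass
    peak_detector_self_exc: float = 1.0
    cos_h: float = -1.0
    cod_h: float = -1.0
    cos_tau: float = 40.0  # slower than CoD: mismatch evaluation wins the race
    cod_tau: float = 15.0
    cos_cod_self_exc: float = 1.5
    cos_cod_mutual_inh: float = 3.0
    match_weight: float = 3.0
    match_settle_ms: float = 200.0  # CoS released only after ~5 tau of evaluation

    # --- overlap / guidance fields K, J, K1, J1 ------------------------
    overlap_h: float = -1.4  # deep enough that a lone ridge cannot ignite
    overlap_tau: float = 15.0
    overlap_beta: float = 4.0
    overlap_gain_scene: float = 0.9  # B -> K
    overlap_gain_memory: float = 0.9  # sigma(F) -> J
    overlap_gain_cue: float = 0.9  # cue slice -> K and J
    guidance_tau: float = 15.0
    guidance_beta: float = 10.0  # crisp threshold: negligible sub-zero leak
    guidance_h_scene: float = -0.35  # K1 base resting level
    guidance_h_memory: float = -2.4  # J1 base resting level
    guidance_gain: float = 12.5  # marginalized overlap peaks -> K1/J1
    # with per-dimension signal s ~ 3.4 per matching item, the linear
    # resting-level rule B(n) = |h| + deboost*n yields guidance peaks for
    # items sharing >= n-1 cued features (K1) or all n of them (J1)
    scene_deboost_per_cue: float = 1.35
    memory_deboost_per_cue: float = 0.7

    # --- task nodes -----------------------------------------------------
    node_h: float = -2.0
    node_tau: float = 15.0
    node_beta: float = 4.0
    node_self_exc: float = 3.0
    node_mutual_inh: float = 4.0
    explore_drive: float = 2.5
    retain_drive: float = 4.0
    search_drive: float = 3.0
    cos_node_inhibition: float = 6.0  # CoS -> active task node
    d_deboost_on_reset: float = -6.0  # attention reset pulse
    reset_pulse_ms: float = 50.0
    post_reset_boost: float = 0.4  # rebound after an attentional reset
    post_reset_ms: float = 100.0
    # saccade race: the next attended location is a temperature-controlled
    # stochastic choice over the selection landscape; ties are uniform,
    # a one-unit guidance advantage wins ~25:1 per candidate
    selection_temperature: float = 0.3
    comparison_timeout_ms: float = 1300.0
    rejection_bump_width_px: float = 30.0
    cue_localization: str = "instructed"  # instructed | onset

    # --- bookkeeping ----------------------------------------------------
    scene_present_threshold: float = 0.25  # fraction of one item's salience mass
    max_rejections_per_item: int = 3  # times set size
    max_trial_ms: float = 15000.0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["vision"] = dataclasses.asdict(self.vision)
        d["features"] = list(self.features)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureConfig":
        d = yaml.safe_load(text)
        vis = d.pop("vision", {})
        for key in ("region", "space_samples"):
            if key in vis:
                vis[key] = tuple(vis[key])
        d["features"] = tuple(d.get("features", ("color", "orientation", "size")))
        return cls(vision=VisionConfig(**vis), **d)

    def replace(self, **kw) -> "ArchitectureConfig":
        return dataclasses.replace(self, **kw)


def default_config() -> ArchitectureConfig:
    """Full-resolution configuration."""
    return ArchitectureConfig()


def experiments_config() -> ArchitectureConfig:
    """Reduced-resolution configuration used by the experiment harness."""
    return ArchitectureConfig(
        vision=VisionConfig(
            space_samples=(25, 20),
            hue_bins=12,
            orientation_bins=8,
            size_levels=3,
        ),
        features=("color", "orientation"),
    )
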