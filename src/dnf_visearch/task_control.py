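"""Task organization: explore / retain / search nodes, CoS/CoD-driven
sequencing, search-cue fields, overlap and guidance fields, and the
autonomous architecture that ties every sub-system together.

Three task nodes organize behavior through mutual inhibition (precedence
retain > search > explore on simultaneous drive):

* explore -- the default: select a salient location, read out its
  features, commit them to scene working memory; the feature match between
  the attended item and its freshly recalled memory trace is the cycle's
  condition of satisfaction (CoS), which deactivates the node; it then
  reactivates for the next cycle unless pre-empted.
* retain -- triggered by an onset transient at the (instructed,
  black-bordered) cue tile: attention is drawn to the transient, the
  retain gates open, and the cue's feature values are stored in sustained
  1-D search-cue fields; the match between cue fields and the attended
  item terminates the episode.
* search -- active once a cue is stored and a scene is visible.  Per
  feature dimension, overlap fields combine sub-threshold scene input (K)
  or memory input (J) with the cue slice; their spatial marginals bias
  attention through two guidance fields.  The scene guidance field's
  resting level is down-regulated per stored cue feature so that with one
  cued feature only full matches guide, and with n > 1 cued features every
  item sharing at least n-1 of them does (the normalization rule that
  makes single-feature search efficient and conjunction search serial).
  Memory guidance is normalized more strictly: only items matching every
  cued feature are guided from memory -- a remembered target pops out.
  A mismatch (CoD) rejects the attended item: attention is destabilized,
  a refractory trace prevents immediate re-selection, and the search node
  re-engages; a full match (CoS) terminates the trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from . import stimuli as stim
from .attention import AttentionState, make_attention, step_attention
from .config import ArchitectureConfig, experiments_config
from .dnf_core import (
    DimensionSpec,
    FieldState,
    InteractionKernel,
    NodeState,
    RngStreams,
    detect_peaks,
    gaussian_bump,
    step_field,
    step_node,
)
from .matching import MatchNetworkState, make_match_network, step_match_network
from .scene_memory import MemoryMaps, make_memory
from .vision_frontend import SpaceFeatureMaps, extract_maps, salience_input

__all__ = [
    "Architecture",
    "SearchOutcome",
    "TaskState",
    "compute_guidance",
    "run_explore_cycle",
    "run_retain",
    "run_search",
    "run_trial",
]

SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class TaskState:
    """Task nodes, cue fields and gates, overlap and guidance fields."""

    explore_node: NodeState
    retain_node: NodeState
    search_node: NodeState
    retain_done: NodeState
    scene_node: NodeState
    cue_fields_I: dict[str, FieldState]
    gate_fields_I1: dict[str, FieldState]
    cue_pd: dict[str, NodeState]
    overlap_K: dict[str, FieldState]
    overlap_J: dict[str, FieldState]
    guidance_K1: FieldState
    guidance_J1: FieldState


@dataclass
class SearchOutcome:
    selected_tile: int | None
    rt_ms: float | None
    rejections: int
    aborted: bool


def _feature_dim(cfg: ArchitectureConfig, feature: str) -> DimensionSpec:
    v = cfg.vision
    return {
        "color": v.hue_dim,
        "orientation": v.orientation_dim,
        "size": v.size_dim,
    }[feature]()


def _guidance_kernel(cfg: ArchitectureConfig) -> InteractionKernel | None:
    # pure threshold detectors: lateral interaction would let crowded
    # guidance peaks suppress each other at large set sizes
    return None


def _make_task_state(cfg: ArchitectureConfig) -> TaskState:
    def node(name: str, **kw) -> NodeState:
        kw.setdefault("self_exc", cfg.node_self_exc)
        return NodeState(h=cfg.node_h, tau=cfg.node_tau, beta=cfg.node_beta,
                         name=name, **kw)

    x, y = cfg.vision.space_dims()
    cue, gate, cue_pd, K, J = {}, {}, {}, {}, {}
    for f in cfg.features:
        fdim = _feature_dim(cfg, f)
        cue[f] = FieldState(
            (fdim,), h=cfg.cue_h, tau=cfg.cue_tau, beta=cfg.cue_beta,
            noise_amplitude=cfg.cue_noise,
            kernel=InteractionKernel(
                exc_amp=cfg.cue_exc_amp,
                exc_width=cfg.cue_exc_width_bins * fdim.spacing,
                inh_amp=cfg.cue_inh_amp,
                inh_width=cfg.cue_inh_width_bins * fdim.spacing,
                global_inh=cfg.cue_global_inh,
            ),
            regime_label="sustained", name=f"I_{f}",
        )
        gate[f] = FieldState(
            (fdim,), h=cfg.gate_h, tau=cfg.gate_tau, beta=cfg.gate_beta,
            kernel=InteractionKernel(
                exc_amp=cfg.gate_exc_amp,
                exc_width=cfg.gate_exc_width_bins * fdim.spacing,
            ),
            regime_label="detection", name=f"I1_{f}",
        )
        cue_pd[f] = NodeState(
            h=cfg.peak_detector_h, tau=cfg.peak_detector_tau,
            self_exc=cfg.peak_detector_self_exc, name=f"pd_cue_{f}",
        )
        K[f] = FieldState(
            (x, y, fdim), h=cfg.overlap_h, tau=cfg.overlap_tau,
            beta=cfg.overlap_beta,
            regime_label="detection", name=f"K_{f}",
        )
        J[f] = FieldState(
            (x, y, fdim), h=cfg.overlap_h, tau=cfg.overlap_tau,
            beta=cfg.overlap_beta,
            regime_label="detection", name=f"J_{f}",
        )
    return TaskState(
        explore_node=node("explore"),
        retain_node=node("retain"),
        search_node=node("search"),
        retain_done=node("retain_done", self_exc=4.0),
        scene_node=NodeState(h=-1.0, tau=cfg.node_tau, name="scene_present"),
        cue_fields_I=cue,
        gate_fields_I1=gate,
        cue_pd=cue_pd,
        overlap_K=K,
        overlap_J=J,
        guidance_K1=FieldState((x, y), h=cfg.guidance_h_scene,
                               tau=cfg.guidance_tau, beta=cfg.guidance_beta,
                               kernel=_guidance_kernel(cfg), name="K1"),
        guidance_J1=FieldState((x, y), h=cfg.guidance_h_memory,
                               tau=cfg.guidance_tau, beta=cfg.guidance_beta,
                               kernel=_guidance_kernel(cfg), name="J1"),
    )


def _supra_output(field: FieldState) -> np.ndarray:
    return np.where(field.u > 0, field.output(), 0.0)


def _squash_profile(p: np.ndarray, threshold: float = 0.3, k: float = 8.0
                    ) -> np.ndarray:
    """Normalize a read-out feature profile to ~binary amplitude.

    Read-out amplitudes vary with bar orientation and grid phase; the
    squash makes any clear activation ~1 while keeping spurious tails
    suppressed, so downstream gains see calibrated inputs."""
    lo = 1.0 / (1.0 + np.exp(k * threshold))
    hi = 1.0 / (1.0 + np.exp(-k * (1.0 - threshold)))
    return (1.0 / (1.0 + np.exp(-k * (p - threshold))) - lo) / (hi - lo)


def _cue_output(field: FieldState, cfg: ArchitectureConfig) -> np.ndarray:
    """Cue-field readout with a raised threshold: a freshly forming peak is
    not yet a stored cue; only the consolidated, self-sustained state
    drives matching, guidance, and the cue peak detector."""
    from .dnf_core import sigmoid

    th = cfg.cue_readout_threshold
    return np.where(field.u > th, sigmoid(field.u - th, field.beta), 0.0)


def _marginalize_feature(out3: np.ndarray, dims3, norm_bins: float) -> np.ndarray:
    """(x, y, f) output -> spatial grid, normalized per stored peak."""
    fdim = dims3[2]
    return out3.sum(axis=2) / (SQRT2PI * norm_bins)


def _marginalize_space(out3: np.ndarray, dims3, norm_cells: float) -> np.ndarray:
    """(x, y, f) output -> 1-D feature profile, normalized per peak."""
    return out3.sum(axis=(0, 1)) / (SQRT2PI * norm_cells) ** 2


class Architecture:
    """The complete autonomous architecture for one replayable trial.

    All neural state lives in fields and nodes stepped with a shared Euler
    clock; processing steps (selections, commitments, rejections, task
    switches) emerge from detection and reverse-detection instabilities
    and are logged as events with their model-time stamps.
    """

    def __init__(self, cfg: ArchitectureConfig | None = None, seed: int = 0):
        self.cfg = cfg or experiments_config()
        self.rng = RngStreams(seed)
        self.attention: AttentionState = make_attention(self.cfg)
        self.memory: MemoryMaps = make_memory(self.cfg)
        self.match: MatchNetworkState = make_match_network(self.cfg)
        self.task: TaskState = _make_task_state(self.cfg)
        x, y = self.cfg.vision.space_dims()
        self.space_dims = (x, y)
        self.rejection_trace = np.zeros((x.samples, y.samples))
        self.t_ms = 0.0
        self.reset_until_ms = -1.0
        self._commit_hold_until = -1.0
        self._commit_hold_drives: dict[str, np.ndarray] = {}
        self._cue_hold_until = -1.0
        self._cue_hold_drives: dict[str, np.ndarray] = {}
        self._last_attended_ms = 0.0
        self._saccade_loc: tuple[float, float] | None = None
        self._dwell_tile: int | None = None
        self._dwell_since_ms = 0.0
        self._last_att_tile: int | None = None
        self.events: list[dict[str, Any]] = []
        self.cue_features: tuple[str, ...] = tuple(self.cfg.features)
        self.cue_tile_center: tuple[float, float] | None = None
        self.item_salience_mass: float = 1.0
        self._prev = {"cos": False, "cod": False}
        self._search_started_ms: float | None = None
        self._outcome: SearchOutcome | None = None
        self.rejections = 0
        self.max_rejections = 10 ** 9

    # -- helpers --------------------------------------------------------

    def log(self, kind: str, **info) -> None:
        self.events.append({"t_ms": round(self.t_ms, 1), "event": kind, **info})

    def attended_location(self) -> tuple[float, float] | None:
        """Location of the current attentional focus.

        The focus is the dominant supra-threshold peak of the selection
        field; transient low blips near threshold do not count, and an
        unresolved competition (two comparable peaks) yields no focus.
        """
        peaks = detect_peaks(self.attention.selection, min_mass=2.0)
        if len(peaks) == 0:
            return None
        best = peaks.peaks[0]
        if best.activation < 1.0:
            return None
        if len(peaks) > 1:
            second = peaks.peaks[1]
            if best.activation - second.activation < 0.8:
                return None
        loc = best.location
        return (loc[0], loc[1])

    def _tile_of(self, loc: tuple[float, float]) -> int:
        col = int((loc[0] - stim._X0) // stim.TILE_PX)
        row = int((loc[1] - stim._Y0) // stim.TILE_PX)
        col = min(max(col, 0), stim.GRID_COLS - 1)
        row = min(max(row, 0), stim.GRID_ROWS - 1)
        return row * stim.GRID_COLS + col

    def _spatial_bump(self, loc, width_px: float, amp: float = 1.0) -> np.ndarray:
        return gaussian_bump(self.space_dims, loc, width_px, amp)

    def _column(self, loc, dims3) -> np.ndarray:
        bump = self._spatial_bump(loc, self.cfg.column_width_px)
        return np.broadcast_to(bump[:, :, None],
                               tuple(d.samples for d in dims3))

    def commit_count(self) -> int:
        return sum(1 for e in self.events if e["event"] == "commit")

    def _choose_saccade(self, landscape: np.ndarray, sal_in: np.ndarray,
                        retain_on: float, cue_bump: np.ndarray | None,
                        guidance: np.ndarray | None = None,
                        blocked: np.ndarray | None = None,
                        ) -> tuple[float, float] | None:
        """Resolve the saccade race over the selection landscape.

        Candidate locations are those carrying salient input (plus the
        instructed cue tile during retention).  The race winner is a
        softmax draw over the local drive (Gumbel perturbation), so equal
        candidates are chosen uniformly, guidance advantages win almost
        always, and inhibited locations are revisited last."""
        cfg = self.cfg
        eligible = sal_in > 0.3
        if retain_on > 0.5 and cue_bump is not None:
            eligible = eligible | (cue_bump > 0.3)
        if guidance is not None and float(np.max(guidance)) > 0.1:
            # during guided search only locations carrying a guidance peak
            # cross threshold; the ungated landscape is the fallback when
            # all guided candidates have been rejected
            guided = eligible & (guidance > 0.1) & (
                self.rejection_trace < 0.5)
            if blocked is not None:
                unblocked = guided & ~blocked
                if unblocked.any():
                    guided = unblocked
            if guided.any():
                eligible = guided
        if not eligible.any():
            return None
        g = self.rng("saccade").gumbel(size=landscape.shape)
        score = np.where(eligible,
                         landscape / cfg.selection_temperature + g, -np.inf)
        idx = np.unravel_index(int(np.argmax(score)), score.shape)
        loc = (float(self.space_dims[0].grid()[idx[0]]),
               float(self.space_dims[1].grid()[idx[1]]))
        # fixations center on items: snap to the tile grid so the read-out
        # column does not straddle tile boundaries
        return stim.tile_center(self._tile_of(loc))

    # -- the single Euler tick ------------------------------------------

    def step(self, maps: SpaceFeatureMaps | None,
             salience: np.ndarray | None, dt: float | None = None) -> None:
        cfg = self.cfg
        dt = cfg.dt if dt is None else dt
        rng = self.rng
        task = self.task
        att = self.attention
        sal_in = (np.zeros(self.rejection_trace.shape) if salience is None
                  else salience)

        # ---- transient detectors ------------------------------------
        onset_out = att.onset.step(sal_in, dt)
        offset_out = att.offset.step(sal_in, dt)
        offset_event = offset_out.sum() > cfg.offset_event_mass
        if offset_event and cfg.ior_reset_on_offset:
            att.ior_trace *= np.exp(-dt / cfg.ior_reset_tau)

        # ---- scene-present and cue-stored detectors ------------------
        scene_drive = 2.0 * (
            sal_in.sum() / self.item_salience_mass
            - cfg.scene_present_threshold
        )
        step_node(task.scene_node, float(np.clip(scene_drive, -4.0, 4.0)), dt)
        scene_on = task.scene_node.output()

        for f in self.cue_features:
            mass = float(_cue_output(task.cue_fields_I[f], cfg).sum())
            step_node(task.cue_pd[f],
                      cfg.peak_detector_gain * mass / (SQRT2PI * 1.2), dt)
        cue_stored = float(np.prod([task.cue_pd[f].output()
                                    for f in self.cue_features]))
        n_cues = float(sum(task.cue_pd[f].output()
                           for f in self.cue_features))

        # ---- task nodes ----------------------------------------------
        cos_out = self.match.cos_node.output()
        cod_out = self.match.cod_node.output()
        onset_at_cue = 0.0
        cue_bump = None
        if self.cue_tile_center is not None:
            cue_bump = self._spatial_bump(self.cue_tile_center, 40.0)
            # tight window: only a transient inside the cue tile triggers
            # retention, not onsets at neighboring tiles
            tight = self._spatial_bump(self.cue_tile_center, 20.0)
            onset_at_cue = float((onset_out * tight).sum())
        retain_out = task.retain_node.output()
        search_out = task.search_node.output()
        explore_out = task.explore_node.output()
        done_out = task.retain_done.output()

        explore_in = (
            cfg.explore_drive * scene_on
            - 2.0 * (1.0 - scene_on)  # no free exploration of a blank display
            - cfg.node_mutual_inh * (retain_out + search_out)
            # once a search cue is stored, search owns the scene: free
            # exploration must not resume between rejection cycles
            - 3.0 * cue_stored * scene_on
            - cfg.cos_node_inhibition * cos_out * explore_out
        )
        # the onset transient triggers retention; once retention is under
        # way, attention dwelling on the cue tile supports the node until
        # the cue match completes
        dwell_at_cue = 0.0
        if self.cue_tile_center is not None:
            dwell_at_cue = float((att.selection.output()
                                  * (att.selection.u > 0)
                                  * cue_bump).sum()) / 4.0
        retain_in = (
            (cfg.retain_drive * float(np.clip(onset_at_cue, 0.0, 1.0))
             + 2.0 * float(np.clip(dwell_at_cue, 0.0, 1.0)) * retain_out)
            * (1.0 - done_out)
            - 1.0 * search_out
            - cfg.cos_node_inhibition * cos_out * retain_out
            - 4.0 * done_out
        )
        search_in = (
            cfg.search_drive * cue_stored * scene_on * (1.0 - retain_out)
            - cfg.node_mutual_inh * retain_out
            - cfg.cos_node_inhibition * cos_out * search_out
            - 2.0 * cod_out
        )
        step_node(task.explore_node, explore_in, dt, rng("explore"))
        step_node(task.retain_node, retain_in, dt, rng("retain"))
        step_node(task.search_node, search_in, dt, rng("search"))
        step_node(task.retain_done, 3.0 * retain_out * cos_out - 0.5, dt)

        explore_on = task.explore_node.output()
        retain_on = task.retain_node.output()
        search_on = task.search_node.output()
        commit_on = float(min(explore_on + retain_on, 1.0))

        # a newly engaged retain task captures attention afresh: whatever
        # exploration was attending is dropped in favor of the cue
        if retain_on > 0.5 and not self._prev.get("retain", False):
            self._begin_reset()
        self._prev["retain"] = retain_on > 0.5

        # ---- selection-field bias ------------------------------------
        guidance_bias = (
            cfg.d_gain_scene_guidance * _supra_output(task.guidance_K1)
            + cfg.d_gain_memory_guidance * _supra_output(task.guidance_J1)
        ) * search_on
        in_reset = self.t_ms < self.reset_until_ms
        reset_pulse = cfg.d_deboost_on_reset if in_reset else 0.0
        any_task = min(explore_on + retain_on + search_on, 1.0)

        instructed = 0.0
        if (cfg.cue_localization == "instructed"
                and self.cue_tile_center is not None and cue_bump is not None):
            instructed = (cfg.d_gain_instruction * retain_on * cue_bump)

        # the selection landscape: everything that biases where attention
        # goes next.  The saccade race over this landscape is resolved as
        # a temperature-controlled stochastic choice (softmax over the
        # per-location drive); the chosen location is then imposed on the
        # selection field, which forms its peak through the ordinary
        # detection instability
        # inhibition of return is strong while freely exploring (never
        # revisit before coverage) and weaker during guided search, where
        # the guidance and working-memory biases carry the ordering
        ior_gain = (cfg.d_gain_ior_explore * commit_on
                    + cfg.d_gain_ior * search_on)
        landscape = (
            cfg.d_gain_salience * _supra_output(att.salience)
            + cfg.d_gain_onset * onset_out
            + guidance_bias
            + instructed
            - ior_gain * att.ior_trace
            - cfg.d_gain_swm * _supra_output(att.swm)
            - cfg.d_gain_rejection * self.rejection_trace
        )
        if any_task <= 0.5:
            self._saccade_loc = None  # fixation is released with the task
        if (self._saccade_loc is None and any_task > 0.5 and not in_reset
                and self._outcome is None):
            self._saccade_loc = self._choose_saccade(
                landscape, sal_in, retain_on, cue_bump,
                guidance_bias if search_on > 0.5 else None)
        sacc_drive = 0.0
        if self._saccade_loc is not None:
            sacc_drive = self._spatial_bump(self._saccade_loc, 25.0, 4.0)
        bias = (
            guidance_bias
            + instructed
            + sacc_drive
            + cfg.d_gain_onset * onset_out
            - cfg.d_gain_rejection * self.rejection_trace
            + reset_pulse
        )

        swm_extra = cfg.swm_deboost if offset_event else 0.0
        step_attention(att, sal_in, bias, dt, rng,
                       commit_swm=commit_on, swm_extra=swm_extra)
        att_loc = self.attended_location()
        if att_loc is not None:
            tile_now = self._tile_of(att_loc)
            if tile_now != self._dwell_tile:
                # a fresh dwell restarts the comparison clock: profiles
                # read during transitions mix two items' features, so the
                # verdict must come from this dwell alone
                self._dwell_tile = tile_now
                self._dwell_since_ms = self.t_ms
                self.match.elapsed_ms = 0.0
                self.match.cos_node.reset()
                self.match.cod_node.reset()
            self._last_att_tile = tile_now
            self._last_attended_ms = self.t_ms

        # ---- scene space/feature selection E and read-out ------------
        # read-outs pool only the attended column's spatial footprint, so
        # flank activation of neighboring items cannot intrude
        att_mask = None
        if att_loc is not None:
            att_mask = self._spatial_bump(att_loc, 1.2 * cfg.column_width_px
                                          ) > 0.3
        att_profiles: dict[str, np.ndarray] = {}
        for f in cfg.features:
            field = self.memory.selection_E[f]
            inp = 0.0 if maps is None else cfg.e_gain_scene * maps.map_for(f)
            if att_loc is not None:
                inp = inp + cfg.e_gain_column * self._column(att_loc, field.dims)
            step_field(field, inp, dt, rng(field.name))
            out = _supra_output(field)
            if att_mask is not None:
                out = out * att_mask[:, :, None]
            att_profiles[f] = _squash_profile(out.max(axis=(0, 1)))

        # ---- memory maps F (commit) and recall G ---------------------
        pool = self.memory.shared_capacity_inhibition()
        committing = att_loc is not None and commit_on > 0.5
        for f in cfg.features:
            field = self.memory.memory_F[f]
            drive = -pool
            if committing:
                col = self._column(att_loc, field.dims)
                # squared profile: the slice's tails must not seed feature
                # drift of peaks stored at neighboring feature values
                sl = np.broadcast_to((att_profiles[f] ** 2)[None, None, :],
                                     field.shape)
                fdrive = commit_on * (cfg.f_gain_column * col
                                      + cfg.f_gain_slice * sl)
                # synaptic persistence: the freshly formed peak keeps its
                # drive briefly after attention resets, so commitment
                # consolidates even when the cycle ends quickly
                self._commit_hold_drives[f] = fdrive
                self._commit_hold_until = self.t_ms + cfg.f_consolidation_ms
                drive = drive + fdrive
            elif (self.t_ms < self._commit_hold_until
                  and f in self._commit_hold_drives):
                drive = drive + self._commit_hold_drives[f]
            step_field(field, drive, dt, rng(field.name))
        if not committing and self.t_ms >= self._commit_hold_until:
            from .scene_memory import evict_overflow

            evicted = evict_overflow(self.memory)
            if evicted is not None:
                self.log("memory_eviction", tile=evicted)

        rec_profiles: dict[str, np.ndarray] = {}
        for f in cfg.features:
            field = self.memory.mem_selection_G[f]
            inp = cfg.g_gain_memory * _supra_output(self.memory.memory_F[f])
            if att_loc is not None:
                inp = inp + cfg.g_gain_column * self._column(att_loc, field.dims)
            step_field(field, inp, dt, rng(field.name))
            out = _supra_output(field)
            if att_mask is not None:
                out = out * att_mask[:, :, None]
            rec_profiles[f] = _squash_profile(out.max(axis=(0, 1)))

        # ---- cue gates I1 and cue fields I ---------------------------
        # only features read out while attention dwells on the cue tile
        # itself may be stored; a flicker to an array item must not blend
        # that item's features into the cue
        cue_tile_idx = (self._tile_of(self.cue_tile_center)
                        if self.cue_tile_center is not None else None)
        at_cue = (self._dwell_tile is not None
                  and self._dwell_tile == cue_tile_idx)
        for f in self.cue_features:
            gatef = task.gate_fields_I1[f]
            gate_att = att_profiles[f] if at_cue else 0.0
            step_field(gatef,
                       cfg.gate_gain_att * gate_att
                       + cfg.gate_boost * retain_on
                       - 2.5 * (1.0 - retain_on),  # hard-closed off-task
                       dt, rng(gatef.name))
            cuef = task.cue_fields_I[f]
            cue_drive = cfg.cue_gain_gate * _supra_output(gatef)
            if retain_on > 0.5 and cue_drive.max() > 1.0:
                # persistence: the cue keeps its drive briefly after the
                # retain episode ends, so both feature dimensions
                # consolidate even when the match completes quickly
                self._cue_hold_drives[f] = cue_drive
                self._cue_hold_until = self.t_ms + cfg.cue_consolidation_ms
            elif (self.t_ms < self._cue_hold_until
                  and f in self._cue_hold_drives):
                cue_drive = np.maximum(cue_drive, self._cue_hold_drives[f])
            step_field(cuef, cue_drive, dt, rng(cuef.name))

        # ---- overlap fields K, J and guidance K1, J1 -----------------
        k1_in = np.zeros(self.rejection_trace.shape)
        j1_in = np.zeros(self.rejection_trace.shape)
        for f in cfg.features:
            fdim = _feature_dim(cfg, f)
            if f in self.cue_features:
                cue_out = _cue_output(task.cue_fields_I[f], cfg)
            else:
                cue_out = np.zeros(fdim.samples)
            Kf = task.overlap_K[f]
            cue_slice = np.broadcast_to(cue_out[None, None, :], Kf.shape)
            k_in = cfg.overlap_gain_cue * cue_slice
            if maps is not None:
                k_in = k_in + cfg.overlap_gain_scene * maps.map_for(f)
            step_field(Kf, k_in, dt, rng(Kf.name))
            k1_in += _marginalize_feature(_supra_output(Kf), Kf.dims, 1.2)

            Jf = task.overlap_J[f]
            j_in = (cfg.overlap_gain_memory
                    * _supra_output(self.memory.memory_F[f])
                    + cfg.overlap_gain_cue * cue_slice)
            step_field(Jf, j_in, dt, rng(Jf.name))
            j1_in += _marginalize_feature(_supra_output(Jf), Jf.dims, 1.2)

        step_field(task.guidance_K1,
                   cfg.guidance_gain * k1_in
                   - cfg.scene_deboost_per_cue * n_cues,
                   dt, rng("K1"))
        step_field(task.guidance_J1,
                   cfg.guidance_gain * j1_in
                   - cfg.memory_deboost_per_cue * n_cues,
                   dt, rng("J1"))

        # ---- match network -------------------------------------------
        expected: dict[str, np.ndarray] = {}
        for f in cfg.features:
            if f in self.cue_features:
                cue_out = _cue_output(task.cue_fields_I[f], cfg)
            else:
                cue_out = np.zeros(_feature_dim(cfg, f).samples)
            expected[f] = (explore_on * rec_profiles[f]
                           + (retain_on + search_on) * cue_out)
        step_match_network(self.match, att_profiles, expected, dt, rng)

        # ---- event edges and sequencing ------------------------------
        cos_now = self.match.cos_node.active
        cod_now = self.match.cod_node.active
        if cos_now and not self._prev["cos"]:
            if search_on > 0.5 and self._search_started_ms is not None:
                tile = (self._tile_of(att_loc) if att_loc
                        else self._last_att_tile)
                self.log("search_cos", tile=tile)
                self._outcome = SearchOutcome(
                    selected_tile=tile,
                    rt_ms=self.t_ms - self._search_started_ms,
                    rejections=self.rejections,
                    aborted=False,
                )
            elif retain_on > 0.5:
                self.log("cue_stored", cue={
                    f: float(_feature_dim(cfg, f).grid()[
                        int(np.argmax(task.cue_fields_I[f].u))])
                    for f in self.cue_features})
                # latch the done node before the comparison clock resets
                task.retain_done.u = max(task.retain_done.u, 2.0)
                if self.cue_tile_center is not None:
                    # instructed: the cue item itself is never the response;
                    # it would otherwise be a permanent full-match attractor
                    self.rejection_trace += 1.5 * self._spatial_bump(
                        self.cue_tile_center, cfg.rejection_bump_width_px)
                self._begin_reset()
            else:
                tile = (self._tile_of(att_loc) if att_loc
                        else self._last_att_tile)
                self.log("commit", tile=tile)
                self._begin_reset()
        if cod_now and not self._prev["cod"]:
            loc = att_loc if att_loc is not None else None
            if search_on > 0.5 and loc is not None:
                self.rejection_trace += self._spatial_bump(
                    loc, cfg.rejection_bump_width_px)
                self.rejection_trace = np.clip(self.rejection_trace, 0.0, 1.5)
                self.log("rejection", tile=self._tile_of(loc))
                self.rejections += 1
            elif search_on <= 0.5:
                # commit verification failed during exploration: retry
                self.log("explore_cod",
                         tile=self._tile_of(loc) if loc else None)
            self._begin_reset()
        self._prev["cos"] = cos_now
        self._prev["cod"] = cod_now

        # a cycle that cannot reach a verdict is abandoned and restarted
        # (no rejection is recorded: nothing was actually compared)
        if (any_task > 0.5
                and self.match.elapsed_ms > cfg.comparison_timeout_ms):
            self.log("cycle_timeout")
            self._begin_reset()

        if search_on > 0.5 and self._search_started_ms is None:
            self._search_started_ms = self.t_ms
            from .scene_memory import memory_snapshot

            self.log("search_started",
                     memory_tiles=[r["tile"] for r in
                                   memory_snapshot(self.memory)])
            self._begin_reset()  # fresh comparison for the first candidate

        self.t_ms += dt

    def _begin_reset(self) -> None:
        """Destabilize attention and restart the comparison clock."""
        self.reset_until_ms = self.t_ms + self.cfg.reset_pulse_ms
        self._saccade_loc = None
        self.match.elapsed_ms = 0.0
        self.match.cos_node.reset()
        self.match.cod_node.reset()

    # -- segment driver --------------------------------------------------

    def present(self, maps: SpaceFeatureMaps | None, duration_ms: float,
                dt: float | None = None, stop_on_outcome: bool = False) -> None:
        dt = self.cfg.dt if dt is None else dt
        sal = None
        if maps is not None:
            sal = salience_input(maps, features=self.cfg.features).grid
        for _ in range(int(round(duration_ms / dt))):
            self.step(maps, sal, dt)
            if stop_on_outcome and self._outcome is not None:
                return


def _frame_maps(arch: Architecture, spec: stim.StimulusArraySpec,
                segment: str) -> SpaceFeatureMaps | None:
    if segment == "blank":
        return None
    frame = stim.render(spec, segment)
    return extract_maps(frame, arch.cfg.vision)


def reference_item_mass(cfg: ArchitectureConfig) -> float:
    """Salience mass of one rendered reference bar, for normalization."""
    ref = stim.StimulusArraySpec(
        items=[stim.ArrayItem(tile=12, color="red", orientation=0.0)],
        target_index=0, condition=1, experiment=1, set_size=4, seed=0,
    )
    maps = extract_maps(stim.render(ref, "array"), cfg.vision)
    return float(salience_input(maps, features=cfg.features).grid.sum())


def run_trial(
    spec: stim.StimulusArraySpec,
    cfg: ArchitectureConfig | None = None,
    seed: int = 0,
    cue_features: tuple[str, ...] | None = None,
) -> tuple[SearchOutcome, Architecture]:
    """Play a full trial timeline through the autonomous architecture.

    ``cue_features`` defaults to color-only in condition 1 (the common
    vertical orientation carries no information) and color + orientation
    in the conjunction conditions.
    """
    arch = Architecture(cfg, seed=seed)
    cfg = arch.cfg
    if cue_features is None:
        cue_features = (("color",) if spec.condition == 1
                        else ("color", "orientation"))
    arch.cue_features = tuple(f for f in cue_features if f in cfg.features)
    arch.cue_tile_center = stim.tile_center(spec.cue_tile)
    arch.item_salience_mass = reference_item_mass(cfg)
    arch.max_rejections = cfg.max_rejections_per_item * spec.set_size

    timeline = stim.timeline_for(spec.experiment, spec.condition)
    for i, (content, duration) in enumerate(timeline.segments):
        maps = _frame_maps(arch, spec, content)
        if duration is not None:
            arch.present(maps, duration)
            continue
        sal = salience_input(maps, features=cfg.features).grid
        t_end = arch.t_ms + cfg.max_trial_ms
        while arch.t_ms < t_end:
            arch.step(maps, sal)
            if arch._outcome is not None:
                break
            if arch.rejections > arch.max_rejections:
                break
    outcome = arch._outcome
    if outcome is None:
        outcome = SearchOutcome(selected_tile=None, rt_ms=None,
                                rejections=arch.rejections, aborted=True)
    return outcome, arch


# ---------------------------------------------------------------------------
# spec-level operations (also used directly by tests)
# ---------------------------------------------------------------------------


def run_explore_cycle(
    arch: Architecture,
    maps: SpaceFeatureMaps,
    max_ms: float = 1500.0,
) -> dict | None:
    """Step the architecture until the next commitment event (or timeout).

    Returns the commit event dict, or None if no salient location led to
    a commitment within the time budget (e.g., an empty array).
    """
    sal = salience_input(maps, features=arch.cfg.features).grid
    n_before = arch.commit_count()
    t0 = arch.t_ms
    while arch.t_ms - t0 < max_ms:
        arch.step(maps, sal)
        if arch.commit_count() > n_before:
            return [e for e in arch.events if e["event"] == "commit"][-1]
    return None


def run_retain(
    arch: Architecture,
    maps: SpaceFeatureMaps,
    max_ms: float = 1500.0,
) -> dict | None:
    """Step until the cue-stored event (retain CoS) or timeout."""
    sal = salience_input(maps, features=arch.cfg.features).grid
    t0 = arch.t_ms
    while arch.t_ms - t0 < max_ms:
        arch.step(maps, sal)
        stored = [e for e in arch.events if e["event"] == "cue_stored"]
        if stored:
            return stored[-1]
    return None


def run_search(
    arch: Architecture,
    maps: SpaceFeatureMaps,
    max_rejections: int | None = None,
    max_ms: float = 12000.0,
) -> SearchOutcome:
    """Step until the search CoS (match found) or abort."""
    cfg = arch.cfg
    sal = salience_input(maps, features=cfg.features).grid
    if max_rejections is not None:
        arch.max_rejections = max_rejections
    t0 = arch.t_ms
    while arch.t_ms - t0 < max_ms:
        arch.step(maps, sal)
        if arch._outcome is not None:
            return arch._outcome
        if arch.rejections > arch.max_rejections:
            break
    return SearchOutcome(selected_tile=None, rt_ms=None,
                         rejections=arch.rejections, aborted=True)


def compute_guidance(
    maps_B: SpaceFeatureMaps,
    memory_F: dict[str, FieldState],
    cue_values: dict[str, float],
    swm_D1: FieldState | None,
    cfg: ArchitectureConfig,
    settle_ms: float = 400.0,
) -> np.ndarray:
    """Steady-state guidance bias for the selection field.

    Builds fresh overlap/guidance fields, imposes the given cue feature
    values as stored cue peaks, relaxes, and returns
    ``g_K1 * sigma(K1) + g_J1 * sigma(J1) - g_swm * sigma(D1)`` restricted
    to supra-threshold activation.  With no cue the bias is identically
    zero (guidance fields stay sub-threshold).
    """
    x, y = cfg.vision.space_dims()
    k1_field = FieldState((x, y), h=cfg.guidance_h_scene, tau=cfg.guidance_tau,
                          beta=cfg.guidance_beta,
                          kernel=_guidance_kernel(cfg), name="K1")
    j1_field = FieldState((x, y), h=cfg.guidance_h_memory, tau=cfg.guidance_tau,
                          beta=cfg.guidance_beta,
                          kernel=_guidance_kernel(cfg), name="J1")
    K, J, cue_profiles = {}, {}, {}
    for f in cfg.features:
        fdim = _feature_dim(cfg, f)
        K[f] = FieldState((x, y, fdim), h=cfg.overlap_h, tau=cfg.overlap_tau,
                          beta=cfg.overlap_beta, name=f"K_{f}")
        J[f] = FieldState((x, y, fdim), h=cfg.overlap_h, tau=cfg.overlap_tau,
                          beta=cfg.overlap_beta, name=f"J_{f}")
        if f in cue_values:
            cue_profiles[f] = gaussian_bump(
                (fdim,), (cue_values[f],), 0.8 * fdim.spacing, 1.0)
        else:
            cue_profiles[f] = np.zeros(fdim.samples)
    n_cues = float(len(cue_values))
    dt = cfg.dt
    for _ in range(int(round(settle_ms / dt))):
        k1_in = np.zeros((x.samples, y.samples))
        j1_in = np.zeros((x.samples, y.samples))
        for f in cfg.features:
            sl = np.broadcast_to(cue_profiles[f][None, None, :], K[f].shape)
            step_field(K[f], cfg.overlap_gain_scene * maps_B.map_for(f)
                       + cfg.overlap_gain_cue * sl, dt)
            k1_in += _marginalize_feature(_supra_output(K[f]), K[f].dims, 1.2)
            mem_out = (_supra_output(memory_F[f]) if f in memory_F
                       else np.zeros(J[f].shape))
            step_field(J[f], cfg.overlap_gain_memory * mem_out
                       + cfg.overlap_gain_cue * sl, dt)
            j1_in += _marginalize_feature(_supra_output(J[f]), J[f].dims, 1.2)
        step_field(k1_field, cfg.guidance_gain * k1_in
                   - cfg.scene_deboost_per_cue * n_cues, dt)
        step_field(j1_field, cfg.guidance_gain * j1_in
                   - cfg.memory_deboost_per_cue * n_cues, dt)
    bias = (cfg.d_gain_scene_guidance * _supra_output(k1_field)
            + cfg.d_gain_memory_guidance * _supra_output(j1_field))
    if swm_D1 is not None:
        bias = bias - cfg.d_gain_swm * _supra_output(swm_D1)
    return bias
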