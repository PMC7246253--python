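"""Attentional selection: salience, spatial selection, IOR, spatial WM,
and onset/offset transient detectors.

The salience field (C) carries one self-stabilized peak per conspicuous
location.  The spatial selection field (D) is in the selection regime --
strong global inhibition admits at most one supra-threshold peak, the
current focus of attention.  Selection is biased away from recently
attended locations by an inhibition-of-return memory trace (D2) and by the
self-sustained, capacity-limited spatial working memory field (D1), and
attracted to locations of rapid salience change by a two-layer onset
detector (D3).  A matching offset detector (D4) responds to disappearing
or moving items; any such transient applies a global deboost to D1,
resetting spatial working memory -- the fragility that distinguishes it
from the scene (feature) working memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ArchitectureConfig
from .dnf_core import (
    DimensionSpec,
    FieldState,
    InteractionKernel,
    PeakSet,
    detect_peaks,
    sigmoid,
    step_field,
)

__all__ = [
    "AttentionState",
    "TransientDetector",
    "make_attention",
    "step_attention",
    "update_ior_trace",
    "detect_onset",
    "detect_offset_and_reset_swm",
]


@dataclass
class TransientDetector:
    """Two-layer transient detector.

    Both layers low-pass filter the same input, one fast and one slow; the
    thresholded difference is a transient response to tonic input shifts
    that decays once the slow layer catches up, even while the input
    persists.  ``polarity`` +1 responds to input increases (onset), -1 to
    decreases (offset).
    """

    fast: FieldState
    slow: FieldState
    polarity: int = 1
    threshold: float = 0.25
    out_gain: float = 3.0

    def step(self, external_input: np.ndarray, dt: float) -> np.ndarray:
        step_field(self.fast, external_input, dt)
        step_field(self.slow, external_input, dt)
        diff = self.polarity * (self.fast.u - self.slow.u)
        return self.out_gain * np.clip(diff - self.threshold, 0.0, None)

    def output(self) -> np.ndarray:
        diff = self.polarity * (self.fast.u - self.slow.u)
        return self.out_gain * np.clip(diff - self.threshold, 0.0, None)

    def reset(self) -> None:
        self.fast.u[...] = 0.0
        self.slow.u[...] = 0.0


def _transient_detector(dims, cfg: ArchitectureConfig, polarity: int,
                        threshold: float) -> TransientDetector:
    return TransientDetector(
        fast=FieldState(dims, u=np.zeros([d.samples for d in dims]), h=0.0,
                        tau=cfg.transient_fast_tau, name="transient_fast"),
        slow=FieldState(dims, u=np.zeros([d.samples for d in dims]), h=0.0,
                        tau=cfg.transient_slow_tau, name="transient_slow"),
        polarity=polarity,
        threshold=threshold,
        out_gain=cfg.transient_out_gain,
    )


@dataclass
class AttentionState:
    """Fields C, D, D1-D4 of the attention sub-system."""

    salience: FieldState  # C
    selection: FieldState  # D
    swm: FieldState  # D1
    ior_trace: np.ndarray  # D2, values in [0, 1]
    onset: TransientDetector  # D3
    offset: TransientDetector  # D4
    dims: tuple[DimensionSpec, DimensionSpec]
    config: ArchitectureConfig
    pool_level: float = 0.0  # inhibitory pool of the selection field

    def selected_peak(self) -> PeakSet:
        return detect_peaks(self.selection, min_mass=2.0)


def make_attention(cfg: ArchitectureConfig) -> AttentionState:
    dims = cfg.vision.space_dims()
    salience = FieldState(
        dims,
        h=cfg.c_h, tau=cfg.c_tau, beta=cfg.c_beta, noise_amplitude=cfg.c_noise,
        kernel=InteractionKernel(
            exc_amp=cfg.c_exc_amp, exc_width=cfg.c_exc_width_px,
            inh_amp=cfg.c_inh_amp, inh_width=cfg.c_inh_width_px,
        ),
        regime_label="detection", name="C",
    )
    selection = FieldState(
        dims,
        h=cfg.d_h, tau=cfg.d_tau, beta=cfg.d_beta, noise_amplitude=cfg.d_noise,
        kernel=InteractionKernel(
            exc_amp=cfg.d_exc_amp, exc_width=cfg.d_exc_width_px,
            inh_amp=cfg.d_inh_amp, inh_width=cfg.d_inh_width_px,
            global_inh=cfg.d_global_inh,
        ),
        regime_label="selection", name="D",
    )
    swm = FieldState(
        dims,
        h=cfg.swm_h, tau=cfg.swm_tau, beta=cfg.swm_beta,
        noise_amplitude=cfg.swm_noise,
        kernel=InteractionKernel(
            exc_amp=cfg.swm_exc_amp, exc_width=cfg.swm_exc_width_px,
            inh_amp=cfg.swm_inh_amp, inh_width=cfg.swm_inh_width_px,
        ),
        regime_label="sustained", name="D1",
    )
    return AttentionState(
        salience=salience,
        selection=selection,
        swm=swm,
        ior_trace=np.zeros([d.samples for d in dims]),
        onset=_transient_detector(dims, cfg, +1, cfg.onset_threshold),
        offset=_transient_detector(dims, cfg, -1, cfg.offset_threshold),
        dims=dims,
        config=cfg,
    )


def step_attention(
    state: AttentionState,
    salience_input: np.ndarray,
    bias_inputs: np.ndarray | float = 0.0,
    dt: float = 5.0,
    rng=None,
    commit_swm: float = 0.0,
    swm_extra: np.ndarray | float = 0.0,
) -> AttentionState:
    """One tick of the attentional sub-system.

    ``bias_inputs`` is the summed excitatory/inhibitory bias for the
    selection field (guidance, onset excitation, boosts, rejection and
    instruction inputs); IOR-trace and spatial-working-memory inhibition
    are applied here.  ``commit_swm`` gates the selection -> D1 projection
    (supra-threshold only while exploration or cue retention is active).
    """
    cfg = state.config
    rng_c = rng("C") if rng else None
    rng_d = rng("D") if rng else None
    rng_m = rng("D1") if rng else None
    step_field(state.salience, cfg.salience_gain * salience_input, dt, rng_c)
    # inhibitory pool: only activation above the pool threshold competes,
    # so one consolidated peak suppresses every other candidate.  The pool
    # is itself a leaky neuron whose lag lets the first winner consolidate
    # before competition shuts the field down.
    pool_drive = float(sigmoid(state.selection.u - cfg.d_pool_threshold,
                               cfg.d_pool_beta).sum() / cfg.d_pool_ref)
    state.pool_level += (dt / cfg.d_pool_tau) * (pool_drive - state.pool_level)
    sel_input = (
        cfg.d_gain_salience * state.salience.output()
        + bias_inputs
        - cfg.d_pool_gain * state.pool_level
        - cfg.d_gain_ior * state.ior_trace
        - cfg.d_gain_swm * state.swm.output()
    )
    step_field(state.selection, sel_input, dt, rng_d)
    sel_out = state.selection.output()
    state.ior_trace = update_ior_trace(state.ior_trace, sel_out, dt, cfg)
    # weak graded competition between retained locations; the hard
    # capacity limit displaces the weakest peak (same slot rule as the
    # scene memory maps)
    peaks = detect_peaks(state.swm, min_mass=1.0)
    swm_input = (cfg.swm_gain_selection * sel_out * float(commit_swm)
                 - cfg.swm_capacity_inh * len(peaks) + swm_extra)
    step_field(state.swm, swm_input, dt, rng_m)
    peaks = detect_peaks(state.swm, min_mass=1.0)
    if len(peaks) > cfg.memory_capacity and float(commit_swm) < 0.5:
        weakest = min(peaks.peaks, key=lambda p: p.activation)
        xi = state.dims[0].index_of(weakest.location[0])
        yi = state.dims[1].index_of(weakest.location[1])
        state.swm.u[max(xi - 2, 0):xi + 3, max(yi - 2, 0):yi + 3] = \
            np.minimum(state.swm.u[max(xi - 2, 0):xi + 3,
                                   max(yi - 2, 0):yi + 3], state.swm.h)
    return state


def update_ior_trace(
    trace: np.ndarray,
    selection_output: np.ndarray,
    dt: float,
    cfg: ArchitectureConfig,
) -> np.ndarray:
    """Memory trace of recent selection: rises toward 1 where the selection
    field is supra-threshold, decays slowly elsewhere."""
    # only a consolidated selection peak counts as "attended"
    active = selection_output > 0.7
    build = (1.0 - trace) * selection_output / cfg.ior_build_tau
    decay = trace / cfg.ior_decay_tau
    return np.clip(trace + dt * np.where(active, build, -decay), 0.0, 1.0)


def detect_onset(
    detector: TransientDetector,
    salience_input: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Transient response to step increases of the salience input."""
    return detector.step(salience_input, dt)


def detect_offset_and_reset_swm(
    detector: TransientDetector,
    salience_input: np.ndarray,
    swm: FieldState,
    dt: float,
    cfg: ArchitectureConfig,
    rng=None,
) -> tuple[np.ndarray, FieldState]:
    """Offset transients globally deboost spatial working memory.

    The disappearance (or displacement) of salient items yields an offset
    transient; any transient above the event mass applies a homogeneous
    deboost that extinguishes all SWM peaks (a global, not local, reset --
    new objects at previously occupied locations must not be treated as
    already inspected).
    """
    out = detector.step(salience_input, dt)
    if out.sum() > cfg.offset_event_mass:
        step_field(swm, np.full(swm.shape, cfg.swm_deboost), dt,
                   rng("D1") if rng else None)
    return out, swm
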