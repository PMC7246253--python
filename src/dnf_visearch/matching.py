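"""Match / mismatch detection between attended and expected feature values.

For each feature dimension the sub-network holds an attended field, an
expected field, and a mismatch detection field.  The mismatch field
receives localized excitatory input from the attended side, a gating
excitation that is only present when the expected side carries a peak, and
broad inhibition centered on the expected value: it therefore goes through
the detection instability exactly when attended and expected peaks exist
at non-overlapping feature values.  The connection kernels set up the
metric of the comparison -- offsets smaller than the inhibitory overlap
width cancel (match), larger offsets do not (mismatch).

Peak-detector nodes signal peak presence per field.  The condition of
dissatisfaction (CoD) fires if any specified dimension carries a mismatch
peak; the condition of satisfaction (CoS) fires only when every specified
dimension has both attended and expected peaks and no mismatch peak.  CoS
and CoD inhibit each other and are never simultaneously active.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .config import ArchitectureConfig
from .dnf_core import (
    DimensionSpec,
    FieldState,
    NodeState,
    step_field,
    step_node,
)

__all__ = [
    "MatchOutcome",
    "MatchNetworkState",
    "make_match_network",
    "step_match_network",
    "evaluate_match",
]


class MatchOutcome(str, Enum):
    COS = "CoS"
    COD = "CoD"
    PENDING = "pending"


class MatchInvariantError(RuntimeError):
    """CoS and CoD simultaneously supra-threshold."""


SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class MatchNetworkState:
    attended: dict[str, FieldState]
    expected: dict[str, FieldState]
    mismatch: dict[str, FieldState]
    att_pd: dict[str, NodeState]
    exp_pd: dict[str, NodeState]
    mm_pd: dict[str, NodeState]
    cos_node: NodeState
    cod_node: NodeState
    config: ArchitectureConfig
    elapsed_ms: float = 0.0

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.attended)

    def reset(self) -> None:
        for d in self.features:
            self.attended[d].reset()
            self.expected[d].reset()
            self.mismatch[d].reset()
            self.att_pd[d].reset()
            self.exp_pd[d].reset()
            self.mm_pd[d].reset()
        self.cos_node.reset()
        self.cod_node.reset()
        self.elapsed_ms = 0.0

    def outcome(self) -> MatchOutcome:
        cos, cod = self.cos_node.active, self.cod_node.active
        if cos and cod:
            raise MatchInvariantError("CoS and CoD active simultaneously")
        if cos:
            return MatchOutcome.COS
        if cod:
            return MatchOutcome.COD
        return MatchOutcome.PENDING


def _feature_dim(cfg: ArchitectureConfig, feature: str) -> DimensionSpec:
    v = cfg.vision
    return {
        "color": v.hue_dim,
        "orientation": v.orientation_dim,
        "size": v.size_dim,
    }[feature]()


def make_match_network(cfg: ArchitectureConfig) -> MatchNetworkState:
    att, exp, mm = {}, {}, {}
    att_pd, exp_pd, mm_pd = {}, {}, {}
    for feature in cfg.features:
        dim = (_feature_dim(cfg, feature),)
        for store, name in ((att, "att"), (exp, "exp"), (mm, "mm")):
            h = cfg.mismatch_h if name == "mm" else cfg.match_h
            store[feature] = FieldState(
                dim, h=h, tau=cfg.match_tau, beta=cfg.match_beta,
                name=f"H_{name}_{feature}",
            )
        for store, name in ((att_pd, "att"), (exp_pd, "exp"), (mm_pd, "mm")):
            store[feature] = NodeState(
                h=cfg.peak_detector_h, tau=cfg.peak_detector_tau,
                self_exc=cfg.peak_detector_self_exc,
                name=f"pd_{name}_{feature}",
            )
    cos = NodeState(h=cfg.cos_h, tau=cfg.cos_tau,
                    self_exc=cfg.cos_cod_self_exc, name="CoS")
    cod = NodeState(h=cfg.cod_h, tau=cfg.cod_tau,
                    self_exc=cfg.cos_cod_self_exc, name="CoD")
    return MatchNetworkState(
        attended=att, expected=exp, mismatch=mm,
        att_pd=att_pd, exp_pd=exp_pd, mm_pd=mm_pd,
        cos_node=cos, cod_node=cod, config=cfg,
    )


def _peak_mass(field: FieldState) -> float:
    """Supra-threshold output mass per reference peak width."""
    dim = field.dims[0]
    out = np.where(field.u > 0.0, field.output(), 0.0)
    ref = SQRT2PI * 1.2  # reference peak ~1.2 bins sigma
    return float(out.sum()) / ref


def step_match_network(
    state: MatchNetworkState,
    attended_inputs: dict[str, np.ndarray],
    expected_inputs: dict[str, np.ndarray],
    dt: float,
    rng=None,
) -> MatchOutcome:
    """One tick of the whole comparison sub-network.

    ``attended_inputs`` / ``expected_inputs`` are 1-D activation profiles
    per feature dimension (amplitude ~1 at the represented value); feature
    dimensions absent from ``expected_inputs`` (or holding no peak) are
    unspecified and excluded from the comparison.
    """
    cfg = state.config
    w = cfg.match_weight
    n_match = 0.0
    n_expected = 0.0
    n_mismatch = 0.0
    for d in state.features:
        att_f, exp_f, mm_f = state.attended[d], state.expected[d], state.mismatch[d]
        a_in = attended_inputs.get(d, 0.0)
        e_in = expected_inputs.get(d, 0.0)
        step_field(att_f, cfg.match_input_gain * np.asarray(a_in, dtype=float),
                   dt, rng(att_f.name) if rng else None)
        step_field(exp_f, cfg.match_input_gain * np.asarray(e_in, dtype=float),
                   dt, rng(exp_f.name) if rng else None)
        # mismatch field: attended excitation + expected-present gate
        # - broad inhibition around the expected value
        dim = mm_f.dims[0]
        overlap = (cfg.match_overlap_bins_size if d == "size"
                   else cfg.match_overlap_bins)
        sig = overlap * dim.spacing
        exp_out = exp_f.output()
        broad = ndimage.gaussian_filter1d(
            exp_out, sig / dim.spacing, mode="wrap" if dim.circular else "constant"
        )
        broad = broad / max(broad.max(), 1e-9) if broad.max() > 1e-6 else broad
        gate = state.exp_pd[d].output()
        mm_in = (
            cfg.match_gain_attended * att_f.output()
            + cfg.match_gain_presence * gate
            - cfg.match_gain_expected * broad
        )
        step_field(mm_f, mm_in, dt, rng(mm_f.name) if rng else None)

        step_node(state.att_pd[d], cfg.peak_detector_gain * _peak_mass(att_f), dt)
        step_node(state.exp_pd[d], cfg.peak_detector_gain * _peak_mass(exp_f), dt)
        step_node(state.mm_pd[d], cfg.peak_detector_gain * _peak_mass(mm_f), dt)

        a_on = state.att_pd[d].output()
        e_on = state.exp_pd[d].output()
        m_on = state.mm_pd[d].output()
        n_expected += e_on
        n_mismatch += m_on
        n_match += a_on * e_on * (1.0 - m_on)

    # all specified dimensions must match: one unmatched expected peak
    # contributes twice the inhibition a matched one contributes excitation.
    # The CoS is held deboosted until the mismatch pathway (one synaptic
    # stage longer than the match pathway) has had time to evaluate.
    state.elapsed_ms += dt
    settle_deboost = 5.0 if state.elapsed_ms < cfg.match_settle_ms else 0.0
    cos_in = (
        w * n_match - 2.0 * w * (n_expected - n_match) - 0.4 * w
        - settle_deboost
        - cfg.cos_cod_mutual_inh * state.cod_node.output()
    )
    cod_in = (
        w * n_mismatch - 0.5 * w
        - cfg.cos_cod_mutual_inh * state.cos_node.output()
    )
    step_node(state.cos_node, cos_in, dt)
    step_node(state.cod_node, cod_in, dt)
    return state.outcome()


def evaluate_match(
    attended: dict[str, np.ndarray],
    expected: dict[str, np.ndarray],
    cfg: ArchitectureConfig | None = None,
    dt: float = 5.0,
    max_ms: float = 1500.0,
    state: MatchNetworkState | None = None,
    rng=None,
) -> MatchOutcome:
    """Run the comparison to a terminal outcome.

    Returns ``pending`` only if the detectors have not stabilized within
    ``max_ms`` (callers must then wait longer).  At least one expected
    dimension must be specified.
    """
    if cfg is None and state is None:
        raise ValueError("need a config or a pre-built network state")
    if state is None:
        state = make_match_network(cfg)
    has_expected = any(np.asarray(v).max() > 0.1 for v in expected.values())
    if not has_expected:
        raise ValueError("expected input specifies no feature dimension")
    state.reset()
    outcome = MatchOutcome.PENDING
    for _ in range(int(round(max_ms / dt))):
        outcome = step_match_network(state, attended, expected, dt, rng)
        if outcome is not MatchOutcome.PENDING:
            break
    return outcome
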