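"""Directed, signed, gated projections between fields of different rank.

Coupling among fields is directional: a source field's thresholded output
enters the target field's input term, possibly after

* marginalization -- integrating out dimensions present only in the source
  (many-to-one connectivity),
* expansion -- broadcasting along dimensions present only in the target,
  producing ridge / slice / column inputs (one-to-many connectivity),
* smoothing along shared dimensions, and a sign and gain.

A projection may be gated by a node: while the gate is sub-threshold the
target receives (almost) nothing.

Amplitude convention: thresholded outputs saturate near 1, so projections
are calibrated in units of "one saturated peak".  Marginalization therefore
normalizes the integral by the mass of a reference peak (``sqrt(2*pi) *
norm_width`` per removed axis) so that a single stored item again arrives
with amplitude ~1 in the target.  Expanded (ridge/slice/column) inputs are
kept individually sub-threshold by the gains chosen in the architecture
config: only coincident inputs push a target field through the detection
instability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dnf_core import (
    ConfigurationError,
    DimensionSpec,
    FieldState,
    NodeState,
    PeakSet,
    gaussian_bump,
)

__all__ = [
    "ProjectionSpec",
    "boost",
    "column_input",
    "project",
    "validate_graph",
]

SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class ProjectionSpec:
    """One directed, signed, gated edge of the architecture graph."""

    source: str
    target: str
    mode: str = "pointwise"  # marginalize | expand | pointwise
    dims: tuple[str, ...] = ()  # marginalized or expanded dimension names
    sign: str = "excitatory"  # excitatory | inhibitory
    gain: float = 1.0
    smoothing_width: float | None = None  # on shared dims, dimension units
    norm_width: float | None = None  # reference peak width for marginalize
    gate: str | None = None  # node name enabling transmission

    def __post_init__(self) -> None:
        if self.mode not in ("marginalize", "expand", "pointwise"):
            raise ConfigurationError(f"unknown projection mode {self.mode!r}")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ConfigurationError(f"unknown sign {self.sign!r}")
        self.dims = tuple(self.dims)

    @property
    def signed_gain(self) -> float:
        return self.gain if self.sign == "excitatory" else -self.gain

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "target": self.target,
            "mode": self.mode,
            "dims": list(self.dims),
            "sign": self.sign,
            "gain": self.gain,
            "smoothing_width": self.smoothing_width,
            "norm_width": self.norm_width,
            "gate": self.gate,
        }


def _dim_names(dims: Sequence[DimensionSpec]) -> tuple[str, ...]:
    return tuple(d.name for d in dims)


def project(
    source_output: np.ndarray,
    spec: ProjectionSpec,
    source_dims: Sequence[DimensionSpec],
    target_dims: Sequence[DimensionSpec],
    gate_open: bool | float = True,
) -> np.ndarray:
    """Map a thresholded source grid into an input grid for the target.

    Shared dimensions (matched by name) must agree in extent and sampling.
    With a closed gate the target input is identically zero.
    """
    source_dims = tuple(source_dims)
    target_dims = tuple(target_dims)
    src_names = _dim_names(source_dims)
    tar_names = _dim_names(target_dims)
    out_shape = tuple(d.samples for d in target_dims)

    gate_factor = float(gate_open) if not isinstance(gate_open, bool) else (
        1.0 if gate_open else 0.0
    )
    if gate_factor == 0.0:
        return np.zeros(out_shape)

    source_output = np.asarray(source_output, dtype=float)
    if source_output.shape != tuple(d.samples for d in source_dims):
        raise ConfigurationError("source output does not match source dims")

    shared = [n for n in src_names if n in tar_names]
    for n in shared:
        s = source_dims[src_names.index(n)]
        t = target_dims[tar_names.index(n)]
        if s.extent != t.extent or s.samples != t.samples or s.circular != t.circular:
            raise ConfigurationError(f"shared dimension {n!r} mismatches")

    removed = tuple(n for n in src_names if n not in tar_names)
    added = tuple(n for n in tar_names if n not in src_names)
    if spec.mode == "marginalize" and not removed:
        raise ConfigurationError("marginalize projection removes no dimension")
    if spec.mode == "pointwise" and (removed or added):
        raise ConfigurationError("pointwise projection requires identical dims")
    if removed and spec.mode != "marginalize":
        raise ConfigurationError(f"source dims {removed} not in target")

    grid = source_output
    # integrate out source-only dimensions, normalized per reference peak
    for n in removed:
        names_now = _dim_names(tuple(d for d in source_dims if d.name not in
                                     removed[: removed.index(n)]))
        axis = names_now.index(n)
        d = source_dims[src_names.index(n)]
        norm = SQRT2PI * spec.norm_width if spec.norm_width else d.spacing * 1.0
        grid = grid.sum(axis=axis) * d.spacing / max(norm, 1e-12)

    # reorder remaining axes to target order
    kept = tuple(n for n in src_names if n not in removed)
    if kept:
        order = [kept.index(n) for n in tar_names if n in kept]
        grid = np.transpose(grid, order)

    # smooth along shared dims
    if spec.smoothing_width and kept:
        sig = []
        modes = []
        for n in (n for n in tar_names if n in kept):
            d = target_dims[tar_names.index(n)]
            sig.append(spec.smoothing_width / d.spacing)
            modes.append("wrap" if d.circular else "constant")
        grid = ndimage.gaussian_filter(grid, tuple(sig), mode=tuple(modes))

    # broadcast along target-only dimensions
    if added:
        shape = [1] * len(target_dims)
        for i, n in enumerate(tar_names):
            if n in kept:
                shape[i] = target_dims[i].samples
        grid = np.broadcast_to(grid.reshape(shape), out_shape).copy()

    return spec.signed_gain * gate_factor * grid


def column_input(
    attended_location,
    target_dims: Sequence[DimensionSpec],
    width: float | None = None,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Spatial tube through a space/feature field at the attended location.

    The input is a Gaussian over the two spatial dimensions centered at the
    attended 2-D location, constant along every non-spatial (feature)
    dimension.  Exactly one attended peak is required.
    """
    if isinstance(attended_location, PeakSet):
        if len(attended_location) != 1:
            raise ValueError(
                f"column input needs exactly one attended peak, "
                f"got {len(attended_location)}"
            )
        attended_location = attended_location.peaks[0].location
    x0, y0 = attended_location
    target_dims = tuple(target_dims)
    spatial = [d for d in target_dims if d.name in ("x", "y")]
    if len(spatial) != 2:
        raise ConfigurationError("column input needs target dims named x and y")
    if width is None:
        width = 1.5 * spatial[0].spacing
    tube2d = gaussian_bump(spatial, (x0, y0), width, amplitude)
    shape = [1] * len(target_dims)
    names = _dim_names(target_dims)
    for i, n in enumerate(names):
        if n in ("x", "y"):
            shape[i] = target_dims[i].samples
    out_shape = tuple(d.samples for d in target_dims)
    # tube2d axes are in (x, y) order of appearance in target_dims
    return np.broadcast_to(tube2d.reshape(shape), out_shape).copy()


def boost(target: FieldState | NodeState, amount: float):
    """Homogeneous additive drive for a field or node.

    Positive amounts ("boosts") enable a sub-network to form peaks; strong
    negative amounts ("deboosts") push existing peaks through the reverse
    detection instability.  Returns the input contribution to add to the
    target's step input.
    """
    if isinstance(target, NodeState):
        return float(amount)
    return np.full(target.shape, float(amount))


def validate_graph(
    specs: Sequence[ProjectionSpec],
    field_dims: dict[str, Sequence[DimensionSpec]],
    node_names: Sequence[str] = (),
) -> None:
    """Check that every edge of an architecture graph is well formed."""
    known = set(field_dims) | set(node_names)
    for spec in specs:
        for end in (spec.source, spec.target):
            if end not in known:
                raise ConfigurationError(f"unknown field/node {end!r} in graph")
        if spec.gate is not None and spec.gate not in known:
            raise ConfigurationError(f"unknown gate node {spec.gate!r}")
        if spec.source in field_dims and spec.target in field_dims:
            src = tuple(field_dims[spec.source])
            tar = tuple(field_dims[spec.target])
            src_names = _dim_names(src)
            tar_names = _dim_names(tar)
            for n in set(src_names) & set(tar_names):
                s = src[src_names.index(n)]
                t = tar[tar_names.index(n)]
                if s.extent != t.extent or s.samples != t.samples:
                    raise ConfigurationError(
                        f"edge {spec.source}->{spec.target}: shared dim {n!r} "
                        f"mismatches"
                    )
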