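"""Numerical core for dynamic neural fields and nodes.

A dynamic neural field carries an activation function ``u(x, t)`` over a
stack of labelled dimensions (visual space in pixels, hue in degrees,
orientation in degrees, a log-size index).  It relaxes toward its negative
resting level ``h`` under a first-order dynamics

    tau * du/dt = -u + h + s(x, t) + noise
                  + integral omega(x - x') sigma(u(x', t)) dx'

where ``sigma`` is a logistic threshold function and ``omega`` a
local-excitation / surround-inhibition interaction kernel with an optional
global-inhibition term.  Supra-threshold peaks (``u > 0``) are the units of
representation: they arise in the detection instability, disappear in the
reverse detection instability, and -- depending on the balance of excitation
and inhibition -- a field operates in a detection, selection (at most one
peak), or sustained (peaks survive input removal) regime.

Zero-dimensional fields are nodes; a node with sufficient self-excitation is
bistable over a range of inputs (hysteresis), which is what shields discrete
processing events against input fluctuations.

Integration is explicit Euler with additive Gaussian noise scaled by
``sqrt(dt)``.  Interaction is evaluated by separable Gaussian convolution,
wrapped on circular dimensions and zero-padded on bounded ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DimensionSpec",
    "FieldState",
    "InteractionKernel",
    "NodeState",
    "NumericalInstabilityError",
    "Peak",
    "PeakSet",
    "RngStreams",
    "detect_peaks",
    "gaussian_bump",
    "interaction_input",
    "sigmoid",
    "step_field",
    "step_node",
]


class NumericalInstabilityError(RuntimeError):
    """Raised when an activation grid leaves the finite range."""


class ConfigurationError(ValueError):
    """Raised for inconsistent field / kernel / projection setups."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DimensionSpec:
    """One labelled field dimension.

    Parameters
    ----------
    name:
        Dimension label, e.g. ``"x"``, ``"hue"``.
    extent:
        ``(lo, hi)`` interval in stimulus units (pixels for space, degrees
        for hue ``[0, 360)`` and orientation ``[0, 180)``, log-size index
        for size).
    samples:
        Number of grid points (``>= 3``).
    circular:
        Whether distances along this dimension wrap around the extent.
    """

    name: str
    extent: tuple[float, float]
    samples: int
    circular: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.extent
        if not hi > lo:
            raise ConfigurationError(f"degenerate extent for {self.name!r}")
        if self.samples < 3:
            raise ConfigurationError(f"need >= 3 samples for {self.name!r}")

    @property
    def length(self) -> float:
        return self.extent[1] - self.extent[0]

    @property
    def spacing(self) -> float:
        # circular grids omit the duplicate endpoint
        n = self.samples if self.circular else self.samples - 1
        return self.length / n

    def grid(self) -> np.ndarray:
        """Sample coordinates in dimension units."""
        lo, hi = self.extent
        return np.linspace(lo, hi, self.samples, endpoint=not self.circular)

    def index_of(self, value: float) -> int:
        """Nearest grid index for a coordinate value."""
        lo, _ = self.extent
        idx = int(round((value - lo) / self.spacing))
        if self.circular:
            return idx % self.samples
        return min(max(idx, 0), self.samples - 1)

    def distance(self, a, b):
        """Metric distance, wrapped for circular dimensions."""
        d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
        if self.circular:
            d = np.minimum(d, self.length - d)
        return d


@dataclass
class InteractionKernel:
    """Difference-of-Gaussians lateral interaction with global inhibition.

    ``exc_amp`` and ``inh_amp`` are the maximal contributions (activation
    units) of a fully saturated, kernel-wide supra-threshold region; widths
    are Gaussian sigmas in dimension units, either one scalar shared by all
    axes or one value per axis.  ``global_inh`` scales inhibition
    proportional to the total supra-threshold output of the field, measured
    in units of one reference peak's mass so that each stored item
    contributes roughly ``global_inh`` of inhibition everywhere.
    """

    exc_amp: float = 0.0
    exc_width: float | Sequence[float] = 1.0
    inh_amp: float = 0.0
    inh_width: float | Sequence[float] = 2.0
    global_inh: float = 0.0

    def _widths(self, value, ndim: int) -> tuple[float, ...]:
        if np.isscalar(value):
            return (float(value),) * ndim
        widths = tuple(float(v) for v in value)
        if len(widths) != ndim:
            raise ConfigurationError(
                f"kernel widths {widths} do not match field rank {ndim}"
            )
        return widths

    def exc_widths(self, ndim: int) -> tuple[float, ...]:
        w = self._widths(self.exc_width, ndim)
        if any(v <= 0 for v in w):
            raise ConfigurationError("kernel widths must be positive")
        return w

    def inh_widths(self, ndim: int) -> tuple[float, ...]:
        w = self._widths(self.inh_width, ndim)
        if any(v <= 0 for v in w):
            raise ConfigurationError("kernel widths must be positive")
        return w


@dataclass
class FieldState:
    """Activation grid plus the dynamic parameters of one neural field."""

    dims: tuple[DimensionSpec, ...]
    u: np.ndarray = None  # type: ignore[assignment]
    h: float = -5.0
    tau: float = 100.0  # ms
    beta: float = 4.0
    noise_amplitude: float = 0.0  # activation std per sqrt(ms)
    kernel: InteractionKernel | None = None
    regime_label: str = "detection"
    name: str = ""

    def __post_init__(self) -> None:
        self.dims = tuple(self.dims)
        if self.tau <= 0 or self.beta <= 0:
            raise ConfigurationError("tau and beta must be positive")
        if self.u is None:
            self.u = np.full(self.shape, self.h, dtype=float)
        else:
            self.u = np.asarray(self.u, dtype=float)
            if self.u.shape != self.shape:
                raise ConfigurationError(
                    f"activation shape {self.u.shape} != grid {self.shape}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(d.samples for d in self.dims)

    @property
    def ndim(self) -> int:
        return len(self.dims)

    def output(self) -> np.ndarray:
        """Thresholded activation ``sigma(u)`` passed on to other fields."""
        return sigmoid(self.u, self.beta)

    def reset(self) -> None:
        self.u[...] = self.h

    def copy(self) -> "FieldState":
        clone = FieldState(
            dims=self.dims,
            u=self.u.copy(),
            h=self.h,
            tau=self.tau,
            beta=self.beta,
            noise_amplitude=self.noise_amplitude,
            kernel=self.kernel,
            regime_label=self.regime_label,
            name=self.name,
        )
        return clone


@dataclass
class NodeState:
    """Zero-dimensional field: a single neural dynamic node.

    ``self_exc`` is the gain of the node's self-excitation term
    ``c * sigma(u)``; large enough values make the node bistable over an
    input interval (hysteresis between on- and off-switch).
    """

    u: float = -5.0
    h: float = -5.0
    tau: float = 50.0
    beta: float = 4.0
    noise_amplitude: float = 0.0
    self_exc: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.beta <= 0:
            raise ConfigurationError("tau and beta must be positive")

    def output(self) -> float:
        return float(sigmoid(self.u, self.beta))

    @property
    def active(self) -> bool:
        return self.u > 0.0

    def reset(self) -> None:
        self.u = self.h


@dataclass(frozen=True)
class Peak:
    location: tuple[float, ...]
    activation: float
    mass: float


@dataclass
class PeakSet:
    peaks: list[Peak] = dataclass_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def locations(self) -> list[tuple[float, ...]]:
        return [p.location for p in self.peaks]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def sigmoid(u, beta: float):
    """Logistic threshold function ``1 / (1 + exp(-beta * u))``."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return 1.0 / (1.0 + np.exp(-beta * np.asarray(u, dtype=float)))


def _boundary_modes(dims: Sequence[DimensionSpec]) -> tuple[str, ...]:
    return tuple("wrap" if d.circular else "constant" for d in dims)


def _sigma_cells(widths: Sequence[float], dims: Sequence[DimensionSpec]):
    return tuple(w / d.spacing for w, d in zip(widths, dims))


def reference_peak_mass(field: FieldState) -> float:
    """Supra-threshold mass of one canonical stored peak.

    Used to express global inhibition "per stored item": a saturated
    Gaussian peak of the kernel's excitatory width has mass of the order of
    the product of ``sqrt(2 pi) * width`` over axes.  Measured in grid
    cells, i.e. total sigma output summed over the grid.
    """
    if field.kernel is None:
        raise ConfigurationError("field has no kernel")
    widths = field.kernel.exc_widths(field.ndim)
    mass = 1.0
    for w, d in zip(widths, field.dims):
        mass *= max(np.sqrt(2.0 * np.pi) * w / d.spacing, 1.0)
    return mass


def interaction_input(field: FieldState, output: np.ndarray | None = None) -> np.ndarray:
    """Lateral-interaction contribution of a field onto itself.

    Convolution of the thresholded output with the difference-of-Gaussians
    kernel minus global inhibition proportional to total supra-threshold
    output (in units of one reference peak).  Circular dimensions use
    wrapped convolution, bounded ones zero padding.
    """
    if field.kernel is None:
        raise ConfigurationError(f"field {field.name!r} has no kernel")
    k = field.kernel
    if output is None:
        output = field.output()
    if output.shape != field.shape:
        raise ConfigurationError("output grid does not match field dims")
    modes = _boundary_modes(field.dims)
    contribution = np.zeros_like(output)
    if k.exc_amp:
        sig = _sigma_cells(k.exc_widths(field.ndim), field.dims)
        contribution += k.exc_amp * ndimage.gaussian_filter(output, sig, mode=modes)
    if k.inh_amp:
        sig = _sigma_cells(k.inh_widths(field.ndim), field.dims)
        contribution -= k.inh_amp * ndimage.gaussian_filter(output, sig, mode=modes)
    if k.global_inh:
        contribution -= k.global_inh * output.sum() / reference_peak_mass(field)
    return contribution


def step_field(
    field: FieldState,
    external_input: np.ndarray | float = 0.0,
    dt: float = 5.0,
    rng: np.random.Generator | None = None,
) -> FieldState:
    """One explicit-Euler step of the field dynamics (in place).

    ``du = dt / tau * (-u + h + s + interaction) + noise * sqrt(dt)``.
    Requires ``dt <= tau / 5``; deterministic for a given ``rng`` state.
    """
    if dt > field.tau / 5.0 + 1e-12:
        raise ValueError(f"dt={dt} too large for tau={field.tau} (need dt <= tau/5)")
    drive = -field.u + field.h + external_input
    if field.kernel is not None:
        drive = drive + interaction_input(field)
    field.u += (dt / field.tau) * drive
    if field.noise_amplitude and rng is not None:
        field.u += field.noise_amplitude * np.sqrt(dt) * rng.standard_normal(field.shape)
    if not np.all(np.isfinite(field.u)):
        raise NumericalInstabilityError(
            f"non-finite activation in field {field.name!r}"
        )
    return field


def step_node(
    node: NodeState,
    external_input: float = 0.0,
    dt: float = 5.0,
    rng: np.random.Generator | None = None,
) -> NodeState:
    """One Euler step of the node dynamics with self-excitation (in place)."""
    if dt > node.tau / 5.0 + 1e-12:
        raise ValueError(f"dt={dt} too large for tau={node.tau} (need dt <= tau/5)")
    drive = -node.u + node.h + external_input + node.self_exc * node.output()
    node.u += (dt / node.tau) * drive
    if node.noise_amplitude and rng is not None:
        node.u += node.noise_amplitude * np.sqrt(dt) * float(rng.standard_normal())
    if not np.isfinite(node.u):
        raise NumericalInstabilityError(f"non-finite activation in node {node.name!r}")
    return node


def detect_peaks(field: FieldState, min_mass: float = 0.0) -> PeakSet:
    """Connected supra-threshold regions of a field.

    A peak is a connected component of ``u > 0`` (wrap-aware on circular
    dimensions), reported with the coordinates of its maximum, the maximal
    activation, and its supra-threshold mass (summed sigma output).
    """
    supra = field.u > 0.0
    if not supra.any():
        return PeakSet([])
    labels, n = ndimage.label(supra)
    labels = _merge_wrapped_labels(labels, field.dims)
    out = field.output()
    peaks: list[Peak] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        masked = np.where(mask, field.u, -np.inf)
        flat_idx = int(np.argmax(masked))
        idx = np.unravel_index(flat_idx, field.shape)
        loc = tuple(float(d.grid()[i]) for d, i in zip(field.dims, idx))
        mass = float(out[mask].sum())
        if mass >= min_mass:
            peaks.append(Peak(location=loc, activation=float(field.u[idx]), mass=mass))
    peaks.sort(key=lambda p: -p.activation)
    return PeakSet(peaks)


def _merge_wrapped_labels(labels: np.ndarray, dims: Sequence[DimensionSpec]) -> np.ndarray:
    """Union components that touch across the seam of circular axes."""
    labels = labels.copy()
    for axis, d in enumerate(dims):
        if not d.circular:
            continue
        first = np.take(labels, 0, axis=axis)
        last = np.take(labels, -1, axis=axis)
        pairs = set(
            (int(a), int(b))
            for a, b in zip(first.ravel(), last.ravel())
            if a and b and a != b
        )
        for a, b in pairs:
            lo, hi = min(a, b), max(a, b)
            labels[labels == hi] = lo
    return labels


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def gaussian_bump(
    dims: Sequence[DimensionSpec],
    center: Sequence[float],
    width: float | Sequence[float],
    amplitude: float = 1.0,
) -> np.ndarray:
    """Separable Gaussian input bump in dimension units (wrap-aware)."""
    dims = tuple(dims)
    if np.isscalar(width):
        width = (float(width),) * len(dims)
    grids = np.meshgrid(*[d.grid() for d in dims], indexing="ij", sparse=True)
    log_g = np.zeros(tuple(d.samples for d in dims))
    for g, c, w, d in zip(grids, center, width, dims):
        dist = d.distance(g, c)
        log_g = log_g - 0.5 * (dist / w) ** 2
    return amplitude * np.exp(log_g)


class RngStreams:
    """One named, replayable random stream per field or node.

    All streams derive from a single trial seed; the per-stream seed mixes
    in a CRC of the stream name so that adding a stream never perturbs the
    draws of existing ones.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._streams: dict[str, np.random.Generator] = {}

    def stream(self, name: str) -> np.random.Generator:
        if name not in self._streams:
            key = zlib.crc32(name.encode("utf8")) & 0x7FFFFFFF
            ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
            self._streams[name] = np.random.default_rng(ss)
        return self._streams[name]

    def __call__(self, name: str) -> np.random.Generator:
        return self.stream(name)
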