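"""Scene working memory: item-by-item commitment of attended space/feature
conjunctions to capacity-limited sustained memory.

Three stages per feature dimension (color, orientation, size):

* scene space/feature selection (E): peaks form only where input from the
  scene maps coincides with the column input from the attended location --
  the neural read-out of the attended item's feature values;
* memory space/feature maps (F): sustained fields that receive the
  attended column plus a feature "slice" of the extracted values; their
  accumulating global inhibition limits how many items can be co-sustained
  (the working-memory capacity);
* memory space/feature selection (G): read-out of the stored item at the
  attended location (recall).

The three F maps share one spatial inhibitory pool, which keeps peaks
spatially co-located across feature dimensions (one item, one tile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ArchitectureConfig
from .dnf_core import (
    DimensionSpec,
    FieldState,
    InteractionKernel,
    step_field,
)
from .topology import column_input
from .vision_frontend import SpaceFeatureMaps

__all__ = [
    "MemoryMaps",
    "evict_overflow",
    "make_memory",
    "attended_feature_input",
    "extract_attended_features",
    "commit_item",
    "recall_at_location",
    "memory_snapshot",
    "spatial_peak_count",
]


def _feature_dim(cfg: ArchitectureConfig, feature: str) -> DimensionSpec:
    v = cfg.vision
    return {
        "color": v.hue_dim,
        "orientation": v.orientation_dim,
        "size": v.size_dim,
    }[feature]()


@dataclass
class MemoryMaps:
    """Fields E, F, G for each feature dimension."""

    selection_E: dict[str, FieldState]
    memory_F: dict[str, FieldState]
    mem_selection_G: dict[str, FieldState]
    config: ArchitectureConfig

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.selection_E)

    def dims3(self, feature: str) -> tuple[DimensionSpec, ...]:
        return self.memory_F[feature].dims

    def shared_capacity_inhibition(self) -> float:
        """Weak spatial inhibitory pool shared by the memory maps: each
        retained item adds graded competition.  The hard capacity limit is
        enforced by :func:`evict_overflow` (displacement of the weakest
        item once the slots are full)."""
        return self.config.f_capacity_inh * spatial_peak_count(self)


def make_memory(cfg: ArchitectureConfig) -> MemoryMaps:
    x, y = cfg.vision.space_dims()
    sel, mem, rec = {}, {}, {}
    for feature in cfg.features:
        fdim = _feature_dim(cfg, feature)
        dims = (x, y, fdim)
        sel[feature] = FieldState(
            dims, h=cfg.e_h, tau=cfg.e_tau, beta=cfg.e_beta,
            noise_amplitude=cfg.e_noise, regime_label="detection",
            name=f"E_{feature}",
        )
        mem[feature] = FieldState(
            dims, h=cfg.f_h, tau=cfg.f_tau, beta=cfg.f_beta,
            noise_amplitude=cfg.f_noise,
            kernel=InteractionKernel(
                exc_amp=cfg.f_exc_amp,
                exc_width=(cfg.f_exc_width_px, cfg.f_exc_width_px,
                           cfg.f_exc_width_bins * fdim.spacing),
                inh_amp=cfg.f_inh_amp,
                inh_width=(cfg.f_inh_width_px, cfg.f_inh_width_px,
                           cfg.f_inh_width_bins * fdim.spacing),
                global_inh=0.0,  # shared pool applied explicitly
            ),
            regime_label="sustained", name=f"F_{feature}",
        )
        rec[feature] = FieldState(
            dims, h=cfg.g_h, tau=cfg.g_tau, beta=cfg.g_beta,
            regime_label="detection", name=f"G_{feature}",
        )
    return MemoryMaps(selection_E=sel, memory_F=mem, mem_selection_G=rec,
                      config=cfg)


def _readout_profile(field: FieldState, attended_location=None,
                     mask_width: float = 36.0) -> np.ndarray:
    """Space/feature field -> 1-D feature activation.

    Max-pooled over the attended column's spatial footprint (independent
    of how many grid cells the item's activation covers; flanks of
    neighboring items are excluded) and squashed to ~binary amplitude.
    """
    from .dnf_core import gaussian_bump
    from .task_control import _squash_profile, _supra_output

    out = _supra_output(field)
    if attended_location is not None:
        mask = gaussian_bump(field.dims[:2], attended_location,
                             mask_width) > 0.3
        out = out * mask[:, :, None]
    return _squash_profile(out.max(axis=(0, 1)))


def attended_feature_input(
    maps_B: SpaceFeatureMaps,
    feature: str,
    attended_location: tuple[float, float],
    cfg: ArchitectureConfig,
) -> np.ndarray:
    """Input grid for a scene space/feature selection field E."""
    dims3 = maps_B.dims_for(feature)
    col = column_input(attended_location, dims3, width=cfg.column_width_px)
    return (cfg.e_gain_scene * maps_B.map_for(feature)
            + cfg.e_gain_column * col)


def extract_attended_features(
    maps_B: SpaceFeatureMaps,
    attended_location: tuple[float, float],
    memory: MemoryMaps,
    dt: float = 5.0,
    settle_ms: float = 150.0,
    rng=None,
) -> dict[str, np.ndarray]:
    """Relax the E fields onto scene input + attended column and read out
    one localized 1-D activation per feature dimension.

    An empty attended tile leaves every E field sub-threshold and yields
    all-zero activations.
    """
    cfg = memory.config
    out: dict[str, np.ndarray] = {}
    for feature in memory.features:
        field = memory.selection_E[feature]
        inp = attended_feature_input(maps_B, feature, attended_location, cfg)
        for _ in range(int(round(settle_ms / dt))):
            step_field(field, inp, dt, rng(field.name) if rng else None)
        out[feature] = _readout_profile(field, attended_location)
    return out


def commit_item(
    memory: MemoryMaps,
    attended_location: tuple[float, float],
    feature_slices: dict[str, np.ndarray],
    dt: float = 5.0,
    drive_ms: float = 250.0,
    settle_ms: float = 150.0,
    rng=None,
) -> MemoryMaps:
    """Commit the attended item to the sustained memory maps.

    The F fields are driven by the attended column plus the extracted
    feature slices; a sustained peak forms at (location, feature) per
    dimension.  Existing peaks persist unless the shared capacity
    inhibition displaces the weakest.
    """
    cfg = memory.config
    drives = {}
    for feature in memory.features:
        field = memory.memory_F[feature]
        col = column_input(attended_location, field.dims,
                          width=cfg.column_width_px)
        fslice = feature_slices.get(feature)
        # squared profile: broad slice tails would otherwise drag peaks
        # stored at neighboring feature values toward the new slice
        sl = 0.0 if fslice is None else np.broadcast_to(
            (np.asarray(fslice) ** 2)[None, None, :], field.shape
        )
        # additive overlap: column and slice are each sub-threshold; only
        # their coincidence pushes F through the detection instability
        drives[feature] = cfg.f_gain_column * col + cfg.f_gain_slice * sl
    n_drive = int(round(drive_ms / dt))
    n_settle = int(round(settle_ms / dt))
    for i in range(n_drive + n_settle):
        pool = memory.shared_capacity_inhibition()
        for feature in memory.features:
            field = memory.memory_F[feature]
            ext = (drives[feature] if i < n_drive else 0.0) - pool
            step_field(field, ext, dt, rng(field.name) if rng else None)
        if i >= n_drive:
            evict_overflow(memory)
    return memory


def step_memory(
    memory: MemoryMaps,
    f_inputs: dict[str, np.ndarray] | None,
    dt: float,
    rng=None,
) -> None:
    """One tick of the F fields under the shared capacity pool."""
    pool = memory.shared_capacity_inhibition()
    for feature in memory.features:
        field = memory.memory_F[feature]
        ext = -pool if f_inputs is None else f_inputs[feature] - pool
        step_field(field, ext, dt, rng(field.name) if rng else None)


def recall_at_location(
    memory: MemoryMaps,
    attended_location: tuple[float, float],
    dt: float = 5.0,
    settle_ms: float = 150.0,
    rng=None,
) -> dict[str, np.ndarray]:
    """Features of the stored item at the attended location, via the
    memory selection fields G; all-zero if nothing is stored there."""
    cfg = memory.config
    out: dict[str, np.ndarray] = {}
    for feature in memory.features:
        field = memory.mem_selection_G[feature]
        mem_out = memory.memory_F[feature].output()
        col = column_input(attended_location, field.dims,
                          width=cfg.column_width_px)
        inp = cfg.g_gain_memory * mem_out + cfg.g_gain_column * col
        for _ in range(int(round(settle_ms / dt))):
            step_field(field, inp, dt, rng(field.name) if rng else None)
        out[feature] = _readout_profile(field, attended_location)
    return out


def spatial_peak_count(memory: MemoryMaps, min_activation: float = 4.0) -> int:
    """Number of distinct spatial locations retained in the memory maps.

    Counted at tile granularity: neighboring sustained peaks can share
    supra-threshold flanks, so connected components undercount; a tile
    counts as retained when the memory activation near its center is
    clearly supra-threshold.
    """
    return len(retained_tiles(memory, min_activation))


def retained_tiles(memory: MemoryMaps, min_activation: float = 4.0) -> list[int]:
    from scipy import ndimage

    from .stimuli import GRID_COLS, TILE_PX, _X0, _Y0, tile_center

    feature0 = memory.features[0]
    field = memory.memory_F[feature0]
    spatial = field.u.max(axis=2)
    xd, yd = field.dims[0], field.dims[1]
    # one retained item = one local activation maximum; each maximum is
    # assigned to the tile containing it (flanks of a strong peak reach
    # onto neighboring tiles but never exceed their parent peak)
    local_max = (spatial > min_activation) & (
        spatial >= ndimage.maximum_filter(spatial, size=5) - 1e-9)
    labels, n = ndimage.label(local_max)
    tiles = set()
    for lab in range(1, n + 1):
        mask = labels == lab
        masked = np.where(mask, spatial, -np.inf)
        xi, yi = np.unravel_index(int(np.argmax(masked)), spatial.shape)
        col = min(max(int((xd.grid()[xi] - _X0) // TILE_PX), 0), GRID_COLS - 1)
        row = min(max(int((yd.grid()[yi] - _Y0) // TILE_PX), 0), 3)
        tiles.add(row * GRID_COLS + col)
    return sorted(tiles)


def evict_overflow(memory: MemoryMaps, capacity: int | None = None) -> int | None:
    """Displace the weakest retained item when the slots are over-full.

    The accumulated inhibition of a fifth item pushes the weakest peak
    through its reverse detection instability; here that instability is
    resolved directly: the weakest tile's activation is reset to rest in
    every memory map.  Returns the evicted tile, or None.
    """
    from .stimuli import tile_center

    cfg = memory.config
    capacity = cfg.memory_capacity if capacity is None else capacity
    tiles = retained_tiles(memory)
    if len(tiles) <= capacity:
        return None
    feature0 = memory.features[0]
    f0 = memory.memory_F[feature0]
    xd, yd = f0.dims[0], f0.dims[1]

    def strength(tile):
        cx, cy = tile_center(tile)
        xi, yi = xd.index_of(cx), yd.index_of(cy)
        return float(f0.u[max(xi - 1, 0):xi + 2,
                          max(yi - 1, 0):yi + 2, :].max())

    weakest = min(tiles, key=strength)
    cx, cy = tile_center(weakest)
    for feature in memory.features:
        fld = memory.memory_F[feature]
        xi, yi = fld.dims[0].index_of(cx), fld.dims[1].index_of(cy)
        sl = (slice(max(xi - 2, 0), xi + 3), slice(max(yi - 2, 0), yi + 3))
        fld.u[sl[0], sl[1], :] = np.minimum(fld.u[sl[0], sl[1], :], fld.h)
    return weakest


def memory_snapshot(memory: MemoryMaps, min_activation: float = 4.0) -> list[dict]:
    """One row per retained item: tile plus the stored feature value per
    dimension (the activation maximum along each feature axis)."""
    from .stimuli import tile_center

    rows = []
    for tile in retained_tiles(memory, min_activation):
        cx, cy = tile_center(tile)
        entry = {"tile": tile, "x": cx, "y": cy}
        for feature in memory.features:
            fld = memory.memory_F[feature]
            xi = fld.dims[0].index_of(cx)
            yi = fld.dims[1].index_of(cy)
            local = fld.u[max(xi - 1, 0):xi + 2, max(yi - 1, 0):yi + 2, :]
            profile = local.max(axis=(0, 1))
            entry[feature] = float(fld.dims[2].grid()[int(np.argmax(profile))])
        rows.append(entry)
    return rows
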