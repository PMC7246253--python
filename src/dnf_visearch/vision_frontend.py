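"""Feed-forward extraction of color, orientation, and size maps.

The frontend turns a raster stimulus frame into three space/feature maps --
the model's formalization of cortical feature maps over visual space:

* color: each sufficiently saturated pixel contributes mass at its hue
  (circular, 360 degrees) and spatial location;
* orientation: four elongate oriented filters at 0/45/90/135 degrees,
  applied to the thresholded saturation of the input and interpolated onto
  a circular 180-degree orientation axis.  Each channel is opponent against
  its orthogonal channel, so isotropic blobs produce no net response;
* size: a pyramid of center-surround (difference-of-Gaussians) filters on
  the thresholded saturation with one-way inhibition along the scale axis
  (larger-scale responses suppress smaller scales at the same location).
  Width and length are combined into a single log-area scale axis.

Maps are sampled on a coarse field grid (default one sample per 10
stimulus pixels) and normalized so that one rendered reference bar yields
a peak response of 1.0 in every map; architecture gains are calibrated in
those units.  The salience input is the sum over features of each map's
conspicuity (the map marginalized over its feature dimension).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

from .dnf_core import DimensionSpec

__all__ = [
    "StimulusFrame",
    "SpaceFeatureMaps",
    "SalienceInput",
    "VisionConfig",
    "extract_color",
    "extract_orientation",
    "extract_size",
    "extract_maps",
    "salience_input",
    "load_frame",
    "save_frame",
]


@dataclass
class StimulusFrame:
    """One raster RGB frame (8-bit per channel) with its trial timestamp."""

    rgb: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.uint8)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("frame must be H x W x 3")


@dataclass(frozen=True)
class VisionConfig:
    """Sampling and filter parameters of the feed-forward pathway."""

    region: tuple[int, int] = (500, 400)  # (width, height) px
    space_samples: tuple[int, int] = (50, 40)  # (nx, ny)
    hue_bins: int = 24  # 15-degree bins
    orientation_bins: int = 12  # 15-degree bins over 180
    size_levels: int = 5
    saturation_threshold: float = 0.2
    spatial_smooth_px: float = 8.0
    hue_smooth_deg: float = 12.0
    orientation_smooth_deg: float = 8.0
    orientation_sigma_long_px: float = 18.0
    orientation_sigma_short_px: float = 4.0
    size_sigma0_px: float = 6.0
    size_scale_step: float = np.sqrt(2.0)
    size_inhibition: float = 0.7
    # thresholded logistic squash applied to calibrated responses: makes
    # per-item amplitudes nearly invariant to orientation and grid phase
    # while keeping sub-peak tails suppressed
    response_saturation: float = 8.0
    response_sat_threshold: float = 0.4

    @property
    def cell_px(self) -> tuple[float, float]:
        return (
            self.region[0] / self.space_samples[0],
            self.region[1] / self.space_samples[1],
        )

    def space_dims(self) -> tuple[DimensionSpec, DimensionSpec]:
        return (
            DimensionSpec("x", (0.0, float(self.region[0])), self.space_samples[0]),
            DimensionSpec("y", (0.0, float(self.region[1])), self.space_samples[1]),
        )

    def hue_dim(self) -> DimensionSpec:
        return DimensionSpec("hue", (0.0, 360.0), self.hue_bins, circular=True)

    def orientation_dim(self) -> DimensionSpec:
        return DimensionSpec(
            "orientation", (0.0, 180.0), self.orientation_bins, circular=True
        )

    def size_dim(self) -> DimensionSpec:
        # unit spacing: level l sits exactly at coordinate l
        return DimensionSpec(
            "size", (0.0, float(self.size_levels - 1)), self.size_levels
        )


@dataclass
class SpaceFeatureMaps:
    """Non-negative feature maps over (x, y, feature); zero on background."""

    color: np.ndarray  # (nx, ny, hue_bins)
    orientation: np.ndarray  # (nx, ny, orientation_bins)
    size: np.ndarray  # (nx, ny, size_levels)
    config: VisionConfig

    def map_for(self, feature: str) -> np.ndarray:
        return getattr(self, feature)

    def dims_for(self, feature: str) -> tuple[DimensionSpec, ...]:
        x, y = self.config.space_dims()
        feat = {
            "color": self.config.hue_dim,
            "orientation": self.config.orientation_dim,
            "size": self.config.size_dim,
        }[feature]()
        return (x, y, feat)


@dataclass
class SalienceInput:
    """Summed conspicuity over features; input to the salience field."""

    grid: np.ndarray  # (nx, ny), non-negative
    dims: tuple[DimensionSpec, DimensionSpec]


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _saturation(frame: StimulusFrame):
    # hue/saturation conversion dominates frontend cost; cache per frame
    cached = getattr(frame, "_hue_sat", None)
    if cached is None:
        hsv = rgb2hsv(frame.rgb)
        cached = (hsv[..., 0] * 360.0, hsv[..., 1])
        frame._hue_sat = cached
    return cached


def _block_mean(img: np.ndarray, cfg: VisionConfig) -> np.ndarray:
    """Downsample an (H, W) pixel image to the (nx, ny) field grid."""
    nx, ny = cfg.space_samples
    h, w = img.shape
    bx, by = w // nx, h // ny
    if bx * nx != w or by * ny != h:
        raise ValueError("region size must be divisible by the grid")
    blocks = img.reshape(ny, by, nx, bx).mean(axis=(1, 3))
    return blocks.T  # (nx, ny)


def _smooth_xyf(grid: np.ndarray, cfg: VisionConfig, feat_sigma_bins: float,
                circular_feat: bool = True) -> np.ndarray:
    sx = cfg.spatial_smooth_px / cfg.cell_px[0]
    sy = cfg.spatial_smooth_px / cfg.cell_px[1]
    modes = ("constant", "constant", "wrap" if circular_feat else "constant")
    return ndimage.gaussian_filter(grid, (sx, sy, feat_sigma_bins), mode=modes)


def _oriented_kernel(angle_deg: float, s_long: float, s_short: float) -> np.ndarray:
    """Elongated Gaussian kernel (unit mass) at a bar-axis angle.

    Angle convention matches the stimulus renderer: 0 = vertical, axis
    direction (sin, cos) in (x, y) grid coordinates.
    """
    half = int(np.ceil(3.0 * max(s_long, s_short)))
    xs, ys = np.mgrid[-half:half + 1, -half:half + 1]
    theta = np.deg2rad(angle_deg)
    ax, ay = np.sin(theta), np.cos(theta)
    along = xs * ax + ys * ay
    perp = -xs * ay + ys * ax
    k = np.exp(-0.5 * ((along / s_long) ** 2 + (perp / s_short) ** 2))
    return k / k.sum()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_color(frame: StimulusFrame, cfg: VisionConfig,
                  calibrated: bool = True) -> np.ndarray:
    """Color space/feature map over (x, y, hue)."""
    hue, sat = _saturation(frame)
    nx, ny = cfg.space_samples
    nb = cfg.hue_bins
    mask = sat > cfg.saturation_threshold
    h, w = sat.shape
    bx, by = w // nx, h // ny
    ys, xs = np.mgrid[0:h, 0:w]
    cx = (xs // bx)[mask]
    cy = (ys // by)[mask]
    hb = (np.floor(hue[mask] / (360.0 / nb)).astype(int)) % nb
    out = np.zeros((nx, ny, nb))
    np.add.at(out, (cx, cy, hb), 1.0)
    out /= float(bx * by)  # coverage fraction per cell
    out = _smooth_xyf(out, cfg, cfg.hue_smooth_deg / (360.0 / nb))
    if calibrated:
        out = _saturate(out * _calibration(cfg).color, cfg)
    return out


def _orientation_channels(frame: StimulusFrame, cfg: VisionConfig
                          ) -> dict[float, np.ndarray]:
    """Opponent responses of the four oriented channels, spatially pooled."""
    _, sat = _saturation(frame)
    s = np.clip(
        (sat - cfg.saturation_threshold) / (1.0 - cfg.saturation_threshold), 0, 1
    )
    grid = _block_mean(s, cfg)
    cell = cfg.cell_px[0]
    s_long = cfg.orientation_sigma_long_px / cell
    s_short = cfg.orientation_sigma_short_px / cell
    angles = (0.0, 45.0, 90.0, 135.0)
    responses = {
        a: ndimage.convolve(grid, _oriented_kernel(a, s_long, s_short),
                            mode="constant")
        for a in angles
    }
    sp = cfg.spatial_smooth_px / cell
    out = {}
    for a in angles:
        opponent = responses[(a + 90.0) % 180.0]
        chan = np.clip(responses[a] - opponent, 0.0, None)
        out[a] = ndimage.gaussian_filter(chan, sp, mode="constant")
    # cross-channel competition: bar ends excite the diagonal channels
    # locally, so each location keeps only its dominant orientation
    stack = np.stack([out[a] for a in angles], axis=-1)
    order = np.sort(stack, axis=-1)
    runner_up = order[..., -2]
    # orientation energy only counts where the stimulus actually is: the
    # flanks of a bar otherwise read as the orthogonal orientation
    presence = np.clip(
        ndimage.gaussian_filter(grid, 4.0 / cell, mode="constant") / 0.15,
        0.0, 1.0)
    for i, a in enumerate(angles):
        out[a] = np.clip(stack[..., i] - runner_up, 0.0, None) * presence
    return out


def extract_orientation(frame: StimulusFrame, cfg: VisionConfig,
                        calibrated: bool = True) -> np.ndarray:
    """Orientation space/feature map over (x, y, orientation).

    Four oriented channels at 0/45/90/135 degrees; each channel's response
    is the positive part of the difference between its elongated filter and
    the orthogonal one, applied to thresholded saturation, and interpolated
    onto the circular 180-degree orientation axis.
    """
    channels = _orientation_channels(frame, cfg)
    nx, ny = cfg.space_samples
    nb = cfg.orientation_bins
    scales = (_calibration(cfg).orientation if calibrated
              else (1.0, 1.0, 1.0, 1.0))
    out = np.zeros((nx, ny, nb))
    for i, a in enumerate((0.0, 45.0, 90.0, 135.0)):
        out[:, :, int(round(a / (180.0 / nb))) % nb] += channels[a] * scales[i]
    out = ndimage.gaussian_filter1d(
        out, cfg.orientation_smooth_deg / (180.0 / nb), axis=2, mode="wrap"
    )
    if calibrated:
        out = _saturate(out, cfg)
    return out


def extract_size(frame: StimulusFrame, cfg: VisionConfig,
                 calibrated: bool = True) -> np.ndarray:
    """Size space/feature map over (x, y, log-size level).

    Center-surround pyramid with one-way inhibition along the scale axis:
    the response at level l is reduced by the summed responses at all
    larger levels at the same location, so each item activates the level
    matching its extent.
    """
    _, sat = _saturation(frame)
    s = np.clip(
        (sat - cfg.saturation_threshold) / (1.0 - cfg.saturation_threshold), 0, 1
    )
    grid = _block_mean(s, cfg)
    cell = cfg.cell_px[0]
    levels = []
    for lev in range(cfg.size_levels):
        sigma = cfg.size_sigma0_px * cfg.size_scale_step ** lev / cell
        center = ndimage.gaussian_filter(grid, sigma, mode="constant")
        surround = ndimage.gaussian_filter(grid, 1.6 * sigma, mode="constant")
        levels.append(np.clip(center - surround, 0.0, None))
    out = np.stack(levels, axis=2)
    for lev in range(cfg.size_levels - 2, -1, -1):
        out[:, :, lev] = np.clip(
            out[:, :, lev]
            - cfg.size_inhibition * out[:, :, lev + 1:].sum(axis=2),
            0.0,
            None,
        )
    if calibrated:
        out = _saturate(out * _calibration(cfg).size, cfg)
    return out


def _saturate(grid: np.ndarray, cfg: VisionConfig) -> np.ndarray:
    k = cfg.response_saturation
    if not k:
        return grid
    th = cfg.response_sat_threshold
    lo = 1.0 / (1.0 + np.exp(k * th))
    hi = 1.0 / (1.0 + np.exp(-k * (1.0 - th)))
    return (1.0 / (1.0 + np.exp(-k * (grid - th))) - lo) / (hi - lo)


def extract_maps(frame: StimulusFrame, cfg: VisionConfig) -> SpaceFeatureMaps:
    """Run the full feed-forward pathway on one frame."""
    return SpaceFeatureMaps(
        color=extract_color(frame, cfg),
        orientation=extract_orientation(frame, cfg),
        size=extract_size(frame, cfg),
        config=cfg,
    )


@functools.lru_cache(maxsize=8)
def _salience_ref(cfg: VisionConfig, features: tuple[str, ...]) -> float:
    """Peak conspicuity sum of one reference bar for these features."""
    maps = extract_maps(_reference_frame(0.0), cfg)
    grid = np.zeros(cfg.space_samples)
    for feature in features:
        grid += maps.map_for(feature).sum(axis=2)
    return float(max(grid.max(), 1e-12))


def salience_input(maps: SpaceFeatureMaps,
                   features: tuple[str, ...] = ("color", "orientation", "size"),
                   calibrated: bool = True) -> SalienceInput:
    """Sum of per-feature conspicuities (maps marginalized over feature),
    normalized so one item contributes a peak of ~1."""
    cfg = maps.config
    grid = np.zeros(cfg.space_samples)
    for feature in features:
        grid += maps.map_for(feature).sum(axis=2)
    if calibrated:
        grid = grid / _salience_ref(cfg, tuple(features))
    return SalienceInput(grid=grid, dims=cfg.space_dims())


# ---------------------------------------------------------------------------
# calibration: one reference bar -> peak response 1.0 in every map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Calibration:
    color: float
    orientation: tuple[float, float, float, float]  # per channel 0/45/90/135
    size: float
    salience_per_feature: float


def _reference_frame(angle: float):
    from . import stimuli  # deferred: stimuli imports StimulusFrame from here

    return stimuli.render(
        stimuli.StimulusArraySpec(
            items=[stimuli.ArrayItem(tile=12, color="red", orientation=angle)],
            target_index=0,
            condition=1,
            experiment=1,
            set_size=4,
            seed=0,
        ),
        "array",
    )


@functools.lru_cache(maxsize=8)
def _calibration(cfg: VisionConfig) -> _Calibration:
    frames = {a: _reference_frame(a) for a in (0.0, 45.0, 90.0, 135.0)}
    color_maxes = [extract_color(f, cfg, calibrated=False).max()
                   for f in frames.values()]
    c = 1.0 / max(np.mean(color_maxes), 1e-12)
    # one scale per oriented channel: the filter bank is not isotropic on
    # the coarse grid, so each channel is normalized by its own reference
    o = tuple(
        1.0 / max(_orientation_channels(frames[a], cfg)[a].max(), 1e-12)
        for a in (0.0, 45.0, 90.0, 135.0)
    )
    size_maxes = [extract_size(f, cfg, calibrated=False).max()
                  for f in frames.values()]
    z = 1.0 / max(np.mean(size_maxes), 1e-12)
    consp = extract_color(frames[0.0], cfg, calibrated=False).sum(axis=2) * c
    s = 1.0 / max(consp.max(), 1e-12)
    return _Calibration(color=c, orientation=o, size=z, salience_per_feature=s)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------


def load_frame(path, timestamp: float = 0.0) -> StimulusFrame:
    from PIL import Image

    img = np.asarray(Image.open(path).convert("RGB"))
    return StimulusFrame(rgb=img, timestamp=timestamp)


def save_frame(frame: StimulusFrame, path) -> None:
    from PIL import Image

    Image.fromarray(frame.rgb).save(path)
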