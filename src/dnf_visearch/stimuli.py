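"""Synthetic search arrays, cue presentation, and condition timelines.

Stimuli are colored oriented bars on a white background, organized in a
5 x 4 grid of 80 x 80-pixel tiles centered in a 500 x 400-pixel region.
The black-bordered middle tile of the second row is reserved for the visual
cue and never occupied by an array item.  Colors are drawn from
{red, green, blue} and orientations from {0, 45, 90, 135} degrees
(0 = vertical).

Three conditions are generated:

* condition 1 (feature search): vertical bars; one target color, all
  distractors in the other color;
* conditions 2 and 3 (conjunction search): a target with features
  ``(c_t, o_t)``; the distractors split equally between the two
  shared-feature combinations ``(c_t, o_d)`` and ``(c_d, o_t)``, plus
  exactly one distractor with the distinct conjunction ``(c_d, o_d)``
  (which keeps the distractor count odd and prevents guessing the target
  from a preview).

Condition 2 differs from condition 3 only by an 800-ms preview of the
search array before the cue appears.  Experiment 1 presents cue and array
together, continuously visible; Experiment 2 interleaves preview, cue, and
array with 100-ms blank displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .vision_frontend import StimulusFrame

__all__ = [
    "ArrayItem",
    "StimulusArraySpec",
    "TrialTimeline",
    "COLORS",
    "ORIENTATIONS",
    "CUE_TILE",
    "generate_array",
    "render",
    "tile_center",
    "timeline_for",
]

GRID_COLS = 5
GRID_ROWS = 4
TILE_PX = 80
REGION_W = 500
REGION_H = 400
_X0 = (REGION_W - GRID_COLS * TILE_PX) // 2  # 50
_Y0 = (REGION_H - GRID_ROWS * TILE_PX) // 2  # 40

#: reserved, black-bordered middle tile of the second row (row-major index)
CUE_TILE = 1 * GRID_COLS + 2

COLORS: dict[str, tuple[int, int, int]] = {
    "red": (255, 0, 0),
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
}
ORIENTATIONS: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)

VALID_SET_SIZES = (4, 6, 8, 14, 18)

BAR_LENGTH_PX = 60.0
BAR_WIDTH_PX = 12.0
CUE_BORDER_PX = 3


@dataclass(frozen=True)
class ArrayItem:
    tile: int
    color: str
    orientation: float

    @property
    def features(self) -> tuple[str, float]:
        return (self.color, self.orientation)


@dataclass
class StimulusArraySpec:
    """Symbolic description of one trial's search array and cue."""

    items: list[ArrayItem]
    target_index: int
    condition: int
    experiment: int
    set_size: int
    seed: int
    cue_tile: int = CUE_TILE

    @property
    def target(self) -> ArrayItem:
        return self.items[self.target_index]

    @property
    def cue_color(self) -> str:
        return self.target.color

    @property
    def cue_orientation(self) -> float:
        return self.target.orientation

    def item_at_tile(self, tile: int) -> ArrayItem | None:
        for item in self.items:
            if item.tile == tile:
                return item
        return None

    def to_dict(self) -> dict:
        return {
            "items": [
                {"tile": i.tile, "color": i.color, "orientation": i.orientation}
                for i in self.items
            ],
            "target_index": self.target_index,
            "condition": self.condition,
            "experiment": self.experiment,
            "set_size": self.set_size,
            "seed": self.seed,
            "cue_tile": self.cue_tile,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusArraySpec":
        return cls(
            items=[ArrayItem(i["tile"], i["color"], i["orientation"])
                   for i in d["items"]],
            target_index=d["target_index"],
            condition=d["condition"],
            experiment=d["experiment"],
            set_size=d["set_size"],
            seed=d["seed"],
            cue_tile=d.get("cue_tile", CUE_TILE),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "StimulusArraySpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class TrialTimeline:
    """Ordered display segments of one trial.

    ``segments`` is a list of ``(content, duration_ms)`` where content is
    one of ``blank``, ``preview``, ``cue``, ``array``, ``array+cue`` and a
    duration of ``None`` means "until response".  ``rt_zero_ms`` is the
    trial time at which the reaction-time clock starts (cue onset in
    Experiment 1, array onset in Experiment 2).
    """

    segments: list[tuple[str, float | None]]
    rt_zero_ms: float

    def onset_of(self, index: int) -> float:
        t = 0.0
        for content, dur in self.segments[:index]:
            t += dur
        return t


def timeline_for(experiment: int, condition: int) -> TrialTimeline:
    """The printed presentation procedure of the two experiments."""
    preview = "preview" if condition == 2 else "blank"
    if experiment == 1:
        segments = [("blank", 200.0), (preview, 800.0), ("array+cue", None)]
        return TrialTimeline(segments, rt_zero_ms=1000.0)
    if experiment == 2:
        segments = [
            ("blank", 100.0),
            (preview, 800.0),
            ("blank", 100.0),
            ("cue", 400.0),
            ("blank", 100.0),
            ("array", None),
        ]
        return TrialTimeline(segments, rt_zero_ms=1500.0)
    raise ValueError(f"unknown experiment {experiment}")


def generate_array(
    condition: int,
    set_size: int,
    seed: int,
    experiment: int = 1,
) -> StimulusArraySpec:
    """Draw one random search array under the condition's composition rules."""
    if set_size not in VALID_SET_SIZES:
        raise ValueError(f"set size {set_size} not in {VALID_SET_SIZES}")
    if condition not in (1, 2, 3):
        raise ValueError(f"unknown condition {condition}")
    rng = np.random.default_rng(seed)
    color_names = list(COLORS)
    c_t, c_d = rng.choice(color_names, size=2, replace=False)

    if condition == 1:
        # feature search: colored vertical bars
        feats = [(c_t, 0.0)] + [(c_d, 0.0)] * (set_size - 1)
    else:
        o_t, o_d = rng.choice(ORIENTATIONS, size=2, replace=False)
        n_shared = (set_size - 2) // 2
        feats = (
            [(c_t, o_t)]
            + [(c_t, o_d)] * n_shared
            + [(c_d, o_t)] * n_shared
            + [(c_d, o_d)]
        )
    assert len(feats) == set_size

    free_tiles = [t for t in range(GRID_COLS * GRID_ROWS) if t != CUE_TILE]
    tiles = rng.choice(free_tiles, size=set_size, replace=False)
    items = [ArrayItem(int(t), str(c), float(o))
             for t, (c, o) in zip(tiles, feats)]
    return StimulusArraySpec(
        items=items,
        target_index=0,
        condition=condition,
        experiment=experiment,
        set_size=set_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def tile_center(tile: int) -> tuple[float, float]:
    """Pixel coordinates (x, y) of a tile's center."""
    row, col = divmod(tile, GRID_COLS)
    return (
        _X0 + (col + 0.5) * TILE_PX,
        _Y0 + (row + 0.5) * TILE_PX,
    )


def _draw_bar(
    frame: np.ndarray,
    center: tuple[float, float],
    orientation: float,
    rgb: tuple[int, int, int],
    length: float = BAR_LENGTH_PX,
    width: float = BAR_WIDTH_PX,
) -> None:
    """Anti-aliased rotated bar, blended over the frame in place.

    Orientation is the bar-axis angle in degrees, 0 = vertical, increasing
    toward the 45-degree diagonal.
    """
    cx, cy = center
    theta = np.deg2rad(orientation)
    ax, ay = np.sin(theta), np.cos(theta)  # bar axis unit vector (px coords)
    half = int(np.ceil(length / 2 + width / 2)) + 2
    x_lo, x_hi = int(cx) - half, int(cx) + half + 1
    y_lo, y_hi = int(cy) - half, int(cy) + half + 1
    x_lo, x_hi = max(x_lo, 0), min(x_hi, frame.shape[1])
    y_lo, y_hi = max(y_lo, 0), min(y_hi, frame.shape[0])
    ys, xs = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    dx = xs + 0.5 - cx
    dy = ys + 0.5 - cy
    along = dx * ax + dy * ay
    perp = -dx * ay + dy * ax
    cov_l = np.clip(length / 2 - np.abs(along) + 0.5, 0.0, 1.0)
    cov_w = np.clip(width / 2 - np.abs(perp) + 0.5, 0.0, 1.0)
    cov = (cov_l * cov_w)[..., None]
    color = np.asarray(rgb, dtype=float)
    patch = frame[y_lo:y_hi, x_lo:x_hi].astype(float)
    frame[y_lo:y_hi, x_lo:x_hi] = np.clip(
        patch * (1.0 - cov) + color * cov, 0, 255
    ).astype(np.uint8)


def _draw_cue_border(frame: np.ndarray, tile: int) -> None:
    row, col = divmod(tile, GRID_COLS)
    x0 = _X0 + col * TILE_PX
    y0 = _Y0 + row * TILE_PX
    b = CUE_BORDER_PX
    frame[y0:y0 + TILE_PX, x0:x0 + b] = 0
    frame[y0:y0 + TILE_PX, x0 + TILE_PX - b:x0 + TILE_PX] = 0
    frame[y0:y0 + b, x0:x0 + TILE_PX] = 0
    frame[y0 + TILE_PX - b:y0 + TILE_PX, x0:x0 + TILE_PX] = 0


def render(
    spec: StimulusArraySpec,
    segment: str,
    timestamp_ms: float = 0.0,
) -> StimulusFrame:
    """Deterministic rasterization of one timeline segment.

    ``blank`` yields an all-white frame; ``preview`` and ``array`` the bars
    only; ``cue`` the cue bar in its black-bordered tile; ``array+cue``
    both.  The black border has zero saturation and is therefore invisible
    to the saturation-gated feature extraction, like the white background.
    """
    frame = np.full((REGION_H, REGION_W, 3), 255, dtype=np.uint8)
    show_items = segment in ("preview", "array", "array+cue")
    show_cue = segment in ("cue", "array+cue")
    if show_items:
        for item in spec.items:
            _draw_bar(
                frame,
                tile_center(item.tile),
                item.orientation,
                COLORS[item.color],
            )
    if show_cue:
        _draw_cue_border(frame, spec.cue_tile)
        _draw_bar(
            frame,
            tile_center(spec.cue_tile),
            spec.cue_orientation,
            COLORS[spec.cue_color],
        )
    return StimulusFrame(rgb=frame, timestamp=timestamp_ms)
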