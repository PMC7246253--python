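"""Experiment harness and capacity-model analytics.

Two closed-form serial-search models describe how working memory should
affect search times over set size ``s`` with memory capacity ``c``.  With
probability ``p = min(c/s, 1)`` the target was committed to memory during
a preview, in which case its attentional selection is immediate (one item
processed).  Otherwise the target is found by serial examination:

* guidance-only model: remaining searches examine on average ``(s + 1)/2``
  items, so the expected number processed is ``p + (1 - p)(s + 1)/2``;
* guidance-plus-inhibition model: the ``c`` memorized distractor locations
  are never examined, giving ``p + (1 - p)(s - c + 1)/2`` -- a shallower
  slope even beyond the capacity limit.

The harness simulates the visual-search experiments with the neural
architecture: per trial it generates a search array, plays the condition's
presentation timeline, measures the model reaction time (search initiation
to match detection), and fits ordinary least squares slopes of mean RT
against set size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stimuli as stim
from .config import ArchitectureConfig, experiments_config
from .scene_memory import spatial_peak_count
from .task_control import Architecture, run_trial

__all__ = [
    "CapacityModel",
    "SlopeFit",
    "TrialRecord",
    "EXPERIMENT_SET_SIZES",
    "expected_items_eq1",
    "expected_items_eq2",
    "serial_search_oracle",
    "ols_slope",
    "slope_reduction_percent",
    "run_experiment",
    "fit_slopes",
    "calibrate_capacity",
    "count_preview_retention",
]

EXPERIMENT_SET_SIZES = (4, 6, 8, 14, 18)


@dataclass(frozen=True)
class CapacityModel:
    """Capacity-limited serial search over ``s`` items with ``c`` slots."""

    set_size: int
    capacity: int

    @property
    def p(self) -> float:
        if self.set_size < 1 or self.capacity < 0:
            raise ValueError("need set_size >= 1 and capacity >= 0")
        return min(self.capacity / self.set_size, 1.0)


def expected_items_eq1(s: int, c: int) -> float:
    """Expected items processed; memory guides but does not inhibit."""
    p = CapacityModel(s, c).p
    return p + (1.0 - p) * (s + 1) / 2.0


def expected_items_eq2(s: int, c: int) -> float:
    """Expected items processed; memorized distractors are not examined."""
    p = CapacityModel(s, c).p
    return p + (1.0 - p) * (s - c + 1) / 2.0


def serial_search_oracle(
    s: int,
    c: int,
    reps: int = 100_000,
    inhibit_memorized: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo serial search: mean items examined and its standard
    error, by explicit enumeration of memory membership and search order.

    ``c`` random items are in memory.  A memorized target is found
    immediately (one item).  Otherwise the searcher examines items in
    random order; with ``inhibit_memorized`` the memorized distractors are
    skipped.
    """
    rng = rng or np.random.default_rng(0)
    c_eff = min(c, s)
    target_in_memory = rng.random(reps) < c_eff / s
    n_candidates = max(s - c_eff, 1) if inhibit_memorized else s
    positions = rng.integers(1, n_candidates + 1, size=reps)
    examined = np.where(target_in_memory, 1, positions)
    return float(examined.mean()), float(examined.std(ddof=1) / np.sqrt(reps))


def ols_slope(set_sizes, values) -> tuple[float, float]:
    """Ordinary least squares fit; returns (slope, intercept)."""
    x = np.asarray(set_sizes, dtype=float)
    y = np.asarray(values, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def slope_reduction_percent(values_with, values_without,
                            set_sizes=EXPERIMENT_SET_SIZES) -> float:
    """Percent reduction of the OLS slope of ``values_with`` relative to
    ``values_without`` over the same set sizes."""
    s_with, _ = ols_slope(set_sizes, values_with)
    s_without, _ = ols_slope(set_sizes, values_without)
    if abs(s_without) < 1e-9:
        raise ZeroDivisionError("baseline series has zero slope")
    return 100.0 * (s_without - s_with) / s_without


# ---------------------------------------------------------------------------
# architecture simulations
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    experiment: int
    condition: int
    set_size: int
    array_seed: int
    model_seed: int
    rt_ms: float | None
    selected_tile: int | None
    target_tile: int
    correct: bool
    rejections: int
    aborted: bool
    memory_items_at_search: int | None = None

    @property
    def valid(self) -> bool:
        return not self.aborted and self.rt_ms is not None and self.correct


@dataclass
class SlopeFit:
    condition: int
    slope: float  # model-ms per item
    intercept: float
    mean_rt: dict[int, float]
    sem_rt: dict[int, float]
    n_valid: dict[int, int]
    n_excluded: int


def run_experiment(
    experiment: int,
    condition: int,
    set_sizes=EXPERIMENT_SET_SIZES,
    trials_per_cell: int = 40,
    seed: int = 0,
    cfg: ArchitectureConfig | None = None,
    progress=None,
) -> tuple[list[TrialRecord], SlopeFit]:
    """Simulate one condition of one experiment and fit the RT slope.

    Stimuli, timing, and presentation follow the behavioral procedure;
    each trial runs the autonomous architecture end to end.  Aborted and
    error trials are excluded from the slope fit but reported.
    """
    cfg = cfg or experiments_config()
    # conditions share the seed stream: the same arrays and model noise
    # are replayed under each presentation procedure, so condition
    # contrasts are paired and array-level variance cancels
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(experiment,))
    base = int(ss.generate_state(1)[0] % (2 ** 28))
    records: list[TrialRecord] = []
    for s_idx, s in enumerate(set_sizes):
        for t in range(trials_per_cell):
            array_seed = base + 1000 * s_idx + t
            model_seed = base + 500_000 + 1000 * s_idx + t
            spec = stim.generate_array(condition, s, seed=array_seed,
                                       experiment=experiment)
            outcome, arch = run_trial(spec, cfg=cfg, seed=model_seed)
            started = [e for e in arch.events
                       if e["event"] == "search_started"]
            mem = None
            if started:
                tiles = started[0].get("memory_tiles", [])
                mem = sum(1 for tl in tiles if tl != spec.cue_tile)
            records.append(TrialRecord(
                experiment=experiment, condition=condition, set_size=s,
                array_seed=array_seed, model_seed=model_seed,
                rt_ms=outcome.rt_ms, selected_tile=outcome.selected_tile,
                target_tile=spec.target.tile,
                correct=outcome.selected_tile == spec.target.tile,
                rejections=outcome.rejections, aborted=outcome.aborted,
                memory_items_at_search=mem,
            ))
            if progress is not None:
                progress(records[-1])
    return records, fit_slopes(records, set_sizes)


def fit_slopes(records: list[TrialRecord],
               set_sizes=EXPERIMENT_SET_SIZES) -> SlopeFit:
    """OLS fit of per-set-size mean RT over set size (valid trials only)."""
    mean_rt, sem_rt, n_valid = {}, {}, {}
    for s in set_sizes:
        rts = [r.rt_ms for r in records if r.set_size == s and r.valid]
        n_valid[s] = len(rts)
        mean_rt[s] = float(np.mean(rts)) if rts else float("nan")
        sem_rt[s] = (float(np.std(rts, ddof=1) / np.sqrt(len(rts)))
                     if len(rts) > 1 else float("nan"))
    usable = [s for s in set_sizes if n_valid[s] > 0]
    slope, intercept = ols_slope(usable, [mean_rt[s] for s in usable])
    return SlopeFit(
        condition=records[0].condition if records else 0,
        slope=slope, intercept=intercept,
        mean_rt=mean_rt, sem_rt=sem_rt, n_valid=n_valid,
        n_excluded=sum(1 for r in records if not r.valid),
    )


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# capacity calibration and preview retention
# ---------------------------------------------------------------------------


def _commit_sequence_count(cfg: ArchitectureConfig, seed: int,
                           n_items: int = 6,
                           explore_ms: float = 3000.0) -> int:
    """Free exploration of an n-item array; number of retained locations."""
    from .task_control import reference_item_mass
    from .vision_frontend import extract_maps, salience_input

    arch = Architecture(cfg, seed=seed)
    arch.cue_tile_center = None  # no cue: pure exploration
    arch.item_salience_mass = reference_item_mass(cfg)
    rng = np.random.default_rng(seed)
    tiles = rng.choice([t for t in range(20) if t != stim.CUE_TILE],
                       size=n_items, replace=False)
    colors = rng.choice(list(stim.COLORS), size=n_items)
    oris = rng.choice(stim.ORIENTATIONS, size=n_items)
    spec = stim.StimulusArraySpec(
        items=[stim.ArrayItem(int(t), str(c), float(o))
               for t, c, o in zip(tiles, colors, oris)],
        target_index=0, condition=3, experiment=1,
        set_size=n_items if n_items in stim.VALID_SET_SIZES else 6,
        seed=seed,
    )
    maps = extract_maps(stim.render(spec, "array"), cfg.vision)
    sal = salience_input(maps, features=cfg.features).grid
    t_end = arch.t_ms + explore_ms
    while arch.t_ms < t_end:
        arch.step(maps, sal)
    return spatial_peak_count(arch.memory)


def calibrate_capacity(
    target_capacity: int = 4,
    cfg: ArchitectureConfig | None = None,
    seeds=range(10),
    lo: float = 0.02,
    hi: float = 0.6,
    iterations: int = 6,
    n_items: int = 6,
) -> tuple[float, ArchitectureConfig]:
    """Bisect the shared global-inhibition gain of the memory maps until a
    six-item exploration retains the target number of items (median count
    over seeds).  Returns the gain and a config carrying it.

    The spatial-working-memory gain is scaled by the same factor so both
    memory subsystems share one capacity limit.
    """
    cfg = cfg or experiments_config()
    base_f = cfg.f_capacity_inh
    base_swm = cfg.swm_capacity_inh

    def with_gain(gain: float) -> ArchitectureConfig:
        return cfg.replace(f_capacity_inh=gain,
                           swm_capacity_inh=base_swm * gain / base_f)

    def median_count(gain: float) -> float:
        c2 = with_gain(gain)
        counts = [_commit_sequence_count(c2, seed=s, n_items=n_items)
                  for s in seeds]
        return float(np.median(counts))

    lo_c, hi_c = median_count(lo), median_count(hi)
    if not (hi_c <= target_capacity <= lo_c):
        raise ValueError(
            f"capacity target {target_capacity} not bracketed: "
            f"gain {lo} -> {lo_c}, gain {hi} -> {hi_c}")
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        m = median_count(mid)
        if m > target_capacity:
            lo = mid
        elif m < target_capacity:
            hi = mid
        else:
            lo = hi = mid
            break
    gain = 0.5 * (lo + hi)
    return gain, with_gain(gain)


def count_preview_retention(
    cfg: ArchitectureConfig | None = None,
    set_size: int = 8,
    n_trials: int = 12,
    seed: int = 0,
) -> list[int]:
    """Number of array items retained in the memory maps at search onset
    for preview trials (the cue occupies one slot of its own)."""
    cfg = cfg or experiments_config()
    counts = []
    for k in range(n_trials):
        spec = stim.generate_array(2, set_size, seed=seed + k, experiment=1)
        outcome, arch = run_trial(spec, cfg=cfg, seed=seed + 10_000 + k)
        started = [e for e in arch.events if e["event"] == "search_started"]
        if started:
            tiles = started[0].get("memory_tiles", [])
            counts.append(sum(1 for t in tiles if t != spec.cue_tile))
    return counts
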