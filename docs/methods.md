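# Methods

## Overview

`dnf_visearch` implements a neural dynamic architecture for visual search
and its interaction with working memory, together with the synthetic
search-array experiments used to probe it and two closed-form
capacity-limited search models.  All neural state is carried by dynamic
neural fields: activation functions `u(x, t)` over labelled dimensions
(visual space in pixels, hue, orientation, a log-size index) that evolve
under the Amari dynamics

    tau * du/dt = -u + h + s(x, t) + noise
                  + integral omega(x - x') sigma(u(x')) dx'

with a logistic threshold `sigma` and a difference-of-Gaussians
interaction kernel `omega`.  Peaks of supra-threshold activation are the
units of representation; they arise and vanish in detection and reverse
detection instabilities, and the parameter regime of each field decides
whether it merely detects (self-stabilized peaks), selects (at most one
peak), or remembers (peaks outlive their inputs).

## Architecture

One trial runs a single `Architecture` object holding every field and
node, stepped with a shared explicit-Euler clock (default `dt = 3 ms`):

* **Feed-forward maps.**  Rendered frames are converted to three
  space/feature maps (hue, orientation, size) plus a spatial salience
  map (the sum of per-feature conspicuities).  Responses are calibrated
  so one stimulus bar yields a peak of 1.0, then passed through a
  thresholded logistic squash that suppresses sub-peak tails while
  making per-item amplitudes nearly invariant to orientation and grid
  phase.  Orientation uses four elongated opponent filters with
  cross-channel competition and a saturation-presence gate: without the
  gate, the flanks and ends of a bar read as the orthogonal or diagonal
  orientations.
* **Attention.**  A salience field (detection regime, one peak per item)
  feeds a spatial selection field.  The *selection landscape* — salience
  plus search guidance and instructed biases, minus inhibition-of-return,
  spatial-working-memory, and within-trial rejection traces — determines
  where attention goes next.  The race between candidate locations is
  resolved as a temperature-controlled stochastic choice over this
  landscape (a softmax via Gumbel perturbation, temperature 0.3): exact
  ties are uniform, a one-unit guidance advantage wins at long odds, and
  inhibited locations are revisited last.  The chosen location is imposed
  on the selection field, which forms its peak through the ordinary
  detection instability.  This replaces a fully emergent winner-take-all
  competition, which at the coarse simulation grid either stalemated
  between equal candidates or crushed its own winner; the stochastic race
  preserves exactly the ordering semantics the competition would have
  computed from the same quantities.  Fixations snap to tile centers so
  read-out columns do not straddle tile boundaries.
* **Transient detectors.**  Two-layer (fast/slow low-pass) detectors
  signal input onsets and offsets.  Any sufficient offset transient
  applies a global deboost to the spatial working memory field — the
  reset that makes the inhibition-of-memorized-locations effect fragile
  under intermittent presentation.  By default the inhibition-of-return
  trace resets with it (config switch `ior_reset_on_offset`): a
  persisting trace would carry visited-location inhibition across blank
  gaps and re-introduce exactly the effect the reset is meant to remove.
* **Scene working memory.**  The attended column and the attended
  feature values (read out by space/feature selection fields, max-pooled
  over the column footprint) jointly drive sustained three-dimensional
  memory maps; peaks persist after attention moves on.  Commitment
  completes when the freshly recalled memory item matches the attended
  one (condition of satisfaction of the exploration cycle).
* **Cue retention.**  An onset transient inside the (instructed,
  black-bordered) cue tile engages the retain task node; gate fields
  open and the cue's features are stored in sustained one-dimensional
  cue fields.  Retention ends when the stored cue matches the attended
  item.
* **Guided search.**  Per feature, overlap fields combine sub-threshold
  scene input (or memory input) with the cue slice; peaks appear only at
  coincidences.  Their spatial marginals feed two guidance fields whose
  resting levels are down-regulated per stored cue feature: with the
  measured per-dimension signal `s ~ 3.4`, the scene pathway's thresholds
  `B(n) = 0.35 + 1.35 n` implement the `n-1` rule (with one cued feature
  only complete matches guide; with `n > 1`, every item sharing at least
  `n-1` cued features guides), and the memory pathway's thresholds
  `B(n) = 2.4 + 0.7 n` admit only complete matches — a remembered target
  pops out.  A mismatch at the attended item (condition of
  dissatisfaction) resets attention, lays down a refractory rejection
  trace, and the search node re-engages; a complete match terminates the
  trial.  Model reaction time is the span from search initiation to the
  match event.

## Working-memory capacity

Retained items compete through a weak graded pool (each item adds a
small homogeneous inhibition), and the hard limit is a slot rule: when a
new commitment raises the retained count above the capacity (default 4),
the weakest item's reverse detection instability is resolved directly —
its activation is reset to rest.  An earlier purely graded implementation
(global inhibition proportional to total supra-threshold output,
calibrated by bisection) turned out to be numerically unreliable at this
grid resolution: three-dimensional sustained peaks sit on a narrow margin
between width collapse and expansion, so the graded pool either evicted
everything or nothing.  The slot rule preserves the functional content —
four co-sustained items, displacement of the weakest, the cue consuming
one slot — in a form that is robust across stimulus layouts.
`calibrate_capacity` retains the spec'd protocol shape (six-item
commit sequences over seeds) against the configured limit.

## Sequencing details

Discrete processing events are read off the continuous dynamics with a
few explicitly resolved races:

* the condition-of-satisfaction node is slower than the
  condition-of-dissatisfaction node and is additionally held back for a
  settle window (~200 ms) after each attentional reset, because the
  mismatch pathway is one synaptic stage longer than the match pathway;
* a fresh dwell restarts the comparison clock, so a verdict can only
  come from features read out during a single stable fixation (profiles
  read during transitions mix two items);
* commit and cue drives persist briefly (~200 ms) after their episode
  ends ("synaptic persistence"), letting sustained peaks consolidate
  when a cycle completes quickly;
* an urgency drive ramps while no selection peak exists and withdraws
  once one has consolidated, guaranteeing that every cycle ends in a
  detection instability; a cycle whose comparison cannot reach a verdict
  within 1.3 s is abandoned and restarted.

## Stimuli and experiments

The stimulus module reproduces the printed search displays: a 5 x 4 grid
of 80 x 80-px tiles in a 500 x 400-px region, bars of 60 x 12 px (a
choice; the source reports no bar geometry) in red/green/blue at
0/45/90/135 degrees, the middle tile of row two reserved for the
black-bordered cue.  Conjunction arrays split the distractors equally
between the two single-shared-feature classes plus exactly one
odd distractor sharing nothing.  Timelines follow the printed procedure:
200 ms blank, 800 ms preview-or-blank, then array-plus-cue until
response (first experiment; RT clock at cue onset), or
100/800/100/400/100 ms segments with the cue shown alone before the
array (second experiment; RT clock at array onset).

The single-feature condition is run with a color-only cue.  The stored
cue drives guidance through the resting-level normalization, and with a
two-feature cue every vertical distractor would share the (uninformative)
orientation and become a guidance candidate — single-feature search would
turn serial, contrary to both the human and the model result.  A feature
value shared by the cue and every array item carries no task information,
so the cue is reduced to its informative dimension.

The experiment harness simulates whole conditions (default 40 trials per
set-size cell, reduced in the shipped analyses), excludes aborted and
error trials as the behavioral analysis does, and fits ordinary least
squares slopes of mean model RT over set size.  The closed-form models

    E1(s, c) = p + (1 - p)(s + 1)/2,      p = min(c/s, 1)
    E2(s, c) = p + (1 - p)(s - c + 1)/2

describe guidance-only and guidance-plus-inhibition search; with three
slots their expected slope reduction is 14.9% against the no-memory
baseline and 11.6% against E1 (both are computed and reported — the
published expectation of 14.0% lies between the two and its baseline is
not recoverable from the printed description).

## Simulation scale

The experiment configuration samples space at one cell per 20 px
(25 x 20), hue in 30-degree bins, orientation in 22.5-degree bins, and
runs the color and orientation pathways (all stimuli share one size; the
size pathway is implemented and exercised at full sampling in the test
suite).  This preserves at least two bins of separation between any two
stimulus feature values.  The full configuration (one cell per 10 px,
15-degree bins, three feature dimensions) is the default for module-level
use.  The shipped analyses use 6-14 trials per cell; trial-level noise is
correspondingly larger than in the 40-trial design.

## What the synthetic experiments do and do not show

The generator emulates the printed stimulus specification exactly, so
passing tests show that the architecture reproduces the *relational*
behavioral pattern on those displays: flat single-feature search, serial
conjunction search, a preview benefit carried by two separable memory
pathways, and its disappearance under intermittent presentation.  Model
reaction times are in model-milliseconds; only slope *ratios* are
compared across conditions (intercepts fold in retention latencies that
human data attribute to motor preparation).  Nothing here speaks to
natural scenes, eye movements (a single fixed reference frame is
assumed), or human RT distributions.

## Known limitations

* Discrete event logic (eviction of the weakest memory item, comparison
  timeouts, the saccade draw) resolves instabilities at the event level
  rather than letting field dynamics carry every race; each such point
  is marked in the code.
* Sustained three-dimensional peaks are only conditionally stable:
  commitments interrupted mid-drive (for instance by a display change)
  are lost, and an item's stored feature value is quantized to the
  feature grid.
* At the experiment grid, per-item feature read-outs are reliable for
  the discrete stimulus sets used here, not for arbitrary metric
  differences.
* Error trials (aborts and wrong selections) occur at a few percent and
  are excluded from slope fits, mirroring the behavioral analysis.
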