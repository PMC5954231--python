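# Methods

## Detection model

The engine consumes a stream of fiducial-marker observations — `(marker_id,
x, y, angle, t)` with positions in normalized camera coordinates (origin
top-left, x rightward, y downward, both in [0, 1]) — and maintains one
*visibility run* per marker: the time its current unbroken visibility began
and its most recent sighting and position.  A run is unbroken while
consecutive sightings are at most `gap_tolerance` apart; the default is two
frame periods (0.133 s at the 15 Hz default sampling rate), because a real
camera drops individual frames without the garment actually leaving view.
Orientation is carried in the data model but consumed by no rule; it is
retained for forward compatibility.

All region rules (front, back, inside, right/left limb) are debounced by
the same persistence requirement: some marker of the region must have an
unbroken run of at least `persist_s` (default 2.0 s) that is still current.
This suppresses the transient wrong-region glimpses that occur whenever a
garment is picked up, folded, or swung past the camera.  A `conservative`
preset raises the window to 3.0 s, reflecting field experience that a
longer debounce can further reduce spurious detections at the cost of
latency.

The closure (velcro) rules are positional: with the four closure markers
208/209 and 211/212 paired across the shirt opening, misalignment holds
when any pairwise |ΔY| exceeds 0.05 or |ΔX| exceeds 0.18, and completion
when all four differences are within threshold.  Three numerical choices
matter here:

* **Boundary policy.** A difference exactly at a threshold satisfies
  neither printed inequality (both are strict).  Equality is assigned to
  *complete*: prompting a correction on an exactly-threshold reading is the
  worse failure mode.  With this policy the two predicates exactly
  partition every determinate input, which the test suite asserts on a
  grid including both boundaries.
* **Missing markers.** If any of the four closure markers has no recent
  position the rules are indeterminate and return `None` ("cannot
  assess"), distinct from an aligned `False`; the engine then emits
  nothing.
* **Debounce asymmetry.** Completion is a strong claim, so the shirt C
  rule additionally requires all four closure markers to pass the
  persistence test before their geometry is trusted; misalignment, which
  only triggers a corrective prompt, requires recent visibility only.
  Positions used are each marker's most recent within the gap window, not
  historical ones.

Pants completion is visibility-based: *all four* upper-front markers must
individually pass the persistence test (a universal, not existential,
quantifier — the person must be standing squarely in front of the camera
with the pants pulled up).

Partial dressing (p) fires when one limb side (front-right/front-left
marker sets for the shirt, low-right/low-left for the pants) has been
visible for at least `partial_timeout_s` (default 5.0 s) while the opposite
side has had **no sighting at all** for that long; a never-seen side counts
as absent.  The alternative, weaker reading — the opposite side visible but
not persistence-qualified — would fire p during ordinary two-sided
dressing, so the strict-absence reading is implemented.  After a p event,
another p may fire only once the opposite side has become visible and then
vanished for the timeout again; this re-arm rule prevents a p flood during
a single long stall.

Emission is edge-triggered: each label fires at the first frame its rule
transitions from unsatisfied to satisfied, with repeats inside a
`refractory_s` window (default 1.0 s) suppressed.  Events sharing a
timestamp are ordered by the fixed precedence F < B < I < R < L < A < M <
p < C purely for reproducibility; nothing downstream depends on the order
beyond determinism.  Comparisons carry a 1 µs slack so streams replayed
through the 6-decimal JSON Lines writer behave identically to in-memory
streams.

## Evaluation harness

A trial's detections are segmented into six phases by milestones computable
from the event sequence alone: phase 2 is the first R/L event, phase 4 the
first subsequent event of the opposite side, phase 6 begins at the first C
after that; phases 1, 3, and 5 are what falls between, and missing
milestones leave later phases empty.  This milestone formalization is the
operative definition of the narrative phase structure (preliminary
error/adjustment, first limb, transition, second limb, transition to
completion, completion); it is the only segmentation that needs no ground
truth.

Each condition has an expectation row per phase: *required* entries are
alternative-sets (any one member satisfies, e.g. {R, L} — either limb may
come first) and *optional* entries are acceptable but not required.  A
required set with no matching event in its phase is one *missed* entry; an
event whose label is in neither set is one *unexpected* entry.  Repeated
identical labels inside a phase satisfy a requirement once; occurrences
beyond the first are tallied in a separate `repeats` diagnostic rather
than as unexpected, since repeat chatter is a distinct phenomenon from a
wrong detection.  In the misaligned condition the acted error makes M a
required phase-5 detection; in every other shirt condition M is optional.
Aggregation reports, per condition per phase, missed counts negative and
unexpected counts positive, plus totals, in the study's table shape.
Trials lost to recording failure enter as an exclusion list, shrinking the
denominators.

The roster enumerator realizes a complete randomized block design: each
participant receives every condition exactly `repetitions` times, with the
within-participant order an independent seeded shuffle (seed derived from
the master seed and the participant index).  The reference design — 11
participants × 9 conditions × 2 repetitions — yields 110 shirt and 88
pants trials; with the four recording-loss exclusions, 194 analyzed trials
carry 2 required limb-worn detections each, i.e. 388.

## Scenario simulator

The simulator emulates what the camera pipeline would report, not body
kinematics: each condition script is a set of piecewise-constant *region
exposures* — a marker presented to the camera over an interval at an
anchored position — rendered onto the frame grid with a small bounded
random walk (steps ~N(0, 0.002), clipped to ±0.01) around the anchor.
Exposure chunks are stored per phase so every scripted exposure lies inside
its truth phase interval, while adjacent chunks of the same marker merge
into one continuous visibility run.

Default phase durations are 3–8 s per phase (about 25–30 s per trial),
chosen as realistic dressing tempo that leaves clear margins around the
2 s persistence and 5 s partial-timeout thresholds; the pants transitions
are kept under the partial timeout except in the partial condition's
deliberate stall.  The closure geometry places aligned pair members
0.05 apart in x and 0.02 in y — inside both thresholds even under the
jitter — and the misaligned script offsets one pair member by 0.10 in y,
clearly outside.  The end-of-trial stillness (default 3 s) extends the
completion phase so completion can qualify.

Two condition scripts deserve comment:

* **Shirt partial** leaves the opposite side fully absent through a long
  phase-3 stall, so p fires as that condition requires.
* **Pants partial** keeps one low-leg side visible one-sidedly for well
  over the timeout, but gives the opposite leg brief single-frame flaps
  into view every ~3 s, as a loose pant leg does while the wearer fidgets.
  Under the strict-absence reading of p, those flaps keep the 5 s absence
  clock from completing, so no p fires — matching the observed behavior
  that partial pants dressing goes unrecorded because folds and transient
  visibility defeat the rule.  The clean pants-partial trial is therefore
  distinguished from correct dressing by its timing, not by a p event.

The noise model layers documented failure modes over the clean script, all
off by default (`NoiseModel()` is noiseless; `NoiseModel.realistic()`
carries moderate magnitudes):

* per-frame dropout with probability `min(1, base + coeff × distance)`,
  the linear form standing in for the qualitative fact that markers become
  harder to recognize at range;
* whole-region fold occlusion for a phase with probability
  `fold_occlusion_p` (garment too large);
* transient back/inside glimpses as a Poisson process (rate
  `glimpse_rate_hz`, exponential durations) injected only during the
  transition phases 3 and 5, clipped short of the phase boundary so the
  debounce latency cannot push a resulting detection past it;
* too-fast donning via `dressing_speed`, which compresses all durations
  until exposures fall below the persistence window and detections
  (ultimately completion) are lost.

No quantitative dropout or glimpse rates are established for this class of
system; the magnitudes are free parameters and nothing in the acceptance
checks depends on their specific values.  Randomness discipline: one
generator per trial seeded with the trial seed; study-level seeds are
`master + trial_index`.  What the simulator does *not* model: marker pose
and perspective distortion, correlated multi-marker occlusion by hands and
hair, recognition confusions between marker IDs, and timing jitter of the
capture pipeline.  Passing the noise-free fidelity checks therefore shows
the rules and scripts are mutually consistent, not that the engine would
reach any particular accuracy on live camera data.

## Session state machine

The session FSM is a pure event-driven transition function over abstract
inputs (presence, drawer open/close, RFID removal, detections, a unitless
stress level), so a recorded log replays byte-identically.  Drawer
sequencing keeps exactly one drawer green at a time; a wrong-drawer open
triggers a redirect prompt; RFID removal from the active drawer arms the
detection context.  Corrective detections (B/I/M/p) prompt in both modes;
progress and praise prompts (R/L/A/C narration) are continuous-mode only —
the independent mode's purpose is to stay silent while things go well.
Stress is an abstract level in place of the skin-conductance hardware:
crossing the soothe threshold (default 0.5) triggers the calming
intervention once per episode, a later sample strictly above the alert
threshold (default 0.8) notifies the caregiver once, and the episode resets
when stress falls below the soothe level.  The stall detector (no
progress-class detection for `stall_s`, default 10 s, under elevated
stress, or `max_corrections` corrective prompts, default 3) issues one
motivational prompt per stall episode.  Prompts are IDs to be resolved
against a caregiver-recorded catalog; audio is out of scope.

## Problem sizes

The test suite runs each condition's fidelity check once, compares the
incremental engine against a full-rescan oracle on 200 random 1000-frame
streams, and estimates the dropout degradation curve at 100 seeds per
dropout level; the acceptance script uses 100 oracle streams of 600 frames
and 50 seeds per dropout level.  These sizes give stable zero/one outcomes
for the deterministic checks and ±0.07 sampling error on the degradation
rates, which the monotonicity conclusion survives comfortably.

## Known limitations

* The engine tracks one garment per run; simultaneous multi-garment
  tracking is out of scope.
* Pants have no front/both-limbs/misaligned labels; their completion proxy
  (upper-front visibility) cannot distinguish correctly fastened from
  merely held-up pants.
* Phase segmentation degrades when a trial produces no limb events at all:
  everything lands in phase 1 and the phase-2/4 requirements register as
  missed, which matches how such a trial should be read but cannot
  localize later errors.
* The velcro thresholds are camera-frame fractions; they implicitly assume
  a roughly constant subject-to-camera distance and would need
  recalibration for a different geometry.
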