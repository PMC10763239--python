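# Methods

This note records the modelling choices behind `ethoquartet`: what the
detector assumes, what every tunable parameter means, what the synthetic
generator does and does not emulate, and the numerical conventions that
make results reproducible.

## Event detection

### Geometry

A mouse is reduced to a two-segment polyline (nose–centre, centre–tail
base). Two animals are **in contact** when the minimum distance between
their polylines is below `contact_distance_cm`; "sniffing" proximity
(nose–nose, nose–anogenital) uses the larger `whisker_distance_cm`
threshold on point distances. Heading is the direction of the
tail-base→nose vector; heading differences live on [0°, 180°]. Side-side
contact requires the headings within `side_side_angle_deg` of parallel
(head-to-tail: of antiparallel) in addition to body contact.

None of these geometric constants is published for the tracking systems
this pipeline is modelled on, so they are explicit configuration with
defaults plausible for adult mice:

| parameter | default | unit | meaning |
|---|---|---|---|
| `fps` | 30 | Hz | frame rate |
| `speed_threshold_cm_s` | 5 | cm/s | moving vs resting |
| `contact_distance_cm` | 1.5 | cm | body–body contact |
| `whisker_distance_cm` | 2.0 | cm | sniffing proximity |
| `side_side_angle_deg` | 45 | deg | parallel/antiparallel band |
| `slope_threshold` | 0.5 | – | body slope above which a posture is rearing |
| `follow_zone_width_bl` / `length_bl` | 1 / 2 | body lengths | follow zone behind the leader |
| `jump_speed_multiplier` | 3 | – | jump = near wall ∧ speed > 3 × threshold |
| `wall_distance_cm` | 2.0 | cm | near-wall band |
| `max_gap_frames` | 0 | frames | debouncing (off by default) |
| `usv_gap_ms` | 750 | ms | USV sequence-splitting gap |
| `usv_jump_threshold_khz` | 10 | kHz | contour step counted as a jump |

A note on the speed threshold: the moving/resting split and the follow
definition use the same 5 cm/s walking threshold. Speeds are mass-centre
centred differences (forward/backward at the recording ends), which blurs
any speed-defined state boundary by at most one frame — the origin of the
±1-frame convention used when comparing detected intervals to scripted
ground truth.

### Conventions

- Frames are 0-based; intervals are inclusive on both ends; a one-frame
  event has duration 1 frame. Durations are reported in frames (the
  canonical unit) and convertible to seconds via `fps`.
- Undetected frames are materialised with `detected=False` and last-known
  coordinates, never dropped: the exclusive-event analysis needs an
  "undetected" state covering every frame. Undetected frames are
  ineligible for every event predicate (speed is undefined there).
- Event intervals are maximal runs of per-frame predicates. `max_gap_frames`
  can bridge brief interruptions; the default is no debouncing because no
  published convention exists.
- Counted group events: make group3/group4 fire when an animal previously
  alone joins a connected contact component, growing it to 3 resp. 4
  members; break contact/group3/group4 fire when a component loses a
  member and are attributed to the fastest member at the transition frame,
  ties broken by animal id (determinism).
- Approach contact: a maximal run of frames with strictly closing body
  distance and the approacher strictly faster, ending at the onset frame of
  the ensuing contact (the interval's end frame *is* the contact start).
- "Jump" is approximate by construction: 2-D poses carry no vertical cue,
  so it is wall proximity plus a high speed, both configurable.

### Dual-route verification

`ethoquartet.bruteforce` re-implements every per-frame predicate with
scalar loops and independent formulas. Tests and the calibration suite
require the vectorised detector's intervals to equal the run-length
encoding of the brute-force labels exactly on batches of simulated
recordings; scripted geometry keeps every frame a safe margin away from the
thresholds, so float-ordering differences cannot flip a predicate.

## Exclusive events and transitions

The 12 exclusive states are assigned per frame by precedence: undetected ≻
nose-nose & side-side ≻ (passive) nose-anogenital & side-side head-to-tail
≻ nose-nose ≻ nose-anogenital ≻ passive nose-anogenital ≻ side-side ≻
side-side head-to-tail ≻ other contact (any remaining contact frame) ≻
move ≻ idle. The precedence among contact labels is not published;
most-specific-first was chosen so the named combined states are reachable,
and it is a single documented constant. Combined states require both
component contacts with the *same* partner on the same frame. Follow and
train2 are deliberately excluded from the exclusive states (they are
composite movement events, not contact states).

Transition proportions divide n(A→B) by the total number of occurrences of
A, *including* a final occurrence with no successor — so a row's
proportions can sum slightly below 1. Whether the terminal occurrence
should be excluded is ambiguous; both behaviours are implemented
(`exclude_terminal=True` row-normalises exactly) and the inclusive variant
is the default. Genotype comparisons run per ordered pair of distinct
labels (132 tests), Shapiro-gated t / Mann–Whitney, Bonferroni ×132 capped
at 1, Cohen's d on the raw proportions; individuals in which the source
event never occurs are dropped from that pair, and pairs with fewer than 2
usable individuals per group or zero variance in both groups are flagged
`skipped` rather than tested.

## Selective interactions

The chance level is computed from the cage composition (same-genotype
partners / all partners), which is 1/3 for 2 wt + 2 del; it is not
hard-coded, so other compositions work. Contact time uses all per-pair
contact frames; a frame with several simultaneous partners credits each
partner a full frame (consistent with non-exclusive event semantics), with
a `fractional_multi_partner` switch for 1/k attribution — the choice is
not dictated by any published convention. Mean contact durations are
compared pairwise (same vs different genotype per focal animal) with a
gated paired t / Wilcoxon.

## USV analysis

Sequences chain consecutive USVs whose silent gap (previous offset to next
onset) is strictly below 750 ms; the gap is measured offset→onset
("separated by" read as silence), with an onset→onset switch available.
Features per contour: range = max − min; mean peak frequency = arithmetic
mean; modulations = sign changes of consecutive differences with plateaus
skipped (an inflexion is a strict rise/fall alternation); jumps =
differences exceeding 10 kHz (threshold unpublished, configurable).
Synchrony: a USV and an event are synchronous iff their time intervals
overlap; an event interval [s, e] in frames spans [s/fps, (e+1)/fps)
seconds. All synchrony metrics are pair-level because the emitter cannot
be identified during close interaction. Over non-exclusive categories the
per-USV flags may overlap (proportions need not sum to 1).

## Statistics

- **LMM**: random-intercept model per variable, genotype fixed (coded
  wt = 0, del = 1, so β is the del − wt shift), cage random, fitted by
  REML via statsmodels MixedLM. The inference on β is a Wald z test (the
  method behind reported β/SE/p is otherwise unspecified); the
  log-likelihood reported is the REML objective. Zero-variance inputs and
  vanishing random-effect variance are flagged (`singular`) rather than
  silently accepted.
- **Gates**: Shapiro–Wilk (α = 0.05) on each sample; for unpaired t
  additionally a two-sided F test of variance equality (Fisher–Snedecor).
  Constant samples count as non-normal. Parametric tests are used only
  when all gates pass; otherwise Wilcoxon signed-rank (paired/one-sample)
  or Mann–Whitney U. The chosen test is always recorded.
- **Effect size**: Cohen's d with an (n−1)-weighted pooled SD; undefined
  (NaN) when the pooled SD is zero.
- **z-score profiles**: per cage, values are centred by the cage mean and
  reduced by the cage sample SD (N−1 throughout — the small-n convention);
  the four z-scores of a quartet then sum to 0 with unit sample SD by
  construction, and the mutant animals' z-scores are tested against 0 with
  the gated one-sample machinery. Cages with zero SD are excluded with a
  warning.
- Bonferroni (×132 for transitions) is the only multiplicity correction;
  no FDR is applied anywhere else.

## Synthetic study conditions

The generator scripts events rather than letting them emerge, so ground
truth is exact by construction:

- **Arena and housing**: 50 × 50 cm arena, 2 or 4 animals, 12/12 h
  light/dark schedule (lights on 07:00), recordings nominally starting
  mid-afternoon. Quartets are 2 wt + 2 del; pairs are same-genotype.
- **Locomotion**: each animal alternates idle blocks (mean 15 s) and move
  blocks (mean 10 s, constant 9 cm/s orbit around a home point in its own
  arena quadrant). Block means are chosen as realistic mouse bout lengths;
  the 9 cm/s walking speed keeps the centred-difference half-step
  (4.5 cm/s) below the 5 cm/s threshold so block edges blur by at most one
  frame. Home-quadrant separation guarantees non-interacting animals never
  come within contact range.
- **Contacts**: pairwise bouts arrive at 2/min (pooled over pairs,
  globally exclusive) with exponential durations of mean 8 s, divided by
  `del_leave_mult` once per Del/+ member of the pair. Each bout places the
  pair in one of seven exact poses (nose-nose, nose-anogenital, side-side,
  side-side head-to-tail, the two named combinations, "other contact")
  whose geometry sits ≥ 0.15 cm / ≥ 10° inside or outside every relevant
  threshold; a ±0.02 cm coordinate jitter cannot flip any predicate.
- **Genotype effects**: `del_speed_mult` scales Del/+ moving speed;
  `del_leave_mult` scales the contact-leaving rate. Defaults are 1.0
  (no effect); recovery analyses script 1.3 and 2.0 respectively.
- **Rearing** is a body-slope excursion (0.9 vs 0.1 baseline, threshold
  0.5) during idle; **dropout** flags random frames undetected with
  last-known coordinates held.
- **USVs**: an inhomogeneous Poisson process with per-state rates
  (contact 20/min > move 4/min > idle 0.5/min, mirroring the qualitative
  call-rate ordering across contexts), lognormal durations around 80 ms,
  and piecewise-monotone contours with a known inflexion count.
- Default durations are minutes, not nights: the analyses are
  scale-invariant in the quantities tested, and desk-scale recordings keep
  the suites fast. The calibration suites use 100–1,000 replicates at
  6–8 cages, mirroring the 6–8 quartets of a realistic cohort.

What the generator does **not** emulate: biomechanically realistic gait or
posture, thigmotaxis, circadian modulation of activity within a night,
social decision-making (partner choice is uniform unless biased
explicitly), acoustic waveforms (only detected-call tables), or tracking
identity swaps. Passing tests therefore demonstrate correctness of the
*computations* on data with known structure — not that real recordings
satisfy the generator's assumptions. In particular the scripted bouts
teleport animals to the meeting pose, so the frames immediately adjacent
to bout boundaries carry unphysical speeds; all ground-truth comparisons
use the ±1-frame boundary convention, and agreement is exact elsewhere
with frame-level recall and precision ≥ 0.99.

## Calibration results the package checks about itself

`ethoquartet.calibration` (exercised by the test suite and
`scripts/acceptance.py`) verifies: type-I error of the genotype LMM on the
null phenotype generator within [0.02, 0.10] at α = 0.05 (500 replicates,
8 cages × 4 animals); near-nominal rejection of the chance-level test
under uniform partner choice (1,000 replicates of 16 animals, 250 draws
each); sign recovery of a 1.3× Del/+ speed multiplier by the distance LMM
and of a 2× contact-leave multiplier by Cohen's d on detected mean contact
durations in ≥ 90% of 100 replicates; and exact detector/brute-force
agreement on 100 random 1,000-frame scripted trajectories.

## Known limitations

- Contact geometry constants are plausible defaults, not reproductions of
  any tracking system's internal thresholds; absolute event counts on real
  data will depend on them.
- The Wald z inference for the LMM coefficient is anticonservative for
  very small cage counts (the measured type-I error of ~0.05–0.07 at
  8 cages is within the accepted band but above nominal).
- Jump detection is a 2-D proxy; rearing relies entirely on the provided
  body-slope scalar.
- The brute-force labeller is O(frames × pairs) in Python and intended
  only for verification-scale recordings.
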