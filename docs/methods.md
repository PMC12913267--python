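# Methods

This note documents the model implemented by `eyesearch`: its assumptions,
parameters, numerical choices, and the design decisions taken where the
underlying architecture left details open.

## Overview

The simulator predicts reaction times (RT) and error rates (ER) for
present/absent visual search by composing three mechanism classes on a
single serial timeline: an early-vision front end (availability +
crowding), noisy saccadic and manual motor processors, and a hard-coded
task strategy executed in 50-ms cognitive cycles. Monte-Carlo aggregation
over independent simulated trials yields condition means per
task × polarity × set size.

## Stimulus displays

Displays are a 22.5° × 22.5° field divided into a 5 × 5 grid of equal
cells (4.5° each). `set_size` objects occupy distinct uniformly chosen
cells; within a cell the object's bounding-box center is uniform subject to
a 0.25° box-to-cell-boundary margin, which constructively guarantees a
minimum 0.5° edge-to-edge separation between objects (no rejection
sampling). On positive trials one uniformly chosen distractor is replaced
by the target; in the Conjunction task at set size 3 the replacement is
constrained so that both distractor types remain represented.

Bounding boxes: digit shapes 1.5° × 2.7° (visual size, the mean of width
and height, 2.1°); bars 1° × 3.5° (size 2.25°), with the long axis along
the bar's orientation. An object's location is its bounding-box center;
eccentricity is Euclidean distance in degrees from the current eye
position.

One stated geometry is internally inconsistent — a 22.5° field cannot
contain 25 cells of 5° — so the field size is taken as authoritative and
cells are 4.5°. The crowding census (below) is insensitive to this choice.

## Availability

A property of an object is detected, independently per object, property,
and fixation, with probability

    P(detect) = Φ((s − θe) / σ),   σ = 0.5

where `s` is object size and `e` eccentricity (both degrees). `θe` is the
50% detection threshold expressed as a size, so small θ means the property
is available far into the periphery. All values of a property share its θ
(red and green are equally detectable). Undetected properties are blank.
Representative values: θ ≈ 0.1 for color (available almost everywhere in
the field), ≈ 0.2 for orientation, ≈ 0.4–0.6 for shape (nearly
foveal-only). Shape is treated as a *unitary* property (values 2, 5, or
blank): partial shape percepts match neither target nor distractor and are
therefore behaviorally equivalent to blanks, which is what a blank value
already encodes.

## Crowding

Objects whose center-to-center distance is below the Bouma critical
spacing — half the eccentricity of the object in question — crowd each
other. The directional relation (j crowds i iff `dist(i,j) < e_i/2`) is
symmetrized and its connected components form *crowding groups*. Within
each multi-object group, each property is scrambled independently: every
group member is visited once in random order and, with probability ϕ, its
current value is exchanged with that of a uniformly chosen other member.
Per group and property, the multiset of values is conserved; a group of
four objects has scrambling applied up to four times per property.

Scrambling operates on the *persistent percept*: before scrambling, the
fixation's availability sample is backed by the perceptual store, so a
remembered value can be scrambled away just like a currently available one.
This detail matters. It means unresolved blanks are *moved* between crowded
objects rather than multiplied — a not-yet-seen object can trade its blank
for a neighbor's remembered distractor value (becoming an illusory
distractor, the model's dominant miss mechanism on positive trials), while
the neighbor becomes an illusory blank and gets revisited. Two rejected
alternatives: scrambling only the raw availability sample with blank
erasure makes far-periphery blank-for-blank swaps destroy stored knowledge
(fixation counts grow by an order of magnitude and RTs become implausibly
long); scrambling the raw sample without erasure makes misses several times
too rare. Store-level scrambling produces both stable search dynamics and
the observed-magnitude miss rates with the same parameter values.

The perceptual store keeps the last non-blank value per object and
property for the whole trial (no decay: trials last a few seconds and
persistence is on the order of seconds, so a decay constant would be
unidentifiable). A scrambled-in blank erases the stored value; mere
unavailability never does. Perception is event-driven: the pipeline runs at
display onset and after each completed saccade, never within a fixation.

### Crowding census

`crowding_census` quantifies how much crowding the display geometry
produces, independent of any perceptual parameter. With the eye at the
center, the mean number of crowders per object rises from ≈ 0.11 at set
size 3 to ≈ 0.97 at set size 18; averaging instead over fixations at every
object, from ≈ 0.15 to ≈ 2.47 (values from this package's acceptance run
at 50 000 displays per set size). Set size is thus confounded with
crowding in this classic design: larger set sizes pack objects more
densely in the same field.

## Motor processors

Saccades: intended eccentricity `e` yields realized length
`~ N(0.95·e, 0.095·e)` (gain 0.95, spread 10% of the mean), truncated at
zero by resampling, and polar-angle noise with SD 1°. Undershoot is not
corrected by secondary saccades; the landing error simply changes all
subsequent eccentricities. Duration is the main-sequence function
`21 + 2.2·length` ms. Angular noise applies to saccades of every length.

Manual responses: a fixed 125 ms for either key (the response keys are
assumed to differ in a single motor feature, making present and absent
equally fast on average). With probability `SlipER` the opposite key is
pressed — an action slip that changes the response but never the timing.

## Task strategies

All strategies alternate two 50-ms phases over the perceptual store (not
the raw fixation sample):

* **Nomination**: an object is a *target* nomination if all its
  task-relevant stored values match the target; a *possible* nomination if
  a relevant value is blank; no nomination if any value definitely
  mismatches. Conjunction possibles carry a priority class — red + blank
  orientation (1), blank color + vertical (2), blank + blank (3) — color
  being the more available property is checked first.
* **Choice**: respond "present" for a target nomination; respond "absent"
  for no nominations; otherwise saccade to the closest possible nomination
  (restricted to the highest occupied priority class; distance ties broken
  uniformly at random, measured from the current, noisy eye position).

Variations:

* **Limited fixations**: once `N_em ≥ N_max` eye movements have been made
  and no target has been found, respond "absent" immediately. The guard is
  checked before every eye-movement command; because its condition
  includes "no target found", it never preempts a confirm-positive
  saccade, but it can preempt the confirm-negative check.
* **Confirm-positive**: an apparent target farther than 1° is fixated
  before responding; crowding is negligible within 1°, so the
  post-fixation percept is trusted. Without this check, Basic Search in
  the Conjunction task produces massive set-size-increasing false alarms
  from illusory targets (both properties are abundant on the display).
* **Confirm-both**: additionally, before the trial's first "absent"
  response, fixate the currently most eccentric object once and re-run
  nomination.
* **Fixed-Eye**: a single nomination/choice pass with the eyes held at
  fixation — target ⇒ present, else absent. This reproduces "pop-out"
  behavior for highly available properties with zero eye movements and
  constant RT.

With perfect perception (θ = ϕ = 0) every strategy is error-free before
slips; misses arise from illusory distractors and premature termination,
false alarms from illusory targets (prevented by confirm-positive) and
slips.

## Trial timeline

Stages are strictly serialized (the modeled strategies are sequential, so
architectural parallelism would be inert): 50 ms perceptual encoding at
onset, one 50-ms onset-detection cycle, a 100-ms strategy start-up delay
(VDelay), then nominate/choose pairs at 2 × 50 ms each; each saccade adds
its realized duration plus a 50-ms post-saccade re-encoding delay, and the
final key press adds 125 ms. Every trial satisfies, exactly,

    RT = 50 + 50 + 100 + 100·C + Σ saccade durations + 50·N_em + 125

with C decision pairs and N_em eye movements, so the no-eye-movement RT is
425 ms (near the observed flat color-search intercepts; residual device
latency is not modeled). The onset-detection cycle's placement before
VDelay is a composition choice — stage durations, not their packaging,
are the committed quantities. A trial aborts with an error if N_em exceeds
10 × set size; at the shipped presets the observed maximum is about 20 at
set size 18, so the guard is far from normal operation and exists to catch
logic errors only.

## Parameters

| Parameter | Meaning | Default / preset values |
| --- | --- | --- |
| θ (per property) | availability threshold coefficient (size/ecc) | color 0.09–0.15, orientation 0.15–0.25, shape 0.375–0.6 |
| σ | detection-function spread (deg) | 0.5, fixed |
| ϕ (per property) | scrambling probability per object per fixation | 0–0.15 |
| g, s | saccade gain, length spread | 0.95, 10% |
| angular SD | saccade direction noise (deg) | 1.0 |
| saccade duration | intercept, slope | 21 ms, 2.2 ms/deg |
| manual time | key-press time (ms) | 125 |
| SlipER | response-flip probability | 0.0015–0.032 |
| N_max | fixation limit (limited-fixations option) | 2, 3, or unlimited |
| cycle, VDelay | cognitive cycle, strategy start-up (ms) | 50, 100 |

The twelve shipped presets pair these with strategies: Shape uses Basic
Search (unlimited), Color uses Fixed-Eye, Conjunction uses Basic Search
with confirm-both and limited fixations (aggregate: θ_C = 0.11,
ϕ_C = 0.025, θ_O = 0.20, ϕ_O = 0.025, N_max = 3, SlipER = 0.014).

## Randomness and reproducibility

One master seed drives everything. `run_design` spawns an independent
child seed sequence per design cell (in cell order), so cells are
statistically independent, individually reproducible, and bit-identical
across runs with the same seed. With ϕ = 0 the scrambling stage consumes
no randomness, making availability-only runs stream-compatible with the
full pipeline.

## What the simulation does and does not emulate

The generator reproduces the published experiment's stimulus geometry,
set sizes, and trial polarities, but not its block/practice structure,
trial sequencing, or response-device latency. Observed human data are not
bundled; goodness-of-fit (r² as squared Pearson correlation, average
absolute relative error, average absolute error) is computed only against
a user-supplied CSV of condition means. Passing tests therefore show that
the *model mechanisms* reproduce the published simulation behavior — eye
movement counts, slope ratios, error-source asymmetries, census values —
not that the model fits any particular participant.

Problem sizes used by the test suite and acceptance script: 50 000
displays per set size for the census, 20 000 trials per design cell for
model runs (100 000 for the negative-trial error-source binomial test).
These give Monte-Carlo standard errors well inside the asserted
tolerances.

## Known limitations

* No microsaccades, fixational drift, corrective saccades, or saccade
  refractory dynamics.
* No texture- or pooling-based crowding model; scrambling swaps whole
  unitary property values.
* Strategies are hard-coded decision procedures, not a general
  production-rule interpreter; strategy learning is out of scope.
* The RT distribution's shape inherits the discreteness of the 50-ms
  cycle structure; only condition means and SDs are intended outputs.
* Whether a scrambling swap may pick the object itself (a no-op) is
  unspecified in the source material; self-swaps are excluded here.
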