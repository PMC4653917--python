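# Methods

## Model

The model worm is a point agent on a virtual plate whose only spatial
structure is a 1-D pH field perpendicular to a straight acidic border.
Coordinates: signed border distance *d* (mm), *d* > 0 inside the acid,
*d* = 0 on the border; headings are measured from the border normal (0° =
straight toward acid), normalized to (−180°, 180°].

Per trial:

1. Start at x ~ Uniform[`init_x_min`, `init_x_max`) (defaults [−3, −2) mm),
   y = 0, heading θ₀ drawn from the density ∝ 1 − |sin θ| on (−90°, 90°]
   by rejection sampling.
2. Every Δt the worm advances v·Δt along its heading. The pH sensor sits
   `sensor_offset` mm from the body along the heading rotated by
   ±`sensor_swing_deg`, alternating sides each step; the field value at the
   sensor's x is the sensed pH *C*.
3. Two independent Bernoulli draws with success probabilities p_r(C) and
   p_c(C) (shifted logistic functions of *C*; see README) decide the step's
   maneuver; reversal takes precedence when both succeed, so
   P(reversal) = p_r and P(curve) = p_c·(1 − p_r).
4. A curve rotates the heading by Normal(φ_c, Δφ_c) degrees toward the side
   whose sample among the two most recent (opposite swing sides) was less
   acidic; ties, and a curve on the very first step, pick a side uniformly.
   A reversal rotates by Normal(137°, 8°) toward a uniformly random side.
   Reorientations are instantaneous and in place: the model describes
   direction changes only, so path length is exactly (steps)·v·Δt.
5. After any reorientation the trial ends if cos(heading) < 0 — the worm
   now points away from the acid. The terminal maneuver, the heading and
   position immediately before the terminal reorientation (reduced to an
   encounter angle in [0°, 90°] and a signed distance), and the elapsed time
   are the trial's event record. Trials that exhaust `max_steps` (default
   10 000 ≈ 2.2 simulated hours) are flagged `step_cap` and excluded from
   statistics by default.

### Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| α_c, α_r | pH | 0.5, 0.5 | width of the curve / reversal threshold sigmoid |
| β_c, β_r | pH | 4.3, 2.7 | center (soft threshold) of each sigmoid |
| φ_c ± Δφ_c | deg | 30 ± 10 | curve reorientation magnitude |
| speed | mm/s | 0.15 | constant crawling speed |
| dt | s | 0.8 | update interval |
| sensor_offset | mm | 0.51 | sensor distance ahead of the body |
| sensor_swing_deg | deg | 30 | lateral swing of the sensor (see below) |
| reversal turn | deg | 137 ± 8 | post-reversal reorientation magnitude |
| init_x_max | mm | −2.0 | upper bound of the start interval |

The decision-parameter defaults are the optimum selected by the grid search
over the candidate lists α_c ∈ {0.125, 0.25, 0.5}, β_c ∈ {2.8, 3.3, 3.8,
4.3}, α_r ∈ {0.125, 0.25, 0.5}, β_r = β_c − {0.4, 0.8, 1.2, 1.6}, φ_c ∈
{30, 60, 80}, Δφ_c ∈ {10, 30, 60}, start bound ∈ {−3, −2, −1} mm (full
Cartesian product: 3888 combinations; `enumerate_grid` reports the count).

### Design choices that were genuinely open

* **Initial-heading reference.** The 1 − |sin θ| density is referenced to
  the border normal, making head-on approaches most frequent and
  border-parallel starts impossible. This guarantees every trial reaches
  the gradient and matches the flux-weighted geometry of crossings into a
  straight border.
* **Sensor swing.** Only the side-to-side alternation of the sensor is
  mechanistically required (it gives the two-sample comparison its lateral
  meaning for curve steering); the amplitude is unknown and exposed as
  `sensor_swing_deg` (default 30°) rather than asserted as fact.
* **Joint law of the two decisions.** Only the tie-break (reversal wins) is
  fixed by the protocol; the two Bernoulli draws are taken independent as
  the minimal assumption.
* **Termination test.** "Reoriented in a less acidic direction" is
  operationalized as a strictly negative border-normal heading component;
  an exactly border-parallel post-turn heading continues the trial.
* **Match criterion of the grid search.** The selection rule behind the
  published fit is unstated; `score_params` uses RMSE over well-populated
  choice-ratio bins plus absolute differences of the per-maneuver mean
  distances and of the overall reversal fraction, all weights 1 by default
  and configurable. Zero iff the statistics match exactly.

### Numerical conventions

* Sigmoid exponents are clipped at ±700 so extreme pH saturates to 0/1
  instead of overflowing.
* Choice-ratio bins are half-open [lo, hi), last bin [80°, 90°] closed;
  distance histogram bins are half-open and aligned to multiples of the
  0.2 mm width. Bins with fewer than 15 events are flagged and excluded
  from the Pearson correlation (computed on bin midpoints vs reversal
  ratio; two-sided p from the t transform); fewer than 3 usable bins leaves
  the correlation undefined rather than misleading.
* SDs use the n−1 denominator; the F test is two-sided with the larger
  variance in the numerator; the t test is classical Student (pooled
  variance), not Welch.
* Reproducibility: each trial's generator is seeded by (master seed, trial
  index), each grid combination by (master seed, combination index), so
  results are independent of execution order and byte-identical across
  runs. CSV floats are written with 6 significant digits.

## Study fields and problem sizes

Gradients are piecewise-linear, monotone, clamped outside their knots.
The standard assay field anchors pH 4.0 at the border with slope 0.5 pH/mm,
clamped at pH 6 (far side) and pH 3 (acid side) — the parametric stand-in
for a measured shallow gradient. Steepness comparisons use a shallow
(1 pH/mm) and a 3× steeper (3 pH/mm) field, both spanning pH 6 → 2 so both
decision centers are reachable. Cohorts are 3000 trials (the fitted-cohort
size); the grid-search recovery check uses a 24-combination subgrid at 1000
trials per combination, which separates the generating point's score from
the runner-up by a factor ≈ 4.

The synthetic event generator (for testing the statistics pipeline without
the simulator) draws encounter angles from the same flux-weighted density,
chooses reversal with probability logistic(intercept + slope·angle),
draws signed distances Normal(μ_maneuver, σ) truncated to the plate span
with μ_curve < μ_rev, and appends geometric serial-avoidance runs
(continuation probability 0.2) so the first-occurrence filter has work to
do. It emulates the statistical structure of scored behavioral tables, not
trajectories; passing tests on it validate the pipeline's arithmetic and
conventions, not any claim about real worms.

## Known limitations

* Reversals translate the worm no distance backwards; curves are single
  discrete heading jumps rather than continuous bends. Both maneuvers of
  the real worm have internal structure (long/short reversals,
  gradual/deep curves) that the model collapses to two classes.
* The recorded model distance is the position just before the terminal
  reorientation; scored real-worm tables typically record the deepest
  excursion during the maneuver. The two observables differ by up to a
  body length and are not reconciled here.
* On steep fields the model reproduces the classic spatial ordering —
  curves fire in less acidic territory than reversals, and shallower
  gradients spread events over significantly more space (F test). On very
  shallow fields the two mean distances nearly coincide (within ~0.1 mm)
  and can invert: gradual steering then completes during the long approach
  before worms ever sample reversal-threshold pH. The angle-dependent
  choice correlation (r ≥ 0.9) is robust across all steepnesses tried.
* Border drift over the course of a real assay, 2-D gradient curvature,
  slowing responses and posture mechanics are all outside the model.
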