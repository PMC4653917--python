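# acidnav

Simulation and behavioral statistics for acidic-pH avoidance navigation in
*Caenorhabditis elegans*.

When a crawling worm meets an acidic region on an agar plate it escapes with
one of two maneuvers: an abrupt **reversal** followed by a large reorientation
(klinokinesis — a biased random walk), or a gradual **curve** that steers it
away without stopping (klinotaxis — directed steering). Which maneuver a worm
picks depends on the angle at which it encounters the acid: shallow, grazing
encounters end in curves, deep head-on encounters in reversals. `acidnav`
implements the *two-distinct-threshold* explanation of this choice as a
stochastic agent-based model, together with the statistics pipeline used to
analyze avoidance-event tables and the exhaustive parameter search used to
fit the model.

## The model

The model worm moves at constant speed v = 0.15 mm/s on a plate with a 1-D
pH gradient perpendicular to a straight acidic border (pH ≈ 4.0 at the
border), updating its position every Δt = 0.8 s. A pH sensor 0.51 mm ahead
of the body, swung alternately left and right, reads the local pH *C* each
step. Two maneuvers fire stochastically per step:

    p_c(C) = 1 / (1 + exp((C − β_c)/α_c))      (curve)
    p_r(C) = 1 / (1 + exp((C − β_r)/α_r))      (reversal)

Each sigmoid is a soft pH threshold — β the center, α the width. With
β_r < β_c the curve threshold lies in *less acidic* territory than the
reversal threshold; the angle-dependent choice then needs no sensing of the
temporal pH derivative at all. A worm entering at a shallow angle completes
its escape by curving (each curve turns Normal(φ_c, Δφ_c) degrees toward the
side with the higher recent pH sample) before reaching reversal territory; a
worm entering steeply overshoots to the reversal threshold and pirouettes
(Normal(137°, 8°) reorientation, random side, reversal preferred when both
fire in one step). A trial ends when a reorientation leaves the worm heading
away from the acid; the terminal maneuver, the encounter angle, and the
signed border distance are recorded.

The published optimal parameter set (`acidnav.PUBLISHED_OPTIMUM`) is α_c = 0.5,
β_c = 4.3, α_r = 0.5, β_r = β_c − 1.6 = 2.7, φ_c = 30°, Δφ_c = 10°, with the
worm started below −2 mm from the border.

## Worked example

```python
from acidnav import (PUBLISHED_OPTIMUM, SimConfig, make_parametric_gradient,
                     run_cohort, bin_choice_ratio, distance_summary)

field = make_parametric_gradient(border_ph=4.0, slope=0.5, span=6.0,
                                 far_ph=6.0, near_ph=3.0)
cohort = run_cohort(3000, field, PUBLISHED_OPTIMUM, SimConfig(), seed=1)
s = bin_choice_ratio(cohort, width=10.0, min_count=15)
print("pearson r = %.3f, p = %.2g" % (s.pearson_r, s.p_value))
for lo, rev, cur, ratio in zip(s.bin_edges[:-1], s.reversal_count,
                               s.curve_count, s.reversal_ratio):
    print("  %2.0f deg: %4d rev %4d curve  ratio %.3f" % (lo, rev, cur, ratio))
```

prints

```
pearson r = 0.924, p = 0.00037
   0 deg:   26 rev  885 curve  ratio 0.029
  10 deg:   20 rev  806 curve  ratio 0.024
  20 deg:   31 rev  598 curve  ratio 0.049
  30 deg:   25 rev  312 curve  ratio 0.074
  40 deg:   38 rev   57 curve  ratio 0.400
  50 deg:   57 rev    3 curve  ratio 0.950
  60 deg:   53 rev    0 curve  ratio 1.000
  70 deg:   42 rev    0 curve  ratio 1.000
  80 deg:   47 rev    0 curve  ratio 1.000
```

The reversal fraction rises monotonically with the encounter angle — curves
dominate below ~40°, reversals above ~50° — and the correlation between bin
midpoint and reversal ratio is strongly positive (r = 0.92). `distance_summary`
on the same cohort gives per-maneuver histograms of the signed border
distance at which each terminal maneuver fired (0.2 mm bins, mean ± SD,
quartiles), and `compare_variances` / `compare_means` run the F and pooled-t
comparisons between conditions.

The same workflow is available from the shell:

```sh
acidnav simulate --n 3000 --seed 1 --out events.csv
acidnav analyze --events events.csv --out summary.json
acidnav synth events --n 500 --seed 1 --out synthetic_events.csv
acidnav grid-search --config cfg.json --reference summary.json --out ranking.csv
```

`grid-search` re-runs the exhaustive fit: it enumerates every combination of
the candidate parameter lists (the published lists give a 3888-point
Cartesian product), simulates a cohort per combination, and ranks
combinations by a weighted distance between their summary statistics and a
reference (binned reversal ratios, per-maneuver mean distances, overall
reversal fraction).

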