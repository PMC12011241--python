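# gaitlat

Analysis pipeline for **mediolateral head–trunk control during treadmill
gait**: from raw 3D marker trajectories to the full within-subject
statistics ladder, with a ground-truthed synthetic gait generator so every
stage is testable without any recorded data.

## The scientific problem

During walking, balance in the frontal plane is maintained by controlling
the high-mass segments — head, thorax, pelvis — relative to the base of
support, whose mediolateral extent is the **step width**. How tightly each
segment is controlled, and how repeatable that control is from stride to
stride, changes with step width (narrow vs wide base) and gait speed
(normal ≈ 4.5 km/h vs slow ≈ 2.2 km/h). This package implements the
standard quantification of that behaviour for treadmill trials recorded at
120 fps with six markers (head top, T4 spinous process, left/right PSIS,
left/right heels):

* **DIS** — per-gait-cycle mediolateral displacement of a segment,
  `DIS = max(ML) − min(ML)` over the cycle (mm);
* **%DIS** — DIS normalised by the cycle's step width,
  `%DIS = DIS / step width` (mm/mm, rendered ×100);
* **CV-%DIS** — the coefficient of variation of %DIS across seven
  consecutive cycles, `CV = SD(%DIS) / mean(%DIS) × 100` (%), the
  repeatability index of segmental control.

Gait cycles are anchored at left heel contacts, detected as local minima
of the (low-pass filtered, 4th-order Butterworth, 6 Hz) vertical heel
trajectory. Per-participant representative values (means over 7 cycles,
2 × 2 condition grid) feed repeated-measures ANOVA:

* two-way, step width × speed, for stride time and step width;
* three-way, step width × speed × body segment, for DIS, %DIS and
  CV-%DIS — with Mauchly's sphericity test and Greenhouse–Geisser
  correction for ≥2-df effects, simple-interaction and simple–simple
  main-effect decomposition after significant interactions (each simple
  effect tested against the corresponding omnibus error term),
  Benjamini–Hochberg adjustment within each decomposition tier, and paired
  segment comparisons with Cohen's d (d_av) and observed power
  (noncentral F at λ = F·df₁).

Intended users: movement scientists analysing treadmill kinematics, and
anyone needing a transparent, testable reference implementation of the
within-subject simple-effects ladder.

## Worked example

Generate a 17-participant synthetic cohort (2 × 2 conditions, 30 s trials
at 120 fps), push it through the full marker-level pipeline, and read the
three-way ANOVA for the repeatability index:

```python
import gaitlat as gl

config = gl.RunConfig(mode="synthetic", seed=7)
result = gl.run_pipeline(config, write=False)

report = result.reports["cv_pct_dis"]
print(report.omnibus[["source", "ss", "df1", "F", "p",
                      "partial_eta_sq", "glyph"]].round(3).to_string(index=False))
```

```
           source       ss  df1      F     p  partial_eta_sq glyph
               sw 3483.533    1 85.804 0.000           0.843   ***
               sp   37.624    1  1.475 0.242           0.084    ns
          segment   12.729    2  0.526 0.596           0.032    ns
          sw x sp  128.463    1  6.478 0.022           0.288     *
     sw x segment   10.271    2  0.323 0.727           0.020    ns
     sp x segment    0.403    2  0.012 0.988           0.001    ns
sw x sp x segment   30.099    2  1.277 0.293           0.074    ns
```

The step-width main effect dominates (F(1,16) = 85.8, η²ₚ = 0.84): with
this generator configuration, walking on a narrow base roughly doubles the
cycle-to-cycle variability of normalised segment sway (mean CV-%DIS 18.6 %
narrow vs 10.3 % wide), while speed and segment effects stay at noise
level — the generator jitters every segment's amplitude with the same 10 %
per-cycle CV, so only the step-width denominator differentiates
conditions. `result.parameter_table` holds the per-participant
representative values; per-cycle tables and 101-point ensemble curves are
written when `write=True`.

The same ladder runs from the shell:

```bash
gaitlat simulate --out cohort/ --n 17 --seed 7     # TRC trials + ground truth
gaitlat analyze-trials --manifest cohort/manifest.csv --out results/
gaitlat analyze-table --table params.xlsx --out results/   # statistics only
```

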