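# gestag

Kinetic modelling of plasma **1,5-anhydroglucitol (1,5-AG)** across
normal and diabetic pregnancy.

1,5-AG is an intermediate-term glycemia biomarker: the kidney filters it
freely and reabsorbs it almost completely, and plasma glucose above
~7.4 mM competitively suppresses that reabsorption, so serum 1,5-AG
falls within days of hyperglycemic excursions. In pregnancy the marker
is additionally pushed down by normal hemodynamics — GFR rises ~1.6-fold
and plasma volume expands — which has discouraged its clinical use in
gestational diabetes. `gestag` is a library (plus a thin CLI) for anyone
who wants to separate those effects quantitatively: it models plasma
1,5-AG with a two-compartment mass balance whose physiological inputs
vary with gestational week.

At frozen gestational week `w`, plasma concentration `C` obeys

```
dC/dt = f(w)·k_i/V(w) − GFR_day(w)·C·(1 − r(w, G))/V(w)
```

with input rate `k_i` (mg/day), fractional plasma mass `f(w)`, plasma
volume `V(w)`, filtration `GFR(w)` and tubular reabsorption fraction
`r(w, G)`. Individuals equilibrate in days, so the package reports the
steady state, where plasma volume cancels:

```
C*(w) = f(w)·k_i / (GFR_day(w)·(1 − r(w, G)))        [µg/mL]
```

Because `1 − r ≈ 0.0016`, tiny changes in reabsorption move the curve
severalfold — the mechanism that makes 1,5-AG glucose-sensitive.

The package provides:

* **`gestag.curves`** — the three gestational physiology curves (GFR
  quadratic, plasma-volume sigmoid, fractional-plasma-mass line), their
  evaluation with physiological-range guards, and least-squares fitting.
* **`gestag.kinetics`** — reabsorption models (glucose-only piecewise
  and a gestational extension that lets `r` decline after week 25), the
  ODE right-hand side, closed-form and ODE-integrated steady states, and
  trajectories.
* **`gestag.sensitivity`** — one-at-a-time sweeps over `k_i`, constant
  `r`, and glucose.
* **`gestag.calibrate`** — Nelder–Mead least-squares calibration of six
  model variants to week-binned 1,5-AG group means, with explicit
  structural-identifiability handling.
* **`gestag.synth`** — seeded synthetic cohorts emulating the literature
  datasets (GFR n=25, plasma volume n=69, body composition n=27, 1,5-AG
  n=543/75), for end-to-end parameter-recovery testing.
* **`gestag.io_` / `gestag.cli`** — CSV/JSON/YAML round-trip I/O, run
  manifests, and the `gestag` command (`synth`, `curves`, `simulate`,
  `calibrate`, `sweep`).

See `docs/methods.md` for assumptions, units, identifiability analysis
and limitations, and `examples/` for runnable walk-throughs.

## Worked example

```python
import numpy as np
import gestag as g

# gestational GFR peaks mid-pregnancy
week, fold = g.gfr_peak(g.GFRQuadratic())
print(f"GFR peak at week {week:.1f}, {fold:.2f}-fold over baseline")

# steady-state 1,5-AG for a normal and a diabetic pregnancy
weeks = np.arange(6.0, 39.0, 4.0)
normal = g.trajectory(weeks, g.KineticParams(k_i=5.0, glucose=5.0))
diabetic = g.trajectory(
    weeks, g.KineticParams(k_i=5.0, glucose=8.9, reabs_form="stickle")
)
print(normal.concentration.round(2))
print(diabetic.concentration.round(2))
```

prints

```
GFR peak at week 27.1, 1.57-fold over baseline
[5.08 4.24 3.6  3.08 2.66 2.29 1.96 1.66 1.36]
[1.58 1.32 1.12 0.96 0.83 0.71 0.61 0.52 0.42]
```

Normal-pregnancy 1,5-AG falls from ~5 to ~1.4 µg/mL across gestation
purely through rising GFR and shifting mass partitioning; the diabetic
curve (mean maximal glucose 8.9 mM) sits ~3× lower because glucose above
the 7.4 mM threshold cuts reabsorption from 0.9984 to 0.99486. Running
`examples/04_calibration.py` shows the calibration stage refitting a
synthetic cohort generated at the published best-fit parameters
(k_i = 5.16, a = 0.99825, b = 5.78e-5): the identifiable ratios
k_i/(1−a) = 2948.57 and b/(1−a) = 0.03303 are recovered to machine
precision with a ~1e-26 objective.

From the shell:

```sh
gestag synth --kind ag_series --n 50 --seed 7 --out ag.csv
gestag calibrate --data ag.csv --variant normal_bestfit_rtime --out fit.json
gestag sweep --parameter k_i --values 2,5 --weeks 6:38:2 --out sweep.csv
```

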