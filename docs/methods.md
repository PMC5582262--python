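# Methods

## The model

1,5-anhydroglucitol (1,5-AG) is a dietary polyol used clinically as an
intermediate-term glycemia marker: it is freely filtered by the kidney
and almost completely reabsorbed in the proximal tubule, and glucose
above a renal threshold competitively displaces it, so plasma 1,5-AG
falls within days of hyperglycemic excursions. During pregnancy the
marker is confounded by normal hemodynamic change — GFR rises ~1.6-fold,
plasma volume expands by roughly a litre — which depresses 1,5-AG even
in normoglycemic women. `gestag` implements a two-compartment
(plasma/tissue) mass balance that makes those renal and hemodynamic
effects explicit so the glycemic signal can be separated from them.

With gestational week `w` frozen, plasma concentration `C` (mg/mL)
evolves in fast time `t` (days) as

    dC/dt = f(w)·k_i/V(w) − GFR_day(w)·C·(1 − r(w, G))/V(w)

| symbol | meaning | unit | default |
|---|---|---|---|
| `k_i` | 1,5-AG input (diet + endogenous) | mg/day | 5 |
| `f(w)` | fractional plasma mass | — | −0.006·w + 0.32 |
| `V(w)` | plasma volume | mL | sigmoid, see below |
| `GFR(w)` | glomerular filtration rate | mL/min | −0.077·w² + 4.17·w + 99.04 |
| `r(w, G)` | tubular reabsorption fraction | — | see below |
| `G` | mean maximal glucose | mM | 5 (normal), 8.9 (diabetic) |

GFR is stored in mL/min and converted ×1440 inside the ODE; this is the
convention that makes the equation dimensionally consistent. Individuals
equilibrate on a time scale of days (clearance rate ≈ GFR_day·(1−r)/V ≈
0.14/day), much faster than gestational change, so the package reports
the steady state at each week:

    C*(w) = f(w)·k_i / (GFR_day(w)·(1 − r(w, G)))      [×1000 → µg/mL]

Plasma volume cancels exactly at steady state; `V(w)` only matters for
the transient, which is out of scope here (the 24–72 h recovery after
acute hyperglycemia is not modelled).

### Reabsorption

Two parameterizations:

* **Glucose-only ("stickle" form)** — `r = 0.9984` for `G ≤ 7.4 mM`,
  else `r = 1.018 − 0.0026·G`. The literature prints both 0.998 and
  0.9984 for the constant branch; 0.9984 is the default because it is
  the value the sensitivity analysis uses (the 0.998 form remains
  available through the parameters). The threshold point 7.4 mM is
  assigned to the constant branch, resolving the small discontinuity
  between the two printed branches there.
* **Gestational form** — `r = a − b·(w − 25)₊ − c·G·1{G > 7.4}` with
  defaults a = 0.9984, b = 0, c = 0.0026/mM, breakpoint week 25.
  Piecewise linear and continuous in week. Allowing `b > 0` captures the
  third-trimester decline in observed 1,5-AG that GFR, plasma volume and
  glucose together cannot explain; candidate biological mechanisms are
  deliberately not modelled.

Every evaluated `r` must lie in (0, 1); values outside raise a typed
error rather than clamping silently. The steady state errs when
`1 − r < 1e-9` (clearance vanishes).

Because `1 − r ≈ 0.0016`, the steady state has enormous leverage in `r`:
raising a constant `r` by 0.003 (0.9954 → 0.9984) multiplies `C*` by
(1−0.9954)/(1−0.9984) = 2.875 — the two-to-threefold gap between
diabetic and normal cohorts.

### Physiological curves

* GFR quadratic: vertex at −a1/(2·a2) = 27.1 weeks, 1.57-fold above the
  week-0 value with the default coefficients.
* Plasma volume sigmoid `num/(d0 + d1·e^{sign·rate·(w − t_mid)}) + offset`:
  as printed the exponent sign (+1) makes volume *decrease* with
  gestation, contradicting the rising cohort data it was fit to. The
  sign is an explicit convention flag defaulting to the printed form (so
  its large-week limit equals `offset`); flip it for physiological
  realism. The steady-state model is invariant to the choice since `V`
  cancels — a property the tests verify.
* Fractional plasma mass: the fitted-equation intercept 0.32 is the
  default (a summary table elsewhere rounds it to 0.3). Evaluation
  outside (0, 1] raises; with the default slope the line stays valid
  over the whole 0–42-week range.

The canonical time unit is weeks everywhere (day conversion happens only
inside the ODE). Quadratic and line fits are solved in closed form
(normal equations / `polyfit`); only the sigmoid is iterative
(`scipy.optimize.least_squares`), initialized at the published values by
default. R² is always 1 − SS_res/SS_tot; a perfect fit of constant data
reports R² = 1, while R² of non-degenerate constant data is a typed
error.

## Calibration

The objective is the unweighted sum of squared differences between
`C*(w)` and week-binned group means of observed 1,5-AG (µg/mL); the
source means carry SDs, but no weighting is applied because the original
workflow minimized the plain squared difference. Minimization is
derivative-free Nelder–Mead with function-value termination tolerance
1e-5 (matching the published tolerance language), box bounds enforced by
the optimizer (k_i ∈ [0.1, 50], a ∈ [0.9, 0.99999], b ∈ [0, 0.01],
c ∈ [0, 0.01], G ∈ [1, 30] — wide margins around every published value),
deterministic initialization from the variant defaults, and no random
restarts. The best-ever evaluated point is returned, so the reported
objective never exceeds the objective at the initialization, and the
recorded best-so-far history is non-increasing by construction.

### Identifiability (a structural property, not an optimizer issue)

At steady state the calibrated parameters enter only through

    k_i / ((1 − a) + b·(w − 25)₊ + c·G·1{G > 7.4}).

Hence:

* `c` and `G` appear only as the product `c·G` — `calibrate` refuses
  specs with both free.
* `(k_i, a, b)` carry an exact one-dimensional scaling ridge: only
  `k_i/(1−a)` and `b/(1−a)` are identifiable from concentration data.
* with `c` fixed, `a` and `c·G` trade off additively: only `a − c·G` is
  identifiable when both `a` and `G` are free.

Fits converge to *a* zero-gradient point on the optimal ridge; which
coordinates it reports depends on the initialization. This is likely why
the historical "best fitted" normal model reports k_i = 2.73 with
a = 0.999 — a different point on essentially the same ridge as
(5.16, 0.99825). Parameter-recovery tests therefore assert the
identifiable combinations (to ≤1e-3) plus the fixed-point property that
a fit initialized at the generating values returns them unchanged;
asserting raw coordinates from an arbitrary initialization would test
the optimizer's path, not the model.

## Sensitivity analysis

Strictly one-at-a-time sweeps over `k_i`, a constant `r` (bypassing the
reabsorption model entirely, via an override on the parameter set), and
`G` (through the glucose-only reabsorption form, matching the original
analysis). Default grids: k_i {2, 3, 4, 5} at r = 0.9984; r {0.995,
0.998, 0.9984} at k_i = 5; G {5, 7.4, 9, 11} mM at k_i = 5. A swept
value that drives `r` out of (0, 1) yields a per-value error entry and
the sweep continues. Global sensitivity indices are out of scope.

## Synthetic cohorts

The generator emulates the literature cohorts the curves were fit to, so
the full pipeline is testable without any external data:

| kind | n | visit weeks | noise SD |
|---|---|---|---|
| gfr | 25 | 0, 16, 26, 36 | 21.2 mL/min |
| plasma_volume | 69 | 0, 8, 14, 20, 26, 32, 38 | 52.3 mL |
| body_composition | 27 | 0, 11, 23, 35 | 0.12 (fraction scale) |
| ag_series | 543 normal / 75 GDM-DM | 6–38 every 2 wk | 3 µg/mL |

Sample sizes, the GFR schedule, and the three noise SDs are the source
cohorts' reported values. The plasma-volume schedule is seven equally
spaced visits (the source says "seven times in pregnancy" without
listing them); the body-composition schedule places one visit per
trimester; the 1,5-AG schedule, cohort noise and per-visit cadence are
this package's choices (the source study's schedule is unpublished).
Total body-mass gain follows a 0.3125 kg/week line (12.5 kg at term, a
typical normal pregnancy), and per-subject plasma-mass gain is the
noisy fraction times that total, so refitting the fraction line closes
the ratio→line loop exactly at zero noise.

Noise is Gaussian, independent across subjects and weeks, truncated
below at 1% of the truth value (and fractions capped at 1). Randomness
uses one `SeedSequence` per cohort spawned into per-subject substreams,
so output is bit-for-bit reproducible given the seed and per-subject
records are stable under schedule edits.

**Truncation caveat:** at the default 3 µg/mL 1,5-AG noise the true
signal is only ~1.4–5 µg/mL, so the positivity floor clips a sizeable
lower tail and biases week means — and everything fit to them — upward
by several percent to ~25% at the lowest-signal weeks. Unbiased
parameter-recovery checks therefore run at sub-truncation noise; the
bias at default noise is itself asserted as documented generator
behavior. More generally the generator has no within-subject
autocorrelation, dropout, or between-subject parameter variation, so
passing recovery tests demonstrate correctness of the estimation
machinery under the stated noise model, not robustness to real-cohort
artifacts.

## Numerical choices

* Fast-time integration: `scipy.integrate.solve_ivp` (LSODA,
  stiff-capable), rtol 1e-12 / atol 1e-16, horizon 365 days in 60-day
  chunks; steady state declared when |dC/dt|/C < 1e-9 per day. Closed
  form and integration agree to ≤1e-6 relative across weeks 6–38 for
  both normal and diabetic defaults (tested; observed agreement is
  ~1e-9).
* Week grid for trajectories must be sorted; weeks outside [0, 42]
  raise.
* Degenerate inputs raise typed errors rather than returning NaN:
  non-positive GFR, fraction outside (0, 1], r outside (0, 1),
  underdetermined fits, zero-variance R².

## Problem sizes

Tests and the acceptance script run on the scales above: 17-week
trajectory grids, cohorts of 25–543 subjects, 100-seed Monte-Carlo loops
for the curve-fit coverage checks, and single Nelder–Mead calibrations
of 2–3 free parameters (a few hundred objective evaluations each). These
sizes match the study conditions; nothing is subsampled.

## Known limitations

* GDM and pre-existing DM are pooled (the underlying physiology data
  cannot separate them), and the same GFR/volume/mass curves are used
  for normal and diabetic pregnancy.
* Point estimates only — no confidence intervals, profiles, or Bayesian
  machinery.
* The published diabetic "best fitted" values (k_i = 10.64,
  G = 6.19 mM) and the R² values of the original curve fits depend on
  digitized cohort data that was never deposited; they are covered by
  the synthetic recovery machinery, not reproduced numerically.
* Transient (non-steady-state) dynamics, fetal shunting, and tissue
  concentrations as a separate output are out of scope.
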