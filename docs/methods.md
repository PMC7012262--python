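# Methods

## The conversion identity

Consider one binary exposure and one binary disease outcome in a closed
population, with joint cell masses as in a cross-sectional 2×2 table
(rows: exposure; columns: disease). Write *m* = P(disease),
*Pd* = P(exposed | case), *Pc* = P(exposed | control),
*Pe* = P(disease | exposed), *Pn* = P(disease | unexposed). Bayes'
rule on the shared joint distribution gives

    Pe = Pd·m / (Pd·m + Pc·(1−m))
    Pn = m·(1−Pd) / (1 − Pd·m − Pc·(1−m))

`convert.cc_to_cohort` implements exactly this; `convert.cohort_to_cc`
is its exact inverse given the exposure prevalence
*q* = P(exposed) = Pd·m + Pc·(1−m). No approximation is involved at any
incidence. The rare-disease approximation is the *m* → 0 limit:
`rr_from_cc` returns the odds ratio analytically at *m* = 0 rather than
evaluating near-zero incidences numerically — the limit is exact and the
analytic branch avoids catastrophic cancellation. The leading error of
OR as an estimate of RR is m·(Pd−Pc)·(1/Pc + 1/(1−Pc)), which is why
the convergence property tests keep Pc away from the edges.

Assumptions: a closed, stationary population; the case-control study's
Pd/Pc and the population incidence m refer to the same population and
disease definition; no confounding adjustment (out of scope).

## The multifactor disease model

`multifactor.FactorModel` holds n independent binary risk factors with
frequencies f1..fn and a threshold r: disease occurs iff at least r
factors are present (a sufficient-cause rule with no interaction terms).
The canonical instance is 2-of-3 (defaults n=3, r=2): any two of three
factors together induce disease, one alone does not. All study-design
quantities are computed by exhaustive enumeration of the 2^n presence
patterns (capped at n=20, ~10^6 rows); the 2-of-3 closed forms

    fd = f1(1−f2)(1−f3)        # exposed (X1) and healthy
    fe = (1−f1)f2f3            # unexposed and diseased
    m  = f1f2 + f1f3 + f2f3 − 2 f1f2f3 = f1 − fd + fe
    Pe = 1 − (1−f2)(1−f3),  Pn = f2f3
    Pd = (f1−fd)/(f1−fd+fe), Pc = fd/(1−f1−fe+fd)

serve as the enumerator's independent oracle in the tests. The central
consistency check — converting (Pd, Pc, m) of any factor of any random
model reproduces that factor's (Pe, Pn) to 1e−10 — validates that the
conversion identity and the generative model describe the same joint
distribution.

`convert.recover_latent` inverts the observable triple: fe = m(1−Pd),
fd = Pc(1−m), f1 = Pd·m + Pc·(1−m). The solution is a convex combination
of probabilities, hence always feasible. `convert.recover_cofactors`
inverts the 2-of-3 cohort rates: f2, f3 are the roots of
t² − (Pe+Pn)t + Pn = 0, returned sorted ascending because the factor
labels are exchangeable; discriminants within 1e−12 below zero are
treated as a double root (tangency noise), anything lower is reported as
infeasible.

## The threshold analysis

`scatterlab` maps the case-control contrast x = Pd − Pc to the cohort
contrast y = Pe − Pn at fixed m. The one-parameter symmetric path
Pc = 1 − Pd (x = 2Pd − 1) runs from (−1, −1) through (0, 0) to (1, 1)
and y is strictly increasing in x along it. Two landmarks:

* **knee** — where Pe crosses 0.5; in closed form Pd = 1 − m, so
  x = 1 − 2m and y = 0.5 − m²/(m² + (1−m)²). At m = 0.05 this is
  (0.90, 0.4972); at m = 0.01, x = 0.98. A brentq-based root search
  (`knee_point_numeric`) cross-checks the closed form.
* **threshold** — the smallest x with y ≥ y_target, by brentq on the
  path (default x-tolerance 1e−9). Reaching a cohort difference of 0.5
  requires x > 0.90 / 0.98 / 0.99 at m = 0.05 / 0.01 / 0.001: for rare
  diseases, only an extreme case-control contrast implies a large cohort
  contrast.

The knee-vs-bisection cross-check solves Pd to ~1e−14 rather than the
user-facing tolerance because dy/dPd ≈ 1/(4m(1−m)) near the knee
amplifies root slack into y.

`full_scatter` evaluates the whole (Pd, Pc) grid (default spacing 0.01
for the grid, 0.001 for the path): off the symmetric path, moderate x can
already carry y > 0.5 (e.g. Pd ≈ 0.5, Pc ≈ 0.01 at m = 0.05), so the
symmetric-path landmarks are a property of that construction, not of the
plane. The grid evaluator returns NaN-masked points only at the two
degenerate corners (Pd = Pc ∈ {0, 1}), where one group is empty.

## Synthetic data

`synth` draws finite-sample studies through `numpy.random.default_rng`
(PCG64) from a single integer seed; identical inputs and seed reproduce
identical draws. Case-control draws fix the case and control group sizes
(the design's defining feature) and sample exposure binomially within
each group; cohort draws fix the exposure groups and sample disease;
population draws realise each factor as an independent Bernoulli per
individual. Default scenario sizes in the tests follow the worked
scenario (Pd = 0.95, Pc = 0.05, m = 0.05; 10^6 per group for the
sampling-consistency check, which brackets the converted RR within 5% of
the analytic 181). The generator emulates sampling noise only: no loss
to follow-up, matching, selection bias or measurement error, so a green
simulation test establishes estimator consistency under ideal sampling,
nothing about those real-world distortions.

## Numerical conventions

* All probability comparisons use absolute tolerance 1e−12 (`ATOL`);
  inputs within 1e−12 outside [0, 1] are clamped, anything further is an
  error.
* Zero denominators raise structured errors naming the degenerate margin
  or group; `odds_ratio(..., allow_infinite=True)` opts into ±inf at
  boundary frequencies for exploratory use. NaN never propagates
  silently.
* Factor indices are 1-based in public interfaces (X1, X2, X3
  convention); combination rows are bit-vectors with factor i in
  column i−1.
* CLI JSON output carries full-precision values plus a `rounded_2dp`
  mirror (round half up), since reported-value conventions differ;
  nothing internal uses the rounded values.

## Known limitations

* The conversion propagates no sampling uncertainty: converted Pe/Pn/RR
  are point transforms of point estimates (confidence intervals are out
  of scope).
* The multifactor model assumes independent factors and a pure threshold
  rule; correlated factors, dose-response and interactions are not
  modelled.
* For m ≥ 0.5 the symmetric path never reaches Pe = 0.5 with Pd ≥ Pc,
  so the knee is undefined there and `knee_point` raises.
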