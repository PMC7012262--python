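# riskbridge

Translate case-control study results into cohort study results — exactly,
not via the rare-disease approximation.

## The problem

A case-control study samples diseased people (cases) and non-diseased
people (controls) and measures how often an exposure occurs in each group:
*Pd* among cases, *Pc* among controls. A cohort study follows exposed and
unexposed people forward and measures disease incidence in each group:
*Pe* and *Pn*. The cohort measures — relative risk RR = *Pe*/*Pn* and the
absolute difference *Pe* − *Pn* — are what clinicians and epidemiologists
actually want, but cohort studies of rare diseases are slow and expensive,
so most aetiological data come from case-control designs, which only yield
the odds ratio OR = *Pd*(1 − *Pc*) / (*Pc*(1 − *Pd*)).

Given one extra number — the disease incidence *m* in the total
population — the two designs are linked exactly:

```
Pe = Pd·m / (Pc·(1−m) + Pd·m)
Pn = m·(1−Pd) / (1 − Pc·(1−m) − Pd·m)
```

At *m* = 0 the implied RR collapses to the OR (the classical rare-disease
approximation); at any real incidence the conversion is exact. The package
implements this conversion, its inverse, the multifactor disease model
(n independent binary risk factors, disease iff at least r are present)
from which it can be derived and validated, recovery of the latent model
parameters (*f1*, *fd*, *fe*) from observed (*Pd*, *Pc*, *m*), a
threshold analysis quantifying when case-control contrasts overstate
cohort contrasts, and a seeded finite-sample study simulator.

## Worked example

```python
import riskbridge as rb

# A case-control study finds the exposure in 95% of cases and 5% of
# controls; the disease affects 5% of the population.
rb.cc_to_cohort(0.95, 0.05, 0.05)   # (0.5, 0.002762430939226522)
rb.rr_from_cc(0.95, 0.05, 0.05)     # 180.99999999999983
```

The implied cohort study: exposed people have a 50% incidence, unexposed
0.28%, a relative risk of 181 — far below the odds ratio of 361 that the
case-control study alone would report.

The same numbers fall out of a 2-of-3 multifactor model, or from the shell:

```bash
$ riskbridge model --freqs 0.05,0.5,0.05 --threshold 2 --factor 1
# -> m=0.05, pe=0.525, pn=0.025, pd=0.525, pc=0.025, rr=21.0, or=43.1

$ riskbridge threshold --m 0.05 --target 0.5
# -> threshold_x=0.9010..., knee_x=0.90, knee_y=0.4972...
```

The `threshold` output says: with a 5% population incidence, the
case-control difference *Pd* − *Pc* must exceed 0.90 before the cohort
difference *Pe* − *Pn* reaches 0.5 — a large case-control contrast can
correspond to a modest cohort contrast. Other subcommands: `convert`,
`scatter` (TSV of the (Pd−Pc, Pe−Pn) curve or grid, optional PNG),
`simulate` (seeded finite-sample draws), `table` (rates/OR/RR from a 2×2
CSV with header `group,case,noncase`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch: the reference
conversion (Pe, Pn, RR at Pd=0.95, Pc=0.05, m=0.05), a cross-design
consistency sweep over random 2-of-3 factor models, the symmetric-path
thresholds and knee at m = 0.05/0.01/0.001, and a million-per-group
simulated case-control study pushed through the conversion.
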