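# metafoot

Time-resolved metabolic footprinting of microbial batch cultures.

When a heterotroph grows on a complex, dilute medium — soil solution,
spent medium, plant exudate mixtures — it takes up dozens of
low-molecular-weight substrates and releases metabolites on
overlapping schedules.  Footprinting experiments sample the
extracellular milieu over the growth curve and ask *which compounds are
used when, how fast, and how efficiently the assimilated carbon becomes
biomass*.  `metafoot` is a library and CLI for the analysis side of such
experiments, aimed at microbial ecophysiologists working with targeted
LC-MS/NMR concentration series, bulk C/N pool measurements and untargeted
feature tables.

## What it computes

**Depletion/appearance kinetics.**  Each compound's time course is fit
with the four-parameter sigmoid

```
y(x) = a / (1 + exp((x − t50)/w)) + o
```

(amplitude *a*, midpoint *t*₅₀, width *w*, offset *o*; the appearance
variant flips the exponent sign) by seeded multi-start bounded least
squares, and classified into four kinetic types: (1) change complete
before the first sample, (2) sigmoid-fittable, (3) non-sigmoidal,
(4) change after the last sample.  Fitted curves yield the **90% usage
window** `t50 ± w·ln 9` (width `2 ln(9) w`), the **maximum depletion
rate** `a/(4w)` (optionally biomass-normalised to mmol h⁻¹ g⁻¹), and
single-linkage temporal clusters of substrate use.

**Growth.**  OD600 sigmoid fits (inflection point), exponential-phase
μ_max from log-linear fitting, generation time ln 2/μ_max, and affine
OD→biomass / OD→protein conversions.

**Carbon use efficiency and budgets.**  From unfiltered vs 0.2-µm
filtered carbon pools: cumulative CUE (biomass C over assimilated C),
per-interval instantaneous CUE, the literal consecutive-sample variant
(with a warning — its denominator is respired, not assimilated, C), and
C/N budget fractions.

**NOSC.**  Nominal oxidation state of carbon from a molecular formula,
`4 − (−Z + 4n_C + n_H − 3n_N − 2n_O − 2n_S + 5n_P)/n_C`, for ranking
substrates by oxidation state / energy content.

**Untargeted feature screening.**  Strict |ln FC| > 1, *P* < 0.05,
max-intensity > 10⁷ filtering, removal of already-targeted compounds
(±0.001 *m/z*, ±30 s), direction splitting, and decreasing-vs-increasing
group comparisons (pooled t on midpoints; Wilcoxon rank-sum on windows,
both W and U conventions reported).

**Synthetic experiments.**  `metafoot.simulate` generates complete
experiments — clustered multiauxic depletion, mass-conserving pools,
logistic growth, feature tables — with known ground truth, for estimator
validation and power exploration.

## Worked example

```python
from metafoot import FitConfig, generate, paper_mimic, run_pipeline

exp = generate(paper_mimic(seed=7))          # synthetic 31-substrate batch
res = run_pipeline(exp.substrates, od=exp.od, pools=exp.pools,
                   formulas=dict(zip(exp.truth["compound"],
                                     exp.truth["formula"])),
                   fit_cfg=FitConfig(seed=9))

u = res.usage_report
print(u[u.kinetic_type == 2][["compound", "t50", "width90", "max_rate",
                              "cluster", "nosc"]].round(2).to_string(index=False))
print(f"growth inflection: {res.growth.inflection:.1f} h")
print(f"cumulative CUE (final time): {res.cue.cumulative[-1]:.3f}")
print(f"assimilated C: {res.budget['assimilated_c']:.1f} mg/L "
      f"({res.budget['fractions']['assimilated_pct_toc']}% of initial TOC)")
```

prints

```
             compound   t50  width90  max_rate  cluster  nosc
           isoleucine 16.68     4.31      0.53        2 -1.00
              leucine 16.94     2.28      4.58        2 -1.00
              proline 17.00     0.00    108.10        2 -0.40
             tyrosine 17.01     0.04     17.44        2 -0.22
           tryptophan 17.07     0.83      0.82        2 -0.18
              citrate 17.32     1.63      1.74        2  1.00
              lactate 17.94     5.13      1.90        2  0.00
            threonine 17.99     2.58      2.44        2  0.00
other reducing sugars 20.49     2.66     31.81        3  0.00
               valine 20.52     3.29     54.66        3 -0.80
              glucose 21.22     3.57     36.53        3  0.00
growth inflection: 21.0 h
cumulative CUE (final time): 0.438
assimilated C: 52.6 mg/L (28.8% of initial TOC)
```

Reading this: the 20 early (type-1) substrates — not shown — form
cluster 1; the fittable substrates fall into a tight cluster of amino and
organic acids with midpoints around 17 h and a later sugar/valine cluster
after the growth inflection.  Midpoints (`t50`, h) order substrate
preference; `width90` (h) is how long the middle 80% of usage took
(widths far below the 2-h sampling resolution, as for proline or
tyrosine here, are reported at the steep end of an unidentifiable family
— the midpoint is still reliable); `max_rate` is µM h⁻¹; `nosc` colours
substrates by oxidation state.  The cumulative CUE estimate says ~44% of
assimilated carbon ended up in biomass (this run's generator designed
0.43).

The same stages are available from the shell:

```
metafoot simulate --preset paper-mimic --seed 7 --outdir data/
metafoot fit --input data/substrates.csv --seed 9 --out fits.csv
metafoot nosc C5H11NO2          # valine  ->  NOSC=-0.80  nC=5
metafoot run --config experiment.yaml --outdir results/
```

## Layout

```
src/metafoot/
  chem.py        formulas, NOSC, carbon-mass conversions
  kinetics.py    closed-form sigmoid math: windows, rates
  fitting.py     multi-start fits, kinetic typing, batch tables
  growth.py      OD fits, mu_max, biomass/protein conversions
  cue.py         CUE estimators, C/N budgets
  features.py    untargeted screening and group comparisons
  simulate.py    synthetic experiments with ground truth
  pipeline.py    readers/writers, clustering, end-to-end run
  cli.py         `metafoot` command-line interface
```

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
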