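# Methods

`metafoot` implements the quantitative core of time-resolved metabolic
footprinting: a batch culture grows on a complex, dilute medium; the
extracellular concentrations of targeted compounds, bulk carbon and
nitrogen pools, and untargeted LC-MS features are measured over time; and
the package turns those time courses into substrate-preference kinetics,
growth parameters, carbon-use-efficiency estimates and element budgets.

## The depletion/appearance model

Substrate depletion is modelled with the four-parameter sigmoid

    y(x) = a / (1 + exp((x - t50)/w)) + o

with amplitude `a` (concentration span depleted), midpoint `t50` (h),
width `w` (h) and offset `o` (predicted final concentration).  Metabolite
appearance uses the sign-flipped exponent `-(x - t50)/w`.  Derived
quantities are closed-form:

* **90% usage window** — the interval between 10% and 90% of modelled
  utilization.  The curve passes `o + 0.9 a` at `t10 = t50 - w ln 9` and
  `o + 0.1 a` at `t90 = t50 + w ln 9`, so `width90 = 2 ln(9) w ≈ 4.394 w`,
  identically for both directions.  The 10%/90% levels are taken on the
  amplitude `a` (the utilised span); the offset is the floor and takes no
  part in the bracket.
* **maximum rate** — `|dy/dx| = (a/w) s(1-s)` peaks at `a/(4w)` at
  `x = t50`; when `t50` falls outside the observation window (default
  0-24 h, configurable) the boundary nearer `t50` carries the maximum and
  the result is flagged as clipped.  Rates divided by biomass density
  (mg dry weight/L) give mmol h⁻¹ g⁻¹ directly — the units cancel with no
  extra factor.

## Fitting and kinetic typing

The sampling design this targets is sparse — a single analysis of the
sterile medium at 0 h plus four destructive harvests (17, 19, 22, 24 h)
with three replicate flasks — so the least-squares surface is multimodal
and is attacked by seeded multi-start: 250 uniform draws (amplitude
0-2x observed span; midpoint within the sampling range ± one mean
inter-sample gap; width 0.1-10 h; offset 0-max observed) refined by
bounded trust-region least squares (constraints a ≥ 0, w > 0, o ≥ 0,
analytic Jacobian, ftol = xtol = 1e-12).  Replicates enter the loss as
independent observations; the single initial value enters once.  Ties in
residual sum of squares break toward smaller `w`, then smaller `t50`, so
results are bit-reproducible given the seed.  Iteration-capped solves
still contribute candidate optima; the converged-start count is reported.

Curves are then classified into four kinetic types, codifying what is
usually done by visual inspection:

1. **early** — the fraction of total observed change already complete at
   the first in-growth sample exceeds `early_frac` (default 0.9), or the
   fitted 90% window closes before the first sample (`t90 < t_first`).
   No usable kinetics; the observed span and floor are still reported.
2. **sigmoidal** — everything not caught by the other rules, with fit
   r² ≥ `r2_min` (default 0.9).
3. **non-sigmoidal** — flat series, non-monotone beyond `noise_tol`
   (default: a reversal larger than 10% of the span), or a poor fit.
4. **late** — change concentrated in the final interval and still
   incomplete, or fitted `t50` beyond the last sample.

Two choices here are deliberate.  Types 1, 3 (non-monotone) and 4 caught
by the data-only rules are never sent to the optimiser — they carry no
fittable kinetic information, and the near-flat residual surfaces are
exactly the ones where the optimiser wastes effort.  And the type-1 rule
uses the fitted `t90`, not `t50`: a midpoint slightly before the first
sample whose usage window reaches into the sampled period is genuinely
fittable (mid-16-hour midpoints with 17-hour first samples occur in real
designs), whereas a window that closes before sampling began is not.
Thresholds are configuration, echoed into every report header.

Temporal clusters of substrate use are assigned by single-linkage 1-D
clustering on type-2 midpoints with a gap threshold (default 1.5 h, the
smallest round value that separates midpoint groups differing by ≥ 2.4 h
while keeping sub-0.9 h neighbours together); type-1 substrates always
form the first cluster.

## Growth

OD600 curves are fit with the same machinery in the appearance direction;
the fitted `t50` is the growth inflection.  An optional anchor
pseudo-observation (e.g. the starter-culture OD) can stabilise the
baseline.  The maximum specific growth rate is the slope of ln(OD) vs
time; when no window is given, every contiguous run of ≥ 3 points is
scanned and the steepest window with r² ≥ 0.98 is chosen and reported.
Generation time is ln 2 / μ_max by identity.  OD converts to biomass and
protein by affine calibrations (defaults 343.09·OD − 5.38 mg/L and
67.19·OD + 2.78 mg BSA-eq/L); negative extrapolations below the biomass
calibration range are flagged, not clamped.

## Carbon use efficiency and budgets

With destructive sampling, biomass carbon is `unfiltered C − 0.2-µm
filtered C`.  Two cumulative estimators are implemented:

* the **literal consecutive-sample ratio** `biomass_C(t) /
  [unfiltered_C(t-1) − unfiltered_C(t)]`, whose denominator is carbon
  lost from the vessel — respired C, not assimilated C.  Under exact mass
  balance this equals CUE/(1−CUE) and exceeds 1 whenever CUE > 0.5; it is
  retained for fidelity with the published formula and always emits a
  warning.
* the **mass-balance form** `biomass_C(t) / [filtered_C(0) −
  filtered_C(t)]` — biomass over assimilated — which is the default for
  all reports.

Instantaneous CUE is Δbiomass/Δassimilated per sampling interval,
reported at the interval midpoint.  The pipeline reports two summary
estimates: the final-time cumulative CUE from replicate-mean pools
(unbiased for the end-of-experiment value) and the plateau of an
appearance-sigmoid fit to per-replicate cumulative CUE values (a
smoother; it can carry a small extrapolation bias when cumulative CUE
overshoots before settling, ~+0.007 on noise-free synthetic data).

Budget arithmetic is straightforward: percent of initial TOC assimilated
and lost, percent of assimilated C lost and in biomass (1 decimal,
rounded half away from zero); nitrogen removed minus amino-acid N and
ammonium N gives the unattributed residual, flagged when attribution
overshoots; per-substrate carbon share is `depleted µM × nC × 12.011 /
1000` over total assimilated C.

## NOSC

The nominal oxidation state of carbon of a formula C_cH_hN_nO_oS_sP_p
with charge Z is `4 − (−Z + 4c + h − 3n − 2o − 2s + 5p)/c`.  The package
convention is the neutral, fully protonated species (Z = 0), which
reproduces the reference table's printed values at two decimals for all
but three rows (citrulline, aspartate, phenylalanine print −0.80, 0.75
and −0.33 where the neutral formula gives +0.33, +1.00 and −0.44); those
three are treated as table-side anomalies in the reproduction suite, and
the formula is not adjusted to match them.  The phosphorus coefficient is
included for completeness although no compound in the reference roster
contains P.  Presentation rounds half away from zero.

## Untargeted feature screening

Feature tables in the style of an XCMS/CAMERA export are screened with
strict thresholds exactly as published — |ln(fold change)| > 1,
P < 0.05, max intensity > 10⁷ — then cleared of already-targeted
compounds by inclusive ±0.001 m/z and ±30 s windows (a 1e-12/1e-9
epsilon keeps exact boundary differences inside the window despite float
representation).  Upstream-supplied fold changes take precedence for the
direction split; otherwise the last/first mean-area ratio is used.
Decreasing and increasing type-2 features are compared with a
pooled-variance two-sample t-test on midpoints (df = n1 + n2 − 2,
structural) and a Wilcoxon rank-sum test on 90% windows.  Because the
literature mixes statistic conventions, both the rank-sum W and the
Mann-Whitney U (W = U + n1(n1+1)/2) are reported; p-values are exact by
permutation for combined n ≤ 20 without ties, else the midrank normal
approximation, with ties flagged.

## The synthetic-experiment generator

The generator produces complete experiments with known ground truth.  Its
defaults are the study conditions: 31 targeted substrates (20 early/type-1,
11 sigmoid-fittable/type-2 whose amplitudes, offsets, midpoints and widths
are the reference table's printed values), sampling at 0/17/19/22/24 h
with 3 replicate flasks, initial TOC 183.1 mg C/L, initial TN 11.3 mg
N/L, designed end-of-experiment cumulative CUE 0.43, and a targeted
roster covering 74.9% of total carbon depletion.  The published
reducing-sugar aggregate includes glucose, so the roster carries an
"other reducing sugars" hexose-equivalent pseudo-compound (amplitude =
aggregate − glucose) to avoid double-counting carbon.  Type-1 substrates
have no published kinetics; they are assigned deterministic early
midpoints (spread over 5-13 h, widths cycling 0.5/0.8/1.1 h).

Pools are built bottom-up so that mass balance is exact before noise:
summed substrate carbon depletion plus an uncharacterized-C sigmoid
(closing the roster to 100% of assimilation) gives assimilated C; biomass
C integrates a time-varying instantaneous-CUE profile — a Gaussian bump
(σ = 1.4 h) centred at 20.5 h over a baseline at 0.4 of the peak,
matching the observation that instantaneous CUE peaks at the growth
inflection and declines quickly after — scaled so cumulative CUE at 24 h
equals the designed value exactly; respired C is the difference
(non-decreasing by construction); filtered C is initial TOC minus
assimilated and unfiltered C is filtered plus biomass.  An infeasible
combination (profile exceeding 1, or assimilation exceeding initial TOC)
raises a configuration error.  OD600 derives from biomass C via a 0.5 g
C/g dry-weight fraction and the inverse biomass calibration.

Noise is multiplicative log-normal with independent replicate flasks: 5%
on compound concentrations and feature areas, 0.5% on bulk C/N pool
measurements and 1.5% on OD — bulk combustion-analyser repeatability is
far better than compound-level quantification, and the reference
experiment's pool standard errors were smaller than plotted point size.
The sterile initial medium is analysed once (a single noisy draw).

The untargeted-feature scenario generates 99 decreasing and 36 increasing
significant features (21 and 15 of them with clean sigmoid kinetics;
midpoints drawn from 17.4-19.4 h vs 20.3-21.3 h, widths 0.9-1.5 h vs
0.35-0.55 h, giving the designed ~2.4 h midpoint separation and ~3.3 h
window difference) plus decoys that each fail exactly one screening
criterion.  Early features complete their change before the first sample;
late ones have midpoints at 27-31 h so essentially no kinetic signal
falls inside the window; non-sigmoidal ones follow a peaked/V-shaped
course.  Fold changes and p-values are treated as upstream-tool outputs
and assigned, not recomputed from the simulated areas — for early/late
and irregular features the areas observed inside the window would not
reproduce them, exactly as in a real export where the upstream grouping
differs.

### What the generator does and does not emulate

It emulates the structure of the data — clustered sigmoidal depletion,
mass-conserving pools, multiauxic growth, a screened feature table — with
phenomenological kinetics.  It does not emulate mechanistic
(Monod/flux-balance) growth, compound identification, chromatographic
artefacts, batch effects, matrix-dependent ionisation, or non-log-normal
error structure.  Passing recovery tests therefore shows the estimators
are correct and well calibrated under the stated design and noise model,
not that real instruments behave this benignly.

## Numerical choices and degenerate inputs

* Widths much smaller than the inter-sample spacing are not identifiable:
  any sufficiently steep step between the same two samples fits equally
  well, and the smallest-w tie-break then reports the steep end of that
  family.  Midpoints remain accurate to the sampling resolution;
  recovery guarantees are therefore stated for t50, not w, on such
  curves.
* Flat series are typed 3 with a degenerate flag; zero amplitude has no
  usage window (error) and zero maximum rate (flagged).
* Division guards: CUE denominators ≤ 0 raise or flag as undefined per
  interval; biomass ≤ 0 is rejected for rate normalisation.
* All simulation, start-draw and fitting randomness flows from explicit
  integer seeds; identical configuration and seed give byte-identical
  tables.

## Problem sizes used in the test suite

Monte-Carlo checks run at sizes that keep the suite quick while leaving
sampling error far from the asserted margins: 200 replicate fits for
midpoint recovery (median |t50 error| < 0.3 h at 5% noise), 12 replicate
experiments for CUE-estimator calibration (mean within ±0.01 of the
designed 0.43), 100 draws for derivative identities, 1000 for the window
identity, and exhaustive enumeration (20 assignments) for the small-n
rank-sum oracle.

## Known limitations

* Only the four-parameter logistic is offered; Gompertz/Monod-type
  alternatives and formal model selection are out of scope (type 3 is a
  catch-all).
* NOSC is a bulk-formula quantity; no atom-resolved oxidation-state
  assignment.
* Substrate-specific use efficiency is not estimated; the temporal
  alignment of a substrate cluster with high instantaneous CUE does not
  identify which substrate carbon went to biomass.
* The literal consecutive-sample CUE ratio is reported only for fidelity;
  its denominator is respiration, and it should not be read as a growth
  yield.
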