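# Methods

## Allometry fitting

All fits are straight lines on log10–log10 axes.  Log base 10 is used
throughout: slopes are base-invariant, and intercepts are reported in
log10 units for direct comparison with published coefficient tables.
Lengths are stored in mm; a fit can be requested in cm, which leaves the
slope unchanged and shifts the intercept by `(1 − slope)·log10(scale)` —
this exists purely so cm-scale intercepts can be read off directly.

OLS is delegated to `scipy.stats.linregress`.  RMA (standardized major
axis) is computed from its closed form, `slope = sign(r)·sd(y)/sd(x)`,
with the line through the bivariate mean.  The RMA slope standard error is
taken equal to the OLS slope standard error (the standard SMA
large-sample result); the RMA intercept s.e. is not reported.  RMA is
undefined when `r = 0` exactly (the slope's sign is arbitrary) and this is
raised as an error rather than resolved by convention.

Residuals are vertical (`y − a − b·x`) or perpendicular
(`vertical / sqrt(1 + b²)`); both are positive above the line, and both
rank every cohort identically, so the choice affects the *scale* of
selection differentials, not which males are selected.

Group homogeneity (`compare_allometries`) is a classical least-squares
ANCOVA: nested design matrices (separate slopes and intercepts → common
slope → single line) compared by full-vs-reduced F tests, both tests
using the separate-slopes residual mean square, so the df pattern is
`(k − 1, N − 2k)`.  An RMA-specific likelihood-ratio slope test is
deliberately not implemented; with the tight correlations this package
targets (r² ≈ 0.9) the two differ negligibly, and the ANCOVA df pattern
matches the convention in the experimental literature this design comes
from.  The F construction is implemented directly from design matrices
(`numpy.linalg.lstsq`); statsmodels is used in the test suite as an
independent oracle, never as the implementation.

## Selection

Truncation selection takes the `n_select` most positive (up) or most
negative (down) residuals; control lines draw a seeded uniform random
subset.  Ties at the truncation boundary are resolved by stable sort on
`fish_id` and logged.  The selection differential is
`S = mean(selected) − mean(measured)`; the *effective* differential
`S_eff` replaces the selected mean with the mean over the sires that
actually bred.  `S_eff` is unweighted by default — the reference
definition of "effective" does not prescribe offspring weighting, and
with `~10` fry per sire the weights are nearly uniform — but
offspring-count weighting is available (`weighting="offspring"`), and the
heritability pipeline is routinely run under both.

## Response and realized heritability

Generation-level environmental shocks make absolute sizes uninformative,
so all response variables are deviations from the same-replicate,
same-generation control line: predicted gonopodium length at a reference
SL (default 22.18 mm, configurable), mean SL, and the allometric slope.
The per-regime trend test is a least-squares linear model
`deviation ~ generation + replicate + generation:replicate` with
generation continuous and sum-to-zero replicate contrasts, each term
tested by a partial (type-III-style) F; with 3 replicates × 9 generations
this yields the `(1, 21)` / `(2, 21)` df pattern.

For heritability the focal trait is each male's residual from the
*control-line* fit of his replicate and generation.  `R_t` is the trait
mean over all measured focal-line males in generation `t` (sign:
observed minus control expectation, so up lines trend positive).  The
round-`τ` effective differential is recomputed on the same trait axis
from the audit's sire ids — guaranteeing R and S share residual mode and
fit method — and `S_c,t` sums rounds with generation `< t`, since
selection among generation-`τ` males shapes generation `τ+1`; `R_1`
therefore pairs with `S_c = 0`.  Two mode bundles are exposed: vertical
residuals from least-squares control fits (default) and perpendicular
residuals from RMA control fits; both rescale R and S by the same factor
to first order, so h² estimates agree closely between them.

`h² = 2 · slope` of the R-on-S_c regression (an exact identity in the
returned estimate), the ×2 reflecting selection on sires only.  The
regression includes an intercept by default (slopes are tested against
zero, not forced through the origin); through-origin is a flag.  All
generations are used by default; generation subsetting is supported but
not the default, as the full series is the conservative choice.  The
regime-level summary is the mean of the three replicate estimates with
s.e. `sd/√3` — per-line regression s.e. understate between-line
variation.  No multiple-testing correction is applied anywhere.

## The simulator

`simsel` is an infinitesimal-model forward simulator:

```
log10 SL   = mu + g_sl + e_gen(t) + e_sl
log10 gono = alpha + beta · log10 SL + d,     d = g_d + e_d
```

`d` is the vertical-residual trait; it is expressed in males only but
transmitted by both sexes.  Offspring breeding values are midparent plus
segregation noise of variance `Va/2`.  Body size and `d` are genetically
independent by default (an optional genetic correlation exists), so
selection on `d` moves the intercept and leaves the slope untouched —
the architecture deliberately encodes the null hypothesis of slope
stability so that slope-trend tests on simulated data probe the test, not
the generator.

Defaults and their rationale:

| parameter | default | why |
|---|---|---|
| `beta`, `alpha` | 0.918, −0.409 (log10-mm; −0.491 on the cm scale) | the wild-population allometry the experiment started from |
| `sigma_log_sl` | 0.05 | ≈12% CV in SL, typical for adult male poeciliids |
| `sigma_d` | 0.0143 | chosen so founder cohorts show R² ≈ 0.91, via `R² = β²σx²/(β²σx² + σd²)` |
| `h2_sl` | 0.3 | a typical body-size heritability |
| `h2_d` | 0.3 | mid-range of the 0–0.5 band the design is meant to resolve; freely settable |
| `sigma_gen_env` | 0.02 | generation shocks of ±5% in SL, visible but not dominant; a free parameter with no measured counterpart |
| cohort sizes 129 / 96, select 40, ~30 sires, 2 dams each, ~10 fry | — | the experiment's protocol numbers |

The generation shock is drawn once per replicate×generation and shared by
that replicate's three lines — exactly the nuisance structure the
deviation-from-control response variables exist to remove.  Breeding
success is Bernoulli with `p = n_sires_expected / n_select`; fry per
successful sire are Poisson truncated at 1; each fry's dam is one of the
sire's `dams_per_sire` random virgin females; sex is Bernoulli(½); the
next measured cohort is a uniform subsample of male fry.  Every line runs
on its own substream spawned deterministically from the master seed, so
output is bit-identical for identical `(config, seed)`.

What the generator does *not* emulate: measurement error on lengths,
overlapping generations or age structure, mortality and condition
dependence, maternal effects, genotype×environment interaction, linkage
or finite-locus effects (no Bulmer-effect recovery dynamics beyond what
truncation itself induces), and any genital- or body-shape traits.
Passing recovery tests therefore show the *estimators* are consistent
under the stated genetic model, not that real data satisfy that model.

## Numerical choices and degenerate inputs

Fits require n ≥ 3 and positive lengths; zero SL variance, constant
regressors, missing control cells and rank-deficient trend designs raise
typed errors rather than returning NaNs.  F statistics clamp round-off
(an RSS difference below ~1e3·eps·‖y‖² counts as zero) so constant data
give F = 0 exactly.  Ranking ties break by `fish_id`; table writers fix
row and column order and render mm to 2 decimals, so write-then-read is
the identity up to that precision.  Morph tables flag (never drop) males
whose gonopodium is outside 10–60% of SL, and drop female rows from
male-only analyses with a logged warning.

## Problem sizes used in validation

The test suite validates parameter recovery with 200 simulated
experiments per generating heritability in {0, 0.1, 0.3, 0.5} (about
three minutes on one CPU), slope-trend stability over 20 seeded
experiments, and the selection-intensity property over 10,000 simulated
cohorts; the acceptance script uses 25 seeds for the experiment-scale
heritability runs and 50 replicates per recovery point.  These sizes give
Monte-Carlo standard errors comfortably below the tolerances asserted.
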