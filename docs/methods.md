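# Methods

## Scope and model family

`maekin` analyses one-factor-at-a-time (OFAT) screening experiments for
solid–liquid extraction: yield-vs-time curves `Y(t)` (mg analyte per g dry
matter) collected at several levels of one design variable while all others
are held fixed. The implemented models assume monotone, saturating
extraction — solute transfer into an excess of solvent, so second-order
solute–solvent kinetics collapse to an apparent (pseudo) first order — and
therefore do not describe degradation regimes where yield falls after a
peak (e.g. extreme microwave power). Such levels are excluded from model
fitting; the synthetic generator can still emit a rise-then-decay stress
curve for robustness testing (see below).

Per-curve models:

* pseudo-first-order, 2 parameters: `Y = Y_max (1 − e^{−k_m t})`.
  `Y_max` ≥ 0 (mg/g) is the asymptotic yield; `k_m` > 0 (1/s) the rate.
* delayed logistic, 3 parameters: `Y = Y_max / (1 + e^{−k_m (t − τ)})`.
  The delay `τ` (s) shifts the inflection; without it the curve would be
  pinned at half its asymptote at `t = 0`. A fitted `τ < 0` is tolerated
  but flagged as degenerate.

Family model (power or ethanol families): the separable surface
`Y(t, x) = A (1 − e^{−x/x_ref}) · logistic(t; k_m, τ)`, a saturating
design-variable factor times a shared logistic time course. The functional
form is an injectable strategy — any callable `(t, x, ref, k_m, tau) →
unit-amplitude yield` can be swapped in without touching the fitting code —
because the precise published algebra of this generalization is not
uniquely determined; the separable form is the package's canonical choice,
with the amplitude `A` treated as a nuisance scale. The three reported
parameters are `(x_ref, k_m, τ)`.

## Fitting

All fits are unweighted nonlinear least squares (no replicate variance
structure is assumed) solved with Levenberg–Marquardt
(`scipy.optimize.least_squares`, `method="lm"`). Positive parameters
(`Y_max`, `k_m`, `x_ref`) are optimized on the log scale so the solver can
move freely without proposing negative rates; `τ` is untransformed.
Defaults: gradient/step/objective tolerances 1e−10, iteration budget 500.
Budget exhaustion sets `converged=False` on the result — never a silent
success. Starting values are data-driven: asymptote at the maximum observed
yield; rate `3 / t_95` with `t_95` the first time the yield exceeds 95% of
its plateau (fallback `3 / median(t)`); delay at the first time the yield
exceeds half its plateau. An optional seeded 8-point Latin-hypercube
multistart (best objective wins; ties go to the smallest rate constant)
guards against rare bad starts; the default is the single heuristic start,
which recovers every shipped reference parameter set from noiseless curves
to machine precision. Parameter covariance comes from the Jacobian at the
optimum (`s² (JᵀJ)⁻¹`, pseudo-inverse if singular, flagged), mapped to
natural units by the delta method.

For the family model the amplitude is profiled out by variable projection:
at every nonlinear iteration `A* = (mᵀy)/(mᵀm)` for the unit-amplitude
surface `m`, clipped at zero. A test verifies that re-solving `A` in closed
form at the optimum moves the pooled objective by less than 1e−12.

Goodness of fit is `Y_RMS / Y_max`: root-mean-square residual divided by
the **fitted asymptote** (not the observed maximum — the asymptote is a
model parameter reported alongside the indicator, and the ratio stays
scale-invariant). For the family fit the denominator is the maximum fitted
yield over all retained (level, time) cells, read as a single scalar per
fit.

Identifiability caveat: when the level range covers only a small fraction
of `x_ref`, the saturation factor `1 − e^{−x/x_ref}` is nearly linear in
`x` and only the product `A/x_ref` is well determined; on data that do not
actually follow the separable surface the optimizer may legitimately push
`x_ref` very large (its linear limit) while predictions stay finite. The
reported covariance and the pooled goodness indicator expose this.

## Factorial screening statistics

The design produces a balanced factor × extraction-time grid with one
observation per cell (replicates are averaged first). The two-way ANOVA
therefore uses the residual (interaction) mean square as the error term:
for `a` levels and `b` times, effect df are `a−1` and `b−1`, error df
`(a−1)(b−1)` — the layout implied by the published error df (120 = 5×24
for six levels × 25 times; 144 = 6×24 for seven levels). With balanced
data Type III and Type I sums of squares coincide, so main-effect SS are
plain row/column mean contrasts, and an unbalanced grid is rejected
outright rather than silently reweighted. The extraction-time grid is the
25-point set {1, 5, 10, …, 120} s — the unique reading of a "1–120 s every
5 s" grid consistent with time df 24. Significance is declared at
`p < α = 0.05` (a published statement to the contrary is read as a
typographical slip, consistent with the tables' own α = 0.05 footnote).
`anova_from_ss` builds the same table directly from known SS/df pairs — the
entry point for reproducing published tables whose raw data exist only as
figures.

Observed power follows the standard statistics-package convention:
noncentrality `λ = df_effect · F`, power
`P[F′(df1, df2, λ) > F_crit(α, df1, df2)]` via `scipy.stats.ncf`. At
`λ = 0` this equals α exactly.

The Student–Newman–Keuls ranking sorts level means descending and tests
spans of size `r` against `q(α, r, df_err) √(MS_err/n)`
(`scipy.stats.studentized_range`, cached — the quantile is expensive).
The step-down non-testing rule is enforced by processing spans largest
first and never testing a span inside an accepted (homogeneous) one;
accepted spans become the homogeneous subsets, and uncovered means become
singletons. A zero error mean square degenerates to grouping exactly equal
means. Equal means are ordered stably, so the ranking is deterministic.

## DPPH assay

Inhibition is `100 (A_ctrl − A_sample)/A_ctrl` (absorbance at 517 nm);
negative values (pro-oxidant artifacts) are returned as-is with a warning.
IC50 defaults to linear interpolation of inhibition against
log10(concentration) between the bracketing pair — assumption-light, exact
when a point hits 50% — with a bounded four-parameter-logistic refit behind
`method="4pl"` for smooth curves. A missing bracket raises an error naming
the failing side. IC50 depends only on inhibition percentages, hence is
invariant to uniform rescaling of all absorbances.

## Synthetic data

The generator emulates the OFAT design: 25-point time grid; power levels
{250, 350, 450, 500, 550} W; ethanol {50…100} % v/v; pre-leach
{1, 5, …, 30} min; truth curves taken verbatim from the shipped
per-condition reference fits (`data/reference_parameters.csv`, both model
families). Noise is additive homoscedastic Gaussian, default sd 0.01 mg/g,
truncated below zero; the default was chosen once so that refitted
goodness indicators land in the published ~0.02 range, and the truncation
bias is negligible (< 1e−4 mg/g) because all default yields sit far above
the noise scale. Proportional (heteroscedastic) noise is available by
flag. One RNG stream, seeded explicitly, drives a whole dataset; the seed
is recorded in run output.

What the generator does **not** emulate: the real replicate structure and
measurement-error magnitude (unpublished), within-run drift, correlated
residuals, and the chemistry behind the yields. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated noise model, not robustness to every feature of bench data. The
optional 900 W level is a synthetic stress fixture (logistic rise times
exponential decay past 50 s) for exercising exclusion logic and is excluded
from model validation by default.

One reference-table oddity is shipped as printed: the 250 W delayed-logistic
row lists identical `Y_max` and `k_m` values, almost certainly a
typesetting duplication in the source table; it is kept verbatim because
the fixture's contract is fidelity to the published numbers, and round-trip
recovery works regardless.

## Problem sizes and numerical checks

The test suite and `scripts/acceptance.py` use: noiseless round trips over
all 36 reference rows; 200 noisy replicates at the 550 W truth for
stochastic recovery (median relative parameter error < 5%, mean indicator
within [0.01, 0.04]); 2,000 null 5×25 grids for the type-I error of the
main-effect test (target [0.04, 0.06] at α = 0.05); 10⁶ Monte-Carlo draws
for the noncentral-F power cross-check (agreement within 3 standard
errors); 100 simulated screens for the SNK top-level hit rate; and
exhaustive grid-search / double-sum / all-pairs brute-force oracles on
small cases. These sizes were chosen as the package's own verification
design and keep the whole suite under a minute on one CPU.

## Known limitations

* The kinetic models cannot represent yield degradation; levels showing it
  must be excluded (the power factor's default exclusion) rather than fit.
* The family model's `x_ref` is weakly identified when the level range is
  far below it (see the identifiability caveat).
* ANOVA requires a complete balanced grid; missing cells are an error, not
  an imputation target.
* IC50 interpolation requires the 50% crossing to be observed in-range;
  extrapolation is deliberately refused.
* No bootstrap or profile-likelihood uncertainty for kinetic parameters;
  the Jacobian-based covariance is asymptotic.
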