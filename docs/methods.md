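# Methods

## Model and assumptions

The package evaluates decision trees in the standard health-economic form:
a root decision among strategies, chance nodes whose branch probabilities
are expressions over named parameters (a reference, a product of
references, or one complement `1 − Σ siblings` per node), and terminal
nodes whose payoff is a linear combination of cost parameters (with
integer multipliers, e.g. two catheters on a re-insertion pathway) plus a
single state utility. Rollback is exact expected value; `enumerate_paths`
provides the same quantity as an explicit sum over root-to-leaf paths and
is used as the independent oracle in the tests (agreement within 1e-9 on
randomly generated trees up to depth 6 and branching 4).

No discounting is applied anywhere: the bundled analysis has a 90-day
horizon, and utilities are defined directly on that 90-day scale (the
published arm values 0.73/0.68 are treated as 90-day QALY numbers, not
annual utilities rescaled by 90/365.25), so the QALY accounting matches
the published one. All computation is carried in RMB at full double
precision; USD conversion (RMB 678.03 = USD 100) and 2-decimal rounding
(half away from zero) happen only at reporting boundaries, so rounding
error never compounds through the model.

## The bundled PICC model: what is data, what is assumption, what is calibrated

Derived from published trial counts:

- second puncture: 1/113 (AGBA), 3/111 (standard) — beta(x, n−x)
  uncertainty, Wilson 95% OWSA ranges;
- CLABSI: 0/113 vs 3/111 — the zero cell uses the Jeffreys point estimate
  (x+½)/(n+1) ≈ 0.00439 so the PSA beta/Dirichlet block is proper;
- unknown fever: 36 cases in 224 patients, pooled to the same per-arm rate
  because the per-arm split was not published; the split is an argument of
  `build_picc_model`, and the default is flagged in the metadata rather
  than presented as a trial result.

Package assumptions (values the source publication does not itemize), all
recorded in model metadata and freely overridable in the JSON model file:

- local-complication rate 0.05 per arm;
- resolution split 0.70 / 0.25 / 0.05 (no removal / removal / worsened),
  shared across arms and complication types, Dirichlet with effective
  sample size 20;
- per-category cost means: laboratory 800, inpatient care 12,000,
  follow-up 1,000, maintenance 1,500, insertion fee 400 per catheter,
  catheter device 2,500 (coated) / 1,600 (standard), complication
  treatment 15,000 (CLABSI) / 2,500 (fever) / 1,500 (local), escalation
  8,000 on worsened pathways — plausible tertiary-hospital price-list
  magnitudes in RMB;
- utility decrements 0.05 / 0.10 / 0.30 below the complication-free state,
  fixing the ordering complication-free > resolved-without-removal >
  resolved-with-removal > worsened.

Calibrated per arm (solved analytically in the builder, labelled in the
metadata as a check of fixture construction, not independent validation):
the residual "other treatments" cost mean (686.00 AGBA / 3537.11
standard) and the complication-free utility level (0.7461 / 0.6978), so
that base-case rollback reproduces the published per-patient means
19,696.23 / 21,987.32 RMB and 0.73 / 0.68 QALYs exactly. Because every
terminal includes the residual category once and exactly one utility, the
calibration is a one-step linear solve. The published QALY-distribution
narrative swaps the two arms' means relative to its own summary figures;
this model follows the summary figures (AGBA 0.73, standard 0.68) and the
report notes the discrepancy rather than resolving it.

The published incremental figures are partially inconsistent with their
own arithmetic: the printed ICER 4271.31 RMB/QALY is not 2291.10/0.05
(= 45,822.00), the printed USD saving 428.44 is not the conversion of RMB
2291.10 (= 337.91), and the threshold 113,120 RMB is printed with two
different USD values (16,884 and 16,683.63; the conversion gives the
latter). The package computes the self-consistent arithmetic and surfaces
every printed figure verbatim in the `reported_figures` metadata block and
the written report. It never silently picks a side.

## Probabilistic sensitivity analysis

Distribution families follow conventional CEA practice since the source
publication states none: beta for standalone probabilities
(method-of-moments from trial counts), gamma for costs (shape 1/CV²,
CV 0.3 by default), Dirichlet for multinomial branch sets with
concentrations equal to base probability × arm size (so every draw lies on
the simplex and the mean equals the base value), utilities held fixed
unless given a distribution. All distributions are mean-centred on base
values by construction, so PSA means converge on the base case (asserted
within 3 Monte Carlo standard errors at n = 10⁴).

One `numpy.random.Generator` per run, seeded by the caller; parameter
draws consume the stream in declaration order (a Dirichlet block is drawn
once, at its first member), making results independent of tree traversal
order. Each iteration re-runs the same recursive rollback used for the
base case — deliberately not a separately vectorized path-sum — so a PSA
with every distribution degenerate equals the base case bitwise, and any
future change to rollback semantics propagates to the PSA automatically.
The 10,000-iteration default takes a few seconds on the bundled model.

CEAC tie rule: at each λ, iterations where several strategies share the
maximal NMB split the win equally, so probabilities sum to one exactly.
Prediction intervals are empirical quantiles with linear interpolation.

## One-way sensitivity analysis

The grid spans the parameter's declared range, endpoints included, with
the base value inserted if even spacing misses it — hence the base row
reproduces base-case rollback bitwise. Default ranges where none are
declared: Wilson 95% intervals for count-based probabilities, ±50% for
other probabilities, ±25% for costs. For members of a joint branch set the
upper end is additionally capped so the node's complement branch stays
non-negative while siblings sit at base. Because rollback is multilinear,
a terminal-cost parameter moves a strategy's expected cost along a line
whose slope is the coefficient-weighted probability of the paths that
reference it; the tests verify this against path enumeration. Tornado
bars rank parameters by the span of a chosen outcome (default:
incremental NMB at the model's threshold) with the parameter name as
tie-break, so the ranking is invariant to target order. A deterministic
base-case ICER does not vary with λ; the WTP sweep therefore reports NMB
and the decision per λ, with the (λ-independent) ICER alongside.

## Bias-corrected bootstrap

`bc_bootstrap` implements the BC percentile interval: B resamples with
replacement at size n, z₀ = Φ⁻¹(#{θ*_b < θ̂}/B) (clipped to
(1/(B+1), B/(B+1)) to avoid infinities; set to 0 with a warning on
constant data), endpoints at the adjusted percentiles Φ(2z₀ + z_{(1∓level)/2}).
The default is BC, matching the stated method of the source analysis; the
accelerated BCa variant (jackknife acceleration
a = Σ(θ̄−θᵢ)³ / [6(Σ(θ̄−θᵢ)²)^{3/2}]) sits behind `accelerated=True`.
Forcing z₀ = 0 reproduces the plain percentile interval exactly, which
the tests use as a decomposition check. `cost_component_cis` resamples
within arm (the arms are independent trial groups) and spawns one child
seed per (arm, category) from a `SeedSequence`, so the whole table is
reproducible from a single seed. Empirical coverage of the mean on
right-skewed gamma(2) data (n=100, B=2000, 500 replications) lands in
[0.92, 0.975].

## Synthetic cohorts

The generator emulates the two-arm trial structure the analysis assumes:
exact arm sizes (113/111 by default), Bernoulli second punctures,
a multinomial complication draw, a conditional resolution draw, gamma
per-category costs (CV 0.3) drawn conditional on the pathway — the
catheter category's mean scales with the number of catheters actually
placed (1 + second puncture + removal), and complication-treatment costs
are exactly zero for complication-free patients — and per-state QALY
accrual. `calibrate_costs` solves the residual category mean so the
analytic expected per-patient total equals a target to the cent; the
default configuration is read off the calibrated model, so cohort
expectations and tree base-case costs agree to numerical precision.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: within-patient correlation between cost
categories beyond pathway conditioning, censoring and varying catheter
dwell times, heavy-tailed cost outliers beyond the gamma family,
covariates (age, diagnosis) and any treatment-effect heterogeneity, and
QALY variation within a health state (utilities are deterministic per
state). Bootstrap and estimation behaviour on real trial records may
differ accordingly.

## Numerical choices and problem sizes

- Branch-probability sums are accepted within 1e-9; rollback re-checks
  validity at every evaluated parameter vector and refuses invalid ones.
- Reported currency rounds half-away-from-zero at 2 decimals.
- Dominance frontier: sort by effect (ties by cost, then name), drop
  strictly dominated, then iteratively remove members that break ICER
  monotonicity (extended dominance); adjacent frontier members carry the
  pairwise ICERs.
- Default analysis sizes — 10,000 PSA iterations and 10,000 bootstrap
  resamples — match the source analysis; the test-suite's simulation
  studies use 200 random trees for the rollback oracle, 500 replications
  for bootstrap coverage and 200 replications at 10⁵ patients per arm for
  probability recovery, sizes at which the checked tolerances (3 standard
  errors; Wilson coverage ≥ 95%) are statistically meaningful while the
  whole suite runs in well under a minute.

## Known limitations

- No Markov / state-transition extension: the 90-day decision tree is the
  whole model; longer-horizon catheter economics would need a cohort
  model this package does not provide.
- No EVPI/EVPPI, two-way scenarios, discounting, equity weighting or
  budget-impact analysis.
- Parameter correlation is limited to the joint Dirichlet branch blocks;
  no general copulas.
- The fixture's unpublished quantities are assumptions; conclusions that
  depend on them (e.g. the split of the cost saving across categories)
  inherit that uncertainty even though the calibrated totals are exact.
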