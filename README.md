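# treecea

Decision-tree cost-effectiveness analysis for health-economic evaluation,
with a bundled, runnable case study comparing chlorhexidine-coated (AGBA)
and standard peripherally inserted central catheters (PICCs) in a
haematology population over a 90-day horizon.

## Who this is for

Health economists and analysts who want a scriptable, fully reproducible
alternative to GUI decision-tree software for catheter-complication (or
any small decision-tree) models: declarative JSON model files in, expected
values, ICERs, sensitivity analyses and publication-ready tables out, every
stochastic step reproducible from a single seed.

## The model

A decision tree assigns each strategy *s* a set of root-to-leaf paths *j*
with probabilities `p_j` (products of chance-node branch probabilities) and
terminal payoffs `(C_j, E_j)` — a sum of per-category costs in RMB and a
per-state utility in QALYs. Expected-value rollback computes

    C_s = Σ_j p_j C_j,    E_s = Σ_j p_j E_j.

Two strategies are compared by the incremental cost-effectiveness ratio
ICER = ΔC/ΔE and the net monetary benefit NMB = λ·E − C at a
willingness-to-pay threshold λ; an intervention is cost-effective at λ iff
its incremental NMB λ·ΔE − ΔC is positive (for ΔE > 0 this is ICER < λ).
A strategy that is cheaper *and* more effective is dominant, and no bare
negative ratio is reported for it. On top of the deterministic model the
package provides:

- **PSA** — probabilistic sensitivity analysis: beta/gamma/Dirichlet
  parameter uncertainty propagated through the tree 10,000 times
  (multinomial branch sets drawn jointly on the simplex), summarized as a
  cost-effectiveness plane, acceptability curve (CEAC) and prediction
  intervals;
- **OWSA** — one-way sensitivity analysis, WTP sweeps, tornado tables;
- **BC bootstrap** — bias-corrected (optionally BCa) bootstrap confidence
  intervals for per-arm, per-category mean costs from patient-level tables,
  10,000 resamples by default;
- **synthetic cohorts** — a generator for two-arm patient-level trial data
  (binomial/multinomial events, gamma costs, per-state QALYs) calibrated so
  arm mean totals hit stated targets exactly.

## The bundled PICC case study

`fixtures/picc_agba_vs_standard.json` models the published two-arm trial:
113 AGBA vs 111 standard PICC patients; second punctures 1 vs 3; CLABSI
0 vs 3 (the zero cell uses the Jeffreys estimate (x+½)/(n+1) so beta/
Dirichlet uncertainty stays proper); 36 unknown-fever cases pooled across
arms because the per-arm split was not published. Each arm runs through
first/second-puncture, complication (none / CLABSI / unknown fever /
local) and resolution (resolved without removal / resolved with removal /
worsened) chance nodes. Per-category cost levels and utility decrements
that the source publication does not itemize are package defaults flagged
as assumptions in the model metadata, and one residual cost category plus
the utility level per arm are **calibrated** so base-case rollback
reproduces the published per-patient means — the metadata labels this a
check of fixture construction, not independent validation.

## Worked example

```
$ treecea cea
AGBA PICC: cost 19696.23 RMB (USD 2904.92), effect 0.7300 QALY
standard PICC: cost 21987.32 RMB (USD 3242.82), effect 0.6800 QALY
delta cost -2291.09 RMB, delta effect 0.0500 QALY, ICER dominant, incremental NMB 7947.09 RMB
report: results/summary.md
```

Reading: the coated catheter saves 2291.09 RMB per patient (USD at the
study's exchange rate RMB 678.03 = USD 100) while gaining 0.05 QALYs, so
it *dominates* the standard catheter — no ICER is quoted because the
ratio's sign is meaningless when one option is both cheaper and more
effective; at the threshold λ = 113,120 RMB/QALY (1.76 × GDP per capita)
the incremental NMB is 7947.09 RMB per patient. The written report also
surfaces the source publication's own printed incremental figures
verbatim, including an ICER (4271.31 RMB/QALY) and a USD saving (428.44)
that are not the arithmetic of its own printed means (2291.10/0.05 =
45,822.00; 2291.10 RMB = USD 337.91): both sets are shown, neither is
altered.

The full pipeline (base case, PSA + CEAC, tornado, WTP sweep, synthetic
cohort, bootstrap cost intervals, run manifest) in one command:

```
$ treecea run --seed 7 --iterations 10000 --bootstrap-b 10000 --out results
```

Library use mirrors the CLI:

```python
import treecea as tc

model = tc.read_model(tc.fixture_path())
outcomes = tc.rollback(model.tree, model.params.base_values())
inc = tc.incremental(outcomes[0], outcomes[1], model.wtp)
cloud = tc.run_psa(model.tree, model.params, 10_000, seed=7)
curve = tc.ceac(cloud, [model.wtp.lambda_rmb_per_qaly])
```

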