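# Methods

This note documents the statistical model, the decision machinery, the
synthetic data-generating process, and the numerical and design choices made
where the problem left room for interpretation.

## Endpoint model and final-analysis decisions

The endpoint is binary response. With `r` responses among `n` patients and a
Jeffreys prior, the response rate posterior is
`p | data ~ Beta(0.5 + r, 0.5 + n − r)`. Final decisions use the
dual-criterion framework with four parameters:

| parameter | meaning | default |
|---|---|---|
| `TV` | target value — desired response rate | 0.15 |
| `LRV` | lower reference value — minimal acceptable rate | 0.05 |
| `alpha_TV` | No-Go when `P(p > TV) ≤ alpha_TV` | 0.10 |
| `alpha_LRV` | Go when `P(p > LRV) ≥ alpha_LRV` | 0.80 |

The No-Go condition is evaluated first. Because `TV > LRV`, both tail
conditions can hold simultaneously for extreme configurations of the α
levels; stopping then wins, which is the conservative reading of a rule list
that names the stop first. With the default α levels this corner never
arises. Boundary ties follow the printed inequality directions (`≤`, `≥`)
exactly. All tail probabilities use the regularized incomplete beta function
(`scipy.stats.beta.sf`), so decision boundaries are deterministic; no Monte
Carlo enters any individual decision.

## Predictive probability of success (PrGo)

At an interim with `r` of `n` patients observed and `m = N − n` to come, the
future response count is beta-binomial under the posterior, and

    PrGo(r, n, N) = Σ_{r'=0}^{m} 1[ P(p > LRV | Beta(0.5+r+r', 0.5+N−r−r')) ≥ alpha_LRV ] · BetaBin(r'; m, 0.5+r, 0.5+n−r).

Only the Go criterion enters the success indicator. At `n = N` the sum
collapses to the indicator of the Go criterion on the current data. The
predictive mass function is computed in log space (gammaln/betaln) and
renormalized; normalization holds to 1e-12. PrGo values are memoized over
the integer grid `(r, n, N)` per criteria, which keeps 5000-replicate
simulations fast (the motivating design touches only a few hundred distinct
states).

In the source formula for the full-population predictive weights the prior
offsets are typeset inconsistently between the two stages' expressions; the
standard Jeffreys beta-binomial predictive is used throughout, which is the
only reading that makes full-population and enriched-stage predictions
comparable.

## Biomarker cutoff estimation and declaration

Candidate cutoffs are midpoints between consecutive *distinct* order
statistics of the biomarker, so `{x > c}` versus `{x ≤ c}` is never
ambiguous at an observed value. For each candidate the fitted step is the
pair of subgroup response means and the criterion is the residual sum of
squares; the minimizing candidate wins, with ties broken toward the smallest
cutoff (largest biomarker-positive group). The fit is *unconstrained*; the
requirement that at least a fraction `pp` of the sample lie above the cutoff
is applied afterwards to the winning split, and a violating optimum means no
admissible cutoff (not the runner-up split). This post-hoc reading matters:
with few responders the global optimum frequently isolates one or two
extreme patients, and rejecting those fits — rather than substituting a
larger-group candidate — is what produces the strong dependence of
declaration frequencies on `pp` seen in the rule-comparison grid.

The probability-based declaration computes
`P(p1 − p0 > diffthr | data) > pthr` with independent improper-prior
posteriors `p1 ~ Beta(r1, n1 − r1)`, `p0 ~ Beta(r0, n0 − r0)`. The nested
phrasing of this criterion ("probability that the probability exceeds") is
not computable as written; the implemented form follows its plain-language
gloss — being `pthr`-certain of a `diffthr` difference in response rates.
Boundary counts give degenerate posteriors, taken as the ε → 0 limit of
`Beta(ε, ·)` / `Beta(·, ε)`: point masses at 0 (no responders) or 1 (all
responders). The probability is evaluated by adaptive quadrature of the
`p1` survival function against the `p0` density (absolute error well below
1e-6, the proper shapes are integers ≥ 1 so the integrand is smooth) and
memoized over the count grid. A 10⁶-draw Monte-Carlo estimator of the same
probability is kept in the test suite as an independent oracle.

Two comparator rules are provided: *naive with step* (fit the step, declare
if the response rate above the fitted cutoff reaches `min_resp_rate`, 15% by
default, i.e. `r⁺ ≥ ⌈0.15 n⁺⌉`) and *naive* (declare if any upper biomarker
tail holding at least `pp` of the sample has that many responses — the
published description of this rule is ambiguous, and this implementation is
one documented reading; it is excluded from quantitative validation).
`pthr = 1` is accepted and never declares, giving a clean "rule off"
configuration whose decisions coincide with the original design.

## Two-stage designs

**Original design** (futility stop only): continue to stage 2 with the full
population iff `PrGo ≥ η_f`, else stop.

**Biomarker-guided design**: attempt declaration first. Without a declared
cutoff, behave as the original design. With one: continue full iff
`PrGo ≥ η_fc`; else enrich iff `PrGo⁺ ≥ η_+`, where `PrGo⁺` is the
predictive probability computed on the biomarker-positive subgroup
(`r⁺` of `n⁺` patients) with enriched final sample size
`N_+ = n_+ + (N_f − n_f)`; else stop. Defaults `η_f = 0.1`, `η_fc = 0.9`,
`η_+ = 0.75` are the calibrated operating point of the motivating trial;
with `η_f = 0.1` the no-cutoff path continues iff at least one response is
observed among the first 14 patients (PrGo rises from 0.037 at r = 0 to
0.35 at r = 1).

`N_+` is not defined numerically in the source material; the convention here
preserves the stage-2 cohort size (all stage-2 recruits are screened
biomarker-positive) and carries the stage-1 biomarker-positive patients into
the final analysis, which is the only reading consistent with the enriched
predictive sum running over `N_+ − n_+` future patients. Stops with and
without a declared cutoff are tracked as distinct interim labels but are
equally terminal.

The final analysis applies the same Go/No-Go/Consider criteria to the pooled
analysis population — all `N_f` patients on the full path, the `N_+`
biomarker-positive patients on the enriched path. `decision_boundaries`
converts the thresholds into observed-response tables (minimal continuing
response count at interim, per-split interim labels, Go/No-Go boundaries at
each final-analysis size).

## Synthetic data generator

The generator emulates the trial's assumed population: biomarker
`X ~ N(3.46, 1.3)` by default (gamma available for skewness sensitivity
work, parameterized by shape and rate with helpers matching a target mean or
variance), and a step response curve — response probability `p1` above the
true cutoff `c`, `p0` at or below it — with `c` the exact analytic
`(1 − q_plus)` quantile of the biomarker distribution, so the
biomarker-positive prevalence is `q_plus` by construction. The nine standard
scenarios cross null (`p0 = p1` at 15%, 5%, 0%) and predictive
(`p1 > p0`) effects with prevalences of 50% and 30%.

During enriched recruitment, stage-2 biomarkers are drawn from the scenario
distribution truncated above the *declared* cutoff (inverse-CDF sampling),
while responses are still governed by the *true* step function — a declared
cutoff below the truth yields a mixed-response enriched cohort, as it would
in practice. Patients screened out during enrichment are not counted in the
recruited total, matching an expected-sample-size definition based on
patients actually enrolled.

What the generator does not emulate: prognostic (treatment-independent)
biomarker effects, smooth dose-response-like biomarker relationships,
measurement error in the biomarker assay, accrual dynamics, or dropout.
Passing simulation checks therefore validate the decision machinery under
the step-model idealization, not robustness of the design to model
misspecification in real data (the gamma option probes distributional
shape only).

## Monte-Carlo engine and reproducibility

Each replicate runs on an independent PCG64 substream spawned from one
master seed (`numpy.random.SeedSequence.spawn`), so results are
bit-reproducible for a given seed and replicate decisions are exchangeable
across designs sharing the seed — the basis of the replicate-by-replicate
equivalence check between the original design and a biomarker design whose
rule never declares. The default replicate count is 5000. Aggregates
reported per scenario: interim decision frequencies, pooled end-of-trial
Go / No-Go-or-futility / Consider frequencies (interim stops pooled with
final No-Go), per-population final-analysis frequencies conditional on
reaching it, declaration probability, expected sample size with quartiles,
and the late-declaration fraction (trials continuing full whose pooled
final cohort declares a cutoff although the interim did not).

The cutoff-estimate summaries (mean, 25th, 75th percentiles) describe the
least-squares fitted cutoff over all replicates where a step exists (at
least one responder and one non-responder), not the declared subset: the
declared subset is selection-biased toward high cutoffs (declarations favor
splits isolating responders), whereas the fitted-cutoff distribution is the
natural description of the estimator, centering near the biomarker median
under null scenarios and above it under predictive ones. All-zero-response
scenarios have no fittable step and report no cutoff summary.

Threshold calibration (`calibrate_thresholds`) grids `(η_fc, η_+)` and
reports overall Go and enrichment probabilities per scenario, flagging pairs
that keep overall Go above a floor under alternative scenarios and below a
ceiling under a null; floor and ceiling are caller-supplied since acceptable
risk levels are trial-specific.

## Known limitations

- The enriched-stage sample-size convention (`N_+`) is one defensible
  reading; expected-sample-size values are reported under it and depend
  on it.
- The naive comparator rule is a documented interpretation of an ambiguous
  description and should not be used for quantitative claims.
- Declaration probabilities inherit the step-fit's small-sample behavior;
  with 14 patients the fitted cutoff is highly variable (interquartile
  ranges of roughly ±0.6 biomarker SD even under predictive scenarios).
- Single-arm only: the design cannot distinguish predictive from prognostic
  biomarker effects; it presumes the prognostic question was settled before
  the trial.
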