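# Methods

This note documents the models, conventions and design choices behind
`fbdrank`, in the order the pipeline runs them.

## Scoping

The hazard registry carries the candidate universe with two boolean flags
that drive the scoping screen: `foodborne` (agents with no evidence of
foodborne transmission are excluded) and `is_toxin_producer_only` (agents
excluded because the toxin they produce is already a listed hazard in its
own right). Encoding the exclusions as data rather than hard-coded names
lets the same screen run on any country's candidate list. The screen
preserves order, partitions its input exactly, and is idempotent on its
retained output. The packaged Ethiopia registry holds 39 candidates — 24
FERG hazards, 4 metals, 9 stakeholder nominations retained, plus the two
screened-out candidates.

## Elicited quantities and uncertainty propagation

Every uncertain input is an elicited triple (best, lower95, upper95).

* **Lognormal (count-like inputs).** The fit is median-preserving:
  mu = ln(best). The spread is the least-squares compromise over the two
  log-bound residuals, which reduces to the closed form
  sigma = (ln upper − ln lower) / (2 z₀.₉₇₅). For log-symmetric triples
  (best = √(lower·upper)) the fitted 2.5% and 97.5% quantiles equal the
  elicited bounds exactly; otherwise the median stays pinned to the best
  estimate and the bounds are compromised symmetrically in log space.
* **Beta (proportions).** Two parameters cannot in general match three
  elicited quantiles, so (a, b) minimize the squared residuals of the
  2.5%, 50% and 97.5% quantiles simultaneously (scipy `least_squares` in
  log-parameter space, method-of-moments initialization).
* **Point mass.** A degenerate interval (lower95 = upper95), which covers
  elicited certainties such as a zero mortality entry.
* **Zero bounds.** A zero lower bound with a positive upper bound is
  replaced by upper95 × 10⁻⁶ before log-fitting — far enough below the
  interval to leave the fitted quantiles visibly unchanged while keeping
  the support positive. A zero best estimate with a positive upper bound
  (not covered by that rule) falls back to the geometric mean of the
  adjusted bounds for the median.

Propagation is by Monte Carlo: each named input is sampled independently
on its own seeded substream (numpy `SeedSequence` children of the root
seed, assigned in sorted name order), the transform is applied draw-wise,
and the result is summarized. Defaults: n = 10⁵ draws; seed 20100101
(a mnemonic for the 2010 reference year). Independence across inputs is a
modelling assumption, tested via variance additivity of sums. Summaries
are the arithmetic mean and the 2.5th/97.5th percentiles under the
linear-interpolation quantile convention (numpy default) — pinned because
bit-reproducible outputs are a pipeline contract.

Monte Carlo quantile noise bounds what interval checks can promise: at
2 × 10⁵ draws the empirical 2.5th percentile of a lognormal with log-sd
1.2 (an elicited spread of one order of magnitude each side of the best
estimate) already carries about 1% relative standard error, growing with
the spread. Validation of the fit→sample→summarize round trip therefore
uses spreads up to a factor 10 per side; wider triples are checked against
the fitted analytic quantiles, which are exact for representable triples
at any spread.

## Burden metrics

Four metrics per hazard, per 100,000 population, from a joint Monte Carlo
over cases, deaths, disability weight, duration and residual life
expectancy: incidence rate, mortality rate, case-fatality ratio (percent),
and DALY rate with its YLL and YLD components. Conventions:

* DALYs carry no age-weighting and no time-discounting.
* YLD for fatal cases is not subtracted; deaths also contribute cases — a
  documented simplification that slightly raises YLD for high-fatality
  hazards.
* One aggregate outcome per hazard; the input reader sums multiple outcome
  rows per hazard so outcome trees can be represented upstream.
* Coherence (deaths ≤ cases) is enforced by rejection sampling, because
  independently elicited inputs can produce incoherent joint draws.
  Rejections are counted, warned above 1% of draws, and treated as a model
  inconsistency above 50% (the elicitation, not the sampler, is then at
  fault). The case-fatality ratio on a zero-case draw is defined as 0,
  which coherence forces anyway.

Metric redundancy is assessed by pairwise Spearman rank correlation on the
hazards × metrics table; pairs at or above the threshold (default 0.9) are
flagged and the more aggregated metric retained under the precedence
DALY > YLL > YLD > mortality > incidence > case-fatality. This is the
mechanism by which a YLL column that tracks mortality is dropped as
redundant. Constant columns have undefined rank correlation and are
skipped with a warning.

## Consensus ranking

Groups rank every scoped hazard High/Medium/Low in two rounds. Resolution
proceeds: round-1 unanimity → round-2 unanimity on the remainder →
escalation → settlement, and every hazard records where it resolved
(`round1`, `round2`, `plenary`, `mode`). Two rules the source procedure
leaves open are made explicit and configurable:

* **Low/Medium settlement.** Disagreements with no High vote are settled
  at the modal category of the last round; a Low/Medium tie settles Medium
  (the conservative choice). Mode-settled hazards can never end High.
* **Plenary tie.** The plenary vote resolves by majority; ties break
  toward the higher category — a public-health-protective default.

The ordinal driver analysis fits a proportional-odds (cumulative logit)
model of the final category on the burden metrics. Because the metrics
span about eight orders of magnitude, each predictor is transformed
log₁₀(x + ε) — ε being the column's smallest positive value × 10⁻³ — then
standardized. Perfectly collinear predictors (|r| > 0.9999) are reduced to
one with a warning. Maximum likelihood (statsmodels `OrderedModel`, BFGS)
is the primary fit; if it fails to converge or separates (any
|coefficient| > 20 on standardized predictors), a ridge-penalized ordered
logit (penalty λ = 1 on slopes only, cutpoints parametrized as ordered
gaps, scipy BFGS) takes over and the result is flagged as a penalized fit.
Separation is expected, not exceptional: rankings produced by thresholding
one metric are perfectly separable in that metric.

## Attribution

Delphi responses are normalized to the simplex per expert × hazard;
round-2 answers replace that expert's round-1 answers hazard-wise; the
aggregate is the arithmetic mean across experts, renormalized. The mean
(rather than median) is the default because it commutes with the
subsequent multiplication into death counts, keeping attribution additive;
the median is available. A study-team literature estimate can enter as a
pseudo-expert with configurable weight (default 1.0, one
expert-equivalent). Single-route hazards are forced to their fixed food
group after aggregation, overriding elicitation; rarely-consumed food
groups can be dropped with row renormalization (a row losing all its mass
is an error, not a silent zero). Deaths are attributed proportionally to
the case attribution — an explicit assumption of the method — and
conservation (row sums equal per-hazard totals) is enforced to 10⁻⁹
relative. Attribution uncertainty is outside the core path; an optional
bootstrap over experts (resampling experts with replacement, default 1000
replicates) yields percentile bands.

## Prioritization

Food-group × ecology-category death tables are merged onto value chains by
element-wise summation over member groups (e.g. eggs into poultry), the
top-k chains by total deaths are selected (stable order on ties), and each
category's chain deaths are distributed over the chain's SCCPs
proportionally to elicited points. Point allocations are elicited per
(SCCP, category); a single weight per SCCP is replicated across categories
at parse time. Points may be non-integer; normalization makes their scale
irrelevant, and a category with positive deaths but zero total points is
an error naming the category. The chain → stage → SCCP → category
hierarchy serializes as nested name/value/children JSON with every
internal node equal to the sum of its children.

The packaged Ethiopia chains reproduce the published SCCP counts
(vegetables 7, dairy 10, poultry/eggs 20, beef/small-ruminant 10) with
descriptions from the study narrative, but the point values themselves
were not published: the fixture weights are illustrative, and no validated
quantity depends on them beyond conservation.

## Synthetic scenarios

The generators produce inputs with the statistical structure each stage
assumes, with known truth, so the pipeline supports parameter-recovery
experiments without any external data:

* **Burden panels.** True incidence rates log-uniform on [10⁻³, 10³] per
  100,000 (the span of real burden tables); case-fatality fractions
  log-uniform on [10⁻⁴, 10⁻¹]; elicited triples (truth/f, truth, truth·f)
  with f uniform on the spread interval (default 2–8) — log-symmetric,
  hence exactly representable by the lognormal fit. f = 1 yields point
  masses, which make downstream recovery exact.
* **Delphi panels.** Expert rows ~ Dirichlet(concentration × truth row),
  default 15 experts at concentration 100 with 3 round-2 revisers at four
  times the concentration, mirroring the case study's panel. Infinite
  concentration returns the truth (noise-free panel). Zero-truth food
  groups stay exactly zero.
* **Group rankings.** Each group thresholds its assigned metric against
  the true cutpoints, with optional neighbor-flip label noise. Zero-noise
  recovery requires all groups to threshold the metric that generated the
  truth; assigning different metrics to different groups is itself the
  mechanism that produces realistic disagreement.
* **SCCP scenarios.** Random chains and allocations ship with expected
  preventable deaths computed by an independent plain-loop oracle that
  shares no code with the production implementation.

What the generators deliberately do **not** emulate: correlation between
hazards' burdens, expert bias or miscalibration (Dirichlet noise is
centered on truth), strategic voting, and within-chain heterogeneity of
food products. Passing recovery tests therefore demonstrates the
machinery is correct and calibrated under the stated noise models, not
that real workshop data are free of those complications.

## Pipeline and reproducibility

All stage randomness derives from the single config seed via named
substreams; reruns of one configuration are byte-identical (tested). Every
output CSV/JSON carries a 12-hex-digit SHA-256 hash of the canonical
configuration. CSV dialect: UTF-8, comma, header row, "." decimals, `#`
comment lines. CLI exit codes: 0 success, 2 validation failure, 1 runtime
error.

Default problem sizes — 10⁵ draws for burden intervals (10⁴ in the
packaged run config), 50 seeds for driver-recovery experiments, 20 seeds
for Delphi recovery curves, 100 random instances for conservation suites —
were chosen so each validation answers its statistical question with
comfortable margin while the whole suite stays quick to iterate on.

## Known limitations

* The four selected metrics are implemented; the source material also
  mentions a larger metric count for non-FERG hazards whose composition is
  not recoverable, so no attempt is made to guess the remainder.
* The published per-hazard burden table is packaged as validated output,
  not recomputed: the elicited inputs behind it (disability weights,
  durations, life expectancies, outcome trees) were never published.
* The per-hazard × food-group death decomposition in the packaged
  attribution fixture is synthetic; only its category-level aggregates are
  published values.
* Expert weighting/calibration (e.g. Cooke's classical model), correlated
  joint elicitation, and second-order uncertainty separation are out of
  scope.
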