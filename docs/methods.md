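# Methods

## Model structure and assumptions

A population of couples is characterised by a single fertility parameter
λ, the mean number of children per couple. Family size is Poisson,
N ~ Poisson(λ), which is the maximum-entropy choice given only the mean and
keeps every aggregate in closed form. Conditional on N, birth sexes are
independent Bernoulli draws, girl with probability p. Son preference enters
only through a deterministic intervention rule applied to a family's birth
history:

* **Universal threshold n.** A family with N ≥ n children whose first n−1
  births were all girls forces birth n male. The intervention probability
  for any such family is p^{n−1}, independent of N.
* **Stopping rule with minimum threshold n.** A family with N ≥ n children
  whose first N−1 births were all girls forces its *last* birth male
  (probability p^{N−1}). This encodes parity progression driven by son
  preference: couples keep going while sonless and stop after a son, so an
  intervention, if any, happens at the final birth. A family of size
  exactly n = 1 intervenes at its only birth (its "first zero births" are
  vacuously all girls); this keeps the threshold-1 limit identical to the
  universal rule's φ = 1 − e^{−λ}.

The default intervention mechanism is preconception ("IVF-like"): the
designated birth simply arrives male. Each couple intervenes at most once.
The intervention converts a birth that would otherwise have been a girl
with probability p, so per intervening couple the expected number of
sex-converted births is p. Writing φ for the intervening fraction among
*all* couples (childless included),

    E[boys]  = λ(1−p) + pφ,
    E[girls] = λp − pφ,

total expected births are conserved at λ. The sex ratio at birth is stored
internally as the proportion of male births R = E[boys]/λ and presented as
boys per 100 girls (or girls per 1000 boys); the representations are
algebraically interchangeable.

Closed forms for φ:

* universal: φ = p^{n−1} · P(N ≥ n);
* stopping rule: φ = (1/p) Σ_{N≥n} Pois(N; λ) p^N
  = (1/p) e^{λ(p−1)} · P(Poisson(λp) ≥ n).

The second identity replaces the partial exponential sum
e^{λp} − Σ_{k<n} (λp)^k/k! by the Poisson survival function (a regularized
incomplete gamma), which is numerically stable for λp well beyond 10;
naive subtraction loses all precision once the partial sum approaches
e^{λp}. Poisson tails for the universal rule likewise use the survival
function rather than 1 − CDF.

The parents-only intervening fraction is Ψ = φ/(1 − e^{−λ}), reported
separately because at low fertility the growing childless share mechanically
depresses φ.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| p | natural probability of a female birth | 0.486 | matches the conventional benchmark p/(1−p) ≈ 0.946, i.e. ≈946 girls per 1000 boys (105.8 boys per 100 girls); overridable everywhere. Applied propensity estimates shift slightly with the benchmark chosen, so output tables record the p used. |
| λ | mean children per couple | — | in applied work the period total fertility rate is used directly as λ; this is a completed-family-size proxy and an acknowledged approximation. |
| n | intervention threshold (birth order / minimum family size) | — | integer ≥ 1; equivalently the "acceptable proportion of female births", APFB = 100 − 100/n percent. |

## Inversion

Solving the balance equations for φ at an observed sex ratio r =
(boys per 100 girls)/100 and fertility λ gives

    φ = λ (p·r − (1−p)) / (p (1 + r)),

the unique propensity consistent with the forward accounting — for the
stopping rule this holds for every threshold n, so the estimate is an
*effective* population propensity requiring no committed n. Its exact
inverse, r(φ, λ), shows the disproportionality effect: at fixed φ > 0 the
SRB rises as λ falls, because the same pφ converted births sit in a smaller
denominator. Observed ratios at or below the natural benchmark yield φ = 0
with the signed raw solution retained for diagnostics (the model contains
no female-favouring intervention); implied φ > 1 is flagged implausible.
Batch estimation fits an ordinary-least-squares line of φ on the SRB across
plausible records (implausible rows are excluded from the fit but retained,
flagged, in the output) so that regions above/below the mean φ-given-SRB
relationship can be read off the residuals.

## Peak finding

Both R(λ) and φ(λ) have interior maxima in λ for most rules. The maximizer
evaluates the closed form on a coarse grid (step 0.05 on (0, λ_hi], default
λ_hi = 20), then refines the bracketing interval by bounded scalar
maximization (golden-section/Brent) to absolute λ-tolerance 1e−4. If the
grid argmax falls on either end of the interval the quantity is treated as
monotone there and the boundary point is returned with a
`PeakBoundaryWarning` (e.g. the universal-rule φ = 1 − e^{−λ}, which is
increasing, or the universal-rule SRB at n = 1, which diverges as λ → 0).

A numerical caveat: the stopping-rule SRB maximum is extremely flat — for
n = 2, p = 0.486 the curve stays within 0.05 boys-per-100-girls of its
maximum over roughly λ ∈ [1.14, 1.29]. The peak *value* is therefore robust
to several decimals while the peak *location* is ill-conditioned; the
optimizer resolves it to the stated λ-tolerance, but readers comparing
locations produced by other software at coarser tolerance should expect
discrepancies of order 0.02 in λ with essentially identical peak values.

## Monte Carlo simulator

The simulator draws, per couple, N from Poisson(λ), then the natural sex of
every birth (a couples × max(N) matrix of Bernoulli(p) draws), applies the
intervention rule to the realized history, and aggregates. Draw order is
fixed — family sizes first, then the birth matrix, then (abortion
mechanism only) the geometric re-conception counts — so identical inputs
and seed give a bit-identical result; reproducing aggregates, not bit
streams, is the cross-implementation contract. Standard errors:

* φ̂: binomial, sqrt(φ̂(1−φ̂)/n_couples);
* SRB = 100·B/G: delta method over i.i.d. per-couple counts,
  Var(B/G) ≈ (var(b) − 2(B/G)cov(b,g) + (B/G)²var(g)) / (n · mean(g)²).

Under the abortion mechanism, only intervening couples whose designated
conception is female (probability p) abort and re-conceive until a male
fetus: abortions per intervening couple are geometric with mean p/(1−p) and
variance p/(1−p)², so the expected abortion total is p/(1−p) ≈ 0.95 per
preconception-style intervention — a similar, not identical, count. Birth
outcomes are unchanged in distribution (and, for the same seed, in
realization).

## Synthetic observation tables

`generate_observation_table` emulates national/state series of (label,
period, TFR, SRB). Deterministic mode writes closed-form SRBs — useful for
exact round-trip tests; noisy mode simulates a finite cohort per row
(default 10⁵ couples, a realistic state-level birth registry scale) and
records the Monte Carlo SE of each SRB so recovered propensities can be
judged against propagated sampling error (dφ/dr = λ/(p(1+r)²)). Scenarios
specify either a fixed φ (couples with children intervene independently at
their last birth with probability Ψ = φ/(1−e^{−λ})) or a stopping-rule
threshold n. What the generator does *not* emulate: heterogeneity in p or
in preference strength, time trends within a period, migration,
birth-registration error, and TFR ≠ completed family size. Passing recovery
tests therefore demonstrates the estimator's self-consistency and its
behaviour under pure sampling noise, not robustness to real-data
mis-specification.

## Design choices

* SRB units are never inferred from magnitudes: file and API inputs declare
  boys-per-100-girls vs proportion-male explicitly, because a silent
  1.06/106 confusion would corrupt every estimate by a factor ~100.
* Period strings are opaque labels (single years and multi-year averages
  coexist in source tables); no date parsing.
* Degenerate regimes (implied E[girls] ≤ 0, possible when a user holds φ
  fixed at tiny λ) return flagged +inf ratios rather than raising, so λ
  scans can cross them.
* Explicit summations, where used at all (test oracles), truncate when the
  remaining Poisson tail bound is below 1e−12; library code uses the
  survival-function closed forms instead.

## Limitations

* Φ is an effective propensity: a mixture of a son-preferring fraction with
  heterogeneous thresholds is summarised by a single number.
* No sampling-uncertainty intervals on Φ from observed SRB denominators are
  produced (the delta-method machinery exists in the simulator and could be
  attached to observed birth counts when available).
* TFR-as-λ is a period/cohort approximation; rapidly changing fertility
  biases it.
* The model conserves family size under intervention; behavioural responses
  of family size to the intervention itself (e.g. stopping earlier because
  a son was ensured) are outside scope, except as already encoded by the
  stopping rule.
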